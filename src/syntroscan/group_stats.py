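"""Per-category two-group comparisons of normalized abundance scores.

For each (by default syntroph-associated) category, the mean normalized
score of the syntrophic group is compared with the non-syntrophic group
using a two-sided Welch (unequal-variance) t-test with Welch-Satterthwaite
degrees of freedom; Student's pooled-variance test is available by flag.
No multiple-testing correction is applied by default, matching the
per-category reporting convention; Bonferroni and Benjamini-Hochberg
adjustments are optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import (
    AbundanceMatrix,
    NON_SYNTROPHIC_GROUP,
    SYNTROPHIC_GROUP,
)

_TIE_EPS = 1e-15


@dataclass
class CategoryComparison:
    category: str
    division: str
    mean_syn: float
    mean_non: float
    t_stat: float
    df: float
    p_value: float
    higher_in: str  # syntrophic | non_syntrophic | tie

    def to_record(self) -> dict:
        return {
            "category": self.category,
            "division": self.division,
            "mean_syn": self.mean_syn,
            "mean_non": self.mean_non,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "higher_in": self.higher_in,
        }


def two_sample_t(a, b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: returns (t, df, p).

    Welch by default: t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    with Welch-Satterthwaite df; p from the t distribution's survival
    function. ``equal_var=True`` gives Student's pooled-variance test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 samples (got {na} and {nb})")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    else:
        sea, seb = va / na, vb / nb
        denom = np.sqrt(sea + seb)
        if sea + seb == 0:
            df = float(na + nb - 2)
        else:
            df = float(
                (sea + seb) ** 2
                / (sea**2 / (na - 1) + seb**2 / (nb - 1))
            )
    if denom == 0:
        t = 0.0 if abs(diff) < _TIE_EPS else float(np.inf * np.sign(diff))
    else:
        t = float(diff / denom)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, min(1.0, p)


def _adjust(pvals: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return pvals
    m = pvals.size
    if method == "bonferroni":
        return np.minimum(1.0, pvals * m)
    if method == "bh":
        order = np.argsort(pvals)
        ranked = pvals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, adj)
        return out
    raise ValueError(f"unknown correction method: {method!r}")


def compare_categories(
    matrix: AbundanceMatrix,
    syn_labels: Iterable[str] = SYNTROPHIC_GROUP,
    non_labels: Iterable[str] = NON_SYNTROPHIC_GROUP,
    division: str | None = "syntroph",
    equal_var: bool = False,
    correction: str | None = None,
) -> list[CategoryComparison]:
    """Compare group mean scores per category.

    ``division="syntroph"`` (default) restricts to syntroph-associated
    categories; None compares all. Groups must be disjoint with at least
    two samples each.
    """
    syn_labels, non_labels = set(syn_labels), set(non_labels)
    if syn_labels & non_labels:
        raise ValueError("group label sets must be disjoint")
    syn_ids = matrix.samples_with_labels(syn_labels)
    non_ids = matrix.samples_with_labels(non_labels)
    if len(syn_ids) < 2 or len(non_ids) < 2:
        raise ValueError(
            f"each group needs >= 2 samples "
            f"(got {len(syn_ids)} syntrophic, {len(non_ids)} non-syntrophic)"
        )
    cats = [
        c for c in matrix.category_names
        if division is None or matrix.divisions[c] == division
    ]
    if not cats:
        raise ValueError("no categories selected for comparison")

    out: list[CategoryComparison] = []
    for c in cats:
        a = matrix.data.loc[syn_ids, c].to_numpy(dtype=float)
        b = matrix.data.loc[non_ids, c].to_numpy(dtype=float)
        t, df, p = two_sample_t(a, b, equal_var=equal_var)
        diff = a.mean() - b.mean()
        if abs(diff) < _TIE_EPS:
            higher = "tie"
        else:
            higher = "syntrophic" if diff > 0 else "non_syntrophic"
        out.append(
            CategoryComparison(
                category=c,
                division=matrix.divisions[c],
                mean_syn=float(a.mean()),
                mean_non=float(b.mean()),
                t_stat=t,
                df=df,
                p_value=p,
                higher_in=higher,
            )
        )
    if correction is not None:
        adj = _adjust(np.array([r.p_value for r in out]), correction)
        for r, q in zip(out, adj):
            r.p_value = float(q)
    return out


def comparisons_frame(results: Sequence[CategoryComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in results])


def abundance_long_table(matrix: AbundanceMatrix,
                         division: str | None = "syntroph") -> pd.DataFrame:
    """Lossless melt of the matrix: (sample_id, label, category, score).

    The long format backs surface/heatmap plots of per-category abundance
    across samples; pivoting it back reproduces the matrix exactly.
    """
    cats = [
        c for c in matrix.category_names
        if division is None or matrix.divisions[c] == division
    ]
    wide = matrix.data[cats].copy()
    wide.insert(0, "sample_id", wide.index)
    wide.insert(1, "label", matrix.labels.values)
    long = wide.melt(
        id_vars=["sample_id", "label"], var_name="category", value_name="score"
    )
    return long
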