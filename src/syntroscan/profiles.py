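"""Per-sample gene-family tallies and normalized category abundance scores.

The score of category *C* in sample *s* is

    score(s, C) = ( sum_{f in C} n_s(f) / |C| ) / G_s

where ``n_s(f)`` is the number of genes in sample *s* annotated with family
*f*, ``|C|`` the number of families in the category, and ``G_s`` the total
number of genes detected in the metagenome (assembled + unassembled when
the user supplies it). Dividing by ``|C|`` makes categories of different
sizes comparable; dividing by ``G_s`` normalizes against metagenome size,
so the score is invariant to sequencing depth when counts scale with it.

Families present in a count table but in no catalog category are ignored
for scoring yet still contribute to ``total_genes`` — the normalization is
against *all* detected genes, not just cataloged ones.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, Category

#: Canonical group labels.
SYNTROPHIC_CULTURE = "syntrophic_culture"
POTENTIALLY_SYNTROPHIC = "potentially_syntrophic"
NON_SYNTROPHIC = "non_syntrophic"
OTHER = "other"
LABELS = (SYNTROPHIC_CULTURE, POTENTIALLY_SYNTROPHIC, NON_SYNTROPHIC, OTHER)

#: Labels pooled into the "Syntrophic" ellipse group, and the complement.
SYNTROPHIC_GROUP = frozenset({SYNTROPHIC_CULTURE, POTENTIALLY_SYNTROPHIC})
NON_SYNTROPHIC_GROUP = frozenset({NON_SYNTROPHIC})

_LABEL_ALIASES = {
    "syntrophic culture": SYNTROPHIC_CULTURE,
    "syntrophic_culture": SYNTROPHIC_CULTURE,
    "potentially syntrophic": POTENTIALLY_SYNTROPHIC,
    "potentially_syntrophic": POTENTIALLY_SYNTROPHIC,
    "potentially syntrophic hydrocarbon": POTENTIALLY_SYNTROPHIC,
    "non-syntrophic": NON_SYNTROPHIC,
    "non_syntrophic": NON_SYNTROPHIC,
    "non-syntrophic hydrocarbon": NON_SYNTROPHIC,
    "other": OTHER,
}


def normalize_label(label: str) -> str:
    """Map a display classification (e.g. 'Non-Syntrophic Hydrocarbon') to
    one of the four canonical labels."""
    key = label.strip().lower().replace("environments", "").strip()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown classification label: {label!r}") from None


@dataclass
class SampleMetadata:
    """Group assignment for one sample."""

    sample_id: str
    label: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            self.label = normalize_label(self.label)
        if not self.display_name:
            self.display_name = self.sample_id


@dataclass
class FamilyCountTable:
    """Family -> gene-count map for one metagenome.

    ``total_genes`` is the total number of detected genes, which need not
    equal the sum of the family counts: a gene may lack any family, or
    carry a family outside the catalog.
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_genes: int = 1

    def __post_init__(self) -> None:
        if self.total_genes < 1:
            raise ValueError(
                f"{self.sample_id}: total_genes must be positive, got {self.total_genes}"
            )
        for fam, n in self.counts.items():
            if n < 0:
                raise ValueError(f"{self.sample_id}: negative count for {fam}")


def count_families(
    annotations: Iterable[tuple[str, str]],
    total_genes: int | None = None,
    sample_id: str = "",
) -> FamilyCountTable:
    """Tally (gene_id, family_id) annotation records into a count table.

    Each record contributes one count to its family, as given; no attempt
    is made to collapse multiple family hits on the same gene. When
    ``total_genes`` is not supplied it is taken as the number of distinct
    gene ids in the stream.
    """
    counts: Counter[str] = Counter()
    genes: set[str] = set()
    for rec in annotations:
        try:
            gene_id, family_id = rec
        except (TypeError, ValueError):
            raise ValueError(f"malformed annotation record: {rec!r}") from None
        counts[family_id] += 1
        if total_genes is None:
            genes.add(gene_id)
    if total_genes is None:
        total_genes = len(genes)
    if total_genes < 1:
        raise ValueError(f"total_genes must be positive, got {total_genes}")
    return FamilyCountTable(sample_id=sample_id, counts=dict(counts),
                            total_genes=total_genes)


def category_score(table: FamilyCountTable, category: Category) -> float:
    """Normalized abundance of one category in one sample (see module docs)."""
    if not category.members:
        raise ValueError(f"empty category: {category.name}")
    if table.total_genes < 1:
        raise ValueError("total_genes must be positive")
    total = sum(table.counts.get(f, 0) for f in category.members)
    return (total / category.size) / table.total_genes


@dataclass
class AbundanceMatrix:
    """Samples x categories grid of normalized scores with group labels."""

    data: pd.DataFrame                 # index: sample_id, columns: category names
    divisions: dict[str, str]          # category name -> division
    labels: pd.Series                  # sample_id -> canonical label

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("abundance matrix contains non-finite values")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundance matrix contains negative values")
        missing = set(self.data.index) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)}")
        self.labels = self.labels.loc[self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def category_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, divisions: str | Sequence[str]) -> "AbundanceMatrix":
        """Restrict columns to one or more divisions, preserving order."""
        if isinstance(divisions, str):
            divisions = (divisions,)
        keep = [c for c in self.data.columns if self.divisions[c] in divisions]
        return AbundanceMatrix(
            data=self.data[keep].copy(),
            divisions={c: self.divisions[c] for c in keep},
            labels=self.labels.copy(),
        )

    def samples_with_labels(self, labels: Iterable[str]) -> list[str]:
        labels = set(labels)
        return [s for s in self.data.index if self.labels[s] in labels]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out["label"] = self.labels.values
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 divisions: dict[str, str] | None = None) -> "AbundanceMatrix":
        df = pd.read_csv(path)
        df = df.set_index("sample_id")
        labels = df.pop("label")
        if divisions is None:
            divisions = {c: "universal" for c in df.columns}
        return cls(data=df, divisions=divisions, labels=labels)


def build_matrix(
    tables: Sequence[FamilyCountTable],
    catalog: Catalog,
    metadata: Sequence[SampleMetadata],
) -> AbundanceMatrix:
    """Score every sample against every catalog category.

    Column order follows catalog order. Emits a warning (not an error) when
    the cohort's total gene counts span three or more orders of magnitude,
    since extreme depth imbalance can leave samples non-comparable even
    after normalization.
    """
    meta_by_id = {}
    for m in metadata:
        if m.sample_id in meta_by_id:
            raise ValueError(f"duplicate sample_id in metadata: {m.sample_id}")
        meta_by_id[m.sample_id] = m
    seen = set()
    for t in tables:
        if t.sample_id in seen:
            raise ValueError(f"duplicate sample_id in tables: {t.sample_id}")
        seen.add(t.sample_id)
        if t.sample_id not in meta_by_id:
            raise ValueError(f"sample without metadata: {t.sample_id}")

    if tables:
        totals = [t.total_genes for t in tables]
        if max(totals) / min(totals) >= 1e3:
            warnings.warn(
                "total gene counts span >= 3 orders of magnitude "
                f"({min(totals)}-{max(totals)}); samples may not be comparable "
                "after normalization",
                UserWarning,
                stacklevel=2,
            )

    rows = {
        t.sample_id: [category_score(t, c) for c in catalog.categories]
        for t in tables
    }
    data = pd.DataFrame.from_dict(
        rows, orient="index", columns=catalog.category_names
    )
    data.index.name = "sample_id"
    labels = pd.Series(
        {t.sample_id: meta_by_id[t.sample_id].label for t in tables},
        name="label",
    )
    return AbundanceMatrix(data=data, divisions=catalog.divisions, labels=labels)


# ---------------------------------------------------------------------------
# text I/O

def read_annotations_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read `gene_id <tab> family_id` records (header optional, # comments)."""
    records = []
    for lineno, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        if lineno == 1 and parts == ["gene_id", "family_id"]:
            continue
        records.append((parts[0], parts[1]))
    return records


def read_counts_tsv(path: str | Path, sample_id: str | None = None) -> FamilyCountTable:
    """Read a pre-tallied `family_id <tab> count` table.

    The total detected-gene count is carried in a header line
    ``#total_genes=<N>``; an optional ``#sample_id=<id>`` line names the
    sample (the file stem is used otherwise).
    """
    path = Path(path)
    total_genes = None
    counts: dict[str, int] = {}
    for lineno, ln in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.match(r"#\s*total_genes\s*=\s*(\d+)", s)
            if m:
                total_genes = int(m.group(1))
            m = re.match(r"#\s*sample_id\s*=\s*(\S+)", s)
            if m and sample_id is None:
                sample_id = m.group(1)
            continue
        parts = s.split("\t")
        if parts == ["family_id", "count"]:
            continue
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        counts[parts[0]] = counts.get(parts[0], 0) + int(parts[1])
    if total_genes is None:
        raise ValueError(f"{path}: missing '#total_genes=<N>' header line")
    return FamilyCountTable(
        sample_id=sample_id or path.stem, counts=counts, total_genes=total_genes
    )


def write_counts_tsv(table: FamilyCountTable, path: str | Path) -> None:
    lines = [
        f"#sample_id={table.sample_id}",
        f"#total_genes={table.total_genes}",
        "family_id\tcount",
    ]
    lines += [f"{fam}\t{n}" for fam, n in sorted(table.counts.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metadata_csv(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata: columns sample_id, label[, display_name]."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: need columns 'sample_id' and 'label'")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                label=str(row["label"]),
                display_name=str(row.get("display_name", "") or ""),
            )
        )
    return out
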