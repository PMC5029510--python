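"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage is testable without access to the original database-backed
metagenome profiles:

* total detected-gene counts drawn log-uniformly across the published
  cohort's span (25,694 to 14,687,361 genes), reproducing its heavy spread
  across orders of magnitude;
* per-family counts proportional to metagenome size, so normalized
  category scores are depth-invariant in expectation. Noise defaults to a
  negative binomial realized as a gamma rate multiplier shared by all
  families of a category within a sample (communities do not vary their
  hydrogenase families independently), then Poisson draws per family:
  marginally each family count is NB with the configured size, and the
  category total keeps the full overdispersion. Pure Poisson noise is
  available but degenerate as a between-sample model: shot noise vanishes
  at high depth, so group scatter would be an artifact of the depth
  distribution rather than of community variation;
* syntrophic samples carry an elevated rate in every syntroph-associated
  category except Fix, whose families (shared with nitrogen fixation) do
  not distinguish the groups; universal categories have group-independent
  rates;
* "other" samples carry the non-syntrophic signal but keep their own label,
  mimicking communities whose syntrophy (if any) is not expressed through
  the cataloged families.

Effect sizes in the real data are unknowable from published plots alone;
the defaults here are order-of-magnitude choices, documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .catalog import Catalog
from .profiles import (
    FamilyCountTable,
    NON_SYNTROPHIC,
    OTHER,
    POTENTIALLY_SYNTROPHIC,
    SampleMetadata,
    SYNTROPHIC_CULTURE,
)

#: Span of total detected-gene counts in the reference cohort.
GENE_COUNT_RANGE = (25_694, 14_687_361)

#: Default expected annotations per member family per detected gene.
UNIVERSAL_BASELINE_RATE = 2e-3
SYNTROPH_BASELINE_RATE = 2e-4

#: Default syntrophic-group rate multipliers. Confurcating hydrogenases get
#: the largest effect; Fix gets none (its families do not separate groups).
DEFAULT_EFFECT = 3.0
CONFURCATING_EFFECT = 3.5
CONFURCATING_CATEGORY = "Confurcating Hydrogenases"
FIX_CATEGORY = "Fix"


@dataclass
class SimulationConfig:
    n_syn: int = 14            # 5 culture + 9 potentially syntrophic
    n_non: int = 24
    n_other: int = 4
    gene_count_range: tuple[int, int] = GENE_COUNT_RANGE
    baseline_rates: dict[str, float] = field(default_factory=dict)
    effect_multipliers: dict[str, float] = field(default_factory=dict)
    dispersion: str = "negbin"     # negbin (default) | poisson
    negbin_size: float = 10.0
    seed: int = 0

    def validate(self, catalog: Catalog) -> None:
        if min(self.n_syn, self.n_non, self.n_other) < 0:
            raise ValueError("sample counts must be non-negative")
        lo, hi = self.gene_count_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid gene_count_range: {self.gene_count_range}")
        if self.dispersion not in ("poisson", "negbin"):
            raise ValueError(f"unknown dispersion: {self.dispersion!r}")
        if self.dispersion == "negbin" and self.negbin_size <= 0:
            raise ValueError("negbin size must be positive")
        for c in catalog.categories:
            if self.baseline_rates.get(c.name, 0.0) < 0:
                raise ValueError(f"negative baseline rate for {c.name}")
            if self.effect_multipliers.get(c.name, 1.0) < 0:
                raise ValueError(f"negative effect multiplier for {c.name}")

    def expected_score(self, category_name: str, category_size: int,
                       group_label: str) -> float:
        """Expected normalized category score for a group (depth-free)."""
        rate = self.baseline_rates[category_name]
        mult = (
            self.effect_multipliers.get(category_name, 1.0)
            if group_label in (SYNTROPHIC_CULTURE, POTENTIALLY_SYNTROPHIC)
            else 1.0
        )
        return rate * mult / category_size

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_syn": self.n_syn,
            "n_non": self.n_non,
            "n_other": self.n_other,
            "gene_count_range": list(self.gene_count_range),
            "baseline_rates": dict(self.baseline_rates),
            "effect_multipliers": dict(self.effect_multipliers),
            "dispersion": self.dispersion,
            "negbin_size": self.negbin_size,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        payload["gene_count_range"] = tuple(payload["gene_count_range"])
        return cls(**payload)


@dataclass
class CohortTruth:
    """Ground truth backing a simulated cohort."""

    group_of: dict[str, str]                      # sample_id -> label
    expected_scores: dict[str, dict[str, float]]  # sample_id -> cat -> E[score]
    config: SimulationConfig


def default_config(catalog: Catalog, seed: int = 0) -> SimulationConfig:
    """Default study conditions for a catalog.

    Universal categories: baseline housekeeping rate, multiplier exactly 1.
    Syntroph categories: lower baseline, syntrophic-group multiplier 3
    (3.5 for confurcating hydrogenases, which show the largest group
    difference), except Fix, which gets multiplier 1 and therefore does not
    separate the groups.
    """
    rates: dict[str, float] = {}
    mults: dict[str, float] = {}
    for c in catalog.categories:
        if c.division == "universal":
            rates[c.name] = UNIVERSAL_BASELINE_RATE
            mults[c.name] = 1.0
        else:
            rates[c.name] = SYNTROPH_BASELINE_RATE
            if c.name == FIX_CATEGORY:
                mults[c.name] = 1.0
            elif c.name == CONFURCATING_CATEGORY:
                mults[c.name] = CONFURCATING_EFFECT
            else:
                mults[c.name] = DEFAULT_EFFECT
    return SimulationConfig(
        baseline_rates=rates, effect_multipliers=mults, seed=seed
    )


def _draw_counts(rng: np.random.Generator, means: np.ndarray,
                 config: SimulationConfig) -> np.ndarray:
    if config.dispersion == "poisson":
        return rng.poisson(means)
    # gamma-Poisson with the multiplier shared across the category's
    # families: each family count is marginally NB(size k, its mean), and
    # the category total is NB(size k) rather than NB(size k*|members|)
    k = config.negbin_size
    g = rng.gamma(k, 1.0 / k)
    return rng.poisson(means * g)


def simulate_cohort(
    config: SimulationConfig, catalog: Catalog
) -> tuple[list[FamilyCountTable], list[SampleMetadata], CohortTruth]:
    """Draw a cohort of family-count tables with known group structure.

    Per sample, total_genes ~ log-uniform over ``gene_count_range``; each
    member family of category C gets a count with mean
    ``baseline_rate(C) * multiplier(C, group) * total_genes / |C|``, so the
    expected category score is independent of metagenome size. Fully
    reproducible for a given seed.
    """
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)

    plan: list[tuple[str, str]] = []
    n_cult = min(5, config.n_syn)
    for i in range(config.n_syn):
        label = SYNTROPHIC_CULTURE if i < n_cult else POTENTIALLY_SYNTROPHIC
        plan.append((f"syn{i + 1:03d}", label))
    plan += [(f"non{i + 1:03d}", NON_SYNTROPHIC) for i in range(config.n_non)]
    plan += [(f"oth{i + 1:03d}", OTHER) for i in range(config.n_other)]

    lo, hi = config.gene_count_range
    tables: list[FamilyCountTable] = []
    metadata: list[SampleMetadata] = []
    group_of: dict[str, str] = {}
    expected: dict[str, dict[str, float]] = {}

    for sample_id, label in plan:
        total_genes = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        total_genes = max(1, total_genes)
        counts: dict[str, int] = {}
        exp_scores: dict[str, float] = {}
        syn_signal = label in (SYNTROPHIC_CULTURE, POTENTIALLY_SYNTROPHIC)
        for cat in catalog.categories:
            rate = config.baseline_rates[cat.name]
            mult = config.effect_multipliers.get(cat.name, 1.0) if syn_signal else 1.0
            mean = rate * mult * total_genes / cat.size
            draws = _draw_counts(rng, np.full(cat.size, mean), config)
            for fam, n in zip(cat.members, draws):
                counts[fam] = counts.get(fam, 0) + int(n)
            exp_scores[cat.name] = rate * mult / cat.size
        tables.append(
            FamilyCountTable(sample_id=sample_id, counts=counts,
                             total_genes=total_genes)
        )
        metadata.append(SampleMetadata(sample_id=sample_id, label=label))
        group_of[sample_id] = label
        expected[sample_id] = exp_scores

    truth = CohortTruth(group_of=group_of, expected_scores=expected,
                        config=config)
    return tables, metadata, truth
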