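"""End-to-end analyses: abundance matrix -> ordination -> group ellipses.

Two standard analyses are provided, mirroring the negative-control /
predictive design of the method:

* **universal** — correlation-matrix PCA on the universal (housekeeping)
  categories only. Because these families track overall community activity
  rather than syntrophy, the syntrophic and non-syntrophic group ellipses
  are expected to overlap heavily: the negative control.
* **combined** — PCA on universal plus syntroph-associated categories.
  Elevated energy-transfer gene abundance pulls syntrophic communities
  apart from non-syntrophic ones, yielding separated ellipses and an
  ellipse-membership classification of each sample.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._base import ParamsMixin
from .catalog import Catalog
from .grouping import (
    ConfidenceEllipse,
    EllipseGroupClassifier,
    classification_frame,
)
from .group_stats import abundance_long_table, compare_categories, comparisons_frame
from .ordination import CorrelationPCA
from .profiles import (
    AbundanceMatrix,
    FamilyCountTable,
    SampleMetadata,
    build_matrix,
    category_score,
)


class SyntrophyAnalysis(ParamsMixin):
    """Fit the full ordination + ellipse analysis on one division set.

    Parameters
    ----------
    catalog : Catalog
    divisions : "universal", "syntroph", or ("universal", "syntroph")
    level : ellipse confidence level
    family : "normal" or "t" ellipse family
    """

    def __init__(self, catalog: Catalog,
                 divisions: Sequence[str] = ("universal", "syntroph"),
                 level: float = 0.95, family: str = "normal"):
        self.catalog = catalog
        self.divisions = divisions
        self.level = level
        self.family = family

    def fit(self, tables: Sequence[FamilyCountTable],
            metadata: Sequence[SampleMetadata]) -> "SyntrophyAnalysis":
        full = build_matrix(tables, self.catalog, metadata)
        divs = (self.divisions,) if isinstance(self.divisions, str) else tuple(
            self.divisions
        )
        self.matrix_ = full.subset(divs)
        self.pca_ = CorrelationPCA().fit(self.matrix_)
        self.classifier_ = EllipseGroupClassifier(
            level=self.level, family=self.family
        ).fit(self.pca_.scores_[:, :2], self.matrix_.labels.values)
        return self

    @property
    def ellipses_(self) -> tuple[ConfidenceEllipse, ConfidenceEllipse]:
        self._check_fitted("classifier_")
        return self.classifier_.ellipses_

    def overlap(self, method: str = "grid", **kwargs) -> float:
        self._check_fitted("classifier_")
        return self.classifier_.overlap(method=method, **kwargs)

    def score_row(self, table: FamilyCountTable) -> np.ndarray:
        """Category-score row for one count table, in model column order."""
        self._check_fitted("pca_")
        return np.array(
            [category_score(table, self.catalog[name])
             for name in self.pca_.feature_names_in_]
        )

    def classify(self, tables: Sequence[FamilyCountTable]) -> pd.DataFrame:
        """Project and classify new samples; returns a results table."""
        self._check_fitted("classifier_")
        rows = np.array([self.score_row(t) for t in tables])
        scores = self.pca_.transform(rows)[:, :2]
        results = self.classifier_.classify(scores, [t.sample_id for t in tables])
        return classification_frame(results)

    def classify_training(self) -> pd.DataFrame:
        """Classification of the training cohort itself."""
        self._check_fitted("classifier_")
        results = self.classifier_.classify(
            self.pca_.scores_[:, :2], self.matrix_.sample_ids
        )
        out = classification_frame(results)
        out.insert(1, "label", self.matrix_.labels.values)
        return out


@dataclass
class AnalysisArtifacts:
    matrix: AbundanceMatrix
    analysis: SyntrophyAnalysis
    overlap: float
    paths: dict[str, Path]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(
    tables: Sequence[FamilyCountTable],
    metadata: Sequence[SampleMetadata],
    catalog: Catalog,
    divisions: Sequence[str],
    outdir: str | Path,
    level: float = 0.95,
    family: str = "normal",
    seed: int = 0,
    with_comparisons: bool = False,
    input_paths: Sequence[Path] = (),
) -> AnalysisArtifacts:
    """Run one analysis and write its artifact tables under ``outdir``.

    Emits: matrix.csv, scores.csv, loadings.csv, scree.csv,
    correlation_circle.csv, ellipses.csv, ellipse_polygons.csv,
    classification.csv, model.json, manifest.json and, when
    ``with_comparisons``, comparisons.csv plus abundance_long.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = SyntrophyAnalysis(
        catalog=catalog, divisions=divisions, level=level, family=family
    ).fit(tables, metadata)
    pca = analysis.pca_
    matrix = analysis.matrix_

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, **kwargs) -> None:
        p = outdir / name
        df.to_csv(p, **kwargs)
        paths[name] = p

    matrix.to_csv(outdir / "matrix.csv")
    paths["matrix.csv"] = outdir / "matrix.csv"

    _write("scores.csv", pca.scores_frame(matrix.sample_ids), index=True)
    loadings = pd.DataFrame(
        pca.loadings_,
        index=pd.Index(pca.feature_names_in_, name="category"),
        columns=[f"PC{j + 1}" for j in range(pca.loadings_.shape[1])],
    )
    _write("loadings.csv", loadings, index=True)
    _write("scree.csv", pca.scree(), index=False)
    _write("correlation_circle.csv", pca.correlation_circle(), index=True)

    e_syn, e_non = analysis.ellipses_
    _write(
        "ellipses.csv",
        pd.DataFrame([e_syn.to_record(), e_non.to_record()]),
        index=False,
    )
    polys = []
    for e in (e_syn, e_non):
        verts = e.boundary(64)
        polys.append(
            pd.DataFrame(
                {"group_label": e.group_label, "x": verts[:, 0], "y": verts[:, 1]}
            )
        )
    _write("ellipse_polygons.csv", pd.concat(polys, ignore_index=True), index=False)

    _write("classification.csv", analysis.classify_training(), index=False)

    overlap = analysis.overlap(method="grid", resolution=256)

    if with_comparisons:
        comps = compare_categories(matrix)
        _write("comparisons.csv", comparisons_frame(comps), index=False)
        _write("abundance_long.csv", abundance_long_table(matrix), index=False)

    pca.to_json(outdir / "model.json")
    paths["model.json"] = outdir / "model.json"

    manifest = {
        "version": __version__,
        "seed": seed,
        "divisions": list(divisions) if not isinstance(divisions, str)
        else [divisions],
        "level": level,
        "ellipse_family": family,
        "n_samples": len(tables),
        "catalog_namespace": catalog.namespace,
        "categories": matrix.category_names,
        "overlap_fraction": overlap,
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
        "outputs": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    paths["manifest.json"] = outdir / "manifest.json"

    return AnalysisArtifacts(
        matrix=matrix, analysis=analysis, overlap=overlap, paths=paths
    )


def run_universal_analysis(tables, metadata, catalog, outdir, **kwargs
                           ) -> AnalysisArtifacts:
    """Negative-control analysis on universal categories only."""
    return run_analysis(tables, metadata, catalog, ("universal",), outdir,
                        **kwargs)


def run_combined_analysis(tables, metadata, catalog, outdir, **kwargs
                          ) -> AnalysisArtifacts:
    """Predictive analysis on universal + syntroph categories, with
    per-category group comparisons."""
    kwargs.setdefault("with_comparisons", True)
    return run_analysis(tables, metadata, catalog, ("universal", "syntroph"),
                        outdir, **kwargs)
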