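"""Bivariate confidence ellipses and ellipse-based group classification.

A group's 95% confidence ellipse is the normal-type ellipse: sample mean,
sample covariance, and a squared Mahalanobis boundary at the chi-square
quantile with 2 degrees of freedom (for level 0.95 this is
-2*ln(0.05) ~ 5.9915). A multivariate-t-flavoured boundary (Hotelling-style
F quantile, heavier tailed at small n) is available via ``family="t"`` for
fidelity experiments; the normal type is the documented default.

Classification of a sample projected into component space tests membership
in both the syntrophic and non-syntrophic group ellipses: inside exactly
one gives that call; inside both is ``ambiguous``; inside neither is
``neither``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._base import ParamsMixin
from .profiles import NON_SYNTROPHIC_GROUP, SYNTROPHIC_GROUP

CALLS = ("syntrophic", "non_syntrophic", "ambiguous", "neither")


def _radius_sq(level: float, n: int, family: str) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if family == "normal":
        return float(stats.chi2.ppf(level, df=2))
    if family == "t":
        if n <= 3:
            raise ValueError("t-type ellipse needs more than 3 points")
        return float(2 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2))
    raise ValueError(f"unknown ellipse family: {family!r}")


@dataclass
class ConfidenceEllipse:
    """Group center + covariance shape + squared Mahalanobis radius."""

    group_label: str
    center: np.ndarray
    shape: np.ndarray           # 2x2 sample covariance, symmetric PD
    level: float
    radius_sq: float
    n_points: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        self.shape = np.asarray(self.shape, dtype=float).reshape(2, 2)
        if not np.allclose(self.shape, self.shape.T, atol=1e-10):
            raise ValueError("shape matrix must be symmetric")
        if np.linalg.det(self.shape) <= 0 or self.shape[0, 0] <= 0:
            raise ValueError("singular covariance")
        if self.radius_sq <= 0:
            raise ValueError("radius_sq must be positive")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0,1)")

    @property
    def area(self) -> float:
        """pi * radius_sq * sqrt(det(shape))."""
        return float(np.pi * self.radius_sq * np.sqrt(np.linalg.det(self.shape)))

    def mahalanobis_sq(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - self.center
        sol = np.linalg.solve(self.shape, d.T).T
        return np.einsum("ij,ij->i", d, sol)

    def contains(self, point) -> bool | np.ndarray:
        """Membership test: squared Mahalanobis distance <= radius_sq."""
        pts = np.asarray(point, dtype=float)
        inside = self.mahalanobis_sq(pts) <= self.radius_sq
        return bool(inside[0]) if pts.ndim == 1 else inside

    def boundary(self, n_vertices: int = 64) -> np.ndarray:
        """Polygon vertices of the ellipse boundary (for plotting)."""
        theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.shape)
        return self.center + np.sqrt(self.radius_sq) * circle @ L.T

    def sample_interior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the ellipse (area-preserving map of disk)."""
        u = rng.random(n)
        theta = rng.random(n) * 2 * np.pi
        disk = np.sqrt(u)[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.shape)
        return self.center + np.sqrt(self.radius_sq) * disk @ L.T

    def to_record(self) -> dict:
        return {
            "group_label": self.group_label,
            "center_x": self.center[0],
            "center_y": self.center[1],
            "cov_xx": self.shape[0, 0],
            "cov_xy": self.shape[0, 1],
            "cov_yy": self.shape[1, 1],
            "level": self.level,
            "radius_sq": self.radius_sq,
            "n_points": self.n_points,
            "area": self.area,
        }


def fit_ellipse(points, level: float = 0.95, group_label: str = "",
                family: str = "normal") -> ConfidenceEllipse:
    """Fit a confidence ellipse to n x 2 component scores.

    Requires at least 3 points and a nonsingular sample covariance
    (collinear or duplicated point sets are rejected).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an n x 2 array of component scores")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to fit an ellipse, got {n}")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= np.finfo(float).tiny:
        raise ValueError("singular covariance (collinear or duplicated points)")
    return ConfidenceEllipse(
        group_label=group_label,
        center=center,
        shape=cov,
        level=level,
        radius_sq=_radius_sq(level, n, family),
        n_points=n,
    )


def contains(ellipse: ConfidenceEllipse, point) -> bool:
    return bool(ellipse.contains(np.asarray(point, dtype=float)))


def intersection_area(e1: ConfidenceEllipse, e2: ConfidenceEllipse,
                      method: str = "grid", resolution: int = 256,
                      n_samples: int = 20_000,
                      seed: int | None = None) -> float:
    """Area of the intersection of two ellipses.

    grid: indicator integration over the bounding box of the smaller
    ellipse (any intersection point lies inside it). monte_carlo: uniform
    sampling inside the smaller ellipse.
    """
    small = e1 if e1.area <= e2.area else e2
    other = e2 if small is e1 else e1
    if method == "grid":
        if resolution < 8:
            raise ValueError(f"grid resolution too small: {resolution}")
        verts = small.boundary(256)
        lo = verts.min(axis=0)
        hi = verts.max(axis=0)
        xs = np.linspace(lo[0], hi[0], resolution)
        ys = np.linspace(lo[1], hi[1], resolution)
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = small.contains(pts) & other.contains(pts)
        return float(inside.sum() * cell)
    if method == "monte_carlo":
        if n_samples < 1:
            raise ValueError(f"n_samples must be positive: {n_samples}")
        rng = np.random.default_rng(seed)
        pts = small.sample_interior(n_samples, rng)
        frac = float(np.mean(other.contains(pts)))
        return frac * small.area
    raise ValueError(f"unknown method: {method!r}")


def overlap_fraction(e1: ConfidenceEllipse, e2: ConfidenceEllipse,
                     method: str = "grid", resolution: int = 256,
                     n_samples: int = 20_000,
                     seed: int | None = None) -> float:
    """area(e1 ∩ e2) / min(area(e1), area(e2)), a bounded overlap index."""
    inter = intersection_area(e1, e2, method=method, resolution=resolution,
                              n_samples=n_samples, seed=seed)
    return min(1.0, inter / min(e1.area, e2.area))


@dataclass
class ClassificationResult:
    sample_id: str
    score2: np.ndarray
    in_syntrophic: bool
    in_non_syntrophic: bool
    call: str = field(init=False)

    def __post_init__(self) -> None:
        if self.in_syntrophic and self.in_non_syntrophic:
            self.call = "ambiguous"
        elif self.in_syntrophic:
            self.call = "syntrophic"
        elif self.in_non_syntrophic:
            self.call = "non_syntrophic"
        else:
            self.call = "neither"


class EllipseGroupClassifier(ParamsMixin):
    """Classify samples in component space by confidence-ellipse membership.

    fit(X, y) takes n x 2 scores and per-sample canonical labels; samples
    labelled syntrophic-culture or potentially-syntrophic form the
    "Syntrophic" ellipse group, non-syntrophic samples the "Non-Syntrophic"
    group, and "other" samples are projected but excluded from both
    ellipses.
    """

    def __init__(self, level: float = 0.95, family: str = "normal"):
        self.level = level
        self.family = family

    def fit(self, X, y) -> "EllipseGroupClassifier":
        pts = np.asarray(X, dtype=float)[:, :2]
        labels = np.asarray(list(y))
        syn = pts[np.isin(labels, list(SYNTROPHIC_GROUP))]
        non = pts[np.isin(labels, list(NON_SYNTROPHIC_GROUP))]
        self.syntrophic_ellipse_ = fit_ellipse(
            syn, level=self.level, group_label="Syntrophic", family=self.family
        )
        self.non_syntrophic_ellipse_ = fit_ellipse(
            non, level=self.level, group_label="Non-Syntrophic", family=self.family
        )
        return self

    @property
    def ellipses_(self) -> tuple[ConfidenceEllipse, ConfidenceEllipse]:
        self._check_fitted("syntrophic_ellipse_")
        return self.syntrophic_ellipse_, self.non_syntrophic_ellipse_

    def overlap(self, method: str = "grid", **kwargs) -> float:
        """Overlap index of the two fitted group ellipses."""
        e1, e2 = self.ellipses_
        return overlap_fraction(e1, e2, method=method, **kwargs)

    def classify(self, X, sample_ids: Sequence[str] | None = None
                 ) -> list[ClassificationResult]:
        self._check_fitted("syntrophic_ellipse_")
        pts = np.atleast_2d(np.asarray(X, dtype=float))[:, :2]
        if sample_ids is None:
            sample_ids = [str(i) for i in range(pts.shape[0])]
        in_syn = self.syntrophic_ellipse_.contains(pts)
        in_non = self.non_syntrophic_ellipse_.contains(pts)
        return [
            ClassificationResult(sid, p, bool(a), bool(b))
            for sid, p, a, b in zip(sample_ids, pts, in_syn, in_non)
        ]

    def predict(self, X) -> np.ndarray:
        """Array of calls: syntrophic / non_syntrophic / ambiguous / neither."""
        return np.array([r.call for r in self.classify(X)])


def classify_sample(model, classifier: EllipseGroupClassifier, table,
                    catalog=None) -> ClassificationResult:
    """Project one sample through a fitted ordination and classify it.

    ``table`` may be a category-score row (array) or a FamilyCountTable,
    in which case ``catalog`` must be provided to score it first.
    """
    from .profiles import FamilyCountTable, category_score

    if isinstance(table, FamilyCountTable):
        if catalog is None:
            raise ValueError("catalog required to score a FamilyCountTable")
        row = np.array(
            [category_score(table, catalog[name])
             for name in model.feature_names_in_]
        )
        sample_id = table.sample_id
    else:
        row = np.asarray(table, dtype=float)
        sample_id = "sample"
    scores = model.transform(row)[:2]
    return classifier.classify(scores.reshape(1, 2), [sample_id])[0]


def classification_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    rows = list(results)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "PC1": [r.score2[0] for r in rows],
            "PC2": [r.score2[1] for r in rows],
            "in_syntrophic": [r.in_syntrophic for r in rows],
            "in_non_syntrophic": [r.in_non_syntrophic for r in rows],
            "call": [r.call for r in rows],
        }
    )
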