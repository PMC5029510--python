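"""Correlation-matrix principal component analysis.

Columns are centered and scaled to unit sample variance (divisor n-1), so
the analysis operates on the correlation matrix of the input; category
scores spanning different absolute ranges contribute on an equal footing.
Components are computed from the singular value decomposition of the
standardized matrix, which is algebraically equivalent to the
eigendecomposition of the correlation matrix but numerically better
conditioned.

Sign convention: every component is flipped so that its largest-magnitude
loading is positive. Eigenvector sign is arbitrary, so comparisons with
other software hold only up to per-component sign.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._base import ParamsMixin
from .profiles import AbundanceMatrix


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, AbundanceMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x categories array")
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to zero mean, unit sample variance (n-1).

    Returns (standardized grid, centers, scales). A zero-variance column is
    an error naming the offending category — silently dropping a constant
    column would change the meaning of the analysis.
    """
    df = _as_frame(X)
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    centers = arr.mean(axis=0)
    scales = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        names = ", ".join(str(df.columns[j]) for j in zero)
        raise ValueError(f"zero variance: {names}")
    return (arr - centers) / scales, centers, scales


class CorrelationPCA(ParamsMixin):
    """PCA on the correlation matrix of a samples x categories table.

    Parameters
    ----------
    n_components : int or None
        Number of components to retain; all (= number of categories) when
        None.

    Attributes (after fit)
    ----------------------
    feature_names_in_ : list of category names
    mean_, scale_ : per-category centers and sample standard deviations
    loadings_ : (n_features, n_components) orthonormal column matrix
    components_ : loadings_.T, sklearn orientation
    explained_variance_ : eigenvalues of the correlation matrix, non-increasing
    explained_variance_ratio_ : eigenvalues / trace
    scores_ : (n_samples, n_components) training scores
    n_samples_ : training sample count
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None) -> "CorrelationPCA":
        df = _as_frame(X)
        if df.shape[1] < 2:
            raise ValueError("need at least 2 categories for ordination")
        Z, centers, scales = standardize(df)
        n, p = Z.shape
        # SVD of Z: eigenvalues of corr = s^2/(n-1); V columns are loadings
        _, s, Vt = np.linalg.svd(Z, full_matrices=True)
        eigvals = np.zeros(p)
        eigvals[: s.size] = s**2 / (n - 1)
        loadings = Vt.T  # p x p orthonormal
        # deterministic sign: largest-|loading| entry of each component positive
        flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                                np.arange(p)])
        flip[flip == 0] = 1.0
        loadings = loadings * flip

        k = p if self.n_components is None else min(self.n_components, p)
        self.feature_names_in_ = list(df.columns)
        self.mean_ = centers
        self.scale_ = scales
        self.loadings_ = loadings[:, :k]
        self.explained_variance_ = eigvals[:k]
        self.eigenvalues_all_ = eigvals
        self.explained_variance_ratio_ = eigvals[:k] / eigvals.sum()
        self.scores_ = Z @ self.loadings_
        self.n_samples_ = n
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    # -- fitted surface ------------------------------------------------------

    @property
    def components_(self) -> np.ndarray:
        self._check_fitted("loadings_")
        return self.loadings_.T

    def transform(self, X) -> np.ndarray:
        """Project new samples: ((x - mean) / scale) @ loadings."""
        self._check_fitted("loadings_")
        if isinstance(X, AbundanceMatrix) or isinstance(X, pd.DataFrame):
            df = _as_frame(X)
            missing = set(self.feature_names_in_) - set(df.columns)
            if missing:
                raise ValueError(f"missing categories: {sorted(missing)}")
            arr = df[self.feature_names_in_].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
        one = arr.ndim == 1
        arr = np.atleast_2d(arr)
        if arr.shape[1] != len(self.feature_names_in_):
            raise ValueError(
                f"expected {len(self.feature_names_in_)} categories, "
                f"got {arr.shape[1]}"
            )
        out = ((arr - self.mean_) / self.scale_) @ self.loadings_
        return out[0] if one else out

    def scree(self) -> pd.DataFrame:
        """Eigenvalue, variance proportion and cumulative proportion table."""
        self._check_fitted("loadings_")
        eig = self.eigenvalues_all_
        prop = eig / eig.sum()
        return pd.DataFrame(
            {
                "component": np.arange(1, eig.size + 1),
                "eigenvalue": eig,
                "proportion": prop,
                "cumulative": np.cumsum(prop),
            }
        )

    def correlation_circle(self, components: tuple[int, int] = (0, 1)) -> pd.DataFrame:
        """Correlation of each category with the chosen component scores.

        Coordinate of category j on component k is loadings[j, k] *
        sqrt(eigenvalue_k) — the Pearson correlation between standardized
        variable j and score k. Points lie in the unit disk.
        """
        self._check_fitted("loadings_")
        k = self.loadings_.shape[1]
        for c in components:
            if not (0 <= c < k):
                raise IndexError(f"component index out of range: {c}")
        cols = {}
        for c in components:
            cols[f"PC{c + 1}"] = self.loadings_[:, c] * np.sqrt(
                self.explained_variance_[c]
            )
        return pd.DataFrame(cols, index=pd.Index(self.feature_names_in_,
                                                 name="category"))

    def scores_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        self._check_fitted("scores_")
        cols = [f"PC{j + 1}" for j in range(self.scores_.shape[1])]
        idx = pd.Index(sample_ids, name="sample_id") if sample_ids is not None else None
        return pd.DataFrame(self.scores_, columns=cols, index=idx)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        self._check_fitted("loadings_")
        payload = {
            "n_components": self.n_components,
            "feature_names": self.feature_names_in_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "loadings": self.loadings_.tolist(),
            "eigenvalues": self.eigenvalues_all_.tolist(),
            "n_samples": self.n_samples_,
            "scores": self.scores_.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CorrelationPCA":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        payload = json.loads(text)
        model = cls(n_components=payload["n_components"])
        model.feature_names_in_ = list(payload["feature_names"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.loadings_ = np.asarray(payload["loadings"], dtype=float)
        model.eigenvalues_all_ = np.asarray(payload["eigenvalues"], dtype=float)
        model.explained_variance_ = model.eigenvalues_all_[
            : model.loadings_.shape[1]
        ]
        model.explained_variance_ratio_ = (
            model.explained_variance_ / model.eigenvalues_all_.sum()
        )
        model.scores_ = np.asarray(payload["scores"], dtype=float)
        model.n_samples_ = payload["n_samples"]
        return model


# ---------------------------------------------------------------------------
# functional wrappers

def fit_pca(matrix, n_components: int | None = None) -> CorrelationPCA:
    """Fit a correlation-matrix PCA to an abundance matrix (or array)."""
    return CorrelationPCA(n_components=n_components).fit(matrix)


def scree(model: CorrelationPCA) -> pd.DataFrame:
    return model.scree()


def correlation_circle(model: CorrelationPCA,
                       components: tuple[int, int] = (0, 1)) -> pd.DataFrame:
    return model.correlation_circle(components)


def project(model: CorrelationPCA, row) -> np.ndarray:
    """Project a new sample (category-score row) into component space."""
    return model.transform(row)
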