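"""Chemometric models: PCA for exploratory dimensionality reduction, a
NIPALS PLS-DA binary classifier, variable-importance-in-projection (VIP)
scoring, and VIP-based biomarker-band annotation.

The PLS-DA here is PLS1 regression on a centered 0/1 class coding, run with
the classical NIPALS deflation so that the weight vectors the VIP score is
defined on are available. For a descriptor matrix ``X`` (column-centered)
and centered response ``y``, component ``a`` extracts

    w_a = X_a' y_a / ||X_a' y_a||      (unit weight)
    t_a = X_a w_a                       (score)
    p_a = X_a' t_a / (t_a' t_a)         (x-loading)
    q_a = y_a' t_a / (t_a' t_a)         (y-loading)

followed by deflation ``X <- X - t_a p_a'`` and ``y <- y - q_a t_a``.
The regression vector is ``B = W (P'W)^-1 q``; a spectrum is called eczema
when its continuous score ``(x - x_mean) B + y_mean`` reaches the decision
threshold (default 0.5, the midpoint of the 0/1 coding; the boundary itself
counts as positive).

VIP for variable j over A components, with ``SS_a = q_a^2 t_a't_a``:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a )

so that ``mean_j VIP_j^2 = 1``; variables with VIP >= 1 are flagged
important.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .dataset import SpectralDataset, ECZEMA
from .exceptions import ConfigError, DegenerateFitError
from .simulate import ConstituentPeak

__all__ = [
    "PLSDAClassifier",
    "SpectralPCA",
    "pca_fit",
    "pls_fit",
    "pls_predict",
    "vip_scores",
    "VIPProfile",
    "annotate_vip_peaks",
]


class SpectralPCA(BaseEstimator, TransformerMixin):
    """PCA via SVD of the column-centered data matrix.

    Attributes (after fit): ``mean_``, ``components_`` (n_components x p,
    orthonormal rows = leading right singular vectors), and
    ``explained_variance_ratio_`` from the squared singular values.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n, p = X.shape
        k = int(self.n_components)
        if k < 1:
            raise ConfigError("n_components must be >= 1")
        max_k = min(n - 1, p) if n > 1 else 1
        if k > max_k:
            warnings.warn(
                f"n_components={k} exceeds the data rank bound {max_k}; reduced", stacklevel=2
            )
            k = max_k
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float((s**2).sum())
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) @ self.components_.T


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """NIPALS PLS-DA binary classifier (see module docstring for the model).

    Parameters
    ----------
    n_components : number of latent variables A.
    positive_label : label coded as y = 1 (default ``"eczema"``).
    threshold : decision cut on the continuous score; ``>=`` is positive.

    Fitted attributes
    -----------------
    x_mean_ (p,), y_mean_ (float), W_ (p x A unit weight vectors),
    P_ (p x A x-loadings), T_ (n x A scores, mutually orthogonal),
    q_ (A, y-loadings), coef_ (p, regression vector B),
    n_components_ (may be < n_components if a component degenerated).
    """

    def __init__(self, n_components: int = 2, positive_label=ECZEMA, threshold: float = 0.5):
        self.n_components = n_components
        self.positive_label = positive_label
        self.threshold = threshold

    # ------------------------------------------------------------------
    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ConfigError(f"PLS-DA needs exactly 2 classes, got {classes.size}")
        if self.positive_label in classes:
            pos = self.positive_label
        else:
            pos = classes[-1]
        self.classes_ = np.array([c for c in classes if c != pos] + [pos])
        return (y == pos).astype(float)

    def fit(self, X, y):
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        X = np.asarray(X, float)
        y01 = self._encode(y)
        n, p = X.shape
        if n != y01.size:
            raise ConfigError("X and y length mismatch")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y01.mean())
        Xa = X - self.x_mean_
        ya = y01 - self.y_mean_

        A = min(self.n_components, n - 1, p)
        W, P, T, q = [], [], [], []
        tt_first = None
        for a in range(A):
            cov = Xa.T @ ya
            nrm = np.linalg.norm(cov)
            if nrm == 0.0:
                if a == 0:
                    raise DegenerateFitError(
                        "zero covariance between spectra and class response"
                    )
                warnings.warn(f"component {a + 1}: zero covariance; truncated", stacklevel=2)
                break
            w = cov / nrm
            t = Xa @ w
            tt = float(t @ t)
            if tt_first is None:
                tt_first = tt
            if tt < 1e-12 * tt_first:
                warnings.warn(
                    f"component {a + 1}: negligible score variance; truncated", stacklevel=2
                )
                break
            p_a = Xa.T @ t / tt
            q_a = float(ya @ t / tt)
            Xa = Xa - np.outer(t, p_a)
            ya = ya - q_a * t
            W.append(w)
            P.append(p_a)
            T.append(t)
            q.append(q_a)

        self.W_ = np.column_stack(W)
        self.P_ = np.column_stack(P)
        self.T_ = np.column_stack(T)
        self.q_ = np.array(q)
        self.n_components_ = self.W_.shape[1]
        self.coef_ = self._coefficients(self.n_components_)
        self.n_features_in_ = p
        return self

    def _coefficients(self, A: int) -> np.ndarray:
        W, P, q = self.W_[:, :A], self.P_[:, :A], self.q_[:A]
        return W @ np.linalg.solve(P.T @ W, q)

    def decision_function(self, X, n_components: int | None = None) -> np.ndarray:
        """Continuous PLS score(s) on the 0/1 class scale."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean_.size:
            raise ConfigError(
                f"expected {self.x_mean_.size} wavenumber columns, got {X.shape[1]}"
            )
        B = self.coef_ if n_components is None else self._coefficients(n_components)
        return (X - self.x_mean_) @ B + self.y_mean_

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        yhat = self.decision_function(X, n_components)
        pos = yhat >= self.threshold
        return np.where(pos, self.classes_[1], self.classes_[0])

    # ------------------------------------------------------------------
    def vip(self) -> "VIPProfile":
        """VIP score per wavenumber (see module docstring)."""
        ss = self.q_**2 * (self.T_**2).sum(axis=0)
        denom = ss.sum()
        if denom == 0:
            raise DegenerateFitError("all component sums of squares are zero")
        p = self.W_.shape[0]
        scores = np.sqrt(p * (self.W_**2 @ ss) / denom)
        return VIPProfile(scores)

    def to_json(self, path: str | Path, grid: np.ndarray | None = None) -> None:
        obj = {
            "model": "plsda-nipals",
            "n_components": int(self.n_components_),
            "positive_label": str(self.classes_[1]),
            "threshold": self.threshold,
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "W": self.W_.tolist(),
            "P": self.P_.tolist(),
            "q": self.q_.tolist(),
            "B": self.coef_.tolist(),
            "grid_cm1": None if grid is None else np.asarray(grid, float).tolist(),
        }
        Path(path).write_text(json.dumps(obj))


class VIPProfile:
    """Per-wavenumber VIP scores; ``threshold`` (default 1.0) is the
    importance cut. Invariant: mean of squared scores is 1."""

    def __init__(self, scores: np.ndarray, threshold: float = 1.0):
        self.scores = np.asarray(scores, float)
        self.threshold = threshold

    def important_mask(self) -> np.ndarray:
        return self.scores >= self.threshold

    def to_csv(self, path: str | Path, grid: np.ndarray) -> None:
        pd.DataFrame({"wavenumber_cm1": np.asarray(grid, float), "vip": self.scores}).to_csv(
            path, index=False
        )


def annotate_vip_peaks(
    profile: VIPProfile,
    peaks: list[ConstituentPeak],
    grid: np.ndarray,
    match_window_cm1: float = 5.0,
) -> pd.DataFrame:
    """For each library peak, the maximum VIP within ±match_window of its
    center (nearest grid point when the window contains none) and whether
    that maximum reaches the importance threshold."""
    grid = np.asarray(grid, float)
    rows = []
    for pk in peaks:
        cols = np.flatnonzero(np.abs(grid - pk.center) <= match_window_cm1)
        if cols.size == 0:
            cols = np.array([np.argmin(np.abs(grid - pk.center))])
        vmax = float(profile.scores[cols].max())
        rows.append(
            {
                "center_cm1": pk.center,
                "assignment": pk.assignment,
                "max_vip": vmax,
                "important": vmax >= profile.threshold,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# thin functional wrappers over the estimators


def pca_fit(dataset: SpectralDataset, n_components: int) -> SpectralPCA:
    return SpectralPCA(n_components).fit(dataset.X)


def pls_fit(dataset: SpectralDataset, n_components: int) -> PLSDAClassifier:
    return PLSDAClassifier(n_components).fit(dataset.X, dataset.labels)


def pls_predict(model: PLSDAClassifier, X_new) -> tuple[np.ndarray, np.ndarray]:
    return model.decision_function(X_new), model.predict(X_new)


def vip_scores(model: PLSDAClassifier) -> VIPProfile:
    return model.vip()
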