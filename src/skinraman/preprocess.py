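"""Spectral preprocessing: AsLS baseline removal, Savitzky-Golay smoothing,
surface-spectrum selection at the keratin amide-I depth maximum, and SNV
normalization.

All steps are stateless row-wise transformers in the scikit-learn idiom
(``fit`` is a no-op that validates parameters), so they compose with
``sklearn.pipeline.Pipeline``. Module-level functions are thin wrappers
over the transformer classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectralDataset
from .exceptions import ConfigError, DegenerateInputError
from .simulate import SubjectRecord, DepthStack

__all__ = [
    "PreprocessConfig",
    "AslsBaseline",
    "SavitzkyGolaySmoother",
    "SNVNormalizer",
    "asls_baseline",
    "savgol_smooth",
    "snv_normalize",
    "locate_surface",
    "preprocess_cohort",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    asls_lambda : smoothness penalty of the Whittaker smoother inside AsLS.
    asls_p : asymmetry weight given to points above the running baseline.
    sg_window / sg_polyorder : Savitzky-Golay window (odd) and poly order.
    surface_marker_cm1 : wavenumber of the keratin amide-I surface marker.
    surface_halfwindow_cm1 : half-width of the averaging window around the
        marker; 0 means the single nearest grid point.
    """

    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_max_iter: int = 10
    asls_tol: float = 1e-6
    sg_window: int = 11
    sg_polyorder: int = 3
    surface_marker_cm1: float = 1655.0
    surface_halfwindow_cm1: float = 0.0

    def __post_init__(self) -> None:
        if self.asls_lambda <= 0:
            raise ConfigError("asls_lambda must be > 0")
        if not (0.0 < self.asls_p < 1.0):
            raise ConfigError("asls_p must be in (0, 1)")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ConfigError("sg_window must be an odd integer >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise ConfigError("sg_polyorder must be < sg_window")
        if self.surface_halfwindow_cm1 < 0:
            raise ConfigError("surface_halfwindow_cm1 must be >= 0")


def _as_2d(X) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X[None, :], True
    return X, False


class AslsBaseline(BaseEstimator, TransformerMixin):
    """Asymmetric least squares (AsLS) baseline estimator/corrector.

    The baseline ``z`` minimizes ``sum_i w_i (y_i - z_i)^2 +
    lam * sum_i (d2 z_i)^2`` where the asymmetric weights are ``p`` for
    points above the baseline and ``1 - p`` below, iterated from uniform
    weights until the weight vector changes by less than ``tol`` (max
    absolute change) or ``max_iter`` sweeps.

    ``transform`` subtracts the per-row baseline; ``baseline`` returns it.
    """

    def __init__(self, lam: float = 1e5, p: float = 0.01, max_iter: int = 10, tol: float = 1e-6):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        if self.lam <= 0 or not (0 < self.p < 1):
            raise ConfigError("AsLS requires lam > 0 and p in (0, 1)")
        self.n_features_in_ = _as_2d(X)[0].shape[1]
        return self

    def _single(self, y: np.ndarray) -> np.ndarray:
        n = y.size
        if n < 3:
            raise ConfigError("AsLS needs at least 3 points")
        if not np.all(np.isfinite(y)):
            raise DegenerateInputError("AsLS input contains non-finite values")
        # lam * D2'D2 is pentadiagonal; upper banded form for solveh_banded
        lam = self.lam
        d0 = np.full(n, 6.0 * lam)
        d0[[0, -1]] = lam
        d0[[1, -2]] = 5.0 * lam
        d1 = np.full(n - 1, -4.0 * lam)
        d1[[0, -1]] = -2.0 * lam
        d2 = np.full(n - 2, lam)
        ab = np.zeros((3, n))
        ab[0, 2:] = d2
        ab[1, 1:] = d1

        w = np.ones(n)
        for _ in range(self.max_iter):
            ab[2] = d0 + w
            z = solveh_banded(ab, w * y, lower=False)
            w_new = np.where(y > z, self.p, 1.0 - self.p)
            delta = np.max(np.abs(w_new - w))
            w = w_new
            if delta < self.tol:
                break
        ab[2] = d0 + w
        return solveh_banded(ab, w * y, lower=False)

    def baseline(self, X) -> np.ndarray:
        """Estimated baseline(s), same shape as the input."""
        X2, was_1d = _as_2d(X)
        Z = np.vstack([self._single(row) for row in X2])
        return Z[0] if was_1d else Z

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, float) - self.baseline(X)


class SavitzkyGolaySmoother(BaseEstimator, TransformerMixin):
    """Row-wise Savitzky-Golay least-squares polynomial smoothing.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy's ``mode="interp"``).
    """

    def __init__(self, window: int = 11, polyorder: int = 3):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        self._validate()
        self.n_features_in_ = _as_2d(X)[0].shape[1]
        return self

    def _validate(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigError("window must be an odd integer >= 3")
        if self.polyorder >= self.window:
            raise ConfigError("polyorder must be < window")

    def transform(self, X) -> np.ndarray:
        self._validate()
        X2, was_1d = _as_2d(X)
        if self.window > X2.shape[1]:
            raise ConfigError(
                f"window ({self.window}) larger than signal length ({X2.shape[1]})"
            )
        out = savgol_filter(X2, self.window, self.polyorder, axis=-1, mode="interp")
        return out[0] if was_1d else out


class SNVNormalizer(BaseEstimator, TransformerMixin):
    """Standard normal variate: each spectrum to mean 0, sample (n-1) sd 1."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_2d(X)[0].shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X2, was_1d = _as_2d(X)
        sd = X2.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise DegenerateInputError("constant spectrum cannot be SNV-normalized")
        out = (X2 - X2.mean(axis=1, keepdims=True)) / sd[:, None]
        return out[0] if was_1d else out


# --------------------------------------------------------------------------
# thin functional wrappers


def asls_baseline(y, config: PreprocessConfig | None = None) -> np.ndarray:
    config = config or PreprocessConfig()
    est = AslsBaseline(config.asls_lambda, config.asls_p, config.asls_max_iter, config.asls_tol)
    return est.baseline(np.asarray(y, float))


def savgol_smooth(y, config: PreprocessConfig | None = None) -> np.ndarray:
    config = config or PreprocessConfig()
    return SavitzkyGolaySmoother(config.sg_window, config.sg_polyorder).transform(y)


def snv_normalize(y) -> np.ndarray:
    return SNVNormalizer().transform(y)


def locate_surface(stack: DepthStack | np.ndarray, config: PreprocessConfig, grid=None) -> int:
    """Depth index of the skin surface: argmax over depths of the (mean)
    intensity at/around the amide-I marker; ties go to the smallest index.

    Expects an already baseline-corrected, smoothed stack.
    """
    if isinstance(stack, DepthStack):
        grid = stack.grid
        intensities = stack.intensities
    else:
        intensities = np.asarray(stack, float)
        if grid is None:
            raise ConfigError("grid required when stack is a bare array")
    grid = np.asarray(grid, float)
    marker = config.surface_marker_cm1
    if not (grid[0] <= marker <= grid[-1]):
        raise ConfigError(f"surface marker {marker} cm^-1 outside grid range")
    hw = config.surface_halfwindow_cm1
    if hw == 0:
        cols = [int(np.argmin(np.abs(grid - marker)))]
    else:
        cols = np.flatnonzero(np.abs(grid - marker) <= hw).tolist()
    profile = intensities[:, cols].mean(axis=1)
    return int(np.argmax(profile))  # argmax returns the first (smallest) maximizer


def preprocess_cohort(
    records: list[SubjectRecord], config: PreprocessConfig | None = None
) -> SpectralDataset:
    """Full chain per subject: per-depth AsLS correction -> SG smoothing ->
    surface localization -> SNV of the selected surface spectrum.

    Returns a SpectralDataset (input subject order preserved) whose ``meta``
    records severity, TEWL and the chosen surface depth index per subject.
    """
    config = config or PreprocessConfig()
    asls = AslsBaseline(config.asls_lambda, config.asls_p, config.asls_max_iter, config.asls_tol)
    sg = SavitzkyGolaySmoother(config.sg_window, config.sg_polyorder)
    snv = SNVNormalizer()

    if not records:
        return SpectralDataset(
            np.empty((0, 0)), np.array([]), np.array([]), np.array([]), pd.DataFrame()
        )

    grid = records[0].stack.grid
    rows, labels, ids, meta_rows = [], [], [], []
    for rec in records:
        if rec.stack.grid.size != grid.size or not np.allclose(rec.stack.grid, grid):
            raise ConfigError(f"subject {rec.subject_id}: wavenumber grid mismatch")
        try:
            corrected = sg.transform(asls.transform(rec.stack.intensities))
            idx = locate_surface(corrected, config, grid)
            surface = snv.transform(corrected[idx])
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"subject {rec.subject_id}: {exc}") from exc
        rows.append(surface)
        labels.append(rec.group)
        ids.append(rec.subject_id)
        meta_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "severity": rec.severity,
                "tewl": rec.tewl,
                "surface_depth_index": idx,
                "surface_depth_index_true": rec.surface_depth_index_true,
            }
        )
    return SpectralDataset(
        np.vstack(rows), grid, np.array(labels), np.array(ids), pd.DataFrame(meta_rows)
    )


def write_provenance(path: str | Path, config: PreprocessConfig, dataset: SpectralDataset) -> None:
    """JSON sidecar: preprocessing config + chosen depth index per subject."""
    chosen = {}
    if dataset.meta is not None and "surface_depth_index" in dataset.meta:
        chosen = dict(
            zip(dataset.meta["subject_id"], (int(i) for i in dataset.meta["surface_depth_index"]))
        )
    Path(path).write_text(
        json.dumps({"config": asdict(config), "surface_depth_index": chosen}, indent=2)
    )
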