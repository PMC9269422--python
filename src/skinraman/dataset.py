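"""In-memory containers for spectral datasets and their CSV dialects.

The package works on two tabular shapes:

* the *cohort* dialect — one wide CSV per cohort whose first column is the
  wavenumber axis and whose remaining columns are per-(subject, depth)
  intensities named ``<subject_id>_d<k>``, plus a companion metadata CSV;
* the *dataset* dialect — one processed surface spectrum per subject
  (rows = subjects, columns = wavenumbers) with id and group columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

ECZEMA = "eczema"
HEALTHY = "healthy"


@dataclass
class SpectralDataset:
    """Subjects x wavenumbers intensity matrix with labels and metadata.

    Attributes
    ----------
    X : ndarray of shape (n_subjects, n_wavenumbers)
        Intensities (SNV units after preprocessing).
    grid : ndarray of shape (n_wavenumbers,)
        Shared wavenumber axis in cm^-1, strictly increasing.
    labels : ndarray of str
        Group label per row, ``"eczema"`` or ``"healthy"``.
    ids : ndarray of str
        Subject identifier per row.
    meta : DataFrame, optional
        Per-subject metadata (severity, TEWL, chosen surface depth, ...).
    """

    X: np.ndarray
    grid: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids)
        n = self.X.shape[0] if self.X.ndim == 2 else 0
        if self.X.ndim != 2:
            self.X = self.X.reshape(n, -1)
        if len(self.labels) != n or len(self.ids) != n:
            raise FormatError(
                f"labels/ids length must match rows of X (n={n}, "
                f"labels={len(self.labels)}, ids={len(self.ids)})"
            )
        if self.X.shape[1] != self.grid.size and n > 0:
            raise FormatError(
                f"X has {self.X.shape[1]} columns but grid has {self.grid.size} points"
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.grid.size

    def y(self, positive_label: str = ECZEMA) -> np.ndarray:
        """0/1 class coding with `positive_label` mapped to 1."""
        return (self.labels == positive_label).astype(float)

    def subset(self, idx) -> "SpectralDataset":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return SpectralDataset(self.X[idx], self.grid, self.labels[idx], self.ids[idx], meta)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the dataset dialect: subject_id, group, then one column
        per wavenumber (cm^-1, formatted to 4 decimals)."""
        cols = [f"{w:.4f}" for w in self.grid]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "group", self.labels)
        df.insert(0, "subject_id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, meta: pd.DataFrame | None = None) -> "SpectralDataset":
        df = pd.read_csv(path)
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column '{col}'")
        spec_cols = [c for c in df.columns if c not in ("subject_id", "group")]
        try:
            grid = np.array([float(c) for c in spec_cols])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric wavenumber column name") from exc
        return cls(
            df[spec_cols].to_numpy(float),
            grid,
            df["group"].to_numpy(),
            df["subject_id"].astype(str).to_numpy(),
            meta,
        )
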