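"""Synthetic depth-resolved confocal Raman cohort generator.

Emulates the statistical structure of an in-vivo volar-forearm Raman study
comparing atopic-eczema patients with healthy controls: a fingerprint-region
wavenumber grid (400-1800 cm^-1, 1384 points), per-subject stacks of spectra
acquired at 10 depths in 10 um steps with the keratin amide-I (1655 cm^-1)
depth profile peaking at the true skin surface, class-dependent band
intensities in the discriminative regions, a decaying fluorescence baseline,
additive detector noise, and a trans-epidermal water loss (TEWL) covariate
drawn from the per-group normal distributions of the emulated study
(eczema 17.77 +/- 9.0891, healthy 10.58 +/- 2.7964, n = 52 vs 20).

Every stochastic quantity flows from ``CohortConfig.seed`` through a
splittable ``numpy.random.SeedSequence``, so an identical config yields a
bit-identical cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ECZEMA, HEALTHY
from .exceptions import ConfigError

__all__ = [
    "ConstituentPeak",
    "ClassProfile",
    "CohortConfig",
    "DepthStack",
    "SubjectRecord",
    "build_grid",
    "load_peak_library",
    "constituent_spectrum",
    "generate_depth_stack",
    "sample_tewl",
    "generate_cohort",
    "lv_recovery_factors",
    "write_cohort",
    "read_cohort",
]

#: discriminative wavenumber intervals (cm^-1) where the two classes differ:
#: NMF / amino-acid region, amide III, CH2/CH3 deformation shoulder, amide I.
DISCRIMINATIVE_BANDS = ((850.0, 930.0), (1240.0, 1330.0), (1410.0, 1480.0), (1640.0, 1680.0))

#: default eczema-vs-healthy intensity multipliers per discriminative band.
#: Healthy is the unit reference; magnitudes are calibrated so the full
#: pipeline recovers the class structure robustly, not physiological claims.
DEFAULT_ECZEMA_MULTIPLIERS = {
    (850.0, 930.0): 0.80,
    (1240.0, 1330.0): 0.82,
    (1410.0, 1480.0): 1.12,
    (1640.0, 1680.0): 1.22,
}


@dataclass(frozen=True)
class ConstituentPeak:
    """A single Lorentzian Raman line."""

    center: float  # cm^-1
    width: float  # half-width at half-maximum, cm^-1
    base_amplitude: float
    assignment: str = ""
    references: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"peak width must be > 0, got {self.width}")
        if self.base_amplitude < 0:
            raise ConfigError("peak base_amplitude must be >= 0")


@dataclass(frozen=True)
class ClassProfile:
    """Class-dependent band intensity multipliers.

    ``band_multipliers`` maps a wavenumber interval ``(lo, hi)`` to the
    multiplier applied to the base amplitude of every peak whose center
    falls inside the interval.
    """

    class_label: str
    band_multipliers: dict = field(default_factory=dict)

    def multiplier_for(self, center: float) -> float:
        for (lo, hi), m in self.band_multipliers.items():
            if lo <= center <= hi:
                if m <= 0:
                    raise ConfigError("band multipliers must be > 0")
                return m
        return 1.0


def healthy_profile() -> ClassProfile:
    return ClassProfile(HEALTHY, {})


def eczema_profile(multipliers: dict | None = None) -> ClassProfile:
    return ClassProfile(ECZEMA, dict(DEFAULT_ECZEMA_MULTIPLIERS if multipliers is None else multipliers))


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 52 eczema (8 mild / 31 moderate /
    13 severe by SCORAD) vs 20 healthy subjects, 10 depths at 10 um,
    1384-point 400-1800 cm^-1 grid, and the printed TEWL group moments.
    """

    n_eczema: int = 52
    n_healthy: int = 20
    severity_counts: tuple = (8, 31, 13)  # mild, moderate, severe
    n_depths: int = 10
    depth_step: float = 10.0  # um
    grid_start: float = 400.0
    grid_stop: float = 1800.0
    n_points: int = 1384
    baseline_amplitude: float = 2.0
    baseline_decay: float = 400.0  # cm^-1
    noise_sd: float = 0.02
    peak_jitter_sd: float = 0.10  # lognormal sigma of per-subject peak amplitudes
    subject_scale_sd: float = 0.15  # lognormal sigma of global intensity scale
    tewl_eczema: tuple = (17.77, 9.0891)
    tewl_healthy: tuple = (10.58, 2.7964)
    sample_fitzpatrick: bool = False
    seed: int = 0
    mode: str = "default"  # {"default", "lv_recovery"}
    # lv_recovery mode: per-factor class-mean offsets (descending) and
    # within-class score standard deviations (calibrated once; see docs).
    lv_effects: tuple = (0.54, 0.39, 0.30, 0.27)
    lv_noise_sds: tuple = (1.60, 0.75, 0.38, 0.014)

    def __post_init__(self) -> None:
        if self.n_eczema < 0 or self.n_healthy < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.n_eczema and sum(self.severity_counts) != self.n_eczema:
            raise ConfigError(
                f"severity_counts {self.severity_counts} must sum to n_eczema={self.n_eczema}"
            )
        if self.n_depths < 1:
            raise ConfigError("n_depths must be >= 1")
        if self.noise_sd < 0 or self.peak_jitter_sd < 0 or self.subject_scale_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.tewl_eczema[1] < 0 or self.tewl_healthy[1] < 0:
            raise ConfigError("TEWL standard deviations must be >= 0")
        if self.mode not in ("default", "lv_recovery"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def grid(self) -> np.ndarray:
        return build_grid(self.grid_start, self.grid_stop, self.n_points)

    # round-trippable plain-dict form (YAML/JSON friendly)
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("severity_counts", "tewl_eczema", "tewl_healthy", "lv_effects", "lv_noise_sds"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for k in ("severity_counts", "tewl_eczema", "tewl_healthy", "lv_effects", "lv_noise_sds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class DepthStack:
    """Per-subject matrix of spectra over depth positions."""

    intensities: np.ndarray  # n_depths x n_points
    depth_step: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape[1] != self.grid.size:
            raise ConfigError("stack column count must equal grid size")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    severity: str  # mild | moderate | severe | none
    tewl: float
    stack: DepthStack
    surface_depth_index_true: int
    fitzpatrick: int | None = None


# --------------------------------------------------------------------------
# building blocks


def build_grid(start: float, stop: float, n_points: int) -> np.ndarray:
    """Uniform wavenumber grid inclusive of both endpoints."""
    if n_points < 2:
        raise ConfigError(f"n_points must be >= 2, got {n_points}")
    if start >= stop:
        raise ConfigError(f"start ({start}) must be < stop ({stop})")
    return np.linspace(start, stop, n_points)


def load_peak_library(path: str | Path | None = None) -> list[ConstituentPeak]:
    """Load the packaged stratum-corneum peak library (or a user CSV with
    columns center_cm1, width_cm1, base_amplitude, assignment, references)."""
    if path is None:
        src = resources.files("skinraman").joinpath("data/peak_library.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return [
        ConstituentPeak(
            float(r.center_cm1),
            float(r.width_cm1),
            float(r.base_amplitude),
            str(r.assignment),
            str(r.references),
        )
        for r in df.itertuples()
    ]


def constituent_spectrum(
    peaks: list[ConstituentPeak],
    profile: ClassProfile,
    grid: np.ndarray,
    amplitude_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of Lorentzian lines ``a * w^2 / ((nu - c)^2 + w^2)`` with
    ``a = base_amplitude * class multiplier (* optional per-peak factor)``.
    """
    if not peaks:
        raise ConfigError("peaks must be non-empty")
    grid = np.asarray(grid, float)
    out = np.zeros_like(grid)
    for i, pk in enumerate(peaks):
        if not (grid[0] <= pk.center <= grid[-1]):
            warnings.warn(
                f"peak center {pk.center} cm^-1 outside grid range "
                f"[{grid[0]}, {grid[-1]}]; evaluated anyway",
                stacklevel=2,
            )
        a = pk.base_amplitude * profile.multiplier_for(pk.center)
        if amplitude_factors is not None:
            a *= amplitude_factors[i]
        out += a * pk.width**2 / ((grid - pk.center) ** 2 + pk.width**2)
    return out


def fluorescence_baseline(grid: np.ndarray, amplitude: float, decay: float) -> np.ndarray:
    """Decaying-exponential autofluorescence background
    ``amplitude * exp(-(nu - nu0) / decay)`` anchored at the grid start."""
    grid = np.asarray(grid, float)
    return amplitude * np.exp(-(grid - grid[0]) / decay)


def depth_weights(n_depths: int, surface_index: int, sd: float = 1.5) -> np.ndarray:
    """Unimodal Gaussian confocal depth-response profile, max 1 at the
    surface index (sd in units of depth rows)."""
    d = np.arange(n_depths)
    return np.exp(-0.5 * ((d - surface_index) / sd) ** 2)


def generate_depth_stack(
    clean_spectrum: np.ndarray,
    config: CohortConfig,
    surface_index: int,
    rng: np.random.Generator,
) -> DepthStack:
    """Depth stack: each row is ``weight(d) * clean + baseline + noise``."""
    if not (0 <= surface_index < config.n_depths):
        raise ConfigError(f"surface_index {surface_index} out of range")
    grid = config.grid()
    w = depth_weights(config.n_depths, surface_index)
    base = fluorescence_baseline(grid, config.baseline_amplitude, config.baseline_decay)
    stack = w[:, None] * np.asarray(clean_spectrum, float)[None, :] + base[None, :]
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, size=stack.shape)
    return DepthStack(stack, config.depth_step, grid)


def sample_tewl(group: str, config: CohortConfig, rng: np.random.Generator) -> float:
    """One draw from the group's untruncated TEWL normal distribution."""
    if group == ECZEMA:
        mean, sd = config.tewl_eczema
    elif group == HEALTHY:
        mean, sd = config.tewl_healthy
    else:
        raise ConfigError(f"unknown group {group!r}")
    return float(rng.normal(mean, sd))


# --------------------------------------------------------------------------
# lv_recovery factors


def lv_recovery_factors(grid: np.ndarray) -> np.ndarray:
    """Four mutually orthogonal unit-norm spectral factor loadings.

    Raised-cosine bumps on disjoint wavenumber windows, hence exactly
    orthogonal; returned as a (4, n_points) array. Later factors (whose
    class-mean offsets are smaller) sit in windows with little constituent
    peak intensity so that per-subject peak-amplitude jitter does not
    drown their class signal.
    """
    windows = ((1020.0, 1140.0), (1340.0, 1460.0), (415.0, 535.0), (1462.0, 1542.0))
    grid = np.asarray(grid, float)
    F = np.zeros((len(windows), grid.size))
    for k, (lo, hi) in enumerate(windows):
        c, h = 0.5 * (lo + hi), 0.5 * (hi - lo)
        inside = np.abs(grid - c) < h
        F[k, inside] = 0.5 * (1.0 + np.cos(np.pi * (grid[inside] - c) / h))
        F[k] /= np.linalg.norm(F[k])
    return F


# --------------------------------------------------------------------------
# cohort assembly

_FITZ_ECZEMA = (12, 38, 2)  # FP score 3 / 4 / 5
_FITZ_HEALTHY = (11, 5, 4)


def generate_cohort(
    config: CohortConfig, peaks: list[ConstituentPeak] | None = None
) -> list[SubjectRecord]:
    """Generate the full synthetic cohort.

    Eczema subjects come first (severity strata in mild, moderate, severe
    order), then healthy controls. Each subject's true surface depth is
    drawn uniformly from the interior indices {2, ..., n_depths - 3}.
    In ``lv_recovery`` mode the class band multipliers are neutralized and
    four mutually orthogonal class-informative spectral factors with
    descending effect sizes carry the entire class signal instead.
    """
    if peaks is None:
        peaks = load_peak_library()
    grid = config.grid()
    n_total = config.n_eczema + config.n_healthy
    if n_total == 0:
        return []

    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(n_total)

    # lv_recovery is a controlled factor-model experiment: the class band
    # multipliers and the per-subject amplitude/scale jitter are switched
    # off so the 4 injected orthogonal factors carry the entire class
    # signal and the within-class spread is exactly the configured one.
    lv_mode = config.mode == "lv_recovery"
    prof_h = healthy_profile()
    prof_e = prof_h if lv_mode else eczema_profile()
    factors = lv_recovery_factors(grid) if lv_mode else None
    jitter_sd = 0.0 if lv_mode else config.peak_jitter_sd
    scale_sd = 0.0 if lv_mode else config.subject_scale_sd

    severities = (
        ["mild"] * config.severity_counts[0]
        + ["moderate"] * config.severity_counts[1]
        + ["severe"] * config.severity_counts[2]
    )
    fitz_pool = {
        ECZEMA: [3] * _FITZ_ECZEMA[0] + [4] * _FITZ_ECZEMA[1] + [5] * _FITZ_ECZEMA[2],
        HEALTHY: [3] * _FITZ_HEALTHY[0] + [4] * _FITZ_HEALTHY[1] + [5] * _FITZ_HEALTHY[2],
    }

    # interior depth indices guarantee the surface peak is resolvable
    lo_idx, hi_idx = 2, config.n_depths - 3
    if hi_idx < lo_idx:
        lo_idx, hi_idx = 0, config.n_depths - 1

    records: list[SubjectRecord] = []
    for i in range(n_total):
        is_ecz = i < config.n_eczema
        group = ECZEMA if is_ecz else HEALTHY
        rng = np.random.default_rng(subject_seeds[i])
        profile = prof_e if is_ecz else prof_h

        jitter = (
            np.exp(rng.normal(0.0, jitter_sd, size=len(peaks)))
            if jitter_sd > 0
            else np.ones(len(peaks))
        )
        scale = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd > 0 else 1.0
        clean = scale * constituent_spectrum(peaks, profile, grid, amplitude_factors=jitter)

        if lv_mode:
            z = 1.0 if is_ecz else -1.0
            effects = np.array(config.lv_effects)
            noise_sds = np.array(config.lv_noise_sds)
            scores = effects * z + noise_sds * rng.normal(size=4)
            # constant positive offset per factor keeps every bump positive,
            # so the asymmetric baseline corrector downstream treats the
            # class-dependent modulation linearly instead of absorbing
            # negative-going deviations into the baseline
            offsets = effects + 3.0 * noise_sds
            clean = clean + 1.0 + (offsets + scores) @ factors

        surface_idx = int(rng.integers(lo_idx, hi_idx + 1))
        stack = generate_depth_stack(clean, config, surface_idx, rng)
        tewl = sample_tewl(group, config, rng)

        if is_ecz:
            sid = f"ecz{i + 1:03d}"
            severity = severities[i] if severities else "none"
        else:
            sid = f"hc{i - config.n_eczema + 1:03d}"
            severity = "none"

        fp = None
        if config.sample_fitzpatrick:
            pool = fitz_pool[group]
            fp = int(pool[int(rng.integers(len(pool)))])

        records.append(SubjectRecord(sid, group, severity, tewl, stack, surface_idx, fp))
    return records


# --------------------------------------------------------------------------
# cohort CSV dialect


def write_cohort(records: list[SubjectRecord], spectra_path: str | Path, meta_path: str | Path) -> None:
    """Write the wide cohort CSV (wavenumber + ``<subject_id>_d<k>`` columns)
    and the companion metadata CSV."""
    if records:
        grid = records[0].stack.grid
    else:
        grid = np.array([])
    data = {"wavenumber_cm1": grid}
    for rec in records:
        for d in range(rec.stack.intensities.shape[0]):
            data[f"{rec.subject_id}_d{d}"] = rec.stack.intensities[d]
    pd.DataFrame(data).to_csv(spectra_path, index=False)

    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "severity": [r.severity for r in records],
            "tewl": [r.tewl for r in records],
            "surface_depth_index_true": [r.surface_depth_index_true for r in records],
            "fitzpatrick": [r.fitzpatrick for r in records],
            "depth_step_um": [r.stack.depth_step for r in records],
        }
    )
    meta.to_csv(meta_path, index=False)


def read_cohort(spectra_path: str | Path, meta_path: str | Path) -> list[SubjectRecord]:
    """Read the cohort dialect back into SubjectRecord objects."""
    from .exceptions import FormatError

    df = pd.read_csv(spectra_path)
    if "wavenumber_cm1" not in df.columns:
        raise FormatError(f"{spectra_path}: missing 'wavenumber_cm1' column")
    grid = df["wavenumber_cm1"].to_numpy(float)
    meta = pd.read_csv(meta_path)

    records = []
    for r in meta.itertuples():
        cols = sorted(
            (c for c in df.columns if c.startswith(f"{r.subject_id}_d")),
            key=lambda c: int(c.rsplit("_d", 1)[1]),
        )
        if not cols:
            raise FormatError(f"{spectra_path}: no spectra for subject {r.subject_id}")
        stack = DepthStack(df[cols].to_numpy(float).T, float(r.depth_step_um), grid)
        fp = None if pd.isna(r.fitzpatrick) else int(r.fitzpatrick)
        records.append(
            SubjectRecord(
                str(r.subject_id),
                str(r.group),
                str(r.severity),
                float(r.tewl),
                stack,
                int(r.surface_depth_index_true),
                fp,
            )
        )
    return records
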