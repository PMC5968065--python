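"""Shared data model for VOI-based differential gene expression analysis.

The workflow compares microarray expression between two brain volumes of
interest (VOIs) derived from probabilistic cytoarchitectonic maps: tissue
samples with MNI coordinates are spatially filtered into the VOIs, probe
signals are aggregated per gene with a winsorized mean, and a permutation
n-way ANOVA with max-statistic family-wise-error correction tests the
VOI-label factor.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "ValidationError",
    "DegenerateDesignError",
    "ProbabilityVolume",
    "VoiMask",
    "TissueSample",
    "ExpressionSet",
    "VoiAssignment",
    "AnalysisConfig",
    "DiffExpressionResult",
    "validate_config",
]


class ValidationError(ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


class DegenerateDesignError(RuntimeError):
    """Statistically degenerate design: confounding, insufficient df (CLI exit code 3)."""


VOI_THRESHOLD_MIN = 10.0
VOI_THRESHOLD_MAX = 100.0


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValidationError("affine contains non-finite entries")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValidationError("affine is not invertible")
    return affine


@dataclass
class ProbabilityVolume:
    """A 3D probabilistic region map: voxel values are probabilities in percent.

    Each voxel holds the percentage of mapped brains in which the
    cytoarchitectonic area occupies that position. ``affine`` maps 0-based
    voxel indices to world coordinates in mm.
    """

    voxels: np.ndarray
    affine: np.ndarray
    space_tag: str = "MNI152"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError(
                f"probability volume must be 3D with positive shape, got {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("probability volume contains non-finite voxels")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < 0.0 or hi > 100.0:
            raise ValidationError(
                f"probability values must lie in [0, 100] percent, got range [{lo}, {hi}]"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class VoiMask:
    """Binary volume of interest obtained by thresholding a probability map."""

    voxels: np.ndarray
    affine: np.ndarray
    source_threshold_pct: float
    name: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError(
                f"mask must be 3D with positive shape, got {self.voxels.shape}"
            )
        self.affine = _check_affine(self.affine)
        t = float(self.source_threshold_pct)
        if not (VOI_THRESHOLD_MIN <= t <= VOI_THRESHOLD_MAX):
            raise ValidationError(
                f"source_threshold_pct must lie in [{VOI_THRESHOLD_MIN:g}, "
                f"{VOI_THRESHOLD_MAX:g}], got {t:g}"
            )
        self.source_threshold_pct = t

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class TissueSample:
    """One microarray tissue sample with a registered MNI coordinate.

    ``covariates`` carries the donor-level independent variables of the
    ANOVA: ``age`` (years, continuous), ``sex`` and ``ethnicity``
    (categorical).
    """

    sample_id: str
    donor_id: str
    mni_xyz: tuple[float, float, float]
    covariates: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not str(self.donor_id):
            raise ValidationError("donor_id must be non-empty")
        xyz = tuple(float(v) for v in self.mni_xyz)
        if len(xyz) != 3 or not all(math.isfinite(v) for v in xyz):
            raise ValidationError(f"mni_xyz must be 3 finite coordinates, got {self.mni_xyz}")
        self.mni_xyz = xyz  # type: ignore[assignment]


class ExpressionSet:
    """Probe-by-sample expression matrix with probe-to-gene annotation.

    Parameters
    ----------
    probes:
        DataFrame with columns ``probe_id``, ``probe_name``, ``gene_symbol``,
        ``entrez_id``; row order matches matrix row order.
    samples:
        Tissue samples; order matches matrix column order.
    z:
        Probe-by-sample matrix of expression values (z-scores if
        ``is_zscored``).
    """

    PROBE_COLUMNS = ("probe_id", "probe_name", "gene_symbol", "entrez_id")

    def __init__(self, probes, samples, z, is_zscored: bool = True):
        import pandas as pd

        probes = pd.DataFrame(probes).reset_index(drop=True)
        missing = [c for c in self.PROBE_COLUMNS if c not in probes.columns]
        if missing:
            raise ValidationError(f"probe table missing columns: {missing}")
        if probes["probe_id"].duplicated().any():
            dups = probes.loc[probes["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicate probe_id values: {dups[:5]}")
        bad = probes["gene_symbol"].isna() | (probes["gene_symbol"].astype(str) == "")
        if bad.any():
            raise ValidationError(
                "every probe must map to exactly one gene_symbol; "
                f"{int(bad.sum())} probes lack one"
            )
        z = np.asarray(z, dtype=float)
        if z.shape != (len(probes), len(samples)):
            raise ValidationError(
                f"matrix shape {z.shape} does not match {len(probes)} probes "
                f"x {len(samples)} samples"
            )
        if is_zscored and z.size and not np.all(np.isfinite(z)):
            raise ValidationError("z-scored matrix contains non-finite values")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id values across samples")
        self.probes = probes
        self.samples = list(samples)
        self.z = z
        self.is_zscored = bool(is_zscored)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def gene_symbols(self) -> list[str]:
        """Gene symbols in first-appearance order of the probe table."""
        seen: dict[str, None] = {}
        for g in self.probes["gene_symbol"]:
            seen.setdefault(g)
        return list(seen)

    def subset_samples(self, sample_ids) -> "ExpressionSet":
        wanted = list(sample_ids)
        index = {s.sample_id: i for i, s in enumerate(self.samples)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        cols = [index[sid] for sid in wanted]
        return ExpressionSet(
            self.probes.copy(),
            [self.samples[i] for i in cols],
            self.z[:, cols],
            self.is_zscored,
        )


@dataclass
class VoiAssignment:
    """VOI-specific labels (TSLs) assigned to tissue samples after spatial filtering."""

    labels: dict[str, str]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        excluded_ids = {sid for sid, _ in self.excluded}
        overlap = excluded_ids & set(self.labels)
        if overlap:
            raise ValidationError(
                f"samples both labeled and excluded: {sorted(overlap)[:5]}"
            )

    def voi_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v)
        return list(seen)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.labels.values():
            out[v] = out.get(v, 0) + 1
        return out


_CONFIG_DEFAULTS: dict[str, Any] = {
    "mode": "all_probes",
    "n_permutations": 10000,
    "alpha": 0.05,
    "voi_threshold_pct": 20.0,
    "winsor_lower_pct": 10.0,
    "winsor_upper_pct": 90.0,
    "rng_seed": 0,
}


@dataclass
class AnalysisConfig:
    """Run configuration.

    Defaults follow the tool's standard settings: 10,000 permutation rounds,
    alpha 0.05, VOI threshold 20%, winsorizing limits 10%/90%.
    """

    mode: str = "all_probes"
    n_permutations: int = 10000
    alpha: float = 0.05
    voi_threshold_pct: float = 20.0
    winsor_lower_pct: float = 10.0
    winsor_upper_pct: float = 90.0
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        unknown = set(d) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_CONFIG_DEFAULTS, **dict(d)}
        return validate_config(cls(**merged))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def validate_config(cfg: AnalysisConfig | Mapping[str, Any]) -> AnalysisConfig:
    """Fill defaults and reject out-of-range values.

    Raises
    ------
    ValidationError
        If the VOI threshold falls outside [10, 100], the winsorizing bounds
        cross, the permutation count is non-positive, or alpha is not in (0,1).
    """
    if isinstance(cfg, Mapping):
        return AnalysisConfig.from_dict(cfg)
    if cfg.mode not in ("all_probes", "single_probe"):
        raise ValidationError(
            f"mode must be 'all_probes' or 'single_probe', got {cfg.mode!r}"
        )
    cfg.n_permutations = int(cfg.n_permutations)
    if cfg.n_permutations < 1:
        raise ValidationError(f"n_permutations must be >= 1, got {cfg.n_permutations}")
    cfg.alpha = float(cfg.alpha)
    if not (0.0 < cfg.alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {cfg.alpha}")
    cfg.voi_threshold_pct = float(cfg.voi_threshold_pct)
    if not (VOI_THRESHOLD_MIN <= cfg.voi_threshold_pct <= VOI_THRESHOLD_MAX):
        raise ValidationError(
            f"voi_threshold_pct must lie in [{VOI_THRESHOLD_MIN:g}, "
            f"{VOI_THRESHOLD_MAX:g}], got {cfg.voi_threshold_pct:g}"
        )
    cfg.winsor_lower_pct = float(cfg.winsor_lower_pct)
    cfg.winsor_upper_pct = float(cfg.winsor_upper_pct)
    if not (0.0 <= cfg.winsor_lower_pct < cfg.winsor_upper_pct <= 100.0):
        raise ValidationError(
            "winsor limits must satisfy 0 <= lower < upper <= 100, got "
            f"({cfg.winsor_lower_pct:g}, {cfg.winsor_upper_pct:g})"
        )
    cfg.rng_seed = int(cfg.rng_seed)
    return cfg


@dataclass
class DiffExpressionResult:
    """Per-unit (gene or probe) outcome of the permutation ANOVA.

    ``p_fwe`` is corrected across the analyzed units via the permutation
    distribution of the maximum F, so ``p_fwe >= p_nominal`` always holds.
    ``per_sample_z`` maps each analyzed sample to its VOI label and the
    response value entered into the ANOVA (winsorized mean in all-probes
    mode, the raw probe z-score in single-probe mode).
    """

    unit_id: str
    gene_symbol: str
    f_observed: float
    df_effect: int
    df_error: int
    p_nominal: float
    p_fwe: float
    per_sample_z: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_nominal <= 1.0) or not (0.0 < self.p_fwe <= 1.0):
            raise ValidationError(
                f"p-values must lie in (0, 1]: nominal={self.p_nominal}, fwe={self.p_fwe}"
            )
        if self.p_fwe < self.p_nominal - 1e-12:
            raise ValidationError(
                f"p_fwe ({self.p_fwe}) must be >= p_nominal ({self.p_nominal})"
            )
        if not self.f_observed >= 0.0:
            raise ValidationError(f"f_observed must be >= 0, got {self.f_observed}")
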