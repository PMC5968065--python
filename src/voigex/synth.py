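"""Synthetic fixtures in the exact external formats the pipeline consumes.

Emulates a probabilistic-atlas / microarray study: two spherical
probability blobs stand in for cytoarchitectonic area maps, a small donor
cohort contributes tissue samples placed inside (and outside) the VOIs,
and probe-level z-scores are Gaussian noise with an optional group-mean
shift ("spike") on chosen genes. Defaults mirror the reference study
conditions: 6 donors, 12 + 18 samples in the two VOIs, 25 genes on the
z-score scale (sigma = 1).

Not modeled: raw microarray intensities, batch effects, spatial
autocorrelation of expression, heavy-tailed noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .types import (
    ExpressionSet,
    ProbabilityVolume,
    TissueSample,
    ValidationError,
    VoiAssignment,
    VoiMask,
)
from . import spatial
from .expression import write_donor_dir

__all__ = [
    "make_probability_maps",
    "make_cohort",
    "make_expression",
    "default_gene_table",
    "simulate_dataset",
    "write_fixture",
    "SyntheticDataset",
]

DEFAULT_SHAPE = (48, 32, 32)
DEFAULT_CENTER1 = (14.0, 16.0, 16.0)
DEFAULT_CENTER2 = (34.0, 16.0, 16.0)
DEFAULT_RADIUS_VOX = 9.0
DEFAULT_PEAK_PCT = 100.0

ETHNICITY_VOCAB = ("caucasian", "african-american", "hispanic")


def default_affine() -> np.ndarray:
    """1 mm isotropic grid with the volume center near the world origin."""
    aff = np.eye(4)
    aff[:3, 3] = (-24.0, -16.0, -16.0)
    return aff


def make_probability_maps(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    center1: Sequence[float] = DEFAULT_CENTER1,
    center2: Sequence[float] = DEFAULT_CENTER2,
    radius_vox: float = DEFAULT_RADIUS_VOX,
    peak_pct: float = DEFAULT_PEAK_PCT,
    affine: np.ndarray | None = None,
) -> tuple[ProbabilityVolume, ProbabilityVolume]:
    """Two spherical probability blobs decaying linearly from the center.

    Voxel value = peak_pct * max(0, 1 - d/radius) with d the distance to
    the center in voxel units; blobs overlap when the spheres intersect.
    """
    if radius_vox <= 0:
        raise ValidationError(f"radius_vox must be positive, got {radius_vox}")
    for c in (center1, center2):
        if not all(0 <= c[d] < shape[d] for d in range(3)):
            raise ValidationError(f"center {tuple(c)} outside shape {shape}")
    if affine is None:
        affine = default_affine()
    grid = np.indices(shape, dtype=float)

    def blob(center):
        d = np.sqrt(sum((grid[a] - center[a]) ** 2 for a in range(3)))
        return (peak_pct * np.clip(1.0 - d / radius_vox, 0.0, 1.0)).astype(np.float32)

    return (
        ProbabilityVolume(blob(center1), affine),
        ProbabilityVolume(blob(center2), affine),
    )


def _uniform_in_ball(rng: np.random.Generator, center, radius: float) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return np.asarray(center, dtype=float) + r * direction


def make_cohort(
    n_donors: int = 6,
    samples_per_voi: tuple[int, int] = (12, 18),
    n_background: int = 0,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    center1: Sequence[float] = DEFAULT_CENTER1,
    center2: Sequence[float] = DEFAULT_CENTER2,
    radius_vox: float = DEFAULT_RADIUS_VOX,
    affine: np.ndarray | None = None,
    placement_radius_vox: float | None = None,
) -> list[TissueSample]:
    """Tissue samples placed uniformly inside each VOI sphere plus background.

    Donors are assigned round-robin across samples; age, sex and ethnicity
    are per-donor attributes (so they are fully determined by the donor
    factor, as in the real cohort). Background samples land inside the
    volume but outside both spheres. Sample placement stays well inside
    the spheres (default 55% of the blob radius) so that thresholding at
    the default 20% recovers the constructed membership exactly.
    """
    if n_donors < 1:
        raise ValidationError("n_donors must be >= 1")
    if affine is None:
        affine = default_affine()
    if placement_radius_vox is None:
        placement_radius_vox = 0.55 * radius_vox
    rng = np.random.default_rng(seed)

    ages = rng.integers(24, 58, size=n_donors)
    sexes = ["F"] + ["M"] * (n_donors - 1)
    ethnicities = [ETHNICITY_VOCAB[int(rng.integers(len(ETHNICITY_VOCAB)))] for _ in range(n_donors)]
    donors = [
        (
            f"donor{d + 1:02d}",
            {"age": int(ages[d]), "sex": sexes[d], "ethnicity": ethnicities[d]},
        )
        for d in range(n_donors)
    ]

    positions: list[np.ndarray] = []
    for center, count in zip((center1, center2), samples_per_voi):
        for _ in range(count):
            positions.append(_uniform_in_ball(rng, center, placement_radius_vox))
    for _ in range(n_background):
        for _attempt in range(10000):
            p = rng.uniform([0.5] * 3, np.asarray(shape, dtype=float) - 1.5)
            far1 = np.linalg.norm(p - np.asarray(center1)) > radius_vox + 1.0
            far2 = np.linalg.norm(p - np.asarray(center2)) > radius_vox + 1.0
            if far1 and far2:
                positions.append(p)
                break
        else:
            raise ValidationError("could not place a background sample outside both VOIs")

    samples = []
    for i, vox in enumerate(positions):
        donor_id, covars = donors[i % n_donors]
        world = (affine @ np.append(vox, 1.0))[:3]
        samples.append(
            TissueSample(
                sample_id=f"S{i + 1:04d}",
                donor_id=donor_id,
                mni_xyz=tuple(world),
                covariates=dict(covars),
            )
        )
    return samples


def default_gene_table(n_genes: int = 25, seed: int = 0) -> dict[str, int]:
    """Synthetic gene symbols with realistic probe counts (1-8, mean ~3)."""
    rng = np.random.default_rng(seed)
    counts = 1 + rng.geometric(0.4, size=n_genes)
    return {
        f"GENE{i + 1:03d}": int(min(c, 8)) for i, c in enumerate(counts)
    }


def make_expression(
    samples: Sequence[TissueSample],
    genes_with_probe_counts: Mapping[str, int],
    spiked_effects: Mapping[str, float] | None = None,
    sigma: float = 1.0,
    seed: int = 0,
    labels: Mapping[str, str] | VoiAssignment | None = None,
) -> ExpressionSet:
    """Probe z-scores ~ Normal(mu, sigma^2) with spiked group-mean shifts.

    For a gene spiked with effect ``delta``, every probe of that gene has
    mean +delta/2 in samples of the second VOI (sorted label order) and
    -delta/2 in the first; all other means are 0. ``labels`` maps
    sample_id to VOI name (a VoiAssignment works directly); unlabeled
    samples stay at mean 0.
    """
    import pandas as pd

    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    spiked = dict(spiked_effects or {})
    unknown = set(spiked) - set(genes_with_probe_counts)
    if unknown:
        raise ValidationError(f"spiked effects reference unknown genes: {sorted(unknown)}")
    if isinstance(labels, VoiAssignment):
        labels = labels.labels
    labels = dict(labels or {})
    voi_names = sorted(set(labels.values()))
    if labels and len(voi_names) != 2:
        raise ValidationError(f"labels must use exactly two VOI names, got {voi_names}")

    sign = np.zeros(len(samples))
    for j, s in enumerate(samples):
        lab = labels.get(s.sample_id)
        if lab is not None:
            sign[j] = -0.5 if lab == voi_names[0] else +0.5

    rows = []
    probe_counter = 0
    for gene, k in genes_with_probe_counts.items():
        if k < 1:
            raise ValidationError(f"gene {gene!r} must have >= 1 probes, got {k}")
        for p in range(k):
            probe_counter += 1
            rows.append(
                {
                    "probe_id": f"P{probe_counter:06d}",
                    "probe_name": f"{gene}_p{p + 1}",
                    "gene_symbol": gene,
                    "entrez_id": 1000 + list(genes_with_probe_counts).index(gene),
                }
            )
    probes = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    mu = np.zeros((len(probes), len(samples)))
    gene_col = probes["gene_symbol"].to_numpy()
    for gene, delta in spiked.items():
        mu[gene_col == gene] = delta * sign[None, :]
    z = mu + rng.normal(0.0, sigma, size=mu.shape)
    return ExpressionSet(probes, list(samples), z, is_zscored=True)


@dataclass
class SyntheticDataset:
    """A fully materialized synthetic study, with ground truth attached."""

    vol1: ProbabilityVolume
    vol2: ProbabilityVolume
    mask1: VoiMask
    mask2: VoiMask
    samples: list[TissueSample]
    assignment: VoiAssignment
    expression: ExpressionSet
    gene_probe_counts: dict[str, int]
    spiked_effects: dict[str, float] = field(default_factory=dict)


def simulate_dataset(
    n_genes: int = 25,
    spiked_effects: Mapping[str, float] | None = None,
    samples_per_voi: tuple[int, int] = (12, 18),
    n_donors: int = 6,
    n_background: int = 0,
    sigma: float = 1.0,
    threshold_pct: float = 20.0,
    seed: int = 0,
    gene_probe_counts: Mapping[str, int] | None = None,
) -> SyntheticDataset:
    """Compose maps, cohort and expression into one coherent study.

    The expression spikes are keyed to the *actual* spatial assignment of
    the generated samples (VOI1 = first blob, VOI2 = second), so the
    generator's ground truth and the pipeline's label assignment agree by
    construction.
    """
    ss = np.random.SeedSequence(seed)
    seed_cohort, seed_expr = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    vol1, vol2 = make_probability_maps()
    mask1 = spatial.threshold_map(vol1, threshold_pct, "VOI1")
    mask2 = spatial.threshold_map(vol2, threshold_pct, "VOI2")
    samples = make_cohort(
        n_donors=n_donors,
        samples_per_voi=samples_per_voi,
        n_background=n_background,
        seed=seed_cohort,
    )
    assignment = spatial.assign_samples(samples, mask1, mask2, vol1, vol2)
    genes = dict(gene_probe_counts or default_gene_table(n_genes, seed=0))
    expression = make_expression(
        samples,
        genes,
        spiked_effects=spiked_effects,
        sigma=sigma,
        seed=seed_expr,
        labels=assignment,
    )
    return SyntheticDataset(
        vol1=vol1,
        vol2=vol2,
        mask1=mask1,
        mask2=mask2,
        samples=samples,
        assignment=assignment,
        expression=expression,
        gene_probe_counts=genes,
        spiked_effects=dict(spiked_effects or {}),
    )


def write_fixture(ds: SyntheticDataset, outdir, compress: bool = False) -> dict[str, str]:
    """Materialize a dataset to disk in the external formats.

    Writes ``voi1_prob.nii``/``voi2_prob.nii`` (``.nii.gz`` when
    ``compress``) and one Allen-layout directory per donor under
    ``microarray/``. Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    p1 = outdir / f"voi1_prob{ext}"
    p2 = outdir / f"voi2_prob{ext}"
    spatial.write_probability_volume(ds.vol1, p1)
    spatial.write_probability_volume(ds.vol2, p2)

    micro = outdir / "microarray"
    donor_order: dict[str, list[int]] = {}
    for j, s in enumerate(ds.expression.samples):
        donor_order.setdefault(s.donor_id, []).append(j)
    for donor_id, cols in donor_order.items():
        sub = ds.expression.subset_samples(
            [ds.expression.samples[j].sample_id for j in cols]
        )
        write_donor_dir(sub, micro / donor_id)
    return {"voi1": str(p1), "voi2": str(p2), "microarray": str(micro)}
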