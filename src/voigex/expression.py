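"""Reading, normalizing and aggregating microarray expression data.

Expects the Allen Human Brain Atlas microarray download layout, one
directory per donor:

* ``SampleAnnot.csv`` — one row per tissue sample, including a sample
  identifier (``sample_id`` or ``well_id``) and MNI coordinates
  ``mni_x``/``mni_y``/``mni_z``;
* ``Probes.csv`` — ``probe_id``, ``probe_name``, ``gene_symbol``,
  ``entrez_id``;
* ``MicroarrayExpression.csv`` — no header; first column probe_id, one
  column per sample in annotation order;
* ``DonorInfo.json`` — sidecar with ``donor_id``, ``age``, ``sex``,
  ``ethnicity``.

Expression values are z-scores; a raw-value path can z-score per probe
within each donor. In all-probes mode, a gene's probes are aggregated per
sample with a winsorized mean (default 10%/90% limits), which is robust to
outlying probe signals.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AnalysisConfig,
    ExpressionSet,
    TissueSample,
    ValidationError,
    VoiAssignment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_donor_expression",
    "read_donor_dir",
    "read_cohort",
    "write_donor_dir",
    "concat_expression",
    "zscore_per_probe",
    "select_genes",
    "winsorized_mean",
    "aggregate_all_probes",
]

SAMPLE_ID_COLUMNS = ("sample_id", "well_id")
MNI_COLUMNS = ("mni_x", "mni_y", "mni_z")


def _sample_id_column(annot: pd.DataFrame) -> str:
    for c in SAMPLE_ID_COLUMNS:
        if c in annot.columns:
            return c
    raise ValidationError(
        f"sample annotation needs one of the identifier columns {SAMPLE_ID_COLUMNS}"
    )


def read_donor_expression(
    sample_annot_path,
    probes_path,
    expression_path,
    donor_id: str | None = None,
    donor_meta: Mapping | None = None,
    is_zscored: bool = True,
) -> ExpressionSet:
    """Read one donor's annotation, probe table and expression matrix.

    ``donor_meta`` supplies the donor covariates (``age``, ``sex``,
    ``ethnicity``) attached to every sample; ``donor_id`` defaults to the
    value in ``donor_meta``.
    """
    # round_trip parsing keeps write -> read -> write lossless to the last ulp
    annot = pd.read_csv(sample_annot_path, float_precision="round_trip")
    for c in MNI_COLUMNS:
        if c not in annot.columns:
            raise ValidationError(f"{sample_annot_path}: missing required column {c!r}")
    id_col = _sample_id_column(annot)

    probes = pd.read_csv(probes_path)
    missing = [c for c in ExpressionSet.PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValidationError(f"{probes_path}: missing required columns {missing}")
    if probes["probe_id"].duplicated().any():
        raise ValidationError(f"{probes_path}: duplicate probe_id values")
    no_gene = probes["gene_symbol"].isna() | (probes["gene_symbol"].astype(str) == "")
    if no_gene.any():
        warnings.warn(
            f"{probes_path}: dropping {int(no_gene.sum())} probes without a gene_symbol",
            stacklevel=2,
        )
        probes = probes.loc[~no_gene].reset_index(drop=True)

    expr = pd.read_csv(expression_path, header=None, float_precision="round_trip")
    if expr.shape[1] - 1 != len(annot):
        raise ValidationError(
            f"{expression_path}: {expr.shape[1] - 1} sample columns but "
            f"{len(annot)} annotation rows"
        )
    expr = expr.set_index(0)
    unknown = set(probes["probe_id"]) - set(expr.index)
    if unknown:
        raise ValidationError(
            f"{expression_path}: probes missing from matrix: {sorted(unknown)[:5]}"
        )
    z = expr.loc[probes["probe_id"]].to_numpy(dtype=float)

    donor_meta = dict(donor_meta or {})
    donor = str(donor_id or donor_meta.get("donor_id") or "")
    if not donor:
        raise ValidationError("donor_id must be given directly or via donor_meta")
    covars = {k: donor_meta[k] for k in ("age", "sex", "ethnicity") if k in donor_meta}
    samples = [
        TissueSample(
            sample_id=str(row[id_col]),
            donor_id=donor,
            mni_xyz=(row["mni_x"], row["mni_y"], row["mni_z"]),
            covariates=dict(covars),
        )
        for _, row in annot.iterrows()
    ]
    return ExpressionSet(probes, samples, z, is_zscored=is_zscored)


def read_donor_dir(path, is_zscored: bool = True) -> ExpressionSet:
    """Read one donor directory (SampleAnnot/Probes/MicroarrayExpression/DonorInfo)."""
    path = Path(path)
    meta_path = path / "DonorInfo.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return read_donor_expression(
        path / "SampleAnnot.csv",
        path / "Probes.csv",
        path / "MicroarrayExpression.csv",
        donor_id=meta.get("donor_id", path.name),
        donor_meta=meta,
        is_zscored=is_zscored,
    )


def concat_expression(sets: Sequence[ExpressionSet]) -> ExpressionSet:
    """Concatenate per-donor sets sharing an identical probe table."""
    if not sets:
        raise ValidationError("no expression sets to concatenate")
    first = sets[0]
    for es in sets[1:]:
        if not first.probes["probe_id"].equals(es.probes["probe_id"]):
            raise ValidationError("probe tables differ between donors")
        if es.is_zscored != first.is_zscored:
            raise ValidationError("mixing z-scored and raw donors")
    samples = [s for es in sets for s in es.samples]
    z = np.hstack([es.z for es in sets])
    return ExpressionSet(first.probes.copy(), samples, z, first.is_zscored)


def read_cohort(root, is_zscored: bool = True) -> ExpressionSet:
    """Read every donor directory under ``root`` and concatenate."""
    root = Path(root)
    donor_dirs = sorted(p for p in root.iterdir() if (p / "SampleAnnot.csv").exists())
    if not donor_dirs:
        raise ValidationError(f"{root}: no donor directories with SampleAnnot.csv found")
    return concat_expression([read_donor_dir(p, is_zscored) for p in donor_dirs])


def write_donor_dir(es: ExpressionSet, path) -> None:
    """Write a single-donor ExpressionSet back into the Allen CSV layout."""
    donors = {s.donor_id for s in es.samples}
    if len(donors) != 1:
        raise ValidationError(f"write_donor_dir expects one donor, got {sorted(donors)}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    annot = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in es.samples],
            "mni_x": [s.mni_xyz[0] for s in es.samples],
            "mni_y": [s.mni_xyz[1] for s in es.samples],
            "mni_z": [s.mni_xyz[2] for s in es.samples],
        }
    )
    annot.to_csv(path / "SampleAnnot.csv", index=False)
    es.probes.to_csv(path / "Probes.csv", index=False)
    expr = pd.DataFrame(es.z, index=es.probes["probe_id"].to_numpy())
    expr.to_csv(path / "MicroarrayExpression.csv", header=False)
    s0 = es.samples[0]
    meta = {"donor_id": s0.donor_id, **{k: s0.covariates.get(k) for k in ("age", "sex", "ethnicity")}}
    (path / "DonorInfo.json").write_text(json.dumps(meta, indent=2) + "\n")


def zscore_per_probe(es: ExpressionSet) -> ExpressionSet:
    """Z-score each probe within each donor (mean 0, sample sd 1, n-1 denominator).

    Constant probe rows within a donor become all-zero with a warning.
    Refuses input already flagged as z-scored.
    """
    if es.is_zscored:
        raise ValidationError("expression set is already z-scored")
    z = np.array(es.z, dtype=float)
    donor_of = np.array([s.donor_id for s in es.samples])
    n_constant = 0
    for donor in dict.fromkeys(donor_of):
        cols = np.flatnonzero(donor_of == donor)
        if cols.size < 2:
            raise ValidationError(
                f"donor {donor!r} has {cols.size} sample(s); need >= 2 to z-score"
            )
        block = z[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        const = sd[:, 0] == 0.0
        n_constant += int(const.sum())
        sd[const] = 1.0
        z[:, cols] = (block - mu) / sd
        z[np.ix_(const, cols)] = 0.0
    if n_constant:
        warnings.warn(
            f"{n_constant} constant probe/donor rows z-scored to all-zero", stacklevel=2
        )
    return ExpressionSet(es.probes.copy(), es.samples, z, is_zscored=True)


def select_genes(es: ExpressionSet, gene_symbols: Iterable[str]) -> ExpressionSet:
    """Restrict to the probes of the requested genes.

    Requested symbols without any probe are reported with a warning; an
    entirely empty selection is an error naming the missing symbols.
    """
    requested = list(dict.fromkeys(gene_symbols))
    have = set(es.probes["gene_symbol"])
    absent = [g for g in requested if g not in have]
    if absent:
        if len(absent) == len(requested):
            raise ValidationError(f"no probes found for requested genes: {absent}")
        warnings.warn(f"requested genes without probes: {absent}", stacklevel=2)
    keep = es.probes["gene_symbol"].isin(requested).to_numpy()
    return ExpressionSet(
        es.probes.loc[keep].reset_index(drop=True),
        es.samples,
        es.z[keep],
        es.is_zscored,
    )


def winsorized_mean(
    values, lower_pct: float = 10.0, upper_pct: float = 90.0
) -> float:
    """Winsorized mean: clamp extreme order statistics, then average.

    With n values and limits (l, u): the k_low = floor(n*l/100) smallest
    values are replaced by the (k_low+1)-th order statistic and the
    k_high = floor(n*(100-u)/100) largest by the (n-k_high)-th, then the
    arithmetic mean of the clamped values is returned. At the default
    10/90 limits and n <= 10 at most one value is clamped per tail.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValidationError("winsorized_mean of empty input")
    if not (0.0 <= lower_pct < upper_pct <= 100.0):
        raise ValidationError(
            f"winsor limits must satisfy 0 <= lower < upper <= 100, got "
            f"({lower_pct:g}, {upper_pct:g})"
        )
    k_low = math.floor(n * lower_pct / 100.0)
    k_high = math.floor(n * (100.0 - upper_pct) / 100.0)
    if k_low:
        v[:k_low] = v[k_low]
    if k_high:
        v[-k_high:] = v[n - k_high - 1]
    return float(v.mean())


def aggregate_all_probes(
    es: ExpressionSet,
    assignment: VoiAssignment,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Gene-by-sample matrix of winsorized means over each gene's probes.

    Winsorizing is applied across the probes of one gene within one sample.
    Only samples labeled in ``assignment`` are kept, in expression-set
    order. Genes appear in first-appearance order of the probe table.
    """
    keep = [s.sample_id for s in es.samples if s.sample_id in assignment.labels]
    if not keep:
        raise ValidationError("no labeled samples present in the expression set")
    sub = es.subset_samples(keep)
    genes = sub.gene_symbols
    rows = np.empty((len(genes), sub.n_samples), dtype=float)
    gene_col = sub.probes["gene_symbol"].to_numpy()
    for gi, gene in enumerate(genes):
        probe_rows = np.flatnonzero(gene_col == gene)
        if probe_rows.size == 0:
            raise ValidationError(f"gene {gene!r} has no probes")
        block = sub.z[probe_rows]
        if probe_rows.size == 1:
            rows[gi] = block[0]
        else:
            for si in range(sub.n_samples):
                rows[gi, si] = winsorized_mean(
                    block[:, si], cfg.winsor_lower_pct, cfg.winsor_upper_pct
                )
    return pd.DataFrame(rows, index=genes, columns=keep)
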