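"""Permutation n-way ANOVA with max-statistic family-wise-error correction.

The z-scores of the labeled tissue samples are the dependent variable;
VOI label (TSL, the factor-of-interest), donor, age, sex and ethnicity are
independent variables, main effects only. The observed F for the TSL
factor is the full-vs-reduced model-comparison F

    F = ((SSE_reduced - SSE_full) / df_effect) / (SSE_full / df_error),

the reduced model dropping only the TSL term. The null distribution is
built by randomly shuffling the TSLs between VOIs under label
exchangeability; one shared relabeling per round is applied to every
analysis unit so that the per-round maximum F across units is a valid
family-wise null, from which FWE-corrected p-values are read off.

Covariates that are exactly collinear with earlier terms (in the Allen
cohort, donor fully determines age, sex and ethnicity) are detected by
rank inspection and dropped deterministically, in the order
ethnicity -> sex -> age before donor is ever touched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AnalysisConfig,
    DegenerateDesignError,
    DiffExpressionResult,
    ExpressionSet,
    TissueSample,
    ValidationError,
    VoiAssignment,
    validate_config,
)
from .expression import aggregate_all_probes

logger = logging.getLogger(__name__)

__all__ = [
    "DesignTable",
    "build_design",
    "anova_f",
    "permute_labels",
    "permutation_pvalues",
    "run_analysis",
    "results_frame",
    "write_results_tsv",
    "write_results_json",
]

# relative tolerance for rank / aliasing decisions
_RANK_TOL = 1e-8


@dataclass
class DesignTable:
    """Response and factors for one analysis unit (gene or probe)."""

    unit_id: str
    gene_symbol: str
    sample_ids: list[str]
    response: np.ndarray
    tsl: np.ndarray
    donor: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    ethnicity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.response = np.asarray(self.response, dtype=float)
        self.tsl = np.asarray(self.tsl, dtype=object)
        self.donor = np.asarray(self.donor, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.ethnicity = np.asarray(self.ethnicity, dtype=object)
        for name in ("response", "tsl", "donor", "age", "sex", "ethnicity"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name!r} length mismatch")
        if not np.all(np.isfinite(self.response)):
            raise ValidationError(f"unit {self.unit_id!r}: non-finite response values")
        if not np.all(np.isfinite(self.age)):
            raise ValidationError(f"unit {self.unit_id!r}: missing age values")
        levels, counts = np.unique(self.tsl.astype(str), return_counts=True)
        if len(levels) != 2:
            raise DegenerateDesignError(
                f"TSL factor must have exactly 2 levels, got {list(levels)}"
            )
        if counts.min() < 2:
            raise DegenerateDesignError(
                "each VOI needs >= 2 labeled samples, got "
                + ", ".join(f"{l}: {c}" for l, c in zip(levels, counts))
            )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def tsl_levels(self) -> list[str]:
        return sorted(set(self.tsl.astype(str)))

    def tsl_dummy(self) -> np.ndarray:
        """Indicator of the second (sorted) TSL level."""
        return (self.tsl.astype(str) == self.tsl_levels()[1]).astype(float)


def _dummies(values: np.ndarray) -> list[np.ndarray]:
    """Drop-first indicator columns over the sorted levels of a factor."""
    levels = sorted(set(values.astype(str)))
    return [(values.astype(str) == lev).astype(float) for lev in levels[1:]]


def _covariate_basis(dt: DesignTable) -> tuple[np.ndarray, list[str]]:
    """Orthonormal basis of the covariate (nuisance) design, with alias pruning.

    Blocks are admitted in priority order intercept, donor, age, sex,
    ethnicity; a column adding no rank is dropped, so fully aliased
    covariates vanish in the reverse order ethnicity, sex, age before donor.
    Returns the basis and the names of covariates dropped entirely.
    """
    n = dt.n
    blocks: list[tuple[str, list[np.ndarray]]] = [
        ("intercept", [np.ones(n)]),
        ("donor", _dummies(dt.donor)),
        ("age", [dt.age - dt.age.mean()]),
        ("sex", _dummies(dt.sex)),
        ("ethnicity", _dummies(dt.ethnicity)),
    ]
    basis: list[np.ndarray] = []
    dropped: list[str] = []
    for name, cols in blocks:
        kept = 0
        for c in cols:
            r = c.astype(float)
            for _ in range(2):  # re-orthogonalize for stability
                for q in basis:
                    r = r - (q @ r) * q
            norm = np.linalg.norm(r)
            if norm > _RANK_TOL * (np.linalg.norm(c) + 1.0):
                basis.append(r / norm)
                kept += 1
        if name != "intercept" and kept == 0:
            dropped.append(name)
    if dropped:
        warnings.warn(
            f"covariates aliased with earlier terms, dropped: {dropped}", stacklevel=3
        )
    return np.column_stack(basis), dropped


def _residualize(Q: np.ndarray, x: np.ndarray) -> np.ndarray:
    r = x - Q @ (Q.T @ x)
    return r - Q @ (Q.T @ r)  # second pass for numerical hygiene


def anova_f(dt: DesignTable) -> tuple[float, int, int]:
    """Observed model-comparison F for the TSL factor: (F, df_effect, df_error).

    Raises DegenerateDesignError when TSL is aliased with the remaining
    covariates (confounded design) or error degrees of freedom vanish.
    """
    Q, _ = _covariate_basis(dt)
    f, df_e, df_err, _ = _f_given_basis(Q, dt.tsl_dummy(), dt.response[None, :], dt.n)
    return float(f[0]), df_e, df_err


def _f_given_basis(
    Q: np.ndarray, t: np.ndarray, Y: np.ndarray, n: int
) -> tuple[np.ndarray, int, int, np.ndarray]:
    """F for adding the single TSL column to the covariate basis, per row of Y."""
    rt = _residualize(Q, t)
    s = float(rt @ rt)
    if s <= _RANK_TOL * n:
        raise DegenerateDesignError(
            "TSL factor is confounded with the remaining covariates"
        )
    df_effect = 1
    df_error = n - Q.shape[1] - 1
    if df_error <= 0:
        raise DegenerateDesignError(f"no error degrees of freedom (df_error={df_error})")
    Ry = Y - (Y @ Q) @ Q.T
    sse_red = np.einsum("ij,ij->i", Ry, Ry)
    num = (Ry @ rt) ** 2 / s
    sse_full = np.maximum(sse_red - num, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(num == 0.0, 0.0, num / (sse_full / df_error))
    return f, df_effect, df_error, sse_red


def permute_labels(tsl: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random rearrangement of the label vector (group sizes preserved)."""
    return rng.permutation(np.asarray(tsl))


def build_design(
    matrix: pd.DataFrame,
    samples: Sequence[TissueSample],
    assignment: VoiAssignment,
    gene_symbols: Mapping[str, str] | None = None,
) -> list[DesignTable]:
    """One DesignTable per analysis unit (matrix row), covariates from samples.

    ``matrix`` is unit-by-sample with sample_id columns; every labeled
    sample must have a column. ``gene_symbols`` maps unit_id to gene
    symbol (defaults to the unit_id itself, as in all-probes mode).
    """
    by_id = {s.sample_id: s for s in samples}
    labeled = [sid for sid in matrix.columns if sid in assignment.labels]
    missing = set(assignment.labels) - set(matrix.columns)
    if missing:
        raise ValidationError(
            f"labeled samples missing from the matrix: {sorted(missing)[:5]}"
        )
    tsl = np.array([assignment.labels[sid] for sid in labeled], dtype=object)
    covs: dict[str, list] = {"donor": [], "age": [], "sex": [], "ethnicity": []}
    for sid in labeled:
        s = by_id.get(sid)
        if s is None:
            raise ValidationError(f"sample {sid!r} has no metadata record")
        covs["donor"].append(s.donor_id)
        for key in ("age", "sex", "ethnicity"):
            if key not in s.covariates or s.covariates[key] is None:
                raise ValidationError(f"sample {sid!r} is missing covariate {key!r}")
            covs[key].append(s.covariates[key])
    sub = matrix[labeled]
    tables = [
        DesignTable(
            unit_id=str(unit),
            gene_symbol=str((gene_symbols or {}).get(unit, unit)),
            sample_ids=list(labeled),
            response=sub.loc[unit].to_numpy(dtype=float),
            tsl=tsl,
            donor=np.array(covs["donor"], dtype=object),
            age=np.array(covs["age"], dtype=float),
            sex=np.array(covs["sex"], dtype=object),
            ethnicity=np.array(covs["ethnicity"], dtype=object),
        )
        for unit in matrix.index
    ]
    if not tables:
        raise ValidationError("no analysis units in the matrix")
    return tables


def _check_shared_design(tables: Sequence[DesignTable]) -> None:
    first = tables[0]
    for dt in tables[1:]:
        same = (
            dt.sample_ids == first.sample_ids
            and np.array_equal(dt.tsl, first.tsl)
            and np.array_equal(dt.donor, first.donor)
            and np.array_equal(dt.age, first.age)
            and np.array_equal(dt.sex, first.sex)
            and np.array_equal(dt.ethnicity, first.ethnicity)
        )
        if not same:
            raise ValidationError(
                "all analysis units must share the same samples, labels and covariates"
            )


def permutation_pvalues(
    tables: Sequence[DesignTable],
    n_permutations: int,
    rng_seed: int,
    report: dict | None = None,
) -> list[DiffExpressionResult]:
    """Nominal and max-statistic FWE-corrected permutation p-values.

    One shared random relabeling per round is applied to every unit. With R
    valid rounds and b exceedances, p = (1 + b) / (1 + R) (add-one
    convention, ties F_perm = F_obs counted as exceedances). The FWE p uses
    the per-round maximum F across all units. Rounds whose relabeling is
    aliased with the covariates cannot be fit; they are excluded from R
    with a warning.
    """
    if n_permutations < 1:
        raise ValidationError(f"n_permutations must be >= 1, got {n_permutations}")
    if not tables:
        raise ValidationError("no analysis units")
    _check_shared_design(tables)
    first = tables[0]
    n = first.n
    Q, dropped = _covariate_basis(first)
    t_obs = first.tsl_dummy()
    Y = np.vstack([dt.response for dt in tables])

    f_obs, df_effect, df_error, _ = _f_given_basis(Q, t_obs, Y, n)

    rng = np.random.default_rng(rng_seed)
    T = rng.permuted(np.tile(t_obs[:, None], (1, n_permutations)), axis=0)
    Rt = T - Q @ (Q.T @ T)
    Rt -= Q @ (Q.T @ Rt)
    s = np.einsum("ij,ij->j", Rt, Rt)
    valid = s > _RANK_TOL * n
    n_failed = int((~valid).sum())
    if n_failed:
        warnings.warn(
            f"{n_failed} permutation rounds produced a degenerate relabeling "
            "and were excluded",
            stacklevel=2,
        )
    r_valid = int(valid.sum())
    if r_valid == 0:
        raise DegenerateDesignError("all permutation rounds failed to fit")

    Ry = Y - (Y @ Q) @ Q.T
    sse_red = np.einsum("ij,ij->i", Ry, Ry)
    num = (Ry @ Rt[:, valid]) ** 2 / s[valid]
    sse_full = np.maximum(sse_red[:, None] - num, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = np.where(num == 0.0, 0.0, num / (sse_full / df_error))

    # ties F_perm == F_obs count as exceedances; tiny relative slack guards fp noise
    thresh = f_obs[:, None] * (1.0 - 1e-12) - 1e-12
    b_nom = (f_perm >= thresh).sum(axis=1)
    max_f = f_perm.max(axis=0)
    b_fwe = (max_f[None, :] >= thresh).sum(axis=1)
    p_nom = (1.0 + b_nom) / (1.0 + r_valid)
    p_fwe = (1.0 + b_fwe) / (1.0 + r_valid)

    if report is not None:
        report["dropped_covariates"] = dropped
        report["n_permutations_valid"] = r_valid
        report["n_permutations_failed"] = n_failed
        report["df_effect"] = df_effect
        report["df_error"] = df_error

    results = []
    for i, dt in enumerate(tables):
        per_sample = {
            sid: (str(lab), float(val))
            for sid, lab, val in zip(dt.sample_ids, dt.tsl, dt.response)
        }
        results.append(
            DiffExpressionResult(
                unit_id=dt.unit_id,
                gene_symbol=dt.gene_symbol,
                f_observed=float(f_obs[i]),
                df_effect=df_effect,
                df_error=df_error,
                p_nominal=float(p_nom[i]),
                p_fwe=float(p_fwe[i]),
                per_sample_z=per_sample,
            )
        )
    return results


def run_analysis(
    es: ExpressionSet,
    assignment: VoiAssignment,
    cfg: AnalysisConfig,
    report: dict | None = None,
) -> list[DiffExpressionResult]:
    """End-to-end differential expression between the two VOIs.

    In all-probes mode the units are genes (winsorized-mean aggregation
    across each gene's probes); in single-probe mode the units are
    individual probes with their raw z-scores. Results are sorted by
    ``p_fwe`` ascending, ties broken by ``f_observed`` descending then
    ``unit_id``.
    """
    cfg = validate_config(cfg)
    counts = assignment.counts()
    if len(counts) != 2 or min(counts.values()) < 2:
        raise DegenerateDesignError(
            f"need two VOIs with >= 2 labeled samples each, got {counts}"
        )
    if cfg.mode == "all_probes":
        matrix = aggregate_all_probes(es, assignment, cfg)
        gene_map = None
    else:
        keep = [s.sample_id for s in es.samples if s.sample_id in assignment.labels]
        sub = es.subset_samples(keep)
        matrix = pd.DataFrame(
            sub.z, index=sub.probes["probe_id"].astype(str).to_numpy(), columns=keep
        )
        gene_map = dict(
            zip(sub.probes["probe_id"].astype(str), sub.probes["gene_symbol"].astype(str))
        )
    tables = build_design(matrix, es.samples, assignment, gene_symbols=gene_map)
    results = permutation_pvalues(
        tables, cfg.n_permutations, cfg.rng_seed, report=report
    )
    results.sort(key=lambda r: (r.p_fwe, -r.f_observed, r.unit_id))
    if report is not None:
        report["n_units"] = len(results)
        report["voi_counts"] = counts
    return results


def results_frame(
    results: Sequence[DiffExpressionResult], assignment: VoiAssignment
) -> pd.DataFrame:
    """Tabular view of results (textual output)."""
    counts = assignment.counts()
    names = sorted(counts)
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "gene_symbol": [r.gene_symbol for r in results],
            "f_observed": [r.f_observed for r in results],
            "df_effect": [r.df_effect for r in results],
            "df_error": [r.df_error for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "p_fwe": [r.p_fwe for r in results],
            "n_voi1": counts[names[0]],
            "n_voi2": counts[names[1]],
        }
    )


def write_results_tsv(
    results: Sequence[DiffExpressionResult], assignment: VoiAssignment, path
) -> None:
    results_frame(results, assignment).to_csv(path, sep="\t", index=False)


def write_results_json(
    results: Sequence[DiffExpressionResult], assignment: VoiAssignment, path
) -> None:
    """Full results including the analyzed per-sample z-scores."""
    import json

    payload = []
    for r in results:
        payload.append(
            {
                "unit_id": r.unit_id,
                "gene_symbol": r.gene_symbol,
                "f_observed": r.f_observed,
                "df_effect": r.df_effect,
                "df_error": r.df_error,
                "p_nominal": r.p_nominal,
                "p_fwe": r.p_fwe,
                "per_sample_z": {
                    sid: {"voi": voi, "z": z} for sid, (voi, z) in r.per_sample_z.items()
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(
            {"results": payload, "excluded_samples": assignment.excluded},
            fh,
            indent=2,
        )
        fh.write("\n")
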