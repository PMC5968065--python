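# Methods

## Model and procedure

voigex tests whether gene expression differs between two brain volumes of
interest (VOIs) defined on a probabilistic cytoarchitectonic atlas. The
analysis is a permutation n-way ANOVA on spatially filtered microarray
tissue samples:

* **Response**: per-sample expression z-scores — the winsorized mean over
  a gene's probes in *all-probes* mode, or one probe's raw z-scores in
  *single-probe* mode.
* **Factors (main effects only)**: the VOI label (TSL, factor of
  interest), donor, age, sex, ethnicity. Age is modeled as a continuous
  covariate; sex and ethnicity as categoricals. No interaction terms are
  fitted.
* **Observed statistic**: the model-comparison F between the full
  main-effects model and the model without the TSL term,
  `F = ((SSE_red − SSE_full)/df_effect)/(SSE_full/df_error)`. With two
  VOI levels, `df_effect = 1`.
* **Null distribution**: TSLs are shuffled uniformly between VOIs
  (group sizes preserved) under label exchangeability. One shared
  relabeling per round is applied to every analysis unit; this is what
  makes the per-round maximum F across units a valid family-wise null.
* **p-values**: with R valid rounds and b exceedances,
  `p = (1 + b)/(1 + R)` (add-one convention, so p is never 0 and the
  identity relabeling is implicitly counted). Ties `F_perm = F_obs` count
  as exceedances — the conservative direction. The FWE-corrected p of a
  unit uses the exceedances of the per-round **maximum** F over all
  units, so `p_fwe ≥ p_nominal` holds structurally and FWE is controlled
  over exactly the set of genes (or probes) analyzed.

### Degenerate designs and aliasing

In the target cohort every donor has a single age, sex and ethnicity, so
those covariates are exact linear combinations of the donor indicators
and the design is rank-deficient. The covariate basis is built
incrementally (intercept, donor, age, sex, ethnicity) with a
rank-revealing orthogonalization (relative tolerance 1e-8); a column that
adds no rank is dropped, which removes fully aliased covariates
deterministically in the order ethnicity → sex → age before donor is
ever touched. Dropped covariates are reported as warnings and in the run
manifest. If the TSL factor itself is aliased with the covariates the
design is confounded and the analysis aborts. Permutation rounds whose
relabeling happens to be aliased (possible in tiny designs) are excluded
from R with a warning rather than imputed.

The F computation residualizes both the response matrix and the TSL
indicator against the covariate basis once; each permutation round then
costs one projection of a single column, which makes 10,000 rounds ×
dozens of units essentially instantaneous and lets calibration studies
run thousands of full pipelines.

## Spatial filtering

* Probability maps are voxelwise percentages in [0, 100]; files stored on
  a [0, 1] scale are detected (max ≤ 1) and rescaled on read.
* VOI masks keep voxels with probability ≥ threshold; thresholds span
  10–100 % (default 20 %). Merging masks (e.g. neighboring areas) is a
  voxelwise union on an identical grid.
* A sample belongs to a mask iff its world coordinate's nearest voxel
  (inverse affine, then round-half-away-from-zero per axis — a fixed
  convention, since `np.round` halves to even) is in bounds and true.
  Samples are point annotations, so nearest-voxel membership is used
  rather than trilinear interpolation.
* A sample inside both masks gets the label whose probability map is
  higher at that voxel; an exact tie excludes it (`"ambiguous"`), which
  is deterministic and symmetric in the two VOIs. Samples in neither
  mask are excluded (`"outside"`).

## Probe aggregation and normalization

* The winsorized mean clamps `k = floor(n·α)` order statistics per tail
  (α = 10 % low, 10 % high by default) to the nearest interior order
  statistic before averaging. For genes with ≤ 10 probes (a single tail
  count of 0 or 1) this is nearly a plain mean — probe-poor genes get
  little robustness benefit, which is inherent to count-based trimming.
* Winsorizing runs **across the probes of one gene within one sample**,
  never across samples.
* Expression input is normally already z-scored. The raw path z-scores
  each probe within each donor (mean 0, sd 1 with the n−1 denominator);
  within-donor normalization matches the per-donor file layout and
  removes donor-level location/scale before the ANOVA ever sees the
  data. Constant rows become all-zero with a warning.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the real study: two
probabilistic blobs (linear decay from a peak, so threshold ↔ VOI size
behaves as in real maps), a 6-donor cohort with donor-determined
covariates (1 female / 5 males, ages 24–57, reproducing the aliasing
problem), 12 + 18 samples inside the VOIs plus background samples
outside, 25 genes with 1–8 probes each (mean ≈ 3, matching the genome-
wide probe-per-gene ratio of the platform), and homoscedastic Gaussian
probe noise with sd 1 on the z-score scale. A spiked gene shifts all its
probes by ±δ/2 between the VOIs. Samples are placed at ≤ 55 % of the
blob radius so the default 20 % threshold recovers the constructed
membership exactly.

Not modeled: raw microarray intensities and their background correction,
batch effects, spatial autocorrelation of expression within a region,
heavy-tailed or probe-specific noise, and inter-probe correlation beyond
the shared gene effect. Passing calibration tests therefore demonstrate
the statistical engine's correctness under exchangeable Gaussian noise,
not robustness to those real-data artifacts.

## Numerical choices

* Rank/alias tolerance 1e-8 (relative); permutation F comparisons use a
  1e-12 relative slack so that exact ties are counted as exceedances
  despite floating-point noise.
* A permutation round with a perfect full-model fit (SSE_full = 0 with a
  nonzero effect) yields F = ∞, which orders correctly in the exceedance
  counts; SSE_full is clipped at 0 against cancellation.
* Results are sorted by `p_fwe` ascending, ties by F descending, then
  unit id lexicographically — a total, reproducible order.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds and inputs give bit-identical p-values.
* CSV reads use pandas' `round_trip` float parsing so write → read →
  write is byte-identical; NIfTI volumes are written as float32.

## Calibration studies (run by the test suite and acceptance script)

Problem sizes were chosen to give tight Monte-Carlo bands while keeping
a full run in seconds: the family-wise error study uses 200 global-null
replicates of the default study (25 genes, 12 + 18 samples, R = 1,000)
and checks the empirical FWER at α = 0.05 against the exact binomial
99 % interval [0.013, 0.105]; the power study uses 100 replicates per
effect size δ ∈ {0, 0.5, 1, 2} z-units and checks that detection is
monotone and that the δ = 2 spike is top-ranked in ≥ 95 % of replicates.
The permutation engine is cross-checked against an exhaustive
enumeration oracle on a 4-sample design and against statsmodels
OLS/`anova_lm` model-comparison F on covariate designs.

## Known limitations

* Only two VOIs per analysis; the factor of interest is strictly binary.
* The tie rule for samples in overlapping VOIs (higher probability wins,
  exact ties excluded) is a design choice; overlapping probabilistic
  maps have no canonical assignment rule.
* FWE correction is max-statistic only; no FDR alternative and no
  parametric F-distribution p-values are produced.
* No registration: maps and sample coordinates must already share one
  reference space.
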