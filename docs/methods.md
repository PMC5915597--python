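# Methods

## Pair universe and voxel bookkeeping

The atlas (integer label volume + affine + name table) fixes a deterministic
voxel enumeration: brain voxels (nonzero labels) ordered by ascending
Fortran-order linear index (first axis fastest). Every matrix row, pair index
and store column refers to voxels through this enumeration; save/load round
trips preserve it exactly. World (mm) coordinates come solely from the
affine applied to 0-based voxel indices, so standard-space (e.g. MNI)
coordinates are reproduced exactly when a standard-space atlas is supplied.

For a seed region R the pair universe is every unordered (ROI voxel, brain
voxel) pair taken once: |R|·(|brain|−|R|) cross pairs plus |R|·(|R|−1)/2
within-ROI pairs. Within-ROI pairs are included a single time (no double
counting); published pair counts of the form |R|·|brain|/2 are approximate
statements of the same universe.

## Per-subject FC

FC is the Pearson correlation of two voxels' time series, Fisher
z-transformed (arctanh). Computation standardizes each voxel row once and
takes chunked dot products; the chunk size is purely a memory bound
(O(chunk × T) extra) and results are bit-identical for any chunking. The
store holds subjects × pairs in float32 (HDF5 datasets `/z`, `/pairs`,
`/subjects`, `/zero_variance`).

Degenerate inputs: a voxel with zero temporal variance has no defined
correlation — its pairs are stored NaN and the (subject, voxel) record kept
in a registry; NaN pairs are excluded from all downstream tests and the
exclusion count is logged. Numerically perfect correlations (duplicated
series) are clipped to ±(1 − 1e−12) before arctanh so z stays finite
(≈ ±13.8) instead of poisoning the combination with ±∞.

## Group testing and cross-site combination

Per site, one linear model per pair: `z ~ 1 + group + covariates`, t and
two-tailed p on the group coefficient with df = n − #parameters. The joint
model reduces exactly to the pooled two-sample t with no covariates (tested
against `scipy.stats.ttest_ind`); rank-deficient designs and sites lacking
two subjects per group are errors (the pipeline skips such sites with a log
note, which also implements single-site contrasts such as
medicated-vs-unmedicated at one site via the single-site identity).

Signed conversion uses `z' = sign(t)·Φ⁻¹(1 − p/2)` with p floored at 1e−300
(|z'| ≲ 37). Converting a two-tailed p through Φ⁻¹(1 − p) would discard the
direction of the effect; the signed form is the standard Stouffer input and
lets increases and decreases combine coherently.

The combination is `Z = Σ w_k z'_k / √(Σ w_k²)` with `w_k = √n_k`. The
square root in the denominator is required for Z ~ N(0,1) under the null
(verified by the null-calibration test); a linear denominator `Σ w_k²` is
not correctly normalized. Sites with a missing z' for a pair drop out of
both sums; a pair missing everywhere stays missing.

Note the combined |Z| is *not* monotone in the number of same-sign sites:
with equal weights, |(z₁+z₂)/√2| ≥ |z₁| only when |z₂| ≥ (√2−1)|z₁|. The
test suite asserts this sharp condition rather than a blanket monotonicity.

## Thresholding and summaries

Three modes: BH-FDR at q (step-up; p* is the largest rejected p, all
p ≤ p* rejected — deterministic under ties), uncorrected α, and uncorrected
α plus cluster-extent filtering. Clusters are 26-connected components (the
common neuroimaging default) of voxels with ≥ 1 significant link; the
extent filter removes all links incident to components of ≤ min voxels, so
only clusters strictly larger than the minimum survive.

Per-voxel summaries: MA_v = number of significant links at v; S_v = Σ|Z|
over those links, signed by Σ Z. The cluster table groups *all* voxels
incident to significant links (seed side included, so the seed region
reports its own row, as in published tables of this design); each row lists
the region names its voxels occupy, the voxel count, Σ|Z| over incident
links — a link joining two reported clusters contributes to both rows — and
the world coordinate of the peak voxel (max S_v). Rows with ≤ 10 voxels
(configurable) are suppressed.

## Clinical correlates

Cluster-table rows define the region-sets ("ROIs") — their count is
data-dependent, not fixed. Per patient and row, the ROI-wise FC is the mean
z over the row's significant links (NaN links skipped; all-NaN → missing).
Partial correlation residualizes both variables on covariates + intercept
and correlates the residuals; p from `t = r·√((n−k−2)/(1−r²))`. Controls are
excluded: the scores and the medication covariate are patient measures. A
covariate constant within a site (medication at an all-medicated site) is
dropped for that site with a log note — the fit then equals the
reduced-covariate fit exactly. A variable explained numerically exactly by
the covariates has residual SS below 1e−24 of its total SS and returns
r = 0, p = 1 by convention. Site results combine exactly as the link tests.

## The cohort simulator

Each region r carries a latent stationary unit-variance AR(1) signal; voxel
i in region r observes `x_i = √c·u_r + √(1−c)·ε_i` with white Gaussian ε,
so same-region voxels correlate at the coherence c and cross-region voxel
pairs at `c·corr(u_a, u_b)`. Declared effects set a per-subject coupling

    ζ = ζ_base + site offset + Δz·1[patient] + Σ β_j·cov_j(standardized) + η

and the latent correlation matrix (identity with `tanh(ζ)/c` on effect
pairs) is factored by its eigendecomposition, `u = L·v`, realizing every
requested correlation exactly and failing cleanly when the set is not
jointly positive semidefinite. Effects therefore live on the Fisher-z scale
the pipeline tests on: the injected group difference *is* Δz.

Defaults (chosen once; units in parentheses): coherence c = 0.75; base
coupling ζ = 0.15; AR(1) coefficient 0.4 (a realistic variance-inflating
stressor for correlation estimates); subject coupling noise η Gaussian,
SD 0.05, clipped at ±2.5 SD — the clipping guarantees the default
three-effect layout stays feasible for every draw (worst-case Σρ² = 0.88 < 1);
site coupling offsets ±0.03; T = 230 time points (≈ 8 min at TR 2 s);
covariates age ~ U(18, 60) years, sex ~ Bernoulli(0.5), education
~ U(6, 20) years, mean FD ~ lognormal(log 0.12, 0.4) mm, standardized by
their theoretical moments inside ζ. The full-scale layout mirrors a
two-site study (96+54 with all patients medicated; 254+282 mixed); the
desk-scale layout is 2 sites × (20+20), T = 120, on a 983-voxel atlas
(27-voxel seed, three 27-voxel targets at +0.25/+0.20/−0.15, seven
125-voxel fillers). Clinical scores are HAMD ~ N(20, 4), BDI ~ N(25, 6),
illness duration ~ lognormal(log 24, 0.6) months for patients (low-score
analogues for controls, duration/medication missing), optionally coupled to
a chosen effect's η at a target correlation for power studies.

Per-subject RNG streams are keyed by (master seed, global subject index),
so cohorts are bit-reproducible and independent of subject order.

What the simulator does *not* emulate: hemodynamic response shape,
physiological noise spectra, spatially smooth noise beyond region
coherence, motion artifacts (mean FD is a pure nuisance covariate with no
signal footprint unless a β is set), registration/preprocessing error.
Passing tests demonstrate the statistical chain is correct under the stated
generative model, not that preprocessing choices on real data are benign.

## Calibration and validation design

The null-calibration cohort (no effects, no covariate slopes) additionally
sets coherence to 0. With spatial coherence, pairs sharing a voxel or a
region have combined-Z correlations of order c, and an iid
Kolmogorov–Smirnov test over ~10⁵ dependent pairs is badly miscalibrated —
it would reject for a perfectly correct implementation. With coherence 0
all voxel series are independent, distinct pairs' statistics are
asymptotically independent, and the KS test is valid; the marginal law of
the combined Z is exact N(0,1) either way (Gaussian data → exact t
reference → exact probability transform). Measured on the 101 601-pair
calibration cohort: |mean| < 0.02, |var − 1| < 0.05, KS p > 0.01.

FDR control is measured as the empirical false discovery proportion of the
full pipeline over 20 replicate desk-scale cohorts with one injected effect.
Because every link of a (seed, region) block shares the same two latents,
false discoveries arrive in blocks and the per-replicate FDP is
heavy-tailed; the mean is compared against q plus two Monte-Carlo standard
errors of the replicate set. Effect recovery checks that the n-weighted
cross-site mean of the group coefficient, averaged over the injected block's
links, returns Δz = 0.25 within ±20%.

Problem sizes used by the default test suite and the acceptance script
(desk-scale cohorts, 983–3 777 voxels, 20–80 subjects, T = 120) were chosen
so the whole suite runs in a few minutes on one CPU while keeping ≥ 10⁵
pairs where the calibration claims need them.

## Known limitations

- The GLM is fit per site with a common residual variance across groups
  (classical pooled model); heteroscedastic alternatives (Welch) are not
  offered.
- BH is applied under the positive-dependence regime induced by the
  generative model; adversarial negative dependence is untested.
- The cluster table attributes a link to every component it touches, so
  Σ|Z| over rows can exceed Σ|Z| over unique links.
- Within-ROI pairs are tested but the seed's own row dominates cluster-table
  Σ|Z| by construction (it touches every significant link).
- The simulator's site effect is a coupling offset; scanner-specific
  spectral or amplitude differences beyond `noise_scale` are not modeled.
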