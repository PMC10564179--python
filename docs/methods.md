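# Methods

## Problem and model

Each column of the input matrix is one subject sampled at one unknown point
of the 24-h cycle.  The method assumes (i) a shared circular covariate: all
genes of a tissue are driven by the same underlying phase per sample; (ii) a
core of rhythmic genes — the 12 seed clock genes *PER1/2/3, CRY1/2, ARNTL,
CLOCK, NR1D1, RORA, DBP, TEF, STAT3* — whose oscillation is strong enough to
expose that phase; and (iii) one canonical peak precedence (*DBP* before
*ARNTL* along the counterclockwise arc, by less than half a cycle) to break
the reflection symmetry that no purely unsupervised method can resolve.

Rhythmic profiles are modeled by the Frequency Modulated Möbius (FMM) wave

    mu(t) = M + A * cos(beta + psi(t)),
    psi(t) = 2 * arctan(omega * tan((t - alpha) / 2)),

a five-parameter family that deforms a sinusoid (omega = 1) into asymmetric
and sharp shapes (omega -> 0) while keeping the parameters interpretable:
M midline and A amplitude in the units of the (normalized) expression
values, alpha a translation angle, beta a shape/skewness angle, omega a
dimensionless sharpness in (0, 1].  The peak phase is the closed form
t_U = alpha + 2 arctan(tan(-beta/2) / omega), the unique maximizer because
psi is a strictly increasing bijection of the circle.  Goodness of fit is
R^2 = 1 - SSE/SST against the mean of the response (R^2 = 0 for constant
input by convention).

## Pipeline

1. **Preprocessing.**  Genes with zero counts in more than 30% of samples
   (`max_zero_frac = 0.30`, boundary retained; "zero" means exactly 0 on
   the input scale, with a configurable epsilon for log-scale data) are
   discarded; each remaining gene is min-max mapped to [-1, 1].  Constant
   genes map to zero vectors, are flagged, and are excluded from all
   rhythmicity fitting.

2. **Preliminary order.**  Circular PCA on the seed-gene submatrix: rows
   are centered, the first two right-singular vectors scaled by their
   singular values form the eigengene pair (sign convention: the largest-
   magnitude entry of each is positive; an error is raised when the second
   singular value vanishes).  Outlier samples are flagged by the whitened
   score radius (|r - median| > 3 * 1.4826 * MAD, at most max(1,
   floor(0.05 m)) flagged, farthest first; MAD below 1e-8 of the median
   radius is treated as zero so that float noise on an exact circle never
   flags anything), removed from all genes, and the matrix re-normalized.
   Each eigengene is then centered and scaled to unit standard deviation
   before the two-argument arctangent — without this whitening, unequal
   singular values compress angles near the minor axis of the score
   ellipse.  Sorting the angles gives the circular order.

   **Orientation.**  Both directions (theta and 2 pi - theta) are
   evaluated by fitting the FMM wave to every seed gene against the
   candidate angles; the direction in which *DBP*'s peak precedes
   *ARNTL*'s by an arc < pi is kept (fallback pair *DBP*/*CRY2* when one
   is absent).  The rotation (starting point) maximizes the number of seed
   peaks in the active half-circle [0, pi); because that count is
   piecewise constant with breakpoints where a peak crosses zero, only
   rotations placing some peak at 0 need to be evaluated; ties anchor
   *ARNTL*'s peak at pi.  When precedence chains are supplied (e.g.
   `{DBP} <= {CRY1,CRY2} <= {ARNTL}`), a pairwise precedence g1 <= g2
   counts as satisfied when the counterclockwise arc from g1's peak to
   g2's is in (0, pi]; the direction satisfying more precedences replaces
   the base choice provided it does not reduce the active-half seed-peak
   count.  The hours convention is 24 h = 2 pi with 0 rad = lights-on
   (6 am) and pi = lights-off (6 pm).

   **Quality gate.**  If the median seed-gene R^2_FMM under the oriented
   angles is below `quality_gate = 0.3`, downstream estimates are deemed
   unreliable: the run stops after the preliminary order unless forced.

3. **TOP rhythmic orderings.**  A fast pre-filter projects each gene
   (read along the circular order) onto the cone of circularly unimodal
   sequences: every rotation (trough cut) and peak position is searched,
   each monotone arm fitted by isotonic least squares.  A single
   incremental pool-adjacent-violators sweep yields the SSEs of all
   prefixes of a rotation, so the full search costs O(m^2) amortized
   merges per gene; ties break lexicographically on (rotation, peak).
   Genes with R^2_ORI < 0.5 are discarded (threshold inclusive on the keep
   side).  Survivors are FMM-fitted; the TOP set comprises genes with
   omega > `min_omega = 0.1` (not spike-like) and R^2_FMM >
   `min_r2_fmm = 0.5`.  Seed genes are always included.  If a quarter of
   the circle contains no TOP peak, the best-R^2 non-spiked gene peaking
   there is added (flagged "coverage-added") so the eigengene plane stays
   identifiable in step re-orderings; forced seeds count toward coverage.

   K = 5 re-orderings are then derived from random subsets of
   ceil(2/3 |TOP|) genes (single RNG seeded by `rng_seed`, default
   20230928).  A subset ordering is accepted when (a) its angles span more
   than half the circle (2 pi - largest gap > pi) and (b) its largest
   circular gap does not exceed the preliminary ordering's largest gap.
   Condition (b) guards against subsets opening spurious holes; because it
   can reject every draw on healthy cohorts whose preliminary gap happens
   to be small, a run that exhausts the attempt budget (default 200) falls
   back to the span-passing orderings with the smallest gaps, with a loud
   warning.  Only a cohort with no span-passing subset at all is an error.

4. **Robust estimation.**  Every TOP gene is fitted under each accepted
   ordering; per gene the medians of M, A, omega and R^2 and the circular
   median of t_U (the input angle minimizing summed shorter-arc distance,
   ties to the smallest angle) form the atlas row, with
   `phase_class = active` for t_U in [0, pi).  Sample times reported in
   `sample_times.tsv` are the preliminary (full-seed) ordering's angles;
   the atlas is per-gene, aggregated over the K subset orderings.

## Fitting

For fixed (alpha, omega) the FMM model is linear in (M, A cos beta,
-A sin beta) through cos(beta + psi) = cos beta cos psi - sin beta sin psi,
so fitting profiles the two nonlinear parameters: an exact least-squares
solve on a grid of 48 equispaced alpha x 24 log-spaced omega in [0.01, 1]
(the 3x3 normal matrices depend only on the sample angles and are inverted
once per ordering, shared across genes), followed by Nelder-Mead refinement
of (alpha, omega) (deterministic given the grid start; omega outside
[0.01, 1] penalized).  psi is computed as 2 atan2(omega sin(u/2), cos(u/2)),
which is continuous through the tangent singularity at u = pi.  Amplitude
non-negativity is automatic (A = hypot of the two linear coefficients);
omega is capped at 1 because larger values re-parameterize smaller ones
with a shifted alpha.  The cosinor (three-parameter sinusoid) is the
omega = 1 submodel and is always evaluated as a final candidate, so
R^2_FMM >= R^2_cosinor holds exactly by construction.  The TOP filter
omega > 0.1 is applied after fitting over the full (0.01, 1] range.

## Validation metrics

Reconstructed phases are defined only up to rotation, so all metrics are
rotation-invariant:

- **Circular correlation** is the Fisher–Lee T-linear coefficient,
  sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) normalized by the pairwise sine
  dispersions.  The sine-moment variant built on circular means was
  considered and rejected: the circular mean is numerically arbitrary for
  uniformly spread angles (zero resultant), which is precisely the regime
  of a well-reconstructed order — the pairwise form returns exactly 1 for
  a shifted copy of equispaced angles, the moment form does not.  Its sign
  carries the direction (negative = reflected).
- **Angular MAD** is the median shorter-arc error after removing the
  single global rotation minimizing that median (candidates: all pairwise
  exact alignments plus a 4096-point grid).
- **rho** is the goodness of a degree-1 circular-circular regression:
  cos y and sin y each regressed on (1, cos x, sin x); rho is the square
  root of the mean of the two component R^2.  It equals 1 for rotations
  and reflections (direction is the orientation step's job).  The
  literature offers several rho estimators; this deterministic choice
  means absolute rho values are comparable across runs of this package
  but only qualitatively with other implementations.

## Synthetic cohorts

The generator produces what the method assumes, with ground truth: sample
times equispaced, uniform, or a two-component von Mises mixture (emulating
clustered times of death); the 12 seed genes as FMM waves with fixed,
biologically ordered peaks (morning cluster before the CRY genes before
ARNTL at pi; defaults cover both half-circles and satisfy
{DBP} <= {CRY1,CRY2} <= {ARNTL}); additional rhythmic genes with stratified
jittered peaks covering all quarters, shapes drawn from `omega_range`
(default (0.3, 1.0); seed genes (0.6, 1.0) since core clock genes are
close to sinusoidal); and confounds — flat noise, monotone drift in emitted
sample index, two-group batch shifts, and narrow Gaussian time-bumps
(width 0.12 rad) that exercise the omega > 0.1 spike filter.  Gaussian
noise has standard deviation `noise_sd` (default 0.1) in amplitude units;
baselines (5–10) and amplitudes (1–3) are in arbitrary positive expression
units.  Columns are emitted in a recorded random permutation.

What the generator does **not** emulate: count noise (the method operates
post-quantification), RNA degradation with postmortem interval,
inter-subject amplitude/phase heterogeneity beyond additive noise, and
correlated gene modules.  Passing tests therefore demonstrate correctness
of the machinery and recoverability under the stated noise model, not
performance on real cohorts.

The canonical fixtures are `clean-equispaced` (m = 50, 12 sinusoidal genes,
no noise — omega is fixed at 1 here because only for pure sinusoids is the
two-eigengene projection an exact monotone map of true time, making exact
order recovery a meaningful check), `noisy-uneven`, `asymmetric-heavy`
(omega in [0.1, 0.4]), `confound-heavy` (40 rhythmic vs 60 confounds,
m = 100, noise 0.1 — the replicated study condition), and `gate-fail`
(seed symbols present but pure noise).

## Problem sizes

The replicated recovery studies use 20 seeded cohorts of m = 100 samples
with 100 genes each in the test suite (10 cohorts in the acceptance
script); the exhaustive unimodal-fit oracle sweep covers all ternary
sequences of length 4–8.  These sizes give stable medians while keeping a
full run of suite plus script in the minutes range on one CPU.

## Known limitations

- The orientation rule presumes the *DBP*→*ARNTL* precedence holds in the
  tissue; species or conditions violating it need a prior chain or a
  different seed pair.
- The reconstructed phases carry an arbitrary rotation; anchoring (e.g.
  ARNTL at pi) is a convention, not an estimate of clock time.
- Outlier detection assumes outliers are individual samples, not
  subpopulations (hence the 5% cap).
- The ORI screen and FMM fit assume a single oscillation per 24 h; genes
  with ultradian components are penalized.
- Absolute rho values depend on the regression-degree choice (see above).
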