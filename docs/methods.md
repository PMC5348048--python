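# Methods

## The inference problem

Microbial surveys along environmental gradients produce, per site, a vector
of relative taxon abundances and a vector of measured environmental
parameters (pH, moisture, nutrient pools, ...).  Co-occurrence analysis
summarizes such data as a symmetric correlation matrix, which cannot
express that taxon *j* may push taxon *i* up while *i* pushes *j* down.
`microbeta` instead estimates a **directed** interaction coefficient per
ordered taxon pair, per environmental parameter and per sample, from the
premise that each taxon's abundance is a smooth function of the gradients
and of the other taxa's abundances.

Writing `A_ik` for the abundance of taxon *i* in sample *k* and `Θ_αk` for
environmental parameter *α*, the chain estimates

1. the local abundance slope `p_iαk = ∂A_ik/∂Θ_αk`, and
2. the local interaction coefficient
   `β_ijαk = (∂p_iαk/∂A_jk) / A_ik`,

the per-abundance rate at which taxon *j* modulates taxon *i*'s response to
gradient *α*.  The construction parallels the generalized Lotka–Volterra
(gLV) equations with the gradient playing the role of time: for
`dA_1/dΘ = r_1 A_1 (1 − A_1/K_1 + B_12 A_2/K_1)` the coefficient recovered
for pair (1,2) is the effective interaction `r_1 B_12 / K_1`, so signs and
relative strengths are comparable to gLV ground truth.  The
interaction-independent ("solitary") part of each taxon's response is
removed by the differentiation and is never estimated.

## Difference regressions

Partial derivatives cannot be read off observational data directly because
samples differ in everything at once.  The estimators therefore use the
first-order Taylor expansion around a reference sample *k*: every other
sample *l* contributes one regression row whose response is the abundance
(or slope) difference and whose regressors are the gradient (and abundance)
differences.  All `l ≠ k` enter one regression with no distance weighting
and **no intercept** — the difference of a sample with itself is exactly
zero, so a constant term has no place in the model.

Two model variants are provided:

* **reduced** (default): slopes are regressed on gradient differences only;
  interactions on abundance differences only.
* **full**: slope regressions additionally include the other taxa's
  abundance differences (their coefficients are returned as cross-slopes
  `∂A_i/∂A_j`), and interaction regressions additionally include gradient
  differences (returned as environmental sensitivities `∂p_iα/∂Θ_α'`).

The self-pair `j = i` is estimated like any other: its sign has a logistic
reading (negative once a taxon saturates its niche, positive while its
response grows with its own abundance).

A caveat of the full variant: if every taxon's abundance is an exact
function of the gradients alone, the abundance differences lie exactly in
the span of the gradient differences and the full design is singular.  The
full variant is therefore only meaningful when abundances carry variation
of their own, and exact-recovery guarantees are stated for the reduced
variant.

## Robust fitting

All regressions use Huber M-estimation (tuning constant 1.345, the
classical 95 %-efficiency choice) solved by iteratively reweighted least
squares, because sequencing noise turns into gross outliers in difference
space and ordinary least squares chases them.  Implementation choices:

* scale: median absolute deviation of the residuals (centered at zero, as
  there is no intercept), re-estimated for 10 burn-in iterations and then
  frozen — with a fixed scale, IRLS minimizes a convex objective and
  converges monotonically;
* convergence: largest coefficient change below `tol × max(1, |β|_∞)`,
  default `tol = 1e-6`, `max_iter = 100`; non-convergence warns and returns
  the last iterate;
* exact fits (zero residual) terminate immediately on the least-squares
  solution, so noise-free constructions are recovered to machine precision;
* responses sharing a design matrix (all taxa for a fixed reference sample,
  all (taxon, parameter) pairs in the interaction stage) are fitted as one
  batch via per-response weighted normal equations.

The implementation is cross-checked in the test suite against
`statsmodels` RLM with the same loss.

## Preprocessing

Order: align samples by identifier → drop every taxon with a zero anywhere
(its abundance appears in a denominator) → divide each column by its sample
standard deviation (n−1 denominator, **no centering**, so signs and zeros
are preserved) → prune collinear columns → check sample size.

Collinearity pruning repeats a numerical rank test (singular values below
the standard `max(N,c)·ε·σ_max` cutoff count as zero); while the matrix is
rank-deficient, one column is drawn uniformly — with a seeded generator —
from the pivot-dependent candidates of a column-pivoted QR decomposition
and removed.  This both stabilizes the regressions and absorbs
closure-induced dependence among relative abundances.  The dimension check
errors when samples ≤ regressors and warns below two samples per regressor.

All coefficients are reported in scaled units; the per-column scale factors
are in the preprocessing report for users who want to invert the scaling.
Because β divides by the scaled abundance, β values are invariant to any
constant rescaling of the raw table (in particular to closure by a constant
total).

## Relative versus absolute abundance

Closure (`x_i = y_i / Σy`) induces compositional dependence.  Writing `S`
for the community total, `∂x_i/∂Θ = ∂y_i/∂Θ / S − x_i (∂S/∂Θ)/S`: when the
total is roughly conserved the second term vanishes, relative slopes are
absolute slopes divided by a constant, and pairwise derivative ratios agree
— interaction signs from relative data then match those from absolute
data.  The package does not transform the data to enforce this; it relies
on the biological regime (buffered overall community size, high diversity)
and verifies it on synthetic data.

One structural consequence matters for estimation: if the table is closed
over exactly the analyzed taxa, rows sum to one, abundance differences sum
to zero, and the interaction design matrix is exactly singular.  Real
surveys report named groups covering only part of the community, so row
sums stay below one; the study emulator reproduces this.

## Summarization

Per ordered pair and parameter, the sample values `β_ijαk` are condensed in
two conservative stages:

1. **Peak median.**  Exact zeros carry no sign and are ignored.  If at
   least 80 % (configurable) of the non-zero values share a sign, that sign
   is the direction; otherwise the parameter is excluded.  A Gaussian
   kernel density estimate (Silverman bandwidth, configurable) over the
   values locates the dominant mode; the contiguous run of sorted values
   whose density stays above half the mode density (configurable fraction)
   forms the peak, and its median is the per-parameter summary `M_α`.
   Fewer than 5 non-zero values exclude the parameter.  A point mass is its
   own peak.
2. **Majority / ratio rule.**  If ≥ 80 % of qualifying `M_α` share a sign,
   the global `β_ij` is the median of that sign group.  Otherwise the
   medians of the positive and the negative group are compared: if one
   exceeds the other more than twofold in absolute value (strictly; a ratio
   of exactly two does not decide), it wins.  Otherwise the pair is
   *indeterminate*; with no qualifying parameter at all it is flagged
   *no-qualifying-parameter*.  Non-determinate pairs carry no numeric value.

Weighted combinations across parameters (`Σ_α C_α β_ijαk`, weights supplied
by the user, e.g. from a constrained ordination) and Euclidean norms over
any axis combination are provided as classical alternatives; norms lose
direction information by construction.

These rules make global values deliberately conservative: most `|β_ij|`
land near zero, and individual local values can be much larger than the
global summary.

## Robustness machinery

Measurement imprecision is emulated by entrywise multiplicative noise
`x (1 + u e)`, `u ~ Uniform(−1, 1)`, applied to the **raw** tables
(rescaling is recomputed per iteration); the relative error is bounded by
the error level `e`.  Preset levels {0.01 %, 0.1 %, 5 %, 10 %, 20 %, 50 %}
span typical sequencing and soil-chemistry uncertainty.  Sampling-site
choice is emulated by retaining `floor(0.9 N)` samples without replacement
— bootstrapping with replacement is unusable here because duplicated
samples produce identically-zero difference rows.

Each iteration reruns the entire chain; per ordered pair, only iterations
with a determinate global value contribute (their count is reported as
`n_valid`).  Summaries: mean, two-sided 95 % t-interval, percentile
interval, and a two-sided one-sample t-test against zero.  A spread below
numerical accumulation noise (≤ 1e−12 relative) is treated as exactly zero,
so unperturbed runs report zero-width intervals.  Seeds derive from one
`SeedSequence`, making reports bit-reproducible.

## Synthetic ground truth

* **gLV simulator** — integrates the gLV system along a single gradient
  (adaptive Runge–Kutta, relative tolerance 1e−8), returning sampled
  abundances, the true slope field (the ODE right-hand side) and the true
  sign matrix `sign(r_i B_ij / K_i)`.  Two-species presets: predator–prey
  (`r = (1.2, 0.5)`, `K = (1.0, 0.6)`, `B = ±0.6`, `A0 = (0.05, 0.9)`,
  `Θ ∈ [0, 4]`, 60 samples) and mutualism (`r = (0.8, 1.2)`, `K = (1, 1)`,
  `B = +0.5`, `A0 = (3.0, 0.3)`, `Θ ∈ [0, 4]`).  Both are deliberately
  transient: interaction information lives in the approach to equilibrium,
  and the partners start on opposite sides of their equilibria so the two
  abundance curves stay linearly independent.  Mutualists started close
  together rise in near-perfect correlation and the cross-coefficients
  become unidentifiable — a genuine identifiability boundary of the method,
  not an implementation artifact.
* **Analytic generator** — abundances as explicit polynomials of the
  gradients with symbolically known derivatives; the oracle for
  exact-recovery tests (multilinear: slopes recovered to machine precision;
  the `A_1 = Θ², A_2 = Θ` construction: `∂p_1/∂A_2 = 2`).
* **Study-shaped emulator** — 150 samples × 17 taxa × 13 parameters.  A pH
  4–8 gradient drives a 17-taxon gLV community with a sparse random
  interaction matrix (20 % of ordered pairs, magnitudes 0.05–0.5, balanced
  signs).  Growth rates 0.3–0.5 keep transients alive across the whole
  gradient.  Initial abundances are displaced several-fold from the
  interacting equilibrium `A* = (I − B)^{-1} K` inside the subspace whose
  linearized relaxation conserves the community total (the displacement is
  projected out of the low-order Krylov space of the Jacobian's transpose
  acting on the ones vector), so taxa redistribute abundance rather than
  bloom or crash collectively — the buffered-biomass regime the
  compositional approximations assume.  Observed tables carry 5 %
  multiplicative noise (typical precision for abundant groups) and are
  closed over the community plus a constant unclassified remainder (8× the
  reported total), keeping row sums well below one.  The other 12 soil
  parameters co-vary smoothly with pH plus independent scatter.

### What the emulator does and does not show

Passing tests on the emulator demonstrate: end-to-end numerical
correctness at study scale, the compositional approximations in their
stated regime, agreement of relative- and absolute-abundance chains, and
stability of the machinery under perturbation and subsampling.  They do
**not** demonstrate faithful recovery of a 17 × 17 interaction matrix from
a single effective gradient: with one latent driver, all abundance
difference vectors are near-collinear and attribution of couplings to
specific pairs rests on curvature alone, so the magnitude ranking of
estimated global values does not track true coupling strengths.  Real
multi-gradient designs (the setting the method targets) provide the
independent variation this emulation intentionally lacks.  Sign-recovery
guarantees are therefore validated on the two-species systems, and the
study-scale emulator is used for structural and stability checks.

## Problem sizes and numerical defaults

Test-suite and acceptance-script runs use the generators at their default
sizes: two-species systems at 40–150 samples, the study emulator at
150 × 17 × 13, 50 seeds for noisy sign recovery, 25–100 iterations for
perturbation intervals and 5–10 for study-scale subsampling.  These sizes
were chosen so a complete validation runs on a laptop-class single core in
a few minutes while keeping every statistical check well-powered.

Degenerate inputs are handled explicitly: all-zero responses fit to zero
coefficients; constant columns error in scaling; singular difference
designs error naming the reference sample; constant taxa produce missing
correlation entries; zero spread in robustness values yields zero-width
intervals with a decisive test against zero (p = 0 for a non-zero mean,
p = 1 otherwise).

## Known limitations

* Only the linear term of the Taylor expansion is used; strongly curved
  responses bias slopes toward secants (visible as growing interval widths
  under increasing perturbation).  Higher-order terms are out of scope.
* Single-gradient data cannot separate many taxa's mutual influences (see
  above); at least as many independently varying gradients as relevant
  drivers are needed for well-attributed couplings.
* Unmeasured environmental drivers masquerade as interactions; the method
  shares this confounding with every observational approach.
* The ratio-of-medians fallback can assign a direction to genuinely
  bimodal pairs; the determinacy flags should always be inspected together
  with the values.
* Weights for the parameter combination are accepted from the user; no
  ordination is computed internally.
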