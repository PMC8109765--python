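# Methods

`metabridge` analyzes how metabolite concentrations co-vary between blood
and cerebrospinal fluid (CSF) in a two-genotype, two-sex, two-age-point
cohort measured by 1D ¹H NMR.  This note documents the models, the choices
that were genuinely open, and what the synthetic cohort does and does not
emulate.

## Spectral preprocessing

Each spectrum is a ppm axis plus intensity vector; axes are stored ascending
(descending files, the NMR convention, are reversed on read so shift
arithmetic has one sign convention).  The default chain is

1. **Baseline**: subtract the pooled mean intensity of the two signal-free
   edge regions (up-field of −3 ppm and down-field of 12.5 ppm).  One mean
   over the union of both regions is used rather than two region-wise means;
   the operation is idempotent.
2. **Reference normalization**: divide by the trapezoidal integral of the
   DSS reference peak window (0 ± 0.05 ppm).  Area is used instead of peak
   height because it is robust to noise on the maximum; after normalization
   the reference integral is exactly 1, putting all samples on a common
   relative-concentration scale.
3. **Alignment**: a single whole-spectrum circular shift maximizing the FFT
   cross-correlation with a designated reference spectrum, restricted to a
   configurable ±max-shift (default 0.02 ppm).  Segment-wise alignment is
   out of scope; the pH-induced shifts emulated here are global.
4. **Windowing**: keep 0.5–9.5 ppm, drop the 4.5–5.2 ppm water region.
5. **Binning**: mean intensity over half-open 0.0008-ppm bins anchored at
   the window start; the final bin is closed on the right (histogram
   convention), so the full window tiles into exactly 11,250 bins; a partial
   trailing bin is kept if it contains a point.  Points within 10⁻⁶ bin
   widths below a boundary are assigned to the next bin so that
   floating-point grid construction cannot split a bin.

Whether normalization precedes or follows baseline subtraction is not
dictated by the model; the default order is baseline first, and the chain
accepts any step order.

## Quantification

A preprocessed sample y is modeled as a nonnegative combination of
unit-total-intensity standard spectra S (rows = standards, interpolated onto
the sample grid and re-normalized):

    min_c ||y − Sᵀc||₂   s.t.  c ≥ 0.

Because sample and standards share the reference scale, the solution c is a
vector of relative concentrations comparable across samples.  The problem is
convex with a unique optimum when S has full column rank, so it is solved
directly by active-set nonnegative least squares; this replaces iterative
two-stage schemes (unconstrained start + bounded curve fitting), which reach
the same optimum but depend on initialization.  The two-stage route is kept
as `mode="two_stage"` (bounded trust-region refinement; the classical
Levenberg–Marquardt algorithm does not accept bounds) and a per-standard
`mode="independent"` fit is available because whole-spectrum joint fitting
vs. metabolite-by-metabolite fitting is a genuine modeling fork: joint
fitting is the default since overlapping multiplets otherwise get
double-counted.  Libraries with condition number above 10⁶ trigger a
collinearity warning.  An all-zero sample returns zero concentrations with a
warning rather than failing a batch.

## Correlation networks

For each sex × genotype group (age points pooled by default), the matrix
ρ[i, j] holds the Spearman correlation between metabolite i in blood and
metabolite j in CSF across matched sample pools; within-fluid correlations
are deliberately never computed.  Ties receive average ranks.

**p-values.** With n ≤ 9 matched pools the permutation null is enumerated
exactly: all n! pairings, two-sided on |ρ|, with the null distribution
cached per n for tie-free data and enumerated per pair under ties.  Above
n = 9 the t approximation t = r√((n−2)/(1−r²)) on n−2 degrees of freedom is
used.  The classical AS89 algorithm is an Edgeworth-corrected approximation
of this same null; exact enumeration is preferred at the tiny n of pooled
designs, and p-values can differ from AS89 in the third decimal.

**Adjacency.** A = ρ where p ≤ α (default α = 0.05, uncorrected, one test
per pair; an optional Benjamini–Hochberg mode was considered and rejected as
default because the pooled-sample n makes per-pair power the binding
constraint).  **Harmonization**: pairs significant in either genotype form a
common list, each genotype contributing its own raw ρ for every listed pair,
so genotype contrasts always compare the same pairs.

**Differential correlation.** For each harmonized pair, z = atanh(r) per
group and

    Z = (z₁ − z₂) / √(1/(n₁−3) + 1/(n₂−3)),

two-sided normal p, flagged at α = 0.05.  The 1/(n−3) variance is exact for
Pearson correlations of Gaussian data and very slightly anticonservative
when fed Spearman correlations (asymptotic variance ≈1.06/(n−3)); the
Monte-Carlo calibration test shows the realized type-I error at n = 20
remains inside [0.04, 0.06].  |r| = 1 (common at tiny n) is clamped to
1 − 10⁻¹⁰ with a warning; groups with n < 4 are rejected.

## Connectedness ranking

With |A| the magnitude adjacency, the symmetric block matrix
M = [[0, |A|], [|A|ᵀ, 0]] counts alternating blood↔CSF paths: column sums of
Mᵏ measure connection through k−1 intermediaries.  The damped series is
summed in closed form,

    T' = M (I − αM)⁻¹,   α = 1/(0.01 + ‖M‖_F),

where the Frobenius norm bounds the spectral radius, guaranteeing
convergence.  Each metabolite's score is its column sum of T' (first n
columns blood, last n CSF).  Scores are reported in T' units; only the
ordering is meaningful — the leading α factor dropped between T and T' is a
positive scalar that cannot change ranks.

Numerical choices: the resolvent is evaluated by an LU solve, never an
explicit inverse; rows/columns of M that are entirely zero are excluded from
the solve and scored exactly 0 (the resolvent preserves zero support and
dropping such rows changes neither ‖M‖_F nor the other scores), making
"score = 0 iff no significant cross-fluid correlation" exact in floating
point; the spectral radius of the active block is checked on every call; an
all-zero network returns zero scores with a warning (α = 100) instead of
aborting batch runs; rank ties break lexicographically by name so output is
deterministic.  An independent truncated-series oracle
Σ_{k≤K} α^{k−1}Mᵏ (accumulated in the damped variable αM so large networks
cannot overflow) cross-checks the resolvent in the test suite at K = 500.

## Group summaries and feature selection

* **Temporal log ratio**: per metabolite and sex × genotype group,
  log10(mean late / mean early); the direction (late over early) is stated
  in every output header because the opposite convention is equally common.
  Nonpositive means yield NaN with a warning.
* **ANOVA**: one-way F across genotype (grouping configurable — pooling the
  sexes or not is a design fork left to the config); the two-group case
  satisfies F = t² exactly, which the suite property-tests.
* **Ridge consensus**: L2-penalized logistic regression (λ default 1.0 on
  standardized features; no principled value exists for relative-unit NMR
  concentrations, so the isotropic default is used) ranks metabolites by
  |coefficient|; the consensus set is the intersection of the top-k ridge
  and top-k ANOVA lists (k default 10).

## Synthetic cohort

The generator defines the conditions under which the pipeline is verified:

* **Design**: 2 fluids × 2 sexes × 2 genotypes × 2 age points, 51 shared
  metabolites, 4 pooled replicates per cell by default (each pool is one
  replicate; the within-pool animal structure is not modeled).  With age
  points pooled this gives n = 8 per correlation network — inside the
  exact-p regime and above the Fisher-test minimum.
* **Dependence**: a Gaussian copula.  Target cross-fluid Spearman matrices
  are converted to latent Pearson correlations via the exact relation
  ρ_P = 2 sin(πρ_S/6), assembled into a joint correlation over
  (blood, CSF) metabolites with identity within-fluid blocks, checked for
  positive semi-definiteness (the offending eigenvalue is reported
  otherwise), and factored by eigendecomposition.  Each replicate draws one
  joint latent vector whose halves become the matched blood and CSF rows, so
  cross-fluid dependence survives the marginal transform exactly (monotone
  maps preserve ranks).
* **Marginals**: log-normal per metabolite (default μ = 0, σ = 0.5, a
  realistic coefficient of variation for relative NMR concentrations);
  genotype/age effects are additive on the log scale (default: ±0.3
  genotype effects on half the panel, ±0.2 age effects on two thirds, with
  alternating signs so the cohort shows both increases and decreases), which
  keeps marginals log-normal and within-group rank correlations untouched.
  Optional log-scale noise attenuates realized correlations and defaults
  to 0.
* **Spectra**: standards are sums of Lorentzian lines (natural line shape
  for solution NMR; default half-width 0.002 ppm) normalized to unit total
  intensity; mixtures add a constant baseline, a global circular shift
  (nearest grid point), i.i.d. Gaussian noise, and a tall Lorentzian
  reference peak at 0 ppm whose on-grid area is recorded in the ground
  truth.

Not emulated: lipoprotein broad resonances and macromolecule baselines,
pH-dependent *local* (per-multiplet) shifts, peak-shape distortions,
within-pool biological variance, and real database standard spectra.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to the full messiness of
measured biofluid spectra.

## Problem sizes in the verification suite

The automated checks use 100 random networks of up to 20 metabolites per
fluid against a K = 500 series oracle (tolerance 10⁻⁸), full n!-enumeration
cross-checks at n = 4…7, a 10,000-replicate Monte-Carlo null for the Fisher
test, 100 seeded quantification replicates with 20 standards at 1% noise,
and 10,000-replicate copula-fidelity draws (±0.05).  These sizes give
Monte-Carlo standard errors comfortably below each tolerance while keeping
the whole suite fast.

## Known limitations

* The exact-p enumeration grows factorially; n = 9 (362,880 permutations
  per tied pair) is the practical ceiling, above which the t approximation
  takes over.
* The Fisher z test assumes independent groups and is approximate for
  Spearman correlations at small n; at n = 8 per group (the default design)
  its power is limited and |ρ| = 1 clamping is common.
* Connectedness scores depend on the significance mask: a single pair
  crossing α can move scores discontinuously; stability under resampling is
  not quantified.
* The bipartite network treats correlation magnitude as undirected
  association strength; no causal or transport interpretation is encoded.
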