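# Methods

## Scope

`cocount` analyses crossover (CO) positions measured cytologically as
fluorescent foci along pachytene chromosome axes / synaptonemal complexes
(SCs).  Inputs are already-measured coordinates (microns along each
bivalent), never images.  The package quantifies crossover interference two
ways — a gamma-shape fit to inter-focus spacings and a coefficient-of-
coincidence (CoC) curve — and provides the routine morphometry around them:
focus counts, SC segment numbers and lengths, CO density, the focus-count vs
SC-length regression, and a two-sample t comparison.  A gamma-renewal
simulator generates cohorts with the same statistical structure so every
stage is testable without any measured data.

## The spacing model and the gamma shape nu

Inter-crossover distances are modelled as i.i.d. gamma variates with shape
`nu` and scale `mu/nu`, where `mu` is the mean spacing.  `nu = 1` is the
exponential/Poisson case (no interference); `nu > 1` gives the more even
spacing that interference produces, and larger `nu` means stronger
interference.  The fit maximises the gamma likelihood over all pooled
adjacent-focus distances:

* the scale is concentrated out (`scale = mean/shape`), and the shape solves
  `log(k) - digamma(k) = log(mean(x)) - mean(log x)` by safeguarded Newton
  iteration (Minka-style closed-form start, bisection fallback, bracket
  `[1e-2, 1e3]` with a warning at the clamps);
* zero or negative spacings are dropped with a logged count — the gamma
  density is undefined at 0 for `nu > 1`;
* a zero-variance sample makes the likelihood unbounded in the shape and
  raises a degenerate-sample error;
* `shape_uncertainty` is a seeded nonparametric bootstrap SD over resamples
  of the spacing list (default 1000 resamples in the CLI, 200 in the
  pipeline).  It is reported for orientation only; no claim is made that it
  matches any particular published uncertainty convention.

Distances can be pooled in microns or as percent of axis length
(`units_flag` records the choice).  The shape is invariant under this
rescaling whenever all bivalents share one length; with unequal lengths the
two modes genuinely differ and both are exposed.

Adjacent-focus pairs that span a gap between two SC segments are excluded by
default (`within_segments=True`), matching measurement along SC segments in
fragmented-SC nuclei.

## The CoC construction

For a group of bivalents (default groups: ranks 1–2 and ranks 3–7, ranked
by descending axis length within each nucleus):

1. each bivalent is divided into `n` equal intervals **of its own axis
   length** (relative-position binning); `n` defaults to round-half-up of
   5 × the group's mean CO count, minimum 2;
2. each focus is assigned to one interval, boundary ties going to the
   lower-index interval;
3. the per-interval CO frequency is the fraction of bivalents with ≥ 1 CO in
   that interval;
4. for every pair of distinct intervals, observed = fraction of bivalents
   with a CO in both, expected = product of the two marginal frequencies;
   pairs with expected = 0 are skipped and counted (`n_skipped`);
5. pairs are pooled by interval separation; the CoC of a pooled distance
   class is (sum observed) / (sum expected), and the class distance in
   microns is separation × the group-mean interval length;
6. the **interference distance** is the abscissa of the first upward
   crossing of CoC = 0.5, linearly interpolated between curve points; it is
   0 when the first class is already ≥ 0.5 and "not reached" when the curve
   never attains 0.5.  The threshold is a parameter so other cut-offs can be
   explored.

Design choices where the procedure was genuinely open:

* **Common interval count, per-bivalent interval size.**  Bivalents of
  unequal length must share an interval coordinate to be pooled; we share
  the count and let the micron size scale with each axis.  A consequence,
  measured on synthetic Poisson cohorts, is that pooling bivalents with very
  different lengths inflates every CoC class by a few percent (4–9% across
  the default 7-length geometry), because interval occupancy probabilities
  differ across lengths and E[p_i p_j] > E[p_i]E[p_j] under mixing.  This is
  a property of the pooling design, not an estimator defect; groups of
  similar-length bivalents (the default grouping) keep it small, and the
  statistical validation of the no-interference limit is run on
  constant-length groups where the effect vanishes.
* Unordered interval pairs are enumerated; observed and expected are
  symmetric, so this changes only the pair count bookkeeping, never a CoC
  value.
* No curve smoothing is applied by default and none is used in any reported
  number.

## E-distribution and the obligatory crossover

`e_distribution` tallies the proportion of units (bivalents, or SC segments
in fragmented phenotypes) carrying exactly k foci.  `E0 = 0` is the
signature of the obligatory crossover.  Proportions sum to 1 within 1e-12 by
construction.

## The synthetic generator

`simulate_track` realises the model the gamma fit assumes: a **stationary
gamma renewal process** on `[0, L]`.  Gaps are Gamma(`nu`, `mu/nu`); the
first arrival is `U × Gamma(nu + 1, mu/nu)` — a draw from the length-biased
gap distribution thinned uniformly, which is exactly the equilibrium
residual distribution — so the process is translation-stationary and free of
chromosome-end edge bias.  A non-stationary variant (first gap from the
plain gamma) is available behind `stationary=False` for sensitivity checks.
`mean_spacing = inf` is the zero-intensity sentinel.

Default conditions (user-overridable, chosen once to emulate wild-type-like
pachytene nuclei):

| parameter | default | rationale |
|---|---|---|
| chromosome_lengths | 7 lengths, descending arithmetic progression (step 0.95 um) summing to 52.2 um | total SC per nucleus ~52 um, 7 bivalents of unequal length |
| mean_spacing | 2.35 um | gives E[total foci] = 52.2/2.35 ≈ 22.2 per nucleus |
| shape | 5.0 | wild-type-like interference level |
| nucleus_length_cv | 0.098 | per-nucleus scale factor on all 7 axes (truncated normal), emulating the ~10% nucleus-to-nucleus spread of total SC length; without it the count-vs-length regression is degenerate by construction |
| obligate_co | False | the unconditioned renewal process is the reference model; the obligate option conditions on ≥ 1 focus by rejection, which preserves the spacing law given a non-zero count |
| noise_sd | 0 | no measurement-error model is assumed; optional Gaussian jitter is clipped to the segment |

`fragment_track` emulates fragmented-SC phenotypes: `n_segments` disjoint
segments keep `retained_fraction` of the axis (each segment at least
`min_segment_length`, default 0.2 um; infeasible geometry raises an error),
the free length is split into gaps with exponential weights and the two
outer gaps down-weighted by `1 + end_bias` so segments crowd towards
chromosome ends; foci outside retained segments are deleted.  Fragmentation
can only delete foci, never create them.  The default mutant-like setting
(2 segments per bivalent, retained fraction 0.6, end bias 2) yields 14 SC
segments per 7-bivalent nucleus at 60% of full SC length, end-biased —
matching the fragmented-SC phenotype the mode emulates.

What the generator does **not** emulate: spatially varying CO intensity
along a chromosome (centromere/telomere effects), between-bivalent coupling
within a nucleus, focus-detection error (merged or missed foci), or any
mechanistic interference model (beam-film etc.).  Passing tests therefore
demonstrate correctness of the estimators under the stationary-renewal
model, not that real chromosomes follow it.

## Numerical choices and degenerate inputs

* Gamma MLE: Newton on the digamma equation, tolerance 1e-12 relative,
  bisection-safeguarded; shape clamp `[1e-2, 1e3]`.
* Interval assignment: `ceil(p/size) - 1` with position 0 in interval 0;
  exact boundary positions go to the lower interval.
* Regression: closed-form normal equations; a numerically constant design
  (relative Sxx below 1e-20) raises a degenerate-design error.
* Sample SD uses the n−1 denominator throughout; a single observation
  reports sd = 0 with a warning.
* Two-sample comparison: pooled-variance Student t by default, Welch behind
  a flag (delegated to `scipy.stats.ttest_ind`).
* Every dropped datum — zero spacings, skipped CoC pairs, cross-gap focus
  pairs — is counted and logged; exclusions are never silent.
* Serialisation uses 17-significant-digit floats so CSV round-trips are
  bit-identical.

## Problem sizes used in the validation suite

The statistical validation runs at sizes chosen so that Monte-Carlo noise is
small against the tolerances being checked: gamma recovery pools ~30,000
spacings (2,000 nuclei) per shape; the Poisson CoC limit uses 20,000
constant-length bivalents; interference-distance monotonicity uses 4,000–
6,000 bivalents per shape and 3 seeded replicates; E0 checks use 10,000
track replicates against the renewal prediction
`P(N=0) = ∫_L^∞ S(x) dx / mu` evaluated by quadrature.

## Known limitations

* The fitted shape on finite bivalents carries a small upward
  finite-window bias (~+4–7% at the default geometry, strongest at low
  `nu`): long spacings are preferentially censored by the chromosome ends.
  The fit deliberately implements the plain pooled-spacings MLE — the
  field's standard procedure — rather than a window-censoring correction.
* CoC values at large inter-interval separations rest on few interval pairs
  and are noisy in small cohorts; `n_pairs` is reported per distance class
  so users can judge.
* The workbook reader ingests raw numeric tables only; mapping worksheet
  columns onto the focus-table schema is intentionally explicit and
  user-supplied, since supplementary-workbook layouts are not standardised.
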