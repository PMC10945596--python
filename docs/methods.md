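# Methods

`longcall` implements the statistical machinery for detecting *recursive
(self-embedded) isochrony* in two-stratum vocal sequences: call series in
which a higher-level element (the full pulse of a great-ape long call)
repeats at a near-constant tempo, while each pulse internally carries a
train of sub-pulses repeating at a faster, type-specific near-constant
tempo. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot establish.

## Rhythm ratios and isochrony bands

For each element type, inter-onset intervals are defined from begin times
only: t_k = onset(k+1) − onset(k) for consecutive same-type elements of one
long call. Sub-pulse intervals additionally require both elements to share
their enclosing full pulse (`within_parent`, default on), so no sub-pulse
interval spans a pulse boundary; the flag exists because cross-pulse gaps
reflect pulse-level, not sub-pulse-level, tempo. Intervals outside the open
window (0.025 s, 5 s) are discarded; removing an interior interval splits
its run, so ratios never bridge a discarded interval.

Adjacent intervals of one run give the scale-free rhythm ratio
r_k = t_k / (t_k + t_{k+1}), which is 0.5 for perfect isochrony, 1/3 and
2/3 for a 1:2 alternation, and invariant under any global time rescaling.
Ratios are classified into an on-isochrony band (0.440, 0.555) and two
off-isochrony flanks (0.400, 0.440) ∪ (0.555, 0.600). Band membership uses
strict inequalities exactly as the band definitions are written; a boundary
value falls in no band. This costs nothing for continuous data
(measure-zero events) and keeps the counting rule unambiguous.

Distribution peaks are read from a Gaussian kernel density estimate:
Silverman's rule bandwidth (overridable), 512-point grid on [0, 1], no
boundary correction. The estimator behind published peak values in this
protocol lineage is not standardized, so peak agreement beyond ~2 decimal
places is bandwidth-sensitive; the bandwidth is therefore exposed. Two
peaks are reported: the global argmax and the argmax restricted to the open
window (0.400, 0.600), the latter being the headline on-isochrony peak. A
degenerate sample (zero variance) falls back to a narrow fixed kernel
rather than failing.

Tempo summaries report both mean(t_k) and mean(1/t_k). These differ
substantially for pooled heterogeneous sequences (Jensen's inequality): a
pooled sub-pulse set with mean interval ~0.18 s has a mean per-interval
rate near 9 Hz, not 1/0.18 ≈ 5.4 Hz. The per-interval mean is the reported
rate.

## Nested (cross-stratum) ratios

The link between strata is nested_ratio = t_k(sub-pulse) / t_k(enclosing
full pulse), where the enclosing pulse's interval is onset-to-next-onset
(consistent with all intervals being onset-based, not pulse duration).
Sub-pulses inside a call's final pulse have no enclosing interval and are
dropped. Concentration of nested ratios is quantified by (a) the KDE peak
on [0, max] and (b) a peakedness test: per unit (long call by default) the
sorted ratios are split into four equal-count blocks; the *central extent*
is the span of the pooled 2nd+3rd blocks and the *peripheral extent* is
the summed span of the 1st and 4th blocks. "Extent" has no canonical
definition in this protocol; the summed-outer-spans form was chosen because
pooling the outer blocks into one span would contain the central span by
construction, making the test vacuous, whereas under a uniform
distribution the two extents defined this way are equal in expectation —
giving the test a proper null. Extents are compared across units with a
one-sided Wilcoxon signed-rank test (central < peripheral): exact null
distribution up to 25 non-zero differences (ties force the normal path),
normal approximation with continuity correction beyond; zero differences
are dropped, and differences equal up to a 1e-9 relative tolerance count
as zero. The pairing unit is a parameter: published W statistics from
other pairings are not expected to be reproduced.

## Band-count model

Whether on-isochrony observations outnumber off-isochrony ones is tested
with a negative-binomial log-link regression on counts aggregated per
element type × individual × band:

    count ~ element_type * band + individual,  offset = log(band_width)

The offset (log 0.115 for on, log 0.085 for off) converts counts to
densities per unit ratio width, so the null of "no band preference" is
counts proportional to widths. Individuals enter as fixed adjustment
terms: with ~10 subjects a variance component for a random intercept is
poorly identified, and the fixed-effect form keeps the model inside the
scientific Python stack; the result records `strategy="fixed_effect_nb"`.

Two numerical choices matter. First, fits are warm-started from the
Poisson solution and run through a BFGS → Newton → Nelder–Mead ladder,
accepting the first fit with finite parameters, likelihood and standard
errors. Second, the likelihood-ratio test against the null model
(individual + offset only) holds the dispersion fixed at its null-model
estimate rather than re-profiling it in each model: at field-study sample
sizes (tens of count cells) separate profiling makes the LRT markedly
anti-conservative (~12% type-I at nominal 5% in our simulations), while
the fixed-null-dispersion LRT is calibrated (~6–8%) and merely
conservative under strong alternatives. Per-type on-vs-off contrasts are
Wald tests from the full maximum-likelihood fit (the applied convention),
Bonferroni-adjusted across types; with the default band coding a positive
estimate means higher on-band density. An exact one-sided binomial test
per type (null proportion 0.115/0.200 = 0.575) is provided as a
model-free cross-check.

## Crossed permuted discriminant function analysis

The pDFA asks whether sub-pulse types are acoustically distinct on the
seven spectrogram measures while controlling for individual identity.
Cases are (control level × test level) cells; cells with fewer than two
cases are dropped with a warning, then control levels left with fewer than
two test levels. Balanced selection draws, per control level, the smallest
cell count of that level from every test level (cap configurable); a
Fisher LDA (pooled within-class covariance, priors proportional to
selected-class frequencies, scikit-learn solver) is fitted on the selected
cases, and accuracy is recorded on the selected cases and on the held-out
remainder. The observed value averages `n_sel` = 100 such cycles. The
null distribution runs `n_perm` = 1000 cycles after shuffling test labels
*within* control levels only — the permutation never moves a case across
individuals, which is what makes the design crossed. Because within-block
shuffling preserves per-cell counts, selection sizes are identical under
permutation. The p-value uses the add-one convention,
p = (1 + #{null ≥ observed}) / (n_perm + 1), so its floor is 1/(n_perm+1);
the chance level is reported as the mean of the null distribution, which
correctly exceeds 1/k for unbalanced designs. Features are used
untransformed (LDA is affine-equivariant); a standardization flag and an
LDA shrinkage term exist for ill-conditioned inputs, and an exactly
singular pooled covariance raises with advice to use them.

One calibration subtlety: the averaged observed statistic (n_sel = 100) is
less noisy than the single-cycle null statistics, so under the null the
p-value is conservative (concentrated around the middle), not uniform.
The calibration test therefore runs the observed side with n_sel = 1,
making observed and null cycles exchangeable, under which p is uniform up
to permutation-grid discreteness.

## Synthetic generator

`SyntheticSpec` defaults encode the study conditions: 10 individuals,
~66 long calls, ~25 pulses per call, full-pulse interval mean 1.696 s with
total cv 0.3, sub-pulse interval means 0.118 s (grumble), 0.239 s
(transitory), 0.186 s (bubble) with total cv 0.3, ~8 sub-pulses per pulse
truncated to fit inside the pulse interval.

Timing variation is multiplicative lognormal throughout (intervals stay
positive; cv is scale-free) and is decomposed exactly on the log scale:
individual factor (log-sd 0.1) × per-call tempo factor shared by both
strata × local per-interval jitter (cv 0.1), with the call factor
absorbing the remainder so each stratum's *marginal* cv equals the
requested total. This decomposition is the substantive modelling choice:
an isochronous sequence has a locally stable tempo, so pooled interval
SDs (which mix individuals and calls) are large while adjacent intervals
are similar. Putting the full cv into iid per-interval jitter instead
would produce ratio distributions far wider than real isochronous data,
only weak on-band dominance, and a nested-ratio mode biased low by
exp(−2·ln(1+cv²)) ≈ 0.84 — i.e. it would fail to emulate the phenomenon
the analysis is built to detect. Because the call-level factor multiplies
both strata, it cancels in nested ratios, whose mode then sits within ~2%
of the sub/full tempo ratio.

Each pulse carries exactly one sub-pulse type. The positional layout puts
grumbles in the first 20% of a call's pulses, transitory elements next,
isolated single pulse-body elements before a block of uninterrupted
(climax) pulses, and bubbles in the tail-off 40% — mirroring build-up /
climax / tail-off structure. Pulse bodies are emitted one per pulse, so
they generate essentially no same-type adjacent intervals; this reproduces
the degenerate element type for which the pipeline must report "no
ratios" rather than fail. Acoustic vectors for the three staccato types
are Gaussian with a shared diagonal covariance; type means sit at the
vertices of an equilateral triangle of side 1.5 pooled SDs in the
duration × peak-frequency plane — a regime where LDA accuracy is
meaningfully between chance and perfect — plus a per-individual offset
(0.5 feature-SD), which is what makes the individual-controlling design
worth testing. `anisochrony_ratio` switches the pulse stratum to a
short:long alternation with preserved mean, the standard negative control
(ratios at 1/3 and 2/3, no isochrony peak).

`generate_null_counts` emits band-count tables with density exactly
proportional to band width (negative binomial, dispersion 0.05) for
calibrating the count model.

What the generator does **not** emulate: long-call climax acoustics,
amplitude or frequency contours, drift or autocorrelation in tempo beyond
the call-level factor, mixed sub-pulse types within one pulse, missing or
mislabelled annotations, and recording noise in the seven measures.
Passing recovery and calibration tests on these data therefore shows the
estimators are correct and calibrated under the assumed structure — not
that real recordings satisfy that structure.

## Problem sizes and reproducibility

All randomness flows through `numpy.random.default_rng` seeds carried in
the specs/configs; fixed seeds make every result, including the full pDFA,
bit-reproducible. The test suite exercises parameter recovery over 20
generator seeds, count-model calibration over 500 null tables, and pDFA
null calibration over 200 replicate datasets at n_perm = 200 — sizes
chosen to put Monte-Carlo error well below the tolerances being asserted
while keeping a full run in a few minutes on one core. The acceptance
script (`scripts/acceptance.py`) recomputes the headline quantities from
scratch at the same sizes.

## Known limitations

- The random-intercept negative-binomial model used in the original
  protocol lineage has no Python implementation; the fixed-effect
  adjustment is a different (more conservative at these sizes) estimator
  of the same contrast.
- KDE peak locations are bandwidth-dependent at the third decimal; treat
  published-vs-recomputed peak differences below ~0.01 as estimator noise.
- The quartile-extent "extent" and the Wilcoxon pairing unit are
  package-defined conventions; statistics computed under other conventions
  (including published W values) are not comparable.
- Reproducing the published field numbers requires the archived field
  annotation tables, which must be supplied externally (see README); they
  are not redistributable within the package.
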