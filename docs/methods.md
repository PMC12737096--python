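# Methods

This note documents the models and procedures gaitval implements, the
conventions chosen where several exist, and what the synthetic-data tests do
and do not demonstrate about real recordings.

## Gait parameters from foot-contact events

A trial is a set of heel-strike (HS) and toe-off (TO) times for each foot plus
the forward position of each heel strike. A gait cycle runs between
consecutive ipsilateral heel strikes (0-based index, half-open in time), and
within a complete right cycle the events must interleave as
HSr(k) < TOL(k) < HSL(k) < TOr(k) < HSr(k+1); the mirrored pattern defines
left cycles, and incomplete terminal cycles are discarded rather than
extrapolated. Per right cycle k:

* GCT(k) = HSr(k+1) − HSr(k)
* stride SL(k) = xHSr(k+1) − xHSr(k); step STPL(k) = xHSr(k+1) − xHSL(k)
  (the displacement of the step that ends the cycle)
* velocity V(k) = SL(k)/GCT(k)
* stance ST(k) = (TOr(k) − HSr(k))/GCT(k)·100; swing SW(k) = 100 − ST(k),
  computed as the complement so the partition ST + SW = 100 holds exactly in
  floating point rather than only algebraically
* single support SS(k) = (HSL(k) − TOL(k))/GCT(k)·100 — the contralateral
  foot's swing interval, which is the time only the reference foot is on the
  ground. A legacy operand order (HSr(k) − TOL(k), which is negative under
  the interleaving above) is selectable via ``ss_formula="printed"`` for
  auditing other software, never as a default.

Cadence is trial-level: 60·steps/walk-time, with the step count defaulting to
the number of heel-strike events and the walk time to the heel-strike span
when not supplied. Per-cycle values are averaged within each side and the two
side means averaged with equal weight. If one side yields no complete cycle
the other side is used alone, with a logged warning.

Positions are one-dimensional along the walking direction; the direction is
taken from the sign of the net heel-strike displacement and positions are
re-oriented so progress is positive, which makes the computation invariant to
the lab's axis convention. All parameters are invariant to time and position
translation; scaling time by c divides velocity and cadence by c and leaves
the percentage phases unchanged (tested properties).

## Reliability: ICC, SEM, MDC

Intra-rater (test-retest) reliability uses the one-way random-effects,
single-measure ICC(1,1) = (MSB − MSW)/(MSB + (k₁−1)MSW); inter-rater
reliability uses the two-way random-effects, absolute-agreement ICC(2,1) =
(MSB − MSE)/(MSB + (k₂−1)MSE + k₂(MSR − MSE)/n). Mean squares come from the
classical balanced decompositions, implemented directly and verified in tests
against both a definitional sum-of-squares oracle (to 1e−12) and pingouin's
ANOVA-based implementation. Only balanced designs are accepted; subjects with
missing cells are dropped upstream with a logged count, so every reported n
is the number of complete subjects used.

Confidence intervals use the standard F-pivot construction for ICC(1,1) and
the Satterthwaite approximation for ICC(2,1) (McGraw–Wong conventions,
cross-checked against pingouin). Results carry a note flagging the CI
convention because no published reference intervals were available to verify
against.

SEM = spread·√(1 − ICC). The "spread" is a convention, not a single
definition, and different groups use different ones, so it is configurable:
``pooled_sd`` (default — the square root of the mean per-session sample
variance, the conventional choice), ``rms_of_values`` and
``rms_of_differences``. MDC = SEM·1.65·√2 at 90% confidence; 1.65 is kept as
the literal constant rather than recomputed from a quantile so the constant
is bit-for-bit stable. ICC bands: < 0.40 poor, 0.40–0.75 moderate, 0.75–0.90
good (exclusive), ≥ 0.90 excellent.

## Validity battery

All comparisons pair per-subject values, by default the mean of each
subject's available trials per system (configurable to a single
rater/session), since trial averaging is also how the per-subject parameters
themselves are formed. α = 0.05 throughout.

**Paired test.** Shapiro–Wilk on the differences gates a two-tailed paired
t-test (normal) vs Wilcoxon signed-rank (non-normal). All-zero differences
return p = 1 with a degenerate flag; constant non-zero differences (Shapiro
undefined) route to Wilcoxon.

**Spearman.** Computed via scipy (Pearson on average ranks); the test suite
checks tie handling against an explicit rank-table oracle. Bands on |r|:
≤ 0.25 weak, ≤ 0.55 moderate, ≤ 0.75 strong, above that very strong. The
conventional verbal scale leaves gaps between its ranges; the cut points
close those gaps at their midpoints.

**Passing–Bablok.** The default is the simplified form: slope m = median of
all pairwise slopes m_ij = (y_j − y_i)/(x_j − x_i) over i < j with x_i ≠ x_j
(undefined slopes excluded from N); C₀.₀₅ = 1.96·√(n(n−1)(2n−5)/18); CI rank
indices L = round((N − C₀.₀₅)/2) and U = round((N + C₀.₀₅)/2), rounded half
away from zero, clamped to [1, N], 1-based into the ascending slopes; ties
kept. Intercept q = median(y_i − m·x_i) with CI endpoints computed from the
slope CI endpoints and sorted ascending (the endpoint pairing can invert for
negative-slope data). This simplified estimator is adequate for
positively-correlated method comparison, the only regime the verdict logic is
meant for; the classical variant with the offset K (slopes below −1 shift the
median and CI ranks, slopes equal to −1 excluded) is available via
``variant="classical"`` for cross-checking against standard implementations.
The rounding convention for L and U is not universal; round-half-away was
chosen and is pinned by a direct-arithmetic test (n = 10: N = 45,
C₀.₀₅ ≈ 16.97, L = 14, U = 31).

**Bland–Altman.** bias = mean(y − x), SD with the n−1 denominator,
LOA = bias ± 1.96·SD, bias CI = bias ± 1.96·SD/√n. The normal 1.96 is used
rather than a t quantile; at n ≈ 30 this makes the bias CI cover 0 in about
94% of null replicates rather than 95% (measured by the calibration test),
a deliberate convention, kept because it is the one standard in this
literature.

**Verdict.** Constant systematic error when 0 lies outside the BA bias CI or
outside the PB intercept CI; proportional systematic error when 1 lies
outside the PB slope CI; "agreement" iff neither fires, with the error types
listed otherwise.

## Synthetic cohort generator

The generator emulates the design of a walkway validation study: by default
30 subjects, 2 raters × 2 sessions each, an 8 m walkway, and two systems
("mocap" reference, "imu" test) recording every walk simultaneously.
Subject-level truths draw cadence, stride length, step length and stance
phase as independent normals from healthy-adult reference moments
(cadence 120.13 ± 10.13 steps/min, stride 1.38 ± 0.13 m, step 0.69 ± 0.06 m,
stance 61.76 ± 2.58 %GCT); velocity, swing and single support follow from
velocity = stride·cadence/120, swing = 100 − stance, and single support =
swing − ds_asymmetry (default 0, i.e. equal double-support halves, making
single support equal the contralateral swing as healthy gait shows).
Non-physiological draws are rejected and redrawn, capped at 100 attempts.

Trial-to-trial noise perturbs the independent quantities (default SD: half
the between-subject SD, i.e. a true test-retest ICC of 0.80 — the level such
studies are typically powered to detect) and the derived parameters are
recomputed, so stance and swing stay complementary within a trial. A
per-parameter additive rater shift models rater effects. Both systems then
record the *same* trial value through linear error models a + b·x + ε — the
shared trial is what gives the two systems realistic correlation, and a and b
are exactly the constant and proportional errors the validity battery must
detect.

Event streams are generated as periodic symmetric gait: right heel strikes
every GCT = 120/cadence, left events half a cycle later, toe-offs placed to
realise the requested stance and single support, and heel-strike positions
advancing by the stride. Feasibility requires 50 < stance < 100 and
0 < single support < 50 (otherwise double support would be negative) and
0 < step < stride. Two identities are inherent to side-averaged event
geometry, not to this generator: averaged step length always equals
stride/2, and averaged stance plus averaged single support always equal 100.
``representable_truth`` projects an arbitrary truth vector onto that
manifold; for projected truths the generate → extract → summarize round trip
is exact to machine precision (tested at 1e−9), and ``walk_duration`` is set
to 60·steps/cadence so cadence round-trips exactly despite the finite
walkway. Optional Gaussian jitter on the within-cycle events emulates
event-detection noise.

What the generator does **not** model: cross-parameter correlation beyond the
deterministic constraints (real velocity–stride–cadence covariation is
richer), left/right asymmetry, stride-to-stride autocorrelation, fatigue or
learning effects across sessions, and any signal-level behaviour (drift,
event-detection failure modes of a trunk-mounted sensor). Passing tests
therefore demonstrate that the statistics recover what the error models
inject under study-shaped sampling — not that any particular hardware is
valid.

## Problem sizes and numerical choices

The test suite and acceptance script use Monte-Carlo sizes chosen to keep
sampling error well inside the asserted tolerances while remaining quick on
one CPU: 100 random instances for the brute-force oracle comparisons, 500
replicates (n = 30, k = 2) for ICC recovery within ±0.05, 200 replicates
(n = 28) for error-detection rates above 90%, and 1000 replicates for null
calibration (bias-CI coverage 95 ± 3 points, paired-test type-I error in
[0.03, 0.07]). Degenerate inputs are handled explicitly: zero total variance
makes the ICC undefined (raised, not NaN), all-tied data make Spearman
undefined, fewer than five pairs reject Passing–Bablok, and identical systems
produce degenerate-but-valid results (ICC = 1, zero-width LOA, agreement).

Report tables round to 2 decimals for display, with full-precision companion
CSVs; p-values print with a "<0.001" floor alongside a raw machine-readable
column. Reports are deterministic: the same table and seed regenerate
byte-identical files, and the run log records the inclusion counts, seed and
a hash of the input table.
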