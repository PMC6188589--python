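# Methods

## The statistic

Extrasystolic coverage of a record of duration T (default 86 400 s) with
eligible extrasystoles at times t₁ … tₙ is

    C = |⋃ᵢ [tᵢ, tᵢ + w) mod T| / T,   w = 1800 s.

Windows are half-open: the instant of the extrasystole counts as
covered, the instant exactly w later does not (a measure-zero
convention fixed for reproducibility). The time axis is circular by
default: an event in the last 30 minutes covers the start of the
record. A `wrap=False` mode truncates windows at T for recordings that
are not a complete circadian cycle. Implementation merges the sorted
half-open windows into disjoint intervals and sums lengths; tests
compare it to an independent 1-second-grid marking oracle, which is
exact for integer event times.

Per-type coverage (V, S, U) uses only events of that type, so overall
coverage is the coverage of the union of the three event sets —
guaranteeing `C_all ≥ max(C_V, C_S, C_U)` and
`C_all ≤ C_V + C_S + C_U`.

Records flagged not analyzable are assigned C = 0 (overall and per
type) while their observed event count is retained. The flag is an
analyst's judgment carried in metadata, never inferred from the
signal: automated atrial-fibrillation detection is out of scope.

## Detection rule

An interval index i is a candidate iff both clauses hold:

1. `rr[i] < (1 − 0.20) · rr[i−1]` — strictly; an exactly-20% reduction
   does not trigger ("more than 20%").
2. every interval in the 10-interval baseline window deviates at most
   10% (again strict at the boundary) from the window median; the
   median of an even window is the midpoint of the central order
   statistics.

Design choices that the rule's verbal statement leaves open:

* The baseline window is `rr[i−10 … i−1]`, i.e. it **includes** the
  reference interval of clause 1, so the interval the reduction is
  measured against is itself certified as sinus. A `window_offset=1`
  config shifts the window one interval earlier for sensitivity
  analysis of this anchoring.
* Indices with fewer than ten real preceding intervals are never
  candidates; there is no padding or partial-window evaluation, so the
  first possible candidate is interval index 11.
* Detection consumes RR values only. Labels (and human rating) enter
  at classification; an optional exclusion mask can drop candidates in
  unreadable segments but defaults to none.

A useful emergent property: closely coupled ectopy (bigeminy) is
self-rejecting, because each event's coupling interval and pause fall
inside the next event's baseline window and exceed the 10% band.

## Classification and adjudication

The ventricular criteria (QRS > 120 ms, absent P-wave, altered T-wave)
are consumed as features, not computed from waveforms — visual
morphology assessment is upstream of this package. All three satisfied
→ V; none → S; one or two → U. Forcing partial matches to U replaces a
human judgment call with a deterministic rule that biases per-type
coverages downward, never upward, and matches the predominantly
conservative behavior observed in practice.

Adjudication of two raters is symmetric and conservative by default:
agreement passes through, type disagreements within {V, S, U} become
U, and any disagreement about eligibility itself becomes X (not
eligible). An `eligible-wins` policy is provided for sensitivity
analysis. Collapsing {V, S, U} → "eligible", X → "erroneous" yields the
two-super-category agreement analysis; collapsing can only increase
percent agreement.

## Cohort statistics

The cohort estimate is the arithmetic mean of per-record coverages, in
two variants: *all-records* (non-analyzable records at their assigned
0%) and *analyzable-only*. Confidence intervals use the percentile
bootstrap with 10 000 resamples by default: records (patients) — not
beats — are resampled with replacement, the mean recomputed, and the
empirical α/2 and 1−α/2 quantiles returned using the
linear-interpolation quantile convention (the choice of quantile
convention is documented here because it is not standardized). The
generator is seeded; per-type CIs derive child seeds from the one
summary seed so the four intervals are jointly reproducible.

Interrater agreement: simple percentage agreement and unweighted
Cohen's kappa κ = (p_o − p_e)/(1 − p_e), with p_e from the product of
the raters' marginal frequencies. If both raters are constant and
identical, κ is returned as 1 with a warning (p_e = 1 makes the
formula indeterminate). Internal values are never rounded; display
rounds coverage to one decimal.

## Synthetic generator

The generator emulates the statistical structure the detector relies
on, at the RR level only:

* sinus RR at time t: `(60/HR)·(1 + A·sin(2πt/86400 + φ))·(1 + ε)`,
  HR = 80 bpm, circadian amplitude A = 0.08, ε Gaussian with
  CV = 0.03, truncated (clipped) at ±3 SD so intervals stay positive
  and the probability of a baseline-band failure is controllable.
  φ is randomized per record unless pinned.
* V events: coupling interval 0.6·r, full compensatory pause
  (2 − 0.6)·r (the sinus lattice is preserved); S events: the same
  coupling with a resetting pause of one r, advancing all later beats
  by 0.4·r. r is the local noiseless sinus RR. Coupling at 60% of the
  sinus interval gives a ~40% reduction, comfortably beyond the 20%
  rule in the noiseless limit.
* event times are two independent Poisson processes, thinned to a
  minimum separation of 12 beats so each event's 10-interval baseline
  is pure sinus — every kept event is *eligible by construction*,
  giving sensitivity analyses an exact denominator. An unthinned mode
  exists to exercise the bigeminy-rejection property.
* optional atrial-fibrillation segments draw RR iid Uniform(0.35 s,
  1.20 s) and suppress ectopic insertion; a record with AF segments is
  flagged not analyzable.

Default event rates are 0.7 VES/h and 1.3 SVES/h. For a Poisson
process the expected coverage is 1 − e^(−λw); these rates put a
default record's expected overall coverage near 63% and the per-type
coverages near 30% (V) and 48% (S), i.e. in the middle of the range
reported for analyzable septic ICU recordings, while individual
records still vary widely.

What the generator does **not** emulate: waveform morphology, realistic
HRV spectra (LF/HF structure), pacing spikes, artifact bursts, or
clustered ("salvo") ectopy beyond the Poisson model. Passing
parameter-recovery tests therefore demonstrates correctness of the
pipeline's logic under its stated assumptions, not detector
performance on real ECG annotations, where baseline instability and
artifacts will reduce sensitivity.

## Numerical choices and problem sizes

* Strict inequalities at both rule boundaries; boundary tests use
  binary-representable values to avoid floating-point ambiguity.
* RR intervals below 0.2 s are rejected as annotation errors unless
  explicitly allowed; beat times round-trip through CSV at 1 ms.
* Oracle comparisons run 200 random cases each (event sets ≤ 500,
  RR series ≤ 5000); parameter recovery uses five simulated 24 h
  records (~1200 inserted events) at CV = 0.02 where detection is
  provably exact (the ±3 SD clip bounds any sinus ratio above 0.88,
  clear of the 0.8 trigger); bootstrap calibration uses 500 cohorts of
  n = 42 Beta(2, 1.2) coverages with 2000 resamples. These sizes make
  the whole suite run in seconds while keeping Monte-Carlo error well
  inside the asserted bands.

## Known limitations

* The eligibility of a candidate ultimately rests on visual rating;
  the deterministic morphology rule here is a stand-in at the
  boundaries (1–2 criteria met).
* Coverage weights all covered minutes equally; decaying-relevance
  windows are deliberately out of scope.
* Non-analyzable status must be supplied; the package does not detect
  atrial fibrillation.
* The bootstrap is percentile-only (no BCa/studentized variants), and
  kappa is unweighted, matching the analysis this package reproduces.
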