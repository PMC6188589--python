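# escov — extrasystolic coverage of 24 h RR-interval recordings

Fluid-responsiveness prediction from extrasystoles exploits the beat
that follows an ectopic heartbeat: the compensatory pause augments
preload, so the post-ectopic pressure response probes the patient's
position on the Frank–Starling curve. The method is only usable when
extrasystoles actually occur, which raises a quantitative question:
**for what fraction of the time is a recent extrasystole available?**

`escov` implements that quantification for critically ill (e.g. septic
ICU) patients as a tested, reusable pipeline operating on beat
annotations of long-term ECG:

* **Detection** — a potentially eligible extrasystole is an RR interval
  reduced by more than 20% relative to its predecessor
  (RRᵢ < 0.8 · RRᵢ₋₁), with a sinus baseline: none of the ten preceding
  RR intervals deviates more than 10% from their median.
* **Classification / adjudication** — candidates are typed as
  ventricular (V), supraventricular (S) or of unknown origin (U), or
  rejected as erroneous (X); two raters' labels are merged by a
  conservative policy (type disagreement → U, eligibility
  disagreement → X).
* **Extrasystolic coverage** — the fraction of the recording lying
  within 30 minutes after at least one eligible extrasystole,

  `coverage = |⋃ᵢ [tᵢ, tᵢ + w)| / T`,  w = 1800 s, T = 86 400 s,

  computed on a circular clock ("closed time loop"): a window crossing
  the end of the 24 h record wraps to its beginning. Records that are
  not analyzable (atrial fibrillation, pacing) are assigned 0%.
* **Cohort statistics** — mean coverage across records (all records,
  or the analyzable subgroup) with percentile-bootstrap confidence
  intervals (10 000 resamples of records), plus interrater agreement:
  simple percentage agreement and unweighted Cohen's kappa, before and
  after collapsing {V, S, U} vs X.
* **Synthetic data** — an arrhythmia-aware RR-tachogram generator
  (circadian sinus rhythm, V ectopics with full compensatory pause,
  S ectopics with resetting pause, optional atrial-fibrillation
  segments, simulated raters with confusion matrices) so the entire
  pipeline is testable without clinical waveforms.

## Worked example

```python
from escov import (SimConfig, simulate_record, rr_from_beats,
                   detect_candidates, coverage_by_type)

beats, truth = simulate_record(SimConfig(seed=42, record_id="demo"))
cands = detect_candidates(rr_from_beats(beats))
events = [(c.time_s, str(beats.labels[c.beat_index])) for c in cands]
res = coverage_by_type(beats, events)
print(f"beats: {beats.n_beats}, inserted ectopics: {len(truth.times)}, "
      f"candidates: {len(cands)}")
print(f"coverage overall {100*res.coverage_all:.1f}%  "
      f"V {100*res.coverage_v:.1f}%  S {100*res.coverage_s:.1f}%")
print(f"ground-truth coverage {100*truth.true_coverage:.1f}%")
```

prints

```
beats: 115584, inserted ectopics: 48, candidates: 46
coverage overall 63.9%  V 30.3%  S 47.8%
ground-truth coverage 67.1%
```

A simulated 24 h record at 80 bpm carries ~115 000 beats; 48 ectopics
were inserted and 46 recovered (at the default 3% beat-to-beat
variability the sinus-baseline clause occasionally rejects a true
event, so the detected coverage of 63.9% slightly under-reads the
ground truth of 67.1%). Roughly two eligible events per hour suffice to
cover about two thirds of the day — availability is governed by event
*spacing*, not raw counts.

The same flow is available from the shell:

```sh
escov simulate --seed 42 --out rec0/ --record-id rec0
escov run --input-dir . --out-dir out/ --seed 7       # detect → adjudicate → coverage → cohort
escov agreement --rater1 a.csv --rater2 b.csv --collapse eligibility --out agreement.json
```

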