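# ppgloss

Discriminating **hypovolemia** (blood loss, BL) from **euvolemia** (no
blood loss, NBL) in multi-channel photoplethysmographic (PPG) recordings.

Early hemorrhage is notoriously hard to spot: heart rate and blood
pressure barely move until roughly 30% of circulating volume is gone. The
pulsatile amplitude of the PPG, however, declines as blood volume falls.
`ppgloss` implements a full detection pipeline around that signal, for
researchers in physiological monitoring and for anyone who wants a
reproducible, testable reference implementation of the method:

1. **Channel selection** — of the several channels a multi-channel pulse
   oximeter records, keep the one with minimum histogram Shannon entropy
   (an inverse signal-quality proxy).
2. **Time-frequency analysis** — variable-frequency complex demodulation
   (VFCDM), a two-stage demodulation (fixed band centers, then refinement
   along each band's instantaneous-frequency trajectory) yielding a
   high-resolution amplitude spectrum A(t, f).
3. **AM_HR trend features** — per 2-minute sequence (seven 1-minute
   windows, 10-s shifts), the mean of max_{f ∈ [0.66, 3] Hz} A(t, f): the
   heart-rate-band amplitude AM_HR. An ordinary-least-squares line
   through AM_HR versus time gives the 4-feature vector
   (r², slope, % change, signed change); negative trends indicate
   blood loss.
4. **Evaluation protocol** — undersample the majority class to balance
   (e.g. 65 NBL → 29 vs 29 BL), repeat over 10 resamples × 10 row
   permutations, and run stratified 4-fold cross-validation of a
   soft-margin RBF-SVM (K(x,y) = exp(−γ‖x−y‖²)) on every cell of a
   7 γ × 58 C grid; average overall accuracy (OA), sensitivity and
   specificity per cell over the 100 runs and report the optimal cell.

A seeded synthetic PPG generator (pulse with harmonics, respiratory
modulation, baseline wander, per-channel noise, linear envelope decay for
the BL class) makes the whole pipeline testable without clinical data.
See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
import pandas as pd
from ppgloss import (SimConfig, simulate_record, featurize_record,
                     clinical_cohort, simulate_cohort,
                     ExperimentConfig, run_experiment, build_param_grid, report)

# one bleeding subject: envelope decays 50% over a 600 s recording
rec = simulate_record(SimConfig(amp_decay_frac=0.5, seed=3), label="BL")
res = featurize_record(rec)
print(res.channel_index, res.series.values.round(3))
print(res.vector)
```

```
0 [0.952 0.851 0.751 0.65  0.551]
FeatureVector(r2=0.9999898360565191, slope=-0.0008347169045682053,
              pct_change=-42.08996657105589, abs_change=-0.4004922325324919)
```

The selected channel (index 0) is the least noisy of the three simulated
channels; the five AM_HR estimates (one per 2-minute sequence) fall almost
linearly (r² ≈ 1) by 42.1% — the envelope decays 50% end-to-end, and the
sequence centers sample it at 60 s and 540 s, so −42.1% is the exact
expected endpoint change. The negative slope and changes mark the record
as hypovolemic.

```python
# full protocol on the 29 BL / 65 NBL synthetic cohort
rows = []
for rec, label in simulate_cohort(clinical_cohort(seed=101)):
    v = featurize_record(rec).vector
    rows.append({"record_id": rec.record_id, "label": label, "r2": v.r2,
                 "slope": v.slope, "pct_change": v.pct_change,
                 "abs_change": v.abs_change})
table = pd.DataFrame(rows)
result = run_experiment(table[table.label == "BL"], table[table.label == "NBL"],
                        ExperimentConfig(seed=0), build_param_grid())
print(report(result)[1])
```

```
optimal gamma=0.001  C=0.01  (averaged over 100 runs)
                 True BL    True NBL
Predicted BL     100.00%      0.00%
Predicted NBL      0.00%    100.00%
OA               100.00%
```

The synthetic cohort's classes are separable by construction (envelope
decay 0.3–0.6 for BL vs drift ±0.05 for NBL), so the protocol recovers
them perfectly; shuffling the labels drives accuracy to chance (~50%).

The same pipeline runs from a shell: `ppgloss simulate`, `ppgloss
entropy`, `ppgloss tfs`, `ppgloss features` (with `--truncate-s` for
early-detection variants that see only the leading portion of each
record), `ppgloss classify`, and `ppgloss run-all` for a seeded
end-to-end demo.

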