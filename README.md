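# epichannel

Channel-level classification of interictal EEG and diagnosis of focal
versus generalized epilepsy.

Interictal scalp EEG — recorded between seizures, often without visible
epileptiform discharges — is hard to read, and deciding whether a
patient's epilepsy is focal (one brain region) or generalized (all
regions) shapes treatment, including surgical candidacy.  `epichannel`
is a Python package for researchers in clinical neurophysiology and
biomedical signal processing who want a fully seeded, testable
implementation of a channel-level pipeline for this problem:

1. **Montage** — derive the 16-channel longitudinal bipolar ("double
   banana") montage from 16 referential 10–20 electrodes:
   each channel is V_anterior(t) − V_posterior(t) along the temporal and
   parasagittal chains (Fp1-F7, F7-T3, …, P4-O2).
2. **Denoising** — 3-level `coif3` discrete wavelet transform, either
   zeroing all detail bands or soft-thresholding them at the universal
   threshold σ√(2 ln n).
3. **Segmentation** — 1 s windows, 50% overlap (a 10 s channel → 19
   segments).
4. **Features** — 15 per segment: mean, SD, peak-to-peak, min, max,
   skewness, kurtosis, crest factor, RSS, RMS, and band powers for
   δ (1–4 Hz), θ (4–8), α (8–14), β (14–30), γ (30–100).
5. **Screening** — Pearson correlation screen (pairwise redundancy +
   point-biserial label association) assembling 5-feature candidate
   groups: a low-correlation core plus one member of the
   high-correlation band-power cluster, e.g. {mean, min, skew, kurt} +
   θ | α | β.
6. **Classifier** — a bidirectional LSTM sequence network
   (sequence input → BiLSTM → dense → softmax → cross-entropy), written
   in NumPy with full BPTT, Adam and gradient clipping; evaluated by
   repeated subject-grouped 80/20 splits and summarized by

   sensitivity = TP/(TP+FN)·100, specificity = TN/(TN+FP)·100,
   accuracy = (TP+TN)/N·100, PPV = TP/(TP+FP)·100, NPV = TN/(TN+FN)·100.

7. **Diagnosis** — apply the trained classifier to all 16 LB channels of
   every subject in a population; with p_c the percentage of subjects
   whose channel c is called epileptic, the across-channel sample
   variance s² of (p_1, …, p_16) is the diagnostic statistic:
   **focal iff s² > threshold** (default 160), because focal pathology
   concentrates detections on one chain while generalized pathology
   spreads them evenly.

Clinical recordings are not redistributable, so the package ships a
seeded synthetic EEG generator (band-limited noise with elevated θ power
on affected channels, 50 Hz line contamination, 1/f background) with
focal, generalized and normal population archetypes.  See
`docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import epichannel as ec

GROUP1 = ("mean", "min", "skew", "kurt", "theta")
sim = ec.SimulationConfig()          # 500 Hz, 10 s, theta gain 3.0 focal

# simulate two cohorts and derive their bipolar montages
focal  = [ec.compute_lb(r) for r in ec.simulate_population(8, "focal", sim, seed=1)]
normal = [ec.compute_lb(r) for r in ec.simulate_population(8, "normal", sim, seed=2)]

# labelled channel sequences: affected channels vs the same channels in controls
sequences = ec.training_sequences(focal, normal, feature_subset=GROUP1)

report = ec.evaluate(sequences,
                     config=ec.NetworkConfig(hidden_units=32, seed=0),
                     n_splits=5, seed=0)
print(report.summary())
```

```
Evaluation (pooled over 5 split(s), positive = epileptic)
========================================================
TP 47  FN 1  FP 0  TN 48
--------------------------------------------------------
accuracy       99.0 %
sensitivity    97.9 %
specificity   100.0 %
ppv           100.0 %
npv            98.0 %
```

Pooled over five subject-grouped 80/20 splits, 95 of 96 held-out
channels are classified correctly — the synthetic θ-power contrast is
recovered through the full montage/DWT/feature/BiLSTM chain.  The fitted
model then diagnoses an unseen focal population:

```python
results = ec.ChannelSequenceClassifier(
    sequences, ec.NetworkConfig(hidden_units=32, seed=0)).fit()
test_pop = [ec.compute_lb(r) for r in ec.simulate_population(10, "focal", sim, seed=3)]
diag, profile = ec.diagnose_population(results, test_pop)
print(profile.to_frame().tail(4).to_string(index=False))
print(f"mean {diag.mean_pct:.2f} %  variance {diag.variance:.2f}  -> {diag.label}")
```

```
channel  percentage
 Fp2-F4        40.0
  F4-C4         0.0
  C4-P4         0.0
  P4-O2        80.0
mean 50.00 %  variance 1146.67  -> focal
```

Temporal-chain channels are detected in 60–90% of subjects while the
parasagittal mid-chain channels stay at 0%, so the profile variance
(1146.67) far exceeds the 160 threshold and the population is correctly
called focal.  A generalized population yields a flat, low profile and a
variance far below the threshold.

The same stages are available from the shell:

```bash
epichannel simulate --group focal --n-subjects 8 --seed 1 --out pop/focal
epichannel metrics --tp 35 --fn 6 --fp 4 --tn 59   # accuracy 90.4 %, ...
epichannel run-all --seed 17 --out runs/demo
```

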