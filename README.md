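# corticode

Decoding tone identity from dense microelectrode recordings of auditory
cortex, with a from-scratch sparse multinomial logistic regression.

## The problem

When a pure tone plays for tens of seconds, the transient onset response of
auditory cortex (the auditory evoked potential, AEP) is followed by
*sustained* activity that is neither time-locked nor reproducible across
trials, so it cannot be characterized by trial averaging. Whether that
sustained activity still carries the tone's identity — and whether it does
so through the cortical place code for frequency (tonotopy) — can instead
be asked with a decoder: extract band-limited power and pairwise phase
locking from the local field potential (LFP) on a 10 × 10 electrode grid,
train a sparse classifier to tell tone from silence (or tone from tone),
and read the tonotopic organization off the recording sites the classifier
keeps.

`corticode` implements that full analysis as a tested, reusable pipeline
for computational neuroscientists. Because no public recordings of this
kind exist, the package includes a first-class synthetic-data generator
that simulates the whole preparation with known ground truth — a tonotopic
cortical surface, tone-burst and 30-s-tone stimulus protocols, spiking and
LFP responses, and the burst-suppression artifacts of anesthesia — so every
stage of the analysis is testable end to end.

## What is inside

| module | contents |
| --- | --- |
| `corticode.synthetic_data` | site maps (96 active sites on a 10 × 10, 400-µm grid; core / belt / non-auditory fields with log-linear CF gradients), stimulus schedules, spike-train and LFP simulation with planted, recoverable effects |
| `corticode.signal_features` | burst-suppression detection (windowed-SD threshold, > 24 sites, ≥ 150 ms), 1–29 s analysis windows, zero-phase band-pass filtering (θ 4–8, α 8–14, β 14–30, low-γ 30–40, high-γ 60–80 Hz), RMS band power, phase-locking value, AEP P1 amplitude |
| `corticode.unit_characterization` | frequency response areas, characteristic frequency (CF), PSTH peak latency, core / belt / non-auditory region labels |
| `corticode.slr` | `SparseLogisticRegression` — softmax classifier with automatic relevance determination (ARD) that prunes irrelevant features to exactly zero; scikit-learn estimator API; stratified cross-validation harness |
| `corticode.analysis` | the study-level experiments: sound-vs-spontaneous discrimination across bands and window lengths, informative-site extraction and CF histograms, per-region contribution rates, and the narrowing frequency-range experiment |

## The decoder

For feature vector **x** (per-site band power, or the phase-locking value
of every site pair) the classifier holds one weight vector per label and
assigns label probabilities through the softmax

p(c | **x**) = exp(**w**<sub>c</sub>·**x** + b<sub>c</sub>) / Σ<sub>l</sub> exp(**w**<sub>l</sub>·**x** + b<sub>l</sub>).

Each weight w<sub>i</sub> carries an independent zero-mean Gaussian prior
with its own precision α<sub>i</sub>. Training alternates a MAP fit of the
weights with a re-estimation of every precision from the Laplace posterior
(automatic relevance determination); a weight whose evidence-optimal
precision diverges is pruned to exactly zero and never returns. The
surviving features — typically a handful out of 96 sites or 4 560 site
pairs — are the *informative sites*, and their characteristic frequencies
and cortical regions are what the representation analyses summarize.

The phase-locking value between sites *j* and *k* over a window of *T*
samples is PLV(j,k) = |(1/T) Σ<sub>t</sub> e<sup>i(θ<sub>j</sub>(t) −
θ<sub>k</sub>(t))</sup>|, with the instantaneous phases θ taken from the
Hilbert transform of the band-passed LFP: 1 for a constant phase
difference, near 0 for independent phases.

## Worked example

Simulate a session of four 30-s tones (12, 22, 32, 50 kHz, two repeats
each, interleaved with 30-s silences), reject burst episodes, and decode
sound versus silence from 1000-ms windows, per band:

```python
import numpy as np
import corticode as cc
from corticode import signal_features as sf
from corticode.slr import cross_validate

site_map = cc.generate_site_map(seed=7)
schedule = cc.generate_long_tone_protocol([12000, 22000, 32000, 50000],
                                          repeats=2, seed=3)
recording = cc.simulate_lfp_session(site_map, schedule, seed=3)

threshold = sf.estimate_burst_threshold(recording)
mask = sf.detect_bursts(recording, threshold)
windows = sf.extract_windows(recording, mask, length_ms=1000,
                             samples_per_label=30, seed=5)
tone = [w for w in windows if w.frequency_hz == 22000.0]
print(f"burst threshold: {threshold:.1f} uV")
for band in ("theta", "high_gamma"):
    fm = sf.build_feature_matrix(recording, tone, band, "band_power")
    res = cross_validate(fm.values, fm.labels, n_folds=6, seed=1)
    n_active = np.mean([len(s) for s in res.selected_features])
    print(f"{band:>10}: {res.mean_accuracy:5.1f}% accuracy, "
          f"{n_active:.1f} informative sites per fold")
fm = sf.build_feature_matrix(recording, tone, "high_gamma", "plv")
res = cross_validate(fm.values, fm.labels, n_folds=6, seed=1)
print(f"high_gamma PLV ({fm.n_features} pairs): {res.mean_accuracy:.1f}% accuracy")
```

prints

```
burst threshold: 57.7 uV
     theta:  51.7% accuracy, 10.7 informative sites per fold
high_gamma: 100.0% accuracy, 1.0 informative sites per fold
high_gamma PLV (4560 pairs): 100.0% accuracy
```

The planted sustained effect lives in the 60–80 Hz band at sites whose CF
matches the tone, so the high-gamma decoder is nearly perfect with a single
surviving site while the theta decoder stays at chance — the band × window
ordering, the tonotopy of the informative sites, and the degradation of
4-way decoding as the four test frequencies crowd into a quarter octave are
all exercised in `tests/test_acceptance.py`.

A thin command-line interface wraps the same functions:

```bash
corticode simulate --seed 3 --out rec.h5
corticode decode --recording rec.h5 --band high_gamma --window-ms 1000 --folds 6 --seed 1
corticode run-all --seed 0 --out study/
```

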