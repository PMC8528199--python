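# seegbench

Benchmarking automated re-referencing ("data cleaning") methods for
stereo-EEG (SEEG) brain–computer interfaces, on synthetic recordings with
known ground truth.

SEEG depth electrodes record field potentials from shafts of contacts
implanted through cortical and subcortical tissue. Before decoding anything
from these signals, a reference must be subtracted to remove shared noise —
and the choice of reference changes decoding performance. This package
implements the six standard schemes and an end-to-end evaluation of their
effect on cued gesture decoding:

| scheme | reference subtracted from contact *i* |
|---|---|
| raw | nothing (benchmark) |
| CAR | mean of all channels |
| GWR | mean of the channels in the same tissue class (gray/white) |
| ESR | mean of the channels on the same shaft |
| bipolar | the adjacent contact: *x<sub>i</sub> − x<sub>i+1</sub>* |
| Laplacian | mean of the two shaft neighbors: *x<sub>i</sub> − (x<sub>i−1</sub>+x<sub>i+1</sub>)/2* |

Around the operators sits the full analysis a decoding study needs:

* **synthetic subjects** (`seegbench.synthetic`) — a cued three-gesture
  experiment (60 trials of 10 s; 4 s rest, 1 s cue, 5 s task) with layered
  pink noise (global common mode, within-shaft fields, channel-private
  activity), heterogeneous drifting electrode coupling, 50-Hz line noise
  with planted extreme channels, class-specific delta and high-gamma power
  modulation on sparse informative channels, and a surface-EMG pair whose
  burst starts at the true movement onset (0.72 ± 0.38 s after the cue);
  the ground truth is returned for testing;
* **preprocessing** (`seegbench.preprocess`) — polyphase resampling to
  1 kHz, line-noise channel rejection (50-Hz peak filter; threshold =
  median + 10 × mean absolute deviation of the pooled filtered samples),
  comb notch + 0.5–400 Hz band-pass (zero phase), EMG movement-onset
  detection (envelope threshold ∧ amplitude threshold, earlier wins), and
  epoching to [−4, 4) s around each onset;
* **decoding** (`seegbench.decode`) — band power from AR(40) Burg spectra
  in 500-ms windows (250-ms hop) over nine sub-bands, z-scored against the
  baseline period, greedy forward channel selection, and a linear-kernel
  SVM under trial-based stratified 10-fold cross-validation (window-level
  accuracy, DA); single-band variants (SDA);
* **comparison statistics** (`seegbench.stats`) — time–frequency difference
  maps (trial-wise paired t-tests on baseline-corrected log spectrograms,
  Bonferroni over channels, −log₁₀ p), permutation-based task relevance
  (Hilbert band power × label permutations), and the regression of spectral
  difference on task relevance with an F-test;
* **the experiment** (`seegbench.pipeline`) — simulate → preprocess →
  re-reference (×6) → decode → compare → report, fully reproducible from a
  single seed.

## Worked example

```python
from seegbench import (SimConfig, simulate_subject, preprocess_subject,
                       apply_scheme, extract_features, baseline_zscore,
                       forward_select_channels, decode_DA)

cfg = SimConfig(n_shafts=2, contacts_per_shaft=6, seed=7)
recording, events, truth = simulate_subject(cfg)
epochs, events, bad = preprocess_subject(recording, events)

for scheme in ("raw", "car", "laplacian"):
    ep = apply_scheme(epochs, scheme)
    feats = baseline_zscore(extract_features(ep))
    selected, trace = forward_select_channels(feats, ep.labels, seed=7)
    result = decode_DA(feats, ep.labels, selected, seed=7)
    print(f"{scheme:10s} DA = {100*result.mean_da:5.1f}%  "
          f"selected: {', '.join(selected)}")
```

prints

```
raw        DA =  36.1%  selected: S0C3, S0C4
car        DA =  50.3%  selected: S1C3, S0C5, S0C4, S0C3
laplacian  DA =  77.7%  selected: S0C4, S1C3, S0C3, S0C1, S1C5
```

Chance is 33.3% for three gestures. Raw signals are dominated by shared
noise that the feature-space classifier cannot fully compensate; the common
average removes the global component (50.3%); the Laplacian additionally
cancels the locally correlated within-shaft fields and recovers most of the
planted effect (77.7%). This ranking — every cleaning method above raw,
with the local references on top — is the package's central reproducible
result; `docs/methods.md` explains the noise model that produces it and
what it does and does not say about clinical recordings.

The full multi-subject comparison, with group statistics, TFD heatmaps and
the relevance regression, runs from the command line:

```bash
seegbench run --seed 1 --out results/
```

and writes `da_table.tsv`, `sda_table.tsv`, `pairwise_tests.tsv`, TFD and
scatter-fit figures, and a reproducibility manifest. Individual stages are
exposed as `seegbench simulate | preprocess | reref | decode | compare |
relevance`.

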