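# gcfusion

Granger-causality graph features and learned multi-band fusion for
classifying multichannel neural time series (EEG-style recordings rated
on arousal/valence scales).

Emotion-related information in EEG is carried both by *where* power sits
(channel, frequency band) and by *how channels drive each other*.
`gcfusion` builds, for each analysis window and each rhythm band
(θ 4–8, α 8–12, β 12–30, γ 30–45 Hz), a directed graph whose nodes carry
differential-entropy features and whose edges are thresholded
Granger-causality estimates, then classifies the windows with a small
graph-convolutional network that *learns how much each band matters*.

## Method

1. **Windowing** — each trial of duration *D* is cut into
   ⌊(D−T_w)/T_o⌋+1 overlapping windows (defaults T_w = 3 s, T_o = 1.5 s),
   and each window is split into the four bands by STFT bin masking.
2. **Node features** — per band and channel, the differential entropy of
   the band-limited signal under the Gaussian model,
   h = ½ ln(2πe σ̂²) nats.
3. **Directed edges** — for every ordered channel pair, the
   Granger-causality value F_{x→y} = ln(σ²_restricted / σ²_full), the log
   ratio of residual variances of the target's autoregression without and
   with the source's L past values (OLS, identical sample range, L = 5 by
   default). The N×N matrix (rows = targets, columns = sources, unit
   diagonal) is binarized by keeping its ⌊N²k⌋ largest entries — a
   rank-based, asymmetric adjacency.
4. **Classifier** — per band, shallow and deep Chebyshev graph
   convolutions G(X, A) = Σ_k θ_k T_k(L̃) X W over that band's adjacency;
   band branches are fused node-wise with learned weights
   (p_θ, p_α, p_β, p_γ) constrained to the simplex (softmax
   parameterization, so Σp = 1 after every step); fused shallow and deep
   tensors pass ReLU → dense → concatenation → dense → softmax, trained
   with cross-entropy and Adam. Ablation variants: shallow/deep/both ×
   fused/concatenated ("cascade").

A seeded synthetic-data generator plants directed VAR couplings (known
ground-truth graph) and class-dependent band variance (known informative
band), so every stage can be verified against ground truth. Real
recordings can be supplied as EDF or as a simple float32 array container
with a JSON sidecar.

## Worked example

```python
import numpy as np
from gcfusion import (ModelConfig, PipelineConfig, build_graph_dataset,
                      cross_validate, simulate_recordings)
from gcfusion.synthdata import beta_band_study_spec

# 80 ten-second 8-channel trials; the "high" class doubles the beta-band
# variance on channels 0-3, and two directed couplings are planted.
recordings, truth = simulate_recordings(beta_band_study_spec(seed=0))
dataset = build_graph_dataset(recordings, PipelineConfig(k=0.5))   # 400 windows
report = cross_validate(dataset, ModelConfig(seed=0), n_folds=5, seed=0)
print("5-fold accuracy:", report.summary(), "%")
print("shallow fusion weights (theta, alpha, beta, gamma):")
print(np.round(np.mean([w["shallow"] for w in report.fusion_weights], axis=0), 3))
```

Output:

```
5-fold accuracy: 96.75 ± 1.68 %
shallow fusion weights (theta, alpha, beta, gamma):
[0.226 0.225 0.32  0.23 ]
```

The classifier separates the classes from the band-resolved graphs, and
the learned fusion weight of the β band — the only band carrying class
information in this study — is the largest, which is exactly the planted
structure. The same objects expose `FusionGCN(...).fit()` → results with
`summary()`, `predict`, `score`, and `ablate(...)` for the variant table;
the `gcfusion` command line wraps the pipeline
(`simulate | preprocess | features | connectivity | train | evaluate | ablate`).

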