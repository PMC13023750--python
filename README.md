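# respgate

Respiratory **self-gating (SG)** versus **camera-based gating (VE)** for
free-breathing 4D flow MRI at mid-field — a tested, reusable analysis
pipeline with synthetic phantoms providing ground truth for every stage.

## The problem

4D flow MRI acquires time-resolved, three-directional velocity data over
several minutes of free breathing, so the data must be retrospectively
sorted ("binned") by respiratory state before reconstruction; the
end-expiratory bin is reconstructed because end-expiration is the most
reproducible respiratory phase. The respiratory surrogate can come from the
imaging data itself — *self-gating* from repeatedly sampled k-space-center
profiles resolved along the superior–inferior (SI) axis — or from a
contactless chest camera. At mid-field (0.6 T) the lower signal- and
contrast-to-noise ratio may degrade self-gating, which motivates a
quantitative comparison of the two surrogates and of the velocity fields
reconstructed from their respective end-expiratory bins.

`respgate` implements that comparison for researchers working on
respiratory motion compensation:

- **Signal model** (`respgate.gre_signal`) — spoiled-GRE steady state
  `S ∝ M0·B0·(1−E1)·sin α / (1−cos α·E1) · e^(−TE/T2*)`, `E1 = e^(−TR/T1)`,
  Ernst angle, and CNR field-ratio sweeps quantifying the mid-field
  contrast penalty.
- **Synthetic acquisitions** (`respgate.synthetic`) — a plateaued
  cosine-power (Lujan-type) breathing waveform `z(t) = z0 − A_k·cos^{2n}(π(t−t_k)/T_k)`;
  a 1D SI tissue phantom (lung/myocardium/liver/fat) whose heart–liver
  interface translates with breathing, sampled to multi-coil k-space-center
  profiles at 22 Hz with complex Gaussian noise; a delayed, rescaled, noisy
  camera surrogate (or synthetic chest video); paired pulsatile
  cylindrical-vessel velocity fields with analytic flow ground truth.
- **Self-gating** (`respgate.self_gating`) — inverse FFT, sum-of-squares
  coil combination `X_sos = √(Σ_c |X_c|²)`, PCA over the first ten
  components, and selection of the component with maximal spectral power
  fraction inside the 0.1–0.7 Hz breathing band.
- **Camera surrogate & alignment** (`respgate.camera`) — patch-based video
  analysis and delay estimation via the lag `Δt` maximizing the normalized
  cross-correlation `cov(x(t), y(t+Δt)) / (σ_x σ_y)`.
- **Binning & agreement** (`respgate.binning`) — three equally populated
  respiratory bins; binary accuracy `(TP+TN)/(TP+TN+FP+FN)` and
  `F1 = 2TP/(2TP+FP+FN)` with end-expiration as the positive class; a
  row-normalized 3×3 consistency matrix.
- **Hemodynamics** (`respgate.flow`, `respgate.velocity`) — flow curves
  `Q = Σ v·ΔA`, stroke volume, peak flow, Bland–Altman, OLS correlation,
  paired Wilcoxon tests; masked vector RMSE, mean directional error
  `1 − ⟨u,v⟩/(‖u‖‖v‖)` over systolic frames, and MIP + 4×4 sliding-kernel
  peak-velocity extraction.
- **Pipeline & CLI** (`respgate.pipeline`, `respgate` command) — one
  seeded, config-driven run or a multi-seed cohort with mean ± SD reporting.

## Worked example

```python
import numpy as np
from respgate import pipeline

res = pipeline.run_comparison(seed=1)
print(res["agreement"].to_text())
print("velocity RMSE [cm/s]:", round(res["velocity"]["rmse_cms"], 2))
```

prints (seed 1, default conditions):

```
reference=SG prediction=VE n=5321
max cross-correlation :   0.9840
zero-lag correlation  :   0.9840
delay [ms]            :    495.0
accuracy              :   0.9117
F1-score              :   0.8675
consistency matrix [% of reference bin]:
  bin 0:  86.75   13.25    0.00
  bin 1:  13.25   83.43    3.33
  bin 2:   0.00    3.33   96.67
velocity RMSE [cm/s]: 3.9
```

Reading this: the camera surrogate was recovered with a 495 ms delay
relative to self-gating (500 ms was injected; the common grid is 45 ms);
after alignment the surrogates agree with cross-correlation 0.98; 86.8% of
self-gated end-expiratory time points land in the camera's end-expiratory
bin (bin 0); and the two "reconstructions" of the velocity phantom —
which differ by a controlled 2.25 cm/s perturbation per component — show a
vector RMSE of 3.9 ≈ 2.25·√3 cm/s.

The same run from the shell:

```bash
respgate run --seed 1 --out out/            # single run
respgate run --seeds 20 --out out/cohort/   # cohort with mean ± SD summary
respgate cnr-sweep --out out/cnr.csv        # CNR field-ratio curves
```

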