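# califlow

Real-time neuron detection and calcium-signal (ΔF/F) extraction for
miniature two-photon imaging video, built as a dataflow pipeline, together
with a ground-truthed calcium-imaging simulator and a quantitative
evaluation harness.

**Who it is for.** Labs running miniature/two-photon calcium imaging who
need neuron positions and per-neuron activity traces *while data is being
acquired* — e.g. as the front end of a closed-loop neuromodulation or
neural-decoding system — and method developers who want a controlled,
fully ground-truthed testbed for motion correction and detection
algorithms.

## What it computes

A video stream S passes through a chain of dataflow actors:

```
ImgSrc → MotionCorrection → Fork ─→ Preprocessing → NeuronDetection → Fork ─→ δ
                              │                                         │
                              └────────────→ SignalExtraction ←─────────┘
                                                    │
                                                β₁ … β_L
```

- **Motion correction** removes per-frame rigid motion by maximizing the
  enhanced correlation coefficient (ECC) between the current frame and a
  running reference — translation first, rotation only when the
  translation result fails an adaptive gate τ = mean − p·σ over the 100
  most recent accepted correlations (p₁ = 2, p₂ = 10). Failed frames are
  logged and replaced by the reference.
- **Neuron detection** finds bright, neuron-shaped blobs by binarizing the
  preprocessed frame at a ladder of thresholds, filtering connected
  components by area and shape, and merging them across levels; during a
  training phase, per-frame detections accumulate into a persistent n×3
  detection matrix δ (x, y, radius), which is frozen for real-time
  operation. A calibration actor (SetParams) loosens the size/threshold
  filters until a target number of neurons is found.
- **Signal extraction** reports, per detected neuron and frame,
  β[i] = (F_i − F0_i)/F0_i — the relative change of the mean intensity in
  the neuron's circular ROI against a rolling 50-frame baseline.
- **The simulator** generates videos with exact ground truth: a leaky
  integrate-and-fire network (dV/dt = (V_rest − V)/λ + θλ(−0.5)ε) drives
  mask-based fluorescence (128 at a spike, half-life 8 frames), with
  injected rigid motion (translation U[−10,10] px, occasional rotation,
  drift regimes) and shot plus temporally autocorrelated noise.
- **Evaluation** scores motion correction (mean |Δx|, |Δy|, |Δθ|, failure
  rate), detection (pixel precision/recall, F1 = 2uv/(u+v), detection
  rate), and trace quality (SNR = 10·log₁₀(R_s/R_n) against a
  1,000-repetition random-region null).

## Worked example

```python
import numpy as np
from califlow import experiments, metrics

# simulate a noisy 300-frame dataset (100 LIF neurons, 400x400, rigid
# motion with 25% rotation occurrence, shot 0.3 / colored 0.5 noise),
# run motion correction + calibration + training-mode detection on it,
# and score the result against the ground truth
cfg = experiments.study_sim_config("s03c05", n_frames=300)
exp = experiments.detection_experiment(cfg, seed=21)

print(exp.score.summary())
rep = metrics.motion_error(exp.result.estimated_track,
                           exp.bundle.motion_track, exp.result.statuses)
print(rep.summary())
```

prints

```
precision=0.5907 recall=0.9858 F1=0.7387 detection_rate(%)=100.0 matched=100/100
mean(Mx)=0.9037 max(Mx)=1.6126 mean(My)=0.2274 max(My)=0.6160 mean(Mrot)=0.010901 max(Mrot)=0.8981 Rfail(%)=0.00
```

— every one of the 100 active ground-truth neurons was matched by a
detected circle (detection rate 100%), the recovered x/y displacements
stay below 1 px of the injected motion on average with no failed frames,
and the mean rotation error is ~0.01°. Precision is below recall because
the circular ROIs overshoot the elliptical truth masks and the training
matrix carries some duplicate rows; the one-to-one matching keeps the
detection rate itself unaffected.

The same flow is available from the shell:

```
califlow simulate --seed 7 --frames 300 --noise s03c05 --p-rot 25 --alpha-rot 6.3153 --out sim/
califlow init     --input sim/frames.tif --out init/      # calibration + training
califlow run      --input sim/frames.tif --init-dir init/ --out run/
califlow evaluate --run-dir run/ --truth-dir sim/ --out report/
```

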