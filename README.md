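# qaerr

Simulation and automatic classification of multileaf-collimator (MLC)
positional delivery errors in patient-specific IMRT QA with a
low-resolution 2D ion-chamber array (27 × 27 chambers, 10 mm pitch).

Pre-treatment QA compares a plan's predicted dose plane with a measured
one; a failed gamma analysis says *that* something is wrong, not *what*.
`qaerr` closes that gap for a common error class — MLC leaf mispositioning —
by:

1. **injecting** defined error families into MLC control-point sequences
   (DICOM RT PLAN or a JSON fixture dialect): a systematic **shift** of both
   banks (2/3 mm, field size unchanged), **opening** / **closing** of every
   pair (1/2 mm per bank, X field size ±2/±4 mm), and per-leaf Gaussian
   **random** errors (σ = 1/2 mm), plus the error-free reference — nine
   labelled variants per beam;
2. **rendering** predicted and measured 27 × 27 dose planes with a
   transparent fluence-convolution engine (aperture rasterization, meterset
   weighting, Gaussian penumbra, detector box-averaging, optional
   measurement noise) that stands in for a TPS and phantom and can be
   swapped for real exports;
3. **building classifier inputs**: a dose-difference map and *signed*
   gamma maps under 3%/2 mm and 2%/1 mm (global normalization, 10% dose
   threshold), where the gamma magnitude γ(r) = min over evaluated points
   r′ of √(‖r−r′‖²/δ² + ΔD²/Δd²) carries the sign of the local dose
   difference (+ hot, − cold), clipped at |γ| = 1.5 and scaled to [−1, 1],
   then bilinearly resized and stacked as three channels;
4. **classifying** the stack with a hybrid network — a convolutional stem
   and residual channel-attention bottleneck stages feeding shifted-window
   multi-head self-attention stages and a 5-class softmax head — trained
   with a plan-level 80:20 split, plan-disjoint 5-fold cross-validation,
   AdamW with cosine annealing, early stopping, label-preserving
   augmentation, and ensemble-mean test inference.

The network runs on a self-contained NumPy autodiff engine (`qaerr.nn`);
there is no deep-learning framework dependency. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
import numpy as np
from qaerr import (EngineParams, beam_dose, measure, synthesize_plan,
                   inject_closing, make_stack)

beam = synthesize_plan(n_beams=1, seed=7)[0]
engine = EngineParams(penumbra_sigma_mm=3.0, transmission=0.02,
                      noise_sd_fraction=0.01, seed=7)

measured = measure(beam_dose(beam, engine), engine)      # error-free delivery
predicted = beam_dose(inject_closing(beam, 2.0), engine) # erroneous prediction

stack = make_stack(predicted, measured, label="closing", size=96)
for name in ("dd", "gamma32", "gamma21"):
    ch = stack.channel(name)
    print(f"{name:8s} mean {ch.mean():+.3f}  min {ch.min():+.3f}  max {ch.max():+.3f}")
```

prints

```
dd       mean +0.108  min -0.085  max +0.999
gamma32  mean +0.084  min -0.194  max +0.981
gamma21  mean +0.120  min -0.284  max +1.000
```

The closing error narrows the *predicted* field, so the measured dose
exceeds the prediction along the field edge: the dose-difference and both
signed gamma channels are hot (positive) on average, saturating at +1 in
the collapsed edge cells. An opening error produces the mirrored cold
signature, a shift a bipolar one, and random errors a patchy mixture —
exactly the structure the classifier learns.

A full synthetic experiment — 20 plans / 60 beams, nine variants each,
through dose rendering, map stacks, 5-fold training and ensemble
evaluation — runs from the command line:

```bash
qaerr train --seed 1 --out runs/demo
```

and writes per-class metrics, ROC/confusion plots and the five fold
checkpoints under `runs/demo/`. Single-channel ablations:
`--channels dd|gamma32|gamma21`.

## Command-line interface

```
qaerr inject    --plan in.dcm --family shift --magnitude 3 --direction +1 --out out.dcm
qaerr manifest  --plans plans/ --out manifest.csv
qaerr simulate  --manifest manifest.csv --plans plans/ --out doses/
qaerr maps      --predicted pred.csv --measured meas.csv --out stack.npz
qaerr train     --seed 1 --out runs/demo   [--config exp.yaml]
qaerr predict   --model runs/demo/fold0.npz --stack stack.npz
```

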