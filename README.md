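# oxirelax

Low-field NMR (LF-NMR) relaxometry is a fast, nondestructive probe of
edible-oil quality: as an oil oxidizes, its proton transverse-relaxation
(T₂) curve shortens and its self-diffusion coefficient D drops, tracking
the wet-chemistry oxidation indices (peroxide value PV, p-anisidine value
p-AV, TOTOX = p-AV + 2·PV). `oxirelax` implements a complete software
sensor around that physics, for food scientists and NMR practitioners who
want a benchtop classification pipeline without wet chemistry in the
loop:

- **Synthetic data generator** — class-conditional multi-exponential CPMG
  echo trains `S(t_k) = Σᵢ aᵢ·exp(−t_k/T₂ᵢ) + ε_k` at `t_k = 2τk`,
  Stejskal–Tanner PFGSE attenuation series `S/S₀ = exp(−bD)` with
  `b = γ²G²δ²(Δ−δ/3)`, and chemistry values drawn inside the class bins,
  so every sample's label re-derives from its own chemistry.
- **Regularized inverse Laplace transform** — non-negative T₂ spectra from
  `min_{f≥0} ‖Kf−s‖₂² + a₁‖f‖₁ + a₂‖f‖₂²` with `K[k,j] = exp(−t_k/T₂ⱼ)`,
  solved exactly by active-set methods (default `a₂ = 0.5` on
  max-normalized signals), plus peak extraction.
- **Labeling engine** — ordinal classes Good / Fair / Bad from (D, PV):
  Good is `D > 0.03×10⁻⁹ m²/s` and `PV < 20 mmol/kg`, Bad is
  `D ≤ 0.02×10⁻⁹` and `PV ≥ 50`, Fair lies between; disagreements are
  resolved by a configurable conflict policy.
- **1-D dilated CNN** — four dilated convolution layers (ReLU), a global
  max-pool that makes the network indifferent to raw curve length, a dense
  head and a 3-way softmax; trained with Adam on raw min-max-normalized
  curves. Forward pass, backprop and optimizer are implemented directly on
  numpy arrays.
- **Evaluation harness** — per-class precision, recall, F1 and support;
  repeated-training experiments aggregated as median [IQR] across
  sessions.

## Worked example

```python
import numpy as np
from oxirelax import (AcquisitionConfig, ModelConfig, generate_dataset,
                      preprocess, train, predict, totox, classify_oxidation,
                      estimate_d, simulate_pfgse, PfgseConfig)
from oxirelax.pipeline import stratified_split

totox(20, 10)                                  # -> 50.0
classify_oxidation(0.015e-9, 60).label         # -> 'Bad'
fit = estimate_d(simulate_pfgse(3e-11, PfgseConfig(), noise_sigma=1e-4, seed=2))
# fit.d = 2.969e-11 m^2/s, fit.r_squared = 0.9989

acq = AcquisitionConfig(n_echoes=2048, noise_sigma=0.01)
records = generate_dataset(150, (126, 77, 187), acq, seed=42)
cfg = ModelConfig(epochs=40, seed=42)
X = np.stack([preprocess(r.curve, cfg.target_len) for r in records])
y = np.array([int(r.true_class) for r in records])
tr, va, te = stratified_split(y, (0.70, 0.15, 0.15), seed=42)
model = train(X[tr], y[tr], cfg, validation=(X[va], y[va]))
model.training_history["val_acc"][-1]          # -> 1.000
label, prob = predict(model, records[te[0]].curve)
# -> ('Bad', 0.994): the network is 99.4% sure this held-out curve is
#    highly oxidized, matching its chemistry-derived label
```

The 23-curve held-out test split scores accuracy 1.000 in this run:
curves from the three oxidation states are well separated at the default
generator settings, so a correctly trained network should be near-perfect.
An optional `boundary_blur` generator mode crowds the chemistry values
against the class thresholds instead of drawing them uniformly.

The same workflow is available from the shell:

```bash
oxi-relax simulate --n 390 --mix 126,77,187 --seed 1 --out-dir data/
oxi-relax label --manifest data/manifest.json --out data/labeled.json
oxi-relax ilt --curve data/curves/S0000.csv --a2 0.5 --out spectrum.csv
oxi-relax train --manifest data/manifest.json --epochs 210 --seed 7 --out model/
oxi-relax classify --model model/ --curve data/curves/S0000.csv
oxi-relax run-experiment --n 390 --repetitions 30 --seed 0 --out-dir runs/
```

## Documentation

See `docs/methods.md` for the underlying models, the generator's
assumptions and limits, numerical choices, and known limitations.
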