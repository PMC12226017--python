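# varxnet

**Joint estimation of intrinsic connectivity and stimulus responses in
multichannel neural time series, with per-connection Granger deviance
statistics.**

When a brain is stimulated — by a movie, a soundtrack, its own eye
movements — every recorded channel responds to the stimulus *and* to
every other channel. Encoding models (temporal response functions)
lump these together into one total response; functional-connectivity
models (VAR / Granger causality) ignore the stimulus and happily
report the shared drive as "connections" between channels. `varxnet`
implements the model that separates the two: the vector autoregression
with exogenous input (VARX),

```
y(t) = Σ_{τ=1..n_a} A(τ) y(t−τ)  +  Σ_{τ=0..n_b−1} B(τ) x(t−τ)  +  e(t)
```

where `y(t)` is the d_y-channel neural signal (e.g. LFP or broadband
high-frequency activity), `x(t)` the d_x stimulus feature channels
(event pulse trains, sound envelope, motion, …), `A` the intrinsic
recurrent filters, `B` the extrinsic feed-forward filters, and `e(t)`
the innovation process driving intrinsic variability. Both filter sets
are estimated together by (optionally ridge-regularized) least squares
on the innovation power.

On top of the fit, the package provides:

- **Granger deviance maps** — for every connection (channel→channel or
  feature→channel), the deviance `D = T·log(σ_r²/σ_f²)` of the reduced
  model that omits the source's lags, its chi-square p-value, and the
  generalized effect size `R² = 1 − exp(−D/T)`. Reduced models are
  solved from the full fit's Gram matrix by block elimination, so a
  full d_y×d_y map costs one fit plus d_y small solves.
- **The factorized system response** `H = (1 − A)⁻¹B` — the total
  stimulus response implied by the fit, which equals the directly
  estimated mTRF of the same data — plus response power and
  full-width-at-half-maximum duration metrics.
- **Comparative analyses**: VARX-vs-VAR spurious-connectivity
  contrast, cumulative feature ladders, condition contrasts with
  mixed-effects models, connection directionality (column means of
  `R − Rᵀ`), and innovation-power noise quenching.
- **A synthetic-data module** that generates every input the analyses
  assume — stimulus features, VARX processes with known ground truth,
  a divisive gain-adaptation variant, and sparse networks for the
  structural-recovery benchmark — so the whole pipeline is testable
  without any data download.

The estimators follow scikit-learn conventions (`fit`, fitted
attributes with trailing underscores, `get_params`/`set_params`) and
compose with sklearn tooling.

## Worked example

Simulate a 4-channel network with two true directed connections and
two stimulus features, then recover both the connectivity and the
stimulus effects:

```python
import numpy as np
import varxnet as vn

spec = vn.oscillator_ground_truth(d_y=4, d_x=2, n_a=2, n_b=12, seed=0)
x = vn.make_stimulus(
    20_000, 60.0,
    [{"kind": "pulse", "rate": 1.0}, {"kind": "continuous", "smoothness": 0.2}],
    seed=1,
)
y = vn.simulate_varx(spec, x, seed=2)

model = vn.VARX(n_a=2, n_b=12, lambda_reg=0.0).fit(y, x)
g_rec = vn.granger_map_from_model(model, "recurrent")
g_in = vn.granger_map_from_model(model, "input")

mask, frac = vn.significance_mask(g_rec, alpha=1e-4)
print("recurrent connections significant at p<1e-4:", f"{frac:.3f}")
true_mask = np.any(spec.A_true != 0, axis=2) & ~np.eye(4, dtype=bool)
print("true cross-coupling edges:\n", true_mask.astype(int))
print("detected edges:\n", mask.astype(int))
print("input effect sizes R2:\n", np.round(g_in.R2, 3))
```

Output:

```
recurrent connections significant at p<1e-4: 0.167
true cross-coupling edges:
 [[0 0 0 1]
 [0 0 0 0]
 [0 1 0 0]
 [0 0 0 0]]
detected edges:
 [[0 0 0 1]
 [0 0 0 0]
 [0 1 0 0]
 [0 0 0 0]]
input effect sizes R2:
 [[0.411 0.828]
 [0.438 0.751]
 [0.431 0.731]
 [0.41  0.732]]
```

The detected edge mask matches the ground truth exactly (2 of 12
possible directed edges, fraction 0.167), and every channel shows a
strong input effect for both features.

How much does recurrence shape the stimulus response? A channel with a
slow recurrent pole (0.95) and a brief two-tap input filter:

```python
from varxnet.validation import response_factorization
out = response_factorization(pole=0.95)
print(f"power H/B:  {out['power_H']/out['power_B']:.1f}x")
print(f"width B: {out['length_B_ms']:.0f} ms   width H: {out['length_H_ms']:.0f} ms")
```

```
power H/B:  17.6x
width B: 17 ms   width H: 125 ms
```

The total response `H` carries ~18× the power of the feed-forward
filter `B` and is roughly 7× longer — the intrinsic dynamic, not the
feed-forward filter, dominates the stimulus response.

## Command line

A thin CLI drives reproducible pipeline runs from a JSON config:

```bash
varxnet simulate --output-dir run --seed 7
varxnet run --stages fit,granger,response,compare,report --output-dir run --seed 7
```

Every artifact carries provenance metadata (config hash, seed,
version); reruns with the same config are byte-identical.

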