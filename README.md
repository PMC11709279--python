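# lamigain

Laminar analysis of direction selectivity in early visual cortex: tuning-curve
fitting and selectivity indices, probe/layer quality control, interlaminar
gain-transmission models with model comparison, and pairwise-conditional
Granger-causality connectivity — exercised end to end on a synthetic
laminar-response generator with known ground truth.

## The scientific problem

Neurons in the early visual cortex respond preferentially to particular
directions of stimulus motion. With a multielectrode linear probe inserted
perpendicular to the cortical surface, one records simultaneously from the
thalamorecipient **input layers** (L4, L6) and the **output layers**
(L2/3, L5) of a single cortical column and can ask how direction selectivity
is transformed as signals pass between these two stages. The analyses here
quantify that transformation: is selectivity inherited, enhanced, or
re-created — and through what kind of gain mechanism?

The package is written for electrophysiologists analyzing trial-resolved
multi-unit activity (MUA) from laminar probes: per-site spike rates and
peristimulus time histograms (PSTHs) recorded under drifting gratings of
varying direction plus interleaved blank (uniform gray) trials.

## Core model and statistics

**Direction tuning** of the time-averaged response is fitted with a
two-lobe von Mises curve,

    R(θ) = α·V(θ − θ_pref; σ₁) + β·V(θ − θ_pref − 180°; σ₂) + R₀,
    V(x; σ) = (e^{σ·cos x} − e^{−σ}) / (e^{σ} − e^{−σ}),

and the direction selectivity index is computed from the fitted curve:

    DSI = (R(θ_pref) − R(θ_null)) / (R(θ_pref) + R(θ_null)),

so DSI = 1/3 means the preferred response is twice the null response.

**Interlaminar transmission** is modeled as a linear gain followed by a
static nonlinearity applied to the repetition-paired, layer-averaged input
response:

    R̂_out(S, i) = f( w(S) · R_in(S, i) ),
    f(g) = (A(g−g₀)/2)·(1 + erf((g−g₀)/(√2σ))) + (Aσ/√(2π))·e^{−(g−g₀)²/(2σ²)},

where f is the Gaussian-smoothed threshold-linear transfer
(exactly A·E[max(g + ε − g₀, 0)] for ε ~ N(0, σ²)). Four variants are
compared: untuned gain (Model I, w constant over conditions S), tuned gain
(Model II, one w per condition), and tuned-gain/untuned-suppression vs
untuned-gain/tuned-suppression ReLU cascades (Models III/IV,
R̂ = [wR − T]₊). Fits minimize the residual J = ΣₛΣᵢ(R̂ − R)² and are
compared by an adjusted goodness of fit, AIC, and BIC. The DSI enhancement
from input to output layers is decomposed into a nonlinearity contribution
(Model I vs input) and a tuned-gain contribution (Model II vs Model I).

**Connectivity** between layer-resolved signals is measured per stimulus
condition with pairwise-conditional Granger causality computed from first
principles: GC(to ← from | rest) = ln(Σ_reduced/Σ_full) from nested VAR
fits, so common inputs are conditioned out.

## Worked example

```python
from lamigain.synthetic_data import make_ground_truth, simulate_probe
from lamigain.data_model_io import screen_sites, layer_averaged_rates
from lamigain.gain_models import fit_gain_model, gain_dsi
import numpy as np

truth = make_ground_truth({"output_noise_scale": 0.0}, seed=1)
ds = simulate_probe(truth, seed=2, with_psth=False)
kind = np.array(["output" if l in ("L2/3", "L5") else "input"
                 for l in ds.layer_labels])
ir = layer_averaged_rates(ds.table, np.flatnonzero(kind == "input"))
orr = layer_averaged_rates(ds.table, np.flatnonzero(kind == "output"))
fit = fit_gain_model(ir, orr, model="II", directions=truth.directions)
print(f"adjR2 = {fit.adj_r2:.4f}")
print(f"fitted gain DSI = {gain_dsi(fit):.4f}  (planted {truth.gain_dsi})")
```

prints

```
adjR2 = 1.0000
fitted gain DSI = 0.3000  (planted 0.3)
```

the refit of a probe whose output trials were generated by the tuned-gain
model recovers the planted gain curve exactly: the gain is direction-tuned
with (w_pref − w_null)/(w_pref + w_null) = 0.3, and the fit explains all
of the output variance.

A full pipeline run (screening → tuning → layers → gain models → GC →
statistics) with a written report:

```
lamigain run --seed 7 --out results/
```

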