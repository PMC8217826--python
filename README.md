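# tonegap

Firing-rate population dynamics of the **auditory continuity illusion**: two
brief tones separated by a silent gap are heard as one continuous tone when
a sufficiently loud noise burst fills the gap. `tonegap` implements an
idealized dynamical-systems account of that illusion for computational
neuroscientists and auditory modelers: a single frequency-tuned neural
population whose persistent activity through the interruption is the model
correlate of perceived continuity.

## The model

The population rate `x(t) ∈ (0, 1)` obeys

```
τ x′ = −x + f(a_E x + I(t)),        f(u) = 1 / (1 + e^{−(u − m)/k})
```

with recurrent excitation `a_E`, sigmoid half-maximum `m` (`k = 1`), and a
sound-driven input assembled from four idealized components:

```
I(t) = I_sustain + I_onset − I_offset − I_inhib
I_sustain = I_T·1_tone + α·I_N·1_noise            (piecewise constant)
I_onset/offset = γ·s,  τ s′ = −s,  s reset to [I_T − β·I_N]_+ at tone edges
I_inhib  = a_I·I_N·(1 − x)·1_noise                (mutual inhibition)
```

Tones (`I_T`) and noise (`I_N`) are unitless drive levels, not waveforms.
Three canonical variants, each calibrated so that `I_T = 1` is the
activation threshold, realize three dynamical routes to continuity:

| variant | mechanism | pathways | knees (I_T) |
|---|---|---|---|
| `model1` | hysteresis | sustained + inhibition | 0.2, 1.0 |
| `model2` | bistability at rest | transients only | −2, 2 |
| `model3` | combined | all | 0.2, 6 |

The knees are saddle-node bifurcations of the equilibrium curve
`I_T(x) = m − ln(1/x − 1) − a_E x`; they exist iff `a_E > 4`. Activation and
deactivation thresholds for transient kicks follow from the saddle's stable
manifold in the `(x, s)` phase plane, which — because rate and transient
share one time constant — is *exactly* the line
`S(x) = (a_E + a_I I_N)/γ · (x_S − x)`.

The package computes equilibria and knees, classifies the `(a_E, m)`
parameter plane, places knees by calibration, builds separatrices, runs
event-driven simulations of tone-only / masking / continuity scenarios, and
tabulates masking `M(I_T)` and continuity `C(I_T)` threshold curves both
analytically and by bisection on simulations.

## Worked example

```python
from tonegap import build_scenario, classify_response, get_preset, integrate

cfg = get_preset("model1")                      # hysteresis variant
for kind, I_T, I_N in [("tone_only", 1.5, 0.0), ("masking", 1.5, 1.0),
                       ("continuity", 1.5, 0.0), ("continuity", 1.5, 8.0)]:
    label = classify_response(integrate(cfg, build_scenario(kind, I_T, I_N)))
    print(kind, I_T, I_N, "->", label.verdict)
```

prints

```
tone_only 1.5 0.0 -> activated
masking 1.5 1.0 -> masked
continuity 1.5 0.0 -> discontinuous
continuity 1.5 8.0 -> continuous
```

A 1.5-level tone activates the population on its own; simultaneous noise of
level 1 already masks it (noise-driven inhibition raises the activation
knee above 1.5); a silent gap breaks the activity, but gap noise of level 8
— above the continuity threshold `C ≈ 6.97` — holds the population active
through the interruption. Threshold curves across variants
(`examples/threshold_curves.py`):

```
variant    kind        I_T=1.5  I_T=2    I_T=3    I_T=4    I_T=5
model1     masking      0.681  1.335  2.593  3.810  4.999
model1     continuity   6.971  6.971  6.971  6.971  6.971
model2     masking      0.750  1.500  3.000  4.500  6.000
model2     continuity   0.750  1.500  3.000  4.500  6.000
model3     masking      0.731  1.476  2.978  4.487  5.999
model3     continuity   2.274  2.728  3.986  5.443  6.980
```

The `examples/` directory holds one short narrative script per capability
(equilibria/knees, scenario simulation, phase-plane separatrix, threshold
curves, parameter sweeps). A thin CLI exposes the same operations:

```
tonegap simulate --model model1 --scenario continuity --IT 1.5 --IN 8
tonegap calibrate --knees -2 2 --gamma
tonegap threshold --model model2 --kind masking --out curve.csv
tonegap reproduce fig6
```

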