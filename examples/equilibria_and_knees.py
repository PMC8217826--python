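"""Knee placement and the shape of the firing-rate equilibrium curve.

Solves for the recurrent excitation a_E and sigmoid half-maximum m that put
the saddle-node knees of the tone-only equilibrium curve at chosen tone
levels, then classifies the resulting dynamical regime.
"""

from tonegap import classify_region, equilibrium_branch, get_preset, knee_IT, solve_knee_placement

for name, (IT_L, IT_R) in (("hysteresis", (0.2, 1.0)),
                           ("bistable", (-2.0, 2.0)),
                           ("combined", (0.2, 6.0))):
    a_E, m = solve_knee_placement(IT_L, IT_R)
    region = classify_region(a_E, m)
    print(f"{name:10s} knees ({IT_L:5.1f}, {IT_R:4.1f}) -> "
          f"a_E = {a_E:.4f}, m = {m:.4f}  (region {region})")

print()
print("The knees are the activation (right) and deactivation (left) tone")
print("levels; their mismatch is the hysteresis that can sustain activity.")

cfg = get_preset("model1")
knees = knee_IT(cfg.population, cfg.inputs, I_N=0.0)
noisy = knee_IT(cfg.population, cfg.inputs, I_N=8.0)
print(f"\nhysteresis variant, no noise : knees at I_T = "
      f"({knees.IT_L:.3f}, {knees.IT_R:.3f})")
print(f"hysteresis variant, I_N = 8  : knees at I_T = "
      f"({noisy.IT_L:.3f}, {noisy.IT_R:.3f})")
print("With loud gap noise the left knee drops below 0: the active state")
print("survives even though the tone is absent, which is the continuity effect.")

branch = equilibrium_branch(cfg, I_N=0.0, n=11)
print("\nsampled equilibrium curve (x, I_T, stability):")
print(branch.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
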