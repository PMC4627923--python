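"""Invert measured densities to vesicle composition.

Loads the packaged reference measurements (pre/post cyclodextrin
equilibrium buoyant densities and the cholesterol mass-remaining
fraction) and solves the two-component mixture model in closed form.
"""

from vesidens import load_reference_dataset, solve_composition

meas = load_reference_dataset()["measurements"]
print(f"inputs: rho_pre={meas.rho_pre} g/mL, rho_post={meas.rho_post} g/mL, "
      f"M={meas.mass_remaining_M}, rho_s={meas.rho_sensitive} g/mL")

sol = solve_composition(meas)
print(f"pre-treatment cholesterol volume fraction : {sol.v_s_pre:.3f}")
print(f"pre-treatment residual volume fraction    : {sol.v_r_pre:.3f}")
print(f"residual component density                : {sol.rho_r:.3f} g/mL")
print(f"post-treatment cholesterol fraction       : {sol.v_s_post:.3f}")
print(f"relative volume after treatment           : {sol.relative_volume:.3f}")
print(f"diameter ratio (cube root)                : {sol.diameter_ratio:.2f}")
print(f"implied radius shrinkage                  : {sol.radius_shrinkage_pct:.0f}%")

# The vesicles are ~57% cholesterol by volume before treatment; removing
# 83.4% of that cholesterol mass shrinks each vesicle to ~53% of its
# original volume, i.e. a ~19% smaller radius.
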