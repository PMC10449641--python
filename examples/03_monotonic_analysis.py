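"""Ultimate load from a monotonic curve, two ways.

A bending-compression force-displacement record yields its ultimate load
either as the maximum force (experimental convention) or via the
plastic-displacement offset criterion u_pl = u - F/k >= 0.07 mm (the
convention for virtual-test curves, which keep hardening past the real
failure point). On a specimen curve that peaks where it actually fails,
both agree.
"""

from poroendure import (
    OffsetCriterion,
    estimate_stiffness,
    tensile_properties,
    ultimate_load_max,
    ultimate_load_offset,
)
from poroendure.synthetic import make_tensile_curve, virtual_monotonic_test

# experimental-style curve (peaks at failure, then softens)
exp_curve = virtual_monotonic_test(0.55, "SP", softening=True)
k = estimate_stiffness(exp_curve)
r_max = ultimate_load_max(exp_curve)
print(f"specimen stiffness (origin-anchored fit below 30% of max force): "
      f"{k:.0f} N/mm")
print(f"max-force ultimate: {r_max.F_ult:.1f} N at u = {r_max.u_at_ult:.3f} mm")

# virtual-test-style curve (keeps hardening) read with the offset criterion
fe_curve = virtual_monotonic_test(0.55, "SP")
r_off = ultimate_load_offset(fe_curve, criterion=OffsetCriterion(0.07))
print(f"offset-criterion ultimate (u_pl = 0.07 mm): {r_off.F_ult:.1f} N")
print("  -> the two criteria agree because the specimen fails at that offset")

# tensile properties of the printed material
strain, stress, _ = make_tensile_curve()
props = tensile_properties(strain, stress)
print(f"tensile: E = {props.E:.1f} GPa, sigma_y = {props.sigma_y:.1f} MPa, "
      f"UTS = {props.UTS:.1f} MPa, A% = {props.A_percent:.2f}")
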