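"""Boundary-tension calibration from pressurized-shell geometry.

The tension the surrounding tissue exerts on the edge of the simulated
meristem section is |F| = (r_ex/2)·w·P0: sphere radius fit to the L1
surface (80.1 µm), mean out-of-plane cell width (7.09 µm), and a
literature turgor-pressure range of 0.66-0.98 MPa.
"""

from samsce import condition_magnitude, magnitude_from_pressure

lo = magnitude_from_pressure(r_ex=80.1, w=7.09, p0=0.66)
hi = magnitude_from_pressure(r_ex=80.1, w=7.09, p0=0.98)
print(f"pressure 0.66 MPa -> |F| = {lo:.1f} uN  (~{float(f'{lo:.2g}'):.0f})")
print(f"pressure 0.98 MPa -> |F| = {hi:.1f} uN  (~{float(f'{hi:.2g}'):.0f})")
print("named conditions (uN):")
for label in ("free", "low", "average", "high", "2x"):
    print(f"  {label:>8}: {condition_magnitude(label):6.0f}")
# The pressure window maps onto the 190-280 uN tension range; 'average'
# (235 uN) is its midpoint, and '2x' doubles the high end for perturbation
# experiments.
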