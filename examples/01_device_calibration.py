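"""Device geometry to physics: IDE cell constant, cantilever spring
constant, and the displacement-to-force calibration."""

from cardiosense import (
    CantileverSpec,
    IDEGeometry,
    cell_constant,
    force_from_displacement,
    spring_constant,
)

# An interdigitated electrode array with 100 um fingers and gaps,
# 2 mm long, 30 fingers.  K below 1 cm^-1 means the electrode geometry
# is sensitive enough for cell-substrate impedance sensing.
ide = IDEGeometry(finger_width=100e-6, finger_spacing=100e-6,
                  finger_length=2e-3, n_fingers=30)
print(f"cell constant K = {cell_constant(ide):.4f} cm^-1  (< 1: high sensitivity)")

# The 6 mm x 2 mm x 15 um SU-8 cantilever (E = 2 GPa).
beam = CantileverSpec(length=6e-3, width=2e-3, thickness=15e-6)
k = spring_constant(beam)
print(f"spring constant k = {k:.6f} N/m")

# Tip force is linear in tip deflection: F = k * delta.
for delta in (500e-9, 50e-6):
    f = force_from_displacement(k, delta)
    print(f"  delta = {delta * 1e6:8.3f} um  ->  F = {f * 1e9:8.2f} nN")
# ~7.8 nN at 500 nm and ~781 nN at 50 um: the dynamic range needed to
# resolve single-layer cardiomyocyte contractions.
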