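"""Material models: temperature and CT-number conversions, Grüneisen coefficient.

Prints the acoustic properties the simulation pipeline derives from raw
material descriptions, and the initial pressure a therapeutic proton pulse
deposits at its Bragg peak.
"""

import numpy as np

import protorange as pr
from protorange.sources import DoseMap

print("Water at 10 / 25 / 40 degC:")
for t in (10.0, 25.0, 40.0):
    print(
        f"  {t:5.1f} degC -> c = {pr.water_speed_of_sound(t):7.1f} m/s, "
        f"rho = {pr.water_density(t):6.1f} kg/m3"
    )

print("\nCT-number (offset scale, water ~ 1000) to tissue properties:")
for name, hu in [("lung", 234.5), ("water", 1000.0), ("soft tissue", 1042.5), ("bone", 1850.0)]:
    print(
        f"  {name:11s} HU {hu:6.1f} -> c = {pr.hu_to_speed(hu):7.1f} m/s, "
        f"rho = {pr.hu_to_density(hu):6.1f} kg/m3"
    )

thermo = pr.ThermoacousticParams(c=1498.0, beta=2.3e-4, cp=4178.0, rho=997.0)
gamma = pr.gruneisen(thermo)
print(f"\nGrüneisen coefficient of water-like tissue: {gamma:.4f}")

# 1 cGy deposited in one Bragg-peak voxel of water-equivalent tissue
medium = pr.MediumGrid(
    spacing=1.0, speed=np.full((5, 5, 1), 1498.0), density=np.full((5, 5, 1), 997.0)
)
dose = np.zeros((5, 5, 1))
dose[2, 2, 0] = 0.01  # Gy
p0 = pr.initial_pressure(DoseMap(dose, 1.0), medium, thermo)
print(f"Initial pressure from a 1.0 cGy Bragg-peak dose: {p0.max():.2f} Pa")
print("(thermoacoustic efficiency times density times dose, Pa per voxel)")
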