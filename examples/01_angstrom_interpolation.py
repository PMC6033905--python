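"""Interpolate sun-photometer AOD to the satellite wavelength (550 nm).

Sun photometers measure AOD at their own wavelengths (here 440 and
675 nm); satellite products report 550 nm.  The two anchor measurements
determine a unique power law in wavelength (the Angstrom relation),
which we evaluate at 550 nm.
"""

from aodfuse import angstrom_interpolate_550

cases = [
    (0.50, 0.50),   # wavelength-flat spectrum (coarse particles)
    (0.40, 0.20),   # steep spectrum (fine-mode pollution aerosol)
    (0.80, 0.55),   # typical hazy-day Beijing spectrum
]

print(f"{'AOD(440)':>9} {'AOD(675)':>9} {'AOD(550)':>9}")
for a440, a675 in cases:
    a550 = angstrom_interpolate_550(a440, a675)
    print(f"{a440:9.3f} {a675:9.3f} {a550:9.4f}")

print()
print("AOD(550) always lies between the two anchors: the interpolation is")
print("a straight line in log-AOD vs log-wavelength through both points.")
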