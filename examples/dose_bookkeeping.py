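"""Electron-budget bookkeeping for a low-dose scanning-diffraction setup.

Builds the reference geometry (300 keV, 128^2 detector binned so the
image pixel is 1.7 A) and prints how a 20 e-/A^2 dose is distributed over
scan exposures and pixels.
"""

from cryoptycho import default_geometry, wavelength_from_energy
from cryoptycho.detector import dose_summary

geom = default_geometry()
print(f"electron wavelength at 300 keV : {wavelength_from_energy(300.0):.3f} pm")
print(f"image pixel size r_d           : {geom.image_pixel_size:.2f} A")
print(f"detector angular Nyquist       : {geom.max_half_angle:.2f} mrad")

dose = 20.0  # e-/A^2, a typical cryo exposure budget
step = 12  # scan step in image pixels (~2 nm)
summary = dose_summary(dose, step, geom)
print(f"\nat {dose:.0f} e-/A^2 with a {step}-pixel scan step:")
print(f"  electrons per exposure       : {summary['electrons_per_pattern']:.0f}")
print(f"  mean e- per detector pixel   : {summary['electrons_per_detector_pixel']:.3f}")
print(f"  e- per image pixel           : {summary['electrons_per_image_pixel']:.1f}")
# The per-image-pixel number (57.8 ~ 58) is what limits any dose-fractionated
# imaging mode at this sampling; the sub-electron detector counts are why a
# Poisson noise model is essential.
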