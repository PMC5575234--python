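"""The three benchmark illuminations: defocused, zone plate, randomized.

Builds each probe on a reduced geometry, prints its 1%-threshold support
area and the scan step that yields 75% area overlap.
"""

from cryoptycho.probes import probe_support_area, step_from_overlap
from cryoptycho.workflows import build_probe, small_geometry

geom = small_geometry()
print(f"geometry: {geom.n_detector_pixels}^2 detector, r_d = "
      f"{geom.image_pixel_size:.2f} A, aperture {geom.probe_half_angle} mrad\n")

for kind in ("defocused", "fzp", "random"):
    probe = build_probe(kind, geom, seed=0)
    area = probe_support_area(probe)
    step = step_from_overlap(probe, overlap=0.75)
    print(f"{kind:10s} support {area:7.0f} A^2  "
          f"(equiv. diameter {2 * (area / 3.14159) ** 0.5 / 10:.1f} nm), "
          f"75%-overlap step {step} px = {step * geom.image_pixel_size / 10:.2f} nm")
# Larger probes take bigger steps at fixed overlap, so they spread the same
# dose over fewer, brighter exposures; the speckled random probe also makes
# neighbouring diffraction patterns maximally dissimilar, which is what the
# reconstruction rewards at low dose.
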