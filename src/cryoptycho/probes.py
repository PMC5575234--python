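"""Probe (illumination) engineering.

Three probe families are provided, all built in the probe-forming aperture
plane and brought to the specimen plane by the lens transform (a unitary
inverse FFT):

* a conventional defocused probe (aperture + quadratic defocus phase),
* a binary Fresnel-zone-plate probe a given distance from its focus,
* a randomized probe: a band-limited random phase screen (holographic
  phase plate) focused by an ideal lens.

The probe grid equals the detector grid (``geom.n_detector_pixels`` per
side) sampled at the diffraction-limited pixel size r_d, so the far field
of a probe is exactly its aperture-plane field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .geometry import (
    ComplexField2D,
    ExperimentGeometry,
    fft2,
    fftfreq_grid,
    ifft2,
)

__all__ = [
    "ProbeField",
    "ProbeSpec",
    "make_defocused_probe",
    "make_fzp_probe",
    "make_random_probe",
    "probe_support_area",
    "step_from_overlap",
    "fresnel_propagate",
]


@dataclass
class ProbeField:
    """Normalized complex illumination at the specimen plane.

    ``sum |psi|^2 == total_electrons`` (electrons per exposure) and the
    Fourier amplitude vanishes outside ``aperture_half_angle``.
    """

    field: ComplexField2D
    total_electrons: float
    aperture_half_angle: float

    def __post_init__(self) -> None:
        power = self.field.power()
        if not np.isclose(power, self.total_electrons, rtol=1e-8):
            raise ValueError(
                f"probe power {power} does not match total_electrons "
                f"{self.total_electrons}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.field.values

    @property
    def pixel_size(self) -> float:
        return self.field.pixel_size


@dataclass
class ProbeSpec:
    """Declarative probe description used in run configurations."""

    kind: str = "defocused"  # one of {"defocused", "fzp", "random"}
    defocus: float = 400.0  # nm, defocused kind
    half_angle: float | None = None  # mrad; None -> geometry default
    fzp_distance_from_focus: float = 600.0  # nm, fzp kind
    fzp_n_zones: int = 8
    correlation_length: float = 4.0  # pixels, random kind
    seed: int = 0

    def build(self, geom: ExperimentGeometry, electrons: float) -> ProbeField:
        if self.kind == "defocused":
            return make_defocused_probe(
                geom, self.defocus, self.half_angle or geom.probe_half_angle, electrons
            )
        if self.kind == "fzp":
            return make_fzp_probe(
                geom,
                self.fzp_distance_from_focus,
                electrons,
                half_angle=self.half_angle,
                n_zones=self.fzp_n_zones,
            )
        if self.kind == "random":
            return make_random_probe(
                geom,
                self.correlation_length,
                self.seed,
                electrons,
                half_angle=self.half_angle,
            )
        raise ValueError(f"unknown probe kind {self.kind!r}")


def _aperture(geom: ExperimentGeometry, half_angle: float):
    """Aperture mask and |q| grid (1/A) on the probe grid, unshifted layout."""
    if not half_angle > 0:
        raise ValueError("aperture half-angle must be positive")
    if half_angle > geom.max_half_angle * (1 + 1e-12):
        raise ValueError(
            f"aperture half-angle {half_angle} mrad exceeds the detector "
            f"Nyquist angle {geom.max_half_angle:.3f} mrad"
        )
    m = geom.n_detector_pixels
    r_d = geom.image_pixel_size
    q = fftfreq_grid((m, m), r_d)  # 1/A
    lam_a = geom.wavelength * 1e-2
    theta_mrad = lam_a * q * 1e3
    return (theta_mrad <= half_angle), q


def _to_probe(
    aperture_field: np.ndarray,
    geom: ExperimentGeometry,
    electrons: float,
    half_angle: float,
) -> ProbeField:
    psi = ifft2(aperture_field)
    power = np.sum(np.abs(psi) ** 2)
    if power == 0:
        raise ValueError("aperture field carries no intensity")
    psi *= np.sqrt(electrons / power)
    return ProbeField(
        field=ComplexField2D(psi, geom.image_pixel_size),
        total_electrons=electrons,
        aperture_half_angle=half_angle,
    )


def make_defocused_probe(
    geom: ExperimentGeometry,
    defocus: float,
    half_angle: float,
    electrons: float = 1.0,
) -> ProbeField:
    """Aperture-limited probe with quadratic defocus phase chi = pi lambda df q^2.

    Parameters
    ----------
    defocus : defocus aberration in nm (finite; 0 gives the focused
        Airy-like spot).
    half_angle : semi-convergence angle in mrad; must not exceed the
        detector's angular Nyquist limit.
    electrons : electrons per exposure (probe normalization).
    """
    if not np.isfinite(defocus):
        raise ValueError("defocus must be finite")
    mask, q = _aperture(geom, half_angle)
    lam_a = geom.wavelength * 1e-2
    df_a = defocus * 10.0  # nm -> A
    chi = np.pi * lam_a * df_a * q**2
    return _to_probe(mask * np.exp(-1j * chi), geom, electrons, half_angle)


def fresnel_propagate(
    field: ComplexField2D, distance: float, wavelength_pm: float
) -> ComplexField2D:
    """Paraxial free-space propagation by ``distance`` (nm), unitary.

    Applies the Fourier-space transfer function exp(-i pi lambda z q^2);
    propagating by +d then -d recovers the input exactly.
    """
    lam_a = wavelength_pm * 1e-2
    z_a = distance * 10.0
    q = fftfreq_grid(field.shape, field.pixel_size)
    transfer = np.exp(-1j * np.pi * lam_a * z_a * q**2)
    return ComplexField2D(ifft2(fft2(field.values) * transfer), field.pixel_size)


def make_fzp_probe(
    geom: ExperimentGeometry,
    distance_from_focus: float,
    electrons: float = 1.0,
    half_angle: float | None = None,
    n_zones: int = 8,
) -> ProbeField:
    """Probe formed by an ideal binary (0/pi) Fresnel zone plate.

    A binary phase plate equals a perfect lens times a sawtooth residual
    phase in [0, pi): the plate's focusing chirp is quantized to {0, pi}
    over ``n_zones`` equal-q^2 zones across the aperture.  The aperture
    field carries that residual (its first diffraction order focuses with
    the classical 4/pi^2 efficiency) plus the defocus chirp for the stated
    distance from focus (nm).
    """
    ha = half_angle if half_angle is not None else geom.probe_half_angle
    mask, q = _aperture(geom, ha)
    lam_a = geom.wavelength * 1e-2
    q_ap = ha * 1e-3 / (geom.wavelength * 1e-12) * 1e-10  # aperture edge, 1/A
    # Reference chirp reaching n_zones * pi at the aperture edge.
    chi_ref = np.pi * n_zones * (q / q_ap) ** 2
    binary = np.where(np.mod(chi_ref, 2 * np.pi) >= np.pi, np.pi, 0.0)
    residual = np.mod(chi_ref + binary, 2 * np.pi) - np.pi  # sawtooth, zero-mean
    z_a = distance_from_focus * 10.0
    chi_defocus = np.pi * lam_a * z_a * q**2
    aperture_field = mask * np.exp(1j * (residual - chi_defocus))
    return _to_probe(aperture_field, geom, electrons, ha)


def make_random_probe(
    geom: ExperimentGeometry,
    correlation_length: float,
    seed: int,
    electrons: float = 1.0,
    half_angle: float | None = None,
    phase_std: float = np.pi,
) -> ProbeField:
    """Randomized probe: smoothed random phase screen focused by a lens.

    The holographic phase plate is modeled as a uniform-random phase field
    on the aperture grid, smoothed with a Gaussian of width
    ``correlation_length`` (aperture-plane pixels, >= 1) and rescaled to a
    standard deviation of ``phase_std``.  For correlation lengths much
    smaller than the aperture the focused intensity is fully developed
    speckle (contrast ~ 1).  Deterministic for a fixed seed.
    """
    if correlation_length < 1:
        raise ValueError("correlation_length must be at least 1 pixel")
    ha = half_angle if half_angle is not None else geom.probe_half_angle
    mask, _ = _aperture(geom, ha)
    rng = np.random.default_rng(seed)
    m = geom.n_detector_pixels
    raw = rng.uniform(0.0, 2.0 * np.pi, size=(m, m))
    smooth = gaussian_filter(raw, sigma=correlation_length, mode="wrap")
    smooth -= smooth.mean()
    std = smooth.std()
    if std > 0:
        smooth *= phase_std / std
    return _to_probe(mask * np.exp(1j * smooth), geom, electrons, ha)


def probe_support_area(probe: ProbeField, threshold: float = 0.01) -> float:
    """Real-space support area in A^2: pixels whose intensity exceeds
    ``threshold`` times the maximum, times r_d^2."""
    intensity = np.abs(probe.values) ** 2
    peak = intensity.max()
    if peak == 0:
        raise ValueError("probe is identically zero")
    count = int(np.count_nonzero(intensity > threshold * peak))
    return count * probe.pixel_size**2


def _lens_area_fraction(x: float) -> float:
    """Shared-area fraction of two unit circles with centre distance x in
    units of the radius (x in [0, 2])."""
    return (2.0 * np.arccos(x / 2.0) - (x / 2.0) * np.sqrt(4.0 - x**2)) / np.pi


def step_from_overlap(
    probe: ProbeField, overlap: float = 0.75, threshold: float = 0.01
) -> int:
    """Scan step (integer pixels) giving the requested fractional *area*
    overlap of the probe's circular-equivalent support.

    The support is the thresholded-intensity pixel set; its circular-
    equivalent radius R solves area = pi R^2.  The step is the centre
    distance at which two such circles share ``overlap`` of their area,
    rounded to the nearest pixel (minimum 1).
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    area = probe_support_area(probe, threshold)
    radius = np.sqrt(area / np.pi)  # A
    if overlap == 0.0:
        step_a = 2.0 * radius
    else:
        x = brentq(lambda t: _lens_area_fraction(t) - overlap, 0.0, 2.0)
        step_a = x * radius
    return max(1, int(round(step_a / probe.pixel_size)))
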