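"""Experiment geometry, grid conventions, and the unitary Fourier contract.

All modules share the conventions fixed here:

* 2D arrays are indexed ``[row, col]`` with index ``(0, 0)`` at the top left;
  positions are expressed in integer pixel units.
* Fourier transforms are unitary (``norm="ortho"``) so that the sum of
  squared moduli — the electron count — is identical in real and reciprocal
  space (Parseval).  Zero frequency sits at index 0 internally;
  :func:`fftshift2`/:func:`ifftshift2` move it to the array centre for
  display.
* Lengths: electron energy in keV, wavelength in pm, camera length in mm,
  detector pixel size in µm, real-space (image) pixel size in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# CODATA values, in eV-based units.
_ELECTRON_REST_ENERGY_EV = 510_998.95  # m0 c^2
_HC_EV_M = 1.239_841_98e-6  # h c in eV * m


def wavelength_from_energy(energy_kev: float) -> float:
    """Relativistic de Broglie wavelength of an electron, in pm.

    lambda = h c / sqrt(E (E + 2 m0 c^2)) with E the kinetic energy.

    Parameters
    ----------
    energy_kev : electron kinetic energy in keV; must be positive.
    """
    if not energy_kev > 0:
        raise ValueError(f"electron energy must be positive, got {energy_kev} keV")
    e_ev = energy_kev * 1e3
    lam_m = _HC_EV_M / np.sqrt(e_ev * (e_ev + 2.0 * _ELECTRON_REST_ENERGY_EV))
    return float(lam_m * 1e12)


def interaction_constant(energy_kev: float) -> float:
    """Electron-specimen interaction constant sigma in rad / (V * Angstrom).

    sigma = (2 pi / (lambda E)) * (m0 c^2 + E) / (2 m0 c^2 + E), the
    standard multislice interaction parameter with E the kinetic energy.
    """
    if not energy_kev > 0:
        raise ValueError("electron energy must be positive")
    e_ev = energy_kev * 1e3
    lam_a = wavelength_from_energy(energy_kev) * 1e-2  # pm -> Angstrom
    return float(
        (2.0 * np.pi / (lam_a * e_ev))
        * (_ELECTRON_REST_ENERGY_EV + e_ev)
        / (2.0 * _ELECTRON_REST_ENERGY_EV + e_ev)
    )


@dataclass(frozen=True)
class ExperimentGeometry:
    """Far-field scanning-diffraction geometry.

    The diffraction-limited half-period resolution of the recorded data,
    which is also the real-space sampling of probe and object, is

        r_d = lambda * camera_length / (n_detector_pixels * detector_pixel_size).

    Attributes
    ----------
    electron_energy : beam energy in keV.
    camera_length : specimen-to-detector distance in mm.
    n_detector_pixels : detector side length in pixels (square detector).
    detector_pixel_size : physical detector pixel pitch in µm.
    probe_half_angle : semi-convergence angle of the probe-forming
        aperture in mrad (carried as metadata; probe constructors take it
        explicitly).
    """

    electron_energy: float = 300.0
    camera_length: float = 55.261
    n_detector_pixels: int = 128
    detector_pixel_size: float = 5.0
    probe_half_angle: float = 9.2

    def __post_init__(self) -> None:
        for name in ("electron_energy", "camera_length", "detector_pixel_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_detector_pixels < 2:
            raise ValueError("n_detector_pixels must be at least 2")

    @property
    def wavelength(self) -> float:
        """Electron wavelength in pm."""
        return wavelength_from_energy(self.electron_energy)

    @property
    def image_pixel_size(self) -> float:
        """Real-space sampling r_d in Angstrom."""
        lam_a = self.wavelength * 1e-2  # pm -> A
        dz_a = self.camera_length * 1e7  # mm -> A
        dpix_a = self.detector_pixel_size * 1e4  # um -> A
        return float(lam_a * dz_a / (self.n_detector_pixels * dpix_a))

    @property
    def angular_pixel_size(self) -> float:
        """Angle subtended by one detector pixel, in mrad."""
        return float(self.detector_pixel_size * 1e-6 / (self.camera_length * 1e-3) * 1e3)

    @property
    def max_half_angle(self) -> float:
        """Angular Nyquist limit of the detector, in mrad."""
        return self.angular_pixel_size * self.n_detector_pixels / 2.0


def diffraction_limited_resolution(geom: ExperimentGeometry) -> float:
    """Half-period diffraction-limited resolution r_d in Angstrom."""
    return geom.image_pixel_size


def geometry_for_pixel_size(
    pixel_size: float,
    *,
    electron_energy: float = 300.0,
    n_detector_pixels: int = 128,
    detector_pixel_size: float = 5.0,
    probe_half_angle: float = 9.2,
) -> ExperimentGeometry:
    """Geometry with the camera length solved for a requested r_d (Angstrom)."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    lam_a = wavelength_from_energy(electron_energy) * 1e-2
    dpix_a = detector_pixel_size * 1e4
    dz_mm = pixel_size * n_detector_pixels * dpix_a / lam_a * 1e-7
    return ExperimentGeometry(
        electron_energy=electron_energy,
        camera_length=dz_mm,
        n_detector_pixels=n_detector_pixels,
        detector_pixel_size=detector_pixel_size,
        probe_half_angle=probe_half_angle,
    )


def default_geometry() -> ExperimentGeometry:
    """The package's reference configuration: 300 keV, 128^2 detector, r_d = 1.7 A."""
    return geometry_for_pixel_size(1.7)


@dataclass
class ComplexField2D:
    """A complex-valued wave or transmission sampled on a square raster.

    ``values`` is a 2D complex array; ``pixel_size`` is the real-space
    sampling in Angstrom.  Index (0, 0) is the top-left corner.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("ComplexField2D requires a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ComplexField2D":
        return ComplexField2D(self.values.copy(), self.pixel_size)

    def power(self) -> float:
        """Total integrated intensity sum |values|^2 (electrons for waves)."""
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class ScanPlan:
    """Integer-pixel probe placements on the object grid.

    ``positions`` holds K unique (row, col) offsets of the top-left corner
    of the probe patch; a patch of shape ``patch_shape`` placed at each
    offset must lie fully inside an object of shape ``object_shape``.
    """

    positions: np.ndarray
    step: int
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be a (K, 2) array of pixel offsets")
        if len(self.positions) < 1:
            raise ValueError("a scan needs at least one position")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("scan positions must be unique")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def validate_against(
        self, object_shape: tuple[int, int], patch_shape: tuple[int, int]
    ) -> None:
        """Raise if any patch would stick out of the object grid."""
        rows, cols = self.positions[:, 0], self.positions[:, 1]
        if rows.min() < 0 or cols.min() < 0:
            raise ValueError("scan positions must be non-negative pixel offsets")
        if (rows.max() + patch_shape[0] > object_shape[0]) or (
            cols.max() + patch_shape[1] > object_shape[1]
        ):
            raise ValueError(
                "scan patch exceeds object grid: position "
                f"({rows.max()}, {cols.max()}) with patch {patch_shape} "
                f"does not fit in object {object_shape}"
            )


def raster_scan(
    object_shape: tuple[int, int],
    patch_shape: tuple[int, int],
    step: int,
    overlap_fraction: float = 0.0,
) -> ScanPlan:
    """Regular raster of top-left offsets with the given step, fully inside
    the object grid."""
    if step < 1:
        raise ValueError("step must be at least 1 pixel")
    rows = np.arange(0, object_shape[0] - patch_shape[0] + 1, step)
    cols = np.arange(0, object_shape[1] - patch_shape[1] + 1, step)
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("patch does not fit inside the object grid")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pos = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return ScanPlan(positions=pos, step=int(step), overlap_fraction=overlap_fraction)


# ---------------------------------------------------------------------------
# Unitary Fourier helpers — the single FFT contract used across the package.

def fft2(a: np.ndarray) -> np.ndarray:
    """Unitary forward 2D DFT (zero frequency at index 0)."""
    return np.fft.fft2(a, norm="ortho")


def ifft2(a: np.ndarray) -> np.ndarray:
    """Unitary inverse 2D DFT."""
    return np.fft.ifft2(a, norm="ortho")


def fftshift2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(a, axes=(-2, -1))


def ifftshift2(a: np.ndarray) -> np.ndarray:
    return np.fft.ifftshift(a, axes=(-2, -1))


def fftfreq_grid(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Radial spatial-frequency magnitude |q| in 1/Angstrom, zero freq at
    index 0 (unshifted layout)."""
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    return np.hypot(fy[:, None], fx[None, :])
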