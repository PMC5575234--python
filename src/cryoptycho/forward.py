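"""Exit-wave formation and the ptychographic measurement operator.

The measurement model is the thin-object (multiplicative) approximation:
for scan position i the exit wave is the shifted probe times the object
patch, and the recorded pattern is the squared modulus of its unitary 2D
DFT,

    I_i(q) = | F[ psi(r + r_i) T(r) ] |^2 .

Stacking all K positions gives a linear complex map T -> F Q T (the
"design matrix" P = FQ) whose squared moduli are the noise-free data.
A multislice propagator is provided for simulation of thick specimens;
the reconstruction always inverts the thin-object model.  A TEM contrast
transfer function (optionally with a Zernike-type phase shift of the
unscattered beam) supports the conventional cryo-EM comparison arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .geometry import (
    ComplexField2D,
    ExperimentGeometry,
    ScanPlan,
    fft2,
    fftfreq_grid,
    ifft2,
    interaction_constant,
)
from .probes import ProbeField, fresnel_propagate

__all__ = [
    "ObjectField",
    "PotentialMap",
    "ForwardOperator",
    "ContrastTransferFunction",
    "thin_object_exit_wave",
    "multislice_exit_wave",
    "far_field_intensity",
    "ctf_image",
    "forward_apply",
]


@dataclass
class ObjectField:
    """Complex specimen transmission function T on an n1 x n2 grid.

    A physical (passive) specimen has |T| <= 1 everywhere; reconstruction
    iterates may transiently violate this, so the check is controlled by
    ``passive``.
    """

    field: ComplexField2D
    passive: bool = True

    def __post_init__(self) -> None:
        if self.passive and np.any(np.abs(self.field.values) > 1.0 + 1e-9):
            raise ValueError("passive object requires |T| <= 1 everywhere")

    @property
    def values(self) -> np.ndarray:
        return self.field.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape

    @property
    def pixel_size(self) -> float:
        return self.field.pixel_size

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.field.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field.values)


@dataclass
class PotentialMap:
    """Sliced 3D specimen potential for multislice simulation.

    ``slices`` is a complex ``(n_slices, ny, nx)`` array: the real part is
    the electrostatic potential in volts, the imaginary part an amplitude
    attenuation coefficient in 1/Angstrom (so a uniform imaginary value of
    1/(2 Lambda) over thickness t attenuates the amplitude by
    exp(-t / 2 Lambda), Lambda being the inelastic mean free path).
    """

    slices: np.ndarray
    voxel_size: float  # in-plane sampling, A
    slice_thickness: float  # A

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.complex128)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a 3D (n_slices, ny, nx) array")
        if not (self.voxel_size > 0 and self.slice_thickness > 0):
            raise ValueError("voxel_size and slice_thickness must be positive")
        if np.any(self.slices.imag < -1e-12):
            raise ValueError("imaginary potential (attenuation) must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def total_thickness(self) -> float:
        return self.n_slices * self.slice_thickness


def thin_object_exit_wave(
    probe: ProbeField, obj: ObjectField, position: tuple[int, int]
) -> ComplexField2D:
    """Pointwise product of the probe with the object patch at ``position``
    (top-left corner, integer pixels).  No wrap-around: out-of-bounds
    placements raise."""
    m1, m2 = probe.field.shape
    n1, n2 = obj.shape
    r, c = int(position[0]), int(position[1])
    if r < 0 or c < 0 or r + m1 > n1 or c + m2 > n2:
        raise ValueError(
            f"probe patch at ({r}, {c}) of shape ({m1}, {m2}) exceeds object "
            f"grid ({n1}, {n2})"
        )
    patch = obj.values[r : r + m1, c : c + m2]
    return ComplexField2D(probe.values * patch, probe.pixel_size)


def far_field_intensity(exit_wave: ComplexField2D) -> np.ndarray:
    """|F[psi_exit]|^2 with the unitary transform (total intensity is
    preserved)."""
    return np.abs(fft2(exit_wave.values)) ** 2


def _bandlimit_mask(shape: tuple[int, int], fraction: float = 2.0 / 3.0) -> np.ndarray:
    q = fftfreq_grid(shape, 1.0)  # cycles/pixel
    return q <= fraction * 0.5


def multislice_exit_wave(
    probe: ProbeField, potential: PotentialMap, geom: ExperimentGeometry
) -> ComplexField2D:
    """Propagate the probe through a sliced potential.

    Each slice applies the transmission exp(i sigma V_re dz - V_im dz)
    (band-limited to 2/3 Nyquist, the usual multislice anti-aliasing
    convention) followed by unitary Fresnel propagation over the slice
    thickness.  sigma is the energy-dependent interaction constant.
    """
    if potential.slices.shape[1:] != probe.field.shape:
        raise ValueError("potential grid does not match the probe grid")
    if not np.isclose(potential.voxel_size, probe.pixel_size, rtol=1e-6):
        raise ValueError(
            "in-plane voxel size must equal the probe pixel size "
            f"({potential.voxel_size} vs {probe.pixel_size})"
        )
    sigma = interaction_constant(geom.electron_energy)
    dz = potential.slice_thickness
    mask = _bandlimit_mask(probe.field.shape)
    wave = ComplexField2D(probe.values.copy(), probe.pixel_size)
    for s in range(potential.n_slices):
        v = potential.slices[s]
        trans = np.exp(1j * sigma * v.real * dz - v.imag * dz)
        if np.any(v != 0):
            trans = ifft2(fft2(trans) * mask)
        wave = ComplexField2D(wave.values * trans, wave.pixel_size)
        wave = fresnel_propagate(wave, dz * 0.1, geom.wavelength)  # A -> nm
    return wave


@dataclass
class ContrastTransferFunction:
    """Wave-optical transfer filter of a conventional TEM.

    Scattered beams acquire the aberration phase chi(q) = pi lambda df q^2
    - (pi/2) Cs lambda^3 q^4; a Zernike-type phase plate instead shifts the
    *unscattered* beam by ``additional_phase`` (pi/2 for the classical
    plate).  An optional radial envelope table damps high frequencies.
    """

    defocus: float = 1.6  # um
    spherical_aberration: float = 0.0  # mm
    additional_phase: float = 0.0  # rad, applied to the unscattered beam
    envelope: tuple[np.ndarray, np.ndarray] | None = None  # (q 1/A, value)

    def sample(self, shape: tuple[int, int], pixel_size: float, wavelength_pm: float):
        """Complex transfer array on the unshifted Fourier grid."""
        lam_a = wavelength_pm * 1e-2
        q = fftfreq_grid(shape, pixel_size)
        df_a = self.defocus * 1e4  # um -> A
        cs_a = self.spherical_aberration * 1e7  # mm -> A
        chi = np.pi * lam_a * df_a * q**2 - 0.5 * np.pi * cs_a * lam_a**3 * q**4
        transfer = np.exp(-1j * chi).astype(np.complex128)
        transfer[0, 0] = np.exp(1j * self.additional_phase)
        if self.envelope is not None:
            q_tab, e_tab = self.envelope
            env = np.interp(q, q_tab, e_tab)
            if np.any(np.abs(env) > 1 + 1e-12):
                raise ValueError("envelope must satisfy |CTF| <= 1")
            transfer *= env
        return transfer


def ctf_image(
    exit_wave: ComplexField2D,
    ctf: ContrastTransferFunction,
    wavelength_pm: float,
) -> np.ndarray:
    """Conventional TEM image intensity |F^-1[F[psi_exit] CTF]|^2.

    With a unity transfer function this reproduces |psi_exit|^2 up to FFT
    round-off.
    """
    transfer = ctf.sample(exit_wave.shape, exit_wave.pixel_size, wavelength_pm)
    filtered = ifft2(fft2(exit_wave.values) * transfer)
    return np.abs(filtered) ** 2


@dataclass
class ForwardOperator:
    """The linear complex map T -> FQT of the ptychographic experiment.

    ``apply`` returns the K complex far-field amplitudes (K, m1, m2);
    ``adjoint`` is its exact adjoint, satisfying <Px, y> = <x, P+y> for
    the unitary-FFT inner products.
    """

    probe: ProbeField
    scanplan: ScanPlan
    object_shape: tuple[int, int]
    _probe_power_map: np.ndarray | None = dataclass_field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scanplan.validate_against(self.object_shape, self.probe.field.shape)

    @property
    def n_positions(self) -> int:
        return self.scanplan.n_positions

    @property
    def n_measurements(self) -> int:
        m1, m2 = self.probe.field.shape
        return self.n_positions * m1 * m2

    def apply(self, t_values: np.ndarray) -> np.ndarray:
        """Complex far-field amplitudes for all positions: (K, m1, m2)."""
        m1, m2 = self.probe.field.shape
        psi = self.probe.values
        out = np.empty((self.n_positions, m1, m2), dtype=np.complex128)
        for i, (r, c) in enumerate(self.scanplan.positions):
            out[i] = fft2(psi * t_values[r : r + m1, c : c + m2])
        return out

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        """Adjoint map from (K, m1, m2) amplitudes back to the object grid."""
        m1, m2 = self.probe.field.shape
        psi_conj = np.conj(self.probe.values)
        acc = np.zeros(self.object_shape, dtype=np.complex128)
        for i, (r, c) in enumerate(self.scanplan.positions):
            acc[r : r + m1, c : c + m2] += psi_conj * ifft2(g[i])
        return acc

    def intensities(self, t_values: np.ndarray) -> np.ndarray:
        """Noise-free patterns |FQT|^2, shape (K, m1, m2)."""
        return np.abs(self.apply(t_values)) ** 2

    def probe_power_map(self) -> np.ndarray:
        """Diagonal of Q+Q: summed probe intensity per object pixel."""
        if self._probe_power_map is None:
            m1, m2 = self.probe.field.shape
            intensity = np.abs(self.probe.values) ** 2
            acc = np.zeros(self.object_shape, dtype=np.float64)
            for r, c in self.scanplan.positions:
                acc[r : r + m1, c : c + m2] += intensity
            self._probe_power_map = acc
        return self._probe_power_map


def forward_apply(obj: ObjectField, operator: ForwardOperator):
    """Noise-free diffraction stack: K far-field intensity patterns."""
    from .detector import DiffractionStack

    return DiffractionStack(
        data=operator.intensities(obj.values),
        electrons_per_pattern=float(operator.probe.total_electrons),
    )
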