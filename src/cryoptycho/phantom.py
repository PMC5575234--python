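"""Synthetic weak-phase specimens and potential-map import.

The phantom emulates a macromolecule embedded in vitreous ice: a compact
cluster of Gaussian pseudo-atoms riding on a weakly fluctuating ice
background.  Phase contrast dominates (peak phase a free parameter,
default 0.3 rad); amplitude contrast is minimal and comes from the
inelastic mean free path, attenuating the amplitude by exp(-t / 2 Lambda)
with a slightly shorter Lambda inside the particle than in the
surrounding ice.

External volumes are read from MRC files (mode 2, float32; slices along
the last axis).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import ObjectField, PotentialMap
from .geometry import ComplexField2D, ExperimentGeometry, interaction_constant

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "potential_to_transmission",
    "load_mrc_potential",
    "save_mrc_potential",
]


@dataclass
class PhantomSpec:
    """Parameters of the pseudo-atom macromolecule-in-ice phantom.

    Defaults give a weak-phase, low-contrast specimen: 0.3 rad peak phase,
    50 nm thickness, and inelastic mean free paths around 320 nm (ice) /
    270 nm (protein) at 300 keV.
    """

    grid: tuple[int, int] = (64, 64)
    pixel_size: float = 1.7  # A
    n_pseudo_atoms: int = 40
    atom_sigma: float = 2.5  # A
    peak_phase: float = 0.3  # rad
    ice_phase_std: float = 0.02  # rad
    thickness: float = 500.0  # A
    imfp_ice: float = 3200.0  # A
    imfp_protein: float = 2700.0  # A
    particle_radius_fraction: float = 0.35
    n_slices: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_phase < np.pi):
            raise ValueError("peak_phase must lie in (0, pi)")
        for name in (
            "pixel_size",
            "atom_sigma",
            "thickness",
            "imfp_ice",
            "imfp_protein",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pseudo_atoms < 1:
            raise ValueError("need at least one pseudo-atom")


def _atom_cloud(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sum of unit-height Gaussians placed uniformly inside the particle
    disc (density map, arbitrary units)."""
    n1, n2 = spec.grid
    yy, xx = np.mgrid[0:n1, 0:n2].astype(float)
    cy, cx = (n1 - 1) / 2.0, (n2 - 1) / 2.0
    radius_px = spec.particle_radius_fraction * min(n1, n2)
    density = np.zeros((n1, n2))
    sigma_px = spec.atom_sigma / spec.pixel_size
    for _ in range(spec.n_pseudo_atoms):
        r = radius_px * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        ay, ax = cy + r * np.sin(theta), cx + r * np.cos(theta)
        density += np.exp(-(((yy - ay) ** 2 + (xx - ax) ** 2) / (2.0 * sigma_px**2)))
    return density


def generate_phantom(spec: PhantomSpec) -> tuple[ObjectField, PotentialMap]:
    """Deterministic (per seed) phantom: transmission function and the
    matching sliced potential.

    The returned transmission satisfies max(phase) == peak_phase to within
    1e-6 and |T| <= 1; the potential map reproduces the same transmission
    through :func:`potential_to_transmission` under the thin-object
    approximation.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.grid

    density = _atom_cloud(spec, rng)
    ice = gaussian_filter(rng.standard_normal((n1, n2)), sigma=2.0)
    ice_std = ice.std()
    if ice_std > 0:
        ice *= spec.ice_phase_std / ice_std
    ice -= ice.min()  # keep the total phase nonnegative

    phase = density / density.max() * spec.peak_phase + ice
    phase *= spec.peak_phase / phase.max()  # exact peak after adding ice

    # Amplitude: exp(-t / 2 Lambda_eff), Lambda interpolating between the
    # ice and protein mean free paths with the local particle density.
    w = np.clip(density / density.max(), 0.0, 1.0)
    inv_lambda = (1.0 - w) / spec.imfp_ice + w / spec.imfp_protein
    amplitude = np.exp(-spec.thickness * inv_lambda / 2.0)

    values = amplitude * np.exp(1j * phase)
    obj = ObjectField(ComplexField2D(values, spec.pixel_size))

    # Sliced potential consistent with the projected phase and attenuation.
    sigma = interaction_constant(300.0)
    dz = spec.thickness / spec.n_slices
    v_real = phase / (sigma * spec.thickness)  # volts, uniform in depth
    v_imag = -np.log(amplitude) / spec.thickness  # 1/A amplitude attenuation
    slices = np.broadcast_to(
        v_real + 1j * v_imag, (spec.n_slices, n1, n2)
    ).copy()
    potential = PotentialMap(
        slices=slices, voxel_size=spec.pixel_size, slice_thickness=dz
    )
    return obj, potential


def potential_to_transmission(
    potential: PotentialMap, geom: ExperimentGeometry
) -> ObjectField:
    """Thin-object transmission from a sliced potential:
    T = exp(i sigma sum_s V_re dz - sum_s V_im dz)."""
    sigma = interaction_constant(geom.electron_energy)
    dz = potential.slice_thickness
    proj_real = potential.slices.real.sum(axis=0) * dz
    proj_imag = potential.slices.imag.sum(axis=0) * dz
    values = np.exp(1j * sigma * proj_real - proj_imag)
    return ObjectField(ComplexField2D(values, potential.voxel_size))


def load_mrc_potential(path, slice_thickness: float | None = None) -> PotentialMap:
    """Read a float (mode 2) MRC volume as a real potential map.

    Slices run along the volume's last (z) axis; the in-plane voxel size
    and the slice thickness default to the header spacings.
    """
    import gemmi

    if not os.path.exists(path):
        raise FileNotFoundError(f"MRC file not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse MRC file {path}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC mode {mode}; only mode 2 (float32)")
    spacing = ccp4.grid.spacing
    if spacing[0] <= 0 or spacing[2] <= 0:
        raise ValueError("MRC header reports a non-positive voxel size")
    if abs(spacing[0] - spacing[1]) > 1e-6 * spacing[0]:
        raise ValueError("in-plane voxel sizes must be equal")
    vol = np.array(ccp4.grid, dtype=np.float64)  # (nx, ny, nz)
    slices = np.moveaxis(vol, 2, 0)  # z first
    return PotentialMap(
        slices=slices.astype(np.complex128),
        voxel_size=float(spacing[0]),
        slice_thickness=float(slice_thickness or spacing[2]),
    )


def save_mrc_potential(path, potential: PotentialMap) -> None:
    """Write the real part of a potential map as a mode-2 MRC volume."""
    import gemmi

    slices = potential.slices.real
    nz, ny, nx = slices.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * potential.voxel_size,
            ny * potential.voxel_size,
            nz * potential.slice_thickness,
            90.0,
            90.0,
            90.0,
        )
    )
    np.asarray(grid)[:] = np.moveaxis(slices, 0, 2).astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
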