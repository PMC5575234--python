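"""Dose calibration and the detector measurement model.

The detector chain applied to each noise-free pattern I0 is

    I = F^-1[ F[ Poisson( F^-1[ F[I0] sqrt(DQE(q)) ] ) ] NTF(q) ],

i.e. the signal is shaped by the square root of the detective quantum
efficiency before shot noise and by the noise transfer function after it.
Both responses are radial tables over fractional Nyquist.  Ptychography
reconstructions normally use the identity response: with heavy detector
binning DQE is near-constant and NTF near unity, so only the simulation
side carries the K2-like curves.

Dose accounting: at dose D (e-/A^2), scan step s (pixels) and image pixel
size r_d (A), each exposure delivers D * (s * r_d)^2 electrons - the dose
share of one scan cell.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .geometry import ExperimentGeometry, ScanPlan, fftfreq_grid

__all__ = [
    "DetectorResponse",
    "DiffractionStack",
    "scale_to_dose",
    "apply_detector",
    "electrons_per_pattern_for_dose",
]


@dataclass
class DiffractionStack:
    """K diffraction patterns: noise-free intensities or detected counts.

    ``data`` has shape (K, m1, m2) and is everywhere nonnegative.  With an
    identity noise transfer function detected stacks hold integer counts;
    a non-trivial NTF correlates neighbouring pixels and yields real
    values.
    """

    data: np.ndarray
    dose: float | None = None  # e-/A^2
    electrons_per_pattern: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("diffraction data must be (K, m1, m2)")
        if np.any(self.data < -1e-9):
            raise ValueError("diffraction intensities must be nonnegative")
        self.data = np.clip(self.data, 0.0, None)

    @property
    def n_patterns(self) -> int:
        return self.data.shape[0]

    @property
    def pattern_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def pattern_sums(self) -> np.ndarray:
        return self.data.sum(axis=(1, 2))


def electrons_per_pattern_for_dose(
    dose: float, step: int, geom: ExperimentGeometry
) -> float:
    """Electrons delivered per exposure: dose x (step * r_d)^2."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    return float(dose * (step * geom.image_pixel_size) ** 2)


def scale_to_dose(
    stack: DiffractionStack,
    dose: float,
    scanplan: ScanPlan,
    geom: ExperimentGeometry,
) -> DiffractionStack:
    """Rescale a noise-free stack so the mean pattern carries the dose-
    calibrated electron count.

    All patterns share one scale factor, preserving the relative
    attenuation between scan positions.  The returned stack records the
    dose; :func:`dose_summary` reports the per-pixel bookkeeping.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    target = electrons_per_pattern_for_dose(dose, scanplan.step, geom)
    sums = stack.pattern_sums()
    mean_sum = sums.mean()
    if dose == 0 or mean_sum == 0:
        data = np.zeros_like(stack.data)
    else:
        data = stack.data * (target / mean_sum)
    return DiffractionStack(data=data, dose=dose, electrons_per_pattern=target)


def dose_summary(
    dose: float, step: int, geom: ExperimentGeometry
) -> dict[str, float]:
    """Dose bookkeeping: electrons per pattern, per detector pixel and per
    image pixel for the given configuration."""
    epp = electrons_per_pattern_for_dose(dose, step, geom)
    n_det = geom.n_detector_pixels**2
    return {
        "electrons_per_pattern": epp,
        "electrons_per_detector_pixel": epp / n_det,
        "electrons_per_image_pixel": dose * geom.image_pixel_size**2,
    }


@dataclass
class DetectorResponse:
    """Radial DQE and NTF tables over fractional Nyquist frequency.

    Both tables are (frequency, value) pairs with values in [0, 1] and a
    strictly positive response at zero frequency; they must extend to the
    Nyquist frequency (fraction 1).  Beyond the last tabulated point the
    final value is held (the Fourier-grid corners lie beyond Nyquist).
    """

    dqe_freq: np.ndarray
    dqe: np.ndarray
    ntf_freq: np.ndarray
    ntf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dqe", "ntf"):
            freq = np.asarray(getattr(self, f"{name}_freq"), dtype=float)
            val = np.asarray(getattr(self, name), dtype=float)
            if freq.ndim != 1 or freq.shape != val.shape:
                raise ValueError(f"{name} table must be two equal 1D columns")
            if np.any(val < 0) or np.any(val > 1):
                raise ValueError(f"{name.upper()} values must lie in [0, 1]")
            if val[np.argmin(freq)] <= 0:
                raise ValueError(f"{name.upper()}(0) must be positive")
            if freq.max() < 1.0 - 1e-9:
                raise ValueError(
                    f"{name.upper()} table must cover the Nyquist frequency"
                )
            setattr(self, f"{name}_freq", freq)
            setattr(self, name, val)

    @classmethod
    def identity(cls) -> "DetectorResponse":
        freq = np.array([0.0, 1.0])
        return cls(freq, np.ones(2), freq.copy(), np.ones(2))

    @classmethod
    def from_csv(cls, dqe_path, ntf_path) -> "DetectorResponse":
        """Two-column CSV files (fractional Nyquist, value), '#' comments."""
        dqe = np.loadtxt(dqe_path, delimiter=",", comments="#")
        ntf = np.loadtxt(ntf_path, delimiter=",", comments="#")
        return cls(dqe[:, 0], dqe[:, 1], ntf[:, 0], ntf[:, 1])

    @classmethod
    def k2_like(cls) -> "DetectorResponse":
        """Bundled smooth parametric curves shaped like a counting direct
        detector (high DQE at low frequency, decaying toward Nyquist)."""
        data = importlib.resources.files("cryoptycho.data")
        with importlib.resources.as_file(data / "k2_dqe.csv") as p_dqe, \
                importlib.resources.as_file(data / "k2_ntf.csv") as p_ntf:
            return cls.from_csv(p_dqe, p_ntf)

    def _radial(self, table_freq, table_val, shape) -> np.ndarray:
        q = fftfreq_grid(shape, 1.0) / 0.5  # fractional Nyquist
        order = np.argsort(table_freq)
        return np.interp(q, table_freq[order], table_val[order])

    def dqe_on(self, shape: tuple[int, int]) -> np.ndarray:
        return self._radial(self.dqe_freq, self.dqe, shape)

    def ntf_on(self, shape: tuple[int, int]) -> np.ndarray:
        return self._radial(self.ntf_freq, self.ntf, shape)


def apply_detector(
    stack: DiffractionStack,
    response: DetectorResponse,
    seed: int,
) -> DiffractionStack:
    """Detect a noise-free stack: sqrt(DQE) shaping, Poisson sampling, NTF.

    Each pattern draws from an independent stream derived from
    ``(seed, pattern index)``, so detection is reproducible per pattern
    regardless of stack order.
    """
    shape = stack.pattern_shape
    sqrt_dqe = np.sqrt(response.dqe_on(shape))
    ntf = response.ntf_on(shape)
    ntf_is_identity = np.allclose(ntf, 1.0)
    dqe_is_identity = np.allclose(sqrt_dqe, 1.0)
    out = np.empty_like(stack.data)
    for i in range(stack.n_patterns):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        i0 = stack.data[i]
        if not dqe_is_identity:
            i0 = np.fft.ifft2(np.fft.fft2(i0) * sqrt_dqe).real
            i0 = np.clip(i0, 0.0, None)  # sqrt(DQE) ringing can undershoot
        counts = rng.poisson(i0).astype(np.float64)
        if not ntf_is_identity:
            counts = np.fft.ifft2(np.fft.fft2(counts) * ntf).real
            counts = np.clip(counts, 0.0, None)
        out[i] = counts
    return DiffractionStack(
        data=out, dose=stack.dose, electrons_per_pattern=stack.electrons_per_pattern
    )
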