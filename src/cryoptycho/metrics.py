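"""Resolution and fidelity metrics.

* Fourier ring correlation (FRC) between two images, with the 1-bit and
  1/2-bit information thresholds of van Heel & Schatz; the resolution is
  the half-period at the first threshold crossing.
* Spatial-frequency-resolved SNR in dB:
  10 log10( sum_ring |F[T]|^2 / sum_ring |F[T] - F[T_model]|^2 ), after
  aligning the model's global complex scale (the metric is otherwise
  gauge-dependent).
* NRMSE: the gauge-aligned relative L2 error
  min_c ||truth - c model|| / ||truth||.
* Averaging of independent reconstructions with global-phase alignment,
  plus the split-half FRC of the two half-ensemble averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ComplexField2D, fft2

__all__ = [
    "FRCCurve",
    "SNRCurve",
    "frc",
    "resolution_from_frc",
    "snr_db",
    "nrmse",
    "align_global_scale",
    "average_reconstructions",
]

_DB_CAP = 120.0


def _as_values(a) -> np.ndarray:
    if isinstance(a, ComplexField2D):
        return a.values
    if hasattr(a, "field"):  # ObjectField / ProbeField
        return a.field.values
    return np.asarray(a)


def _pixel_size(a, default: float = 1.0) -> float:
    if isinstance(a, ComplexField2D):
        return a.pixel_size
    if hasattr(a, "field"):
        return a.field.pixel_size
    return default


@dataclass
class FRCCurve:
    """Per-ring correlation with sample counts and information thresholds."""

    frequency: np.ndarray  # ring centres, 1/A
    correlation: np.ndarray
    n_samples: np.ndarray
    threshold_one_bit: np.ndarray
    threshold_half_bit: np.ndarray
    pixel_size: float

    @property
    def nyquist(self) -> float:
        return 0.5 / self.pixel_size


@dataclass
class SNRCurve:
    frequency: np.ndarray  # 1/A
    snr_db: np.ndarray


def _ring_index(shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    r = np.hypot(fy[:, None], fx[None, :])
    idx = np.rint(r).astype(int)
    n_rings = min(shape) // 2 + 1
    return idx, n_rings


def _one_bit_threshold(n: np.ndarray) -> np.ndarray:
    rn = np.sqrt(np.maximum(n, 1.0))
    return (0.5 + 2.4142 / rn) / (1.5 + 1.4142 / rn)


def _half_bit_threshold(n: np.ndarray) -> np.ndarray:
    rn = np.sqrt(np.maximum(n, 1.0))
    return (0.2071 + 1.9102 / rn) / (1.2071 + 0.9102 / rn)


def frc(a, b, ring_width: float = 1.0) -> FRCCurve:
    """Fourier ring correlation of two equally sampled images.

    Per ring of width ``ring_width`` reciprocal pixels:
    Re(sum F_a conj(F_b)) / sqrt(sum |F_a|^2 sum |F_b|^2); symmetric in
    its arguments.
    """
    av, bv = _as_values(a), _as_values(b)
    if av.shape != bv.shape:
        raise ValueError("FRC requires equally shaped images")
    px_a, px_b = _pixel_size(a), _pixel_size(b)
    if not np.isclose(px_a, px_b, rtol=1e-9):
        raise ValueError("FRC requires equal pixel sizes")
    fa, fb = fft2(av), fft2(bv)
    idx, n_rings = _ring_index(av.shape)
    idx_c = np.rint(idx / ring_width).astype(int)
    n_rings = int(np.rint((n_rings - 1) / ring_width)) + 1
    flat = idx_c.ravel()
    sel = flat < n_rings
    cross = np.bincount(
        flat[sel], weights=np.real(fa * np.conj(fb)).ravel()[sel], minlength=n_rings
    )
    pa = np.bincount(
        flat[sel], weights=(np.abs(fa) ** 2).ravel()[sel], minlength=n_rings
    )
    pb = np.bincount(
        flat[sel], weights=(np.abs(fb) ** 2).ravel()[sel], minlength=n_rings
    )
    n = np.bincount(flat[sel], minlength=n_rings).astype(float)
    denom = np.sqrt(pa * pb)
    corr = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    freq = np.arange(n_rings) * ring_width / (av.shape[0] * px_a)
    return FRCCurve(
        frequency=freq,
        correlation=corr,
        n_samples=np.maximum(n, 1.0),
        threshold_one_bit=_one_bit_threshold(n),
        threshold_half_bit=_half_bit_threshold(n),
        pixel_size=px_a,
    )


def resolution_from_frc(
    curve: FRCCurve, criterion: str = "half_bit", fixed_value: float = 0.143
) -> tuple[float, bool]:
    """Half-period resolution (A) at the first crossing of the threshold.

    Returns ``(resolution, crossed)``; without a crossing the
    diffraction-limit half-period (the pixel size) is returned with
    ``crossed=False``.  The crossing frequency is linearly interpolated
    between rings.
    """
    if curve.frequency.size == 0:
        raise ValueError("empty FRC curve")
    if criterion == "one_bit":
        thr = curve.threshold_one_bit
    elif criterion == "half_bit":
        thr = curve.threshold_half_bit
    elif criterion == "fixed_value":
        thr = np.full_like(curve.correlation, fixed_value)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    diff = curve.correlation - thr
    # Skip the DC ring; find the first sign change.
    for k in range(1, len(diff) - 1):
        if diff[k] >= 0 and diff[k + 1] < 0:
            f0, f1 = curve.frequency[k], curve.frequency[k + 1]
            w = diff[k] / (diff[k] - diff[k + 1])
            f_cross = f0 + w * (f1 - f0)
            return float(0.5 / f_cross), True
        if k == 1 and diff[k] < 0:
            # Below threshold from the start: resolution at the first ring.
            return float(0.5 / curve.frequency[1]), True
    return float(curve.pixel_size), False


def align_global_scale(truth: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Model scaled by the complex scalar minimizing ||truth - c model||."""
    denom = np.vdot(model, model)
    if denom == 0:
        return model
    c = np.vdot(model, truth) / denom
    return c * model


def align_global_phase(ref: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate v by the global phase best matching ref (amplitude kept).

    Unlike the full complex-scale fit this is unbiased for noisy fields,
    so it is the alignment used when averaging reconstructions (whose
    only true ambiguity is the global phase)."""
    inner = np.vdot(v, ref)
    if inner == 0:
        return v
    return v * np.exp(1j * np.angle(inner))


def snr_db(truth, model, ring_width: float = 1.0) -> SNRCurve:
    """Per-ring power SNR of a model image against the truth, in dB.

    The model's global complex scale is aligned first; values are capped
    at +/- 120 dB.
    """
    tv, mv = _as_values(truth), _as_values(model)
    if tv.shape != mv.shape:
        raise ValueError("SNR requires equally shaped images")
    px = _pixel_size(truth)
    mv = align_global_scale(tv, mv)
    ft, fm = fft2(tv), fft2(mv)
    idx, n_rings = _ring_index(tv.shape)
    idx_c = np.rint(idx / ring_width).astype(int)
    n_rings = int(np.rint((n_rings - 1) / ring_width)) + 1
    flat = idx_c.ravel()
    sel = flat < n_rings
    sig = np.bincount(
        flat[sel], weights=(np.abs(ft) ** 2).ravel()[sel], minlength=n_rings
    )
    err = np.bincount(
        flat[sel], weights=(np.abs(ft - fm) ** 2).ravel()[sel], minlength=n_rings
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(err > 0, sig / np.where(err > 0, err, 1.0), np.inf)
        vals = 10.0 * np.log10(ratio)
    vals = np.where(sig == 0, 0.0, vals)
    vals = np.clip(np.nan_to_num(vals, posinf=_DB_CAP, neginf=-_DB_CAP),
                   -_DB_CAP, _DB_CAP)
    freq = np.arange(n_rings) * ring_width / (tv.shape[0] * px)
    return SNRCurve(frequency=freq, snr_db=vals)


def nrmse(truth, model) -> float:
    """Gauge-aligned relative L2 error min_c ||truth - c model||/||truth||."""
    tv, mv = _as_values(truth), _as_values(model)
    if tv.shape != mv.shape:
        raise ValueError("NRMSE requires equally shaped arrays")
    t_norm = np.linalg.norm(tv)
    if t_norm == 0:
        raise ValueError("NRMSE is undefined for a zero truth")
    aligned = align_global_scale(tv, mv)
    return float(np.linalg.norm(tv - aligned) / t_norm)


def average_reconstructions(fields: list) -> tuple[ComplexField2D, FRCCurve]:
    """Align (global complex scalar, to the first field) and average.

    Also returns the split-half FRC between the averages of the first and
    second halves of the list — the resolution estimate used when pooling
    independent low-dose reconstructions.
    """
    if len(fields) < 2:
        raise ValueError("averaging needs at least two reconstructions")
    ref = _as_values(fields[0])
    px = _pixel_size(fields[0])
    values = [ref.astype(np.complex128)]
    for f in fields[1:]:
        v = _as_values(f)
        if v.shape != ref.shape:
            raise ValueError("all reconstructions must share one shape")
        values.append(v.astype(np.complex128))
    # Two-pass global-phase alignment: the first field is a noisy
    # reference, so align everything to it once, then to the provisional
    # mean.
    stack = np.stack([values[0]] + [align_global_phase(ref, v) for v in values[1:]])
    provisional = stack.mean(axis=0)
    stack = np.stack([align_global_phase(provisional, v) for v in values])
    mean = stack.mean(axis=0)
    half = len(values) // 2
    avg_a = stack[:half].mean(axis=0)
    avg_b = stack[half:].mean(axis=0)
    curve = frc(
        ComplexField2D(avg_a, px), ComplexField2D(avg_b, px)
    )
    return ComplexField2D(mean, px), curve
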