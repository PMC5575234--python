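"""Plug-in denoisers acting on a domain-colored complex field.

The sparse prior needs a denoised reference T_sparse.  The complex
transmission is mapped to three real channels by domain coloring —
phase -> hue, amplitude -> value (normalized by its maximum),
saturation = 1 — each channel is denoised independently, and the result
is mapped back to a complex field.  The identity mapping round-trips
exactly.

The bundled default is wavelet shrinkage with a biorthogonal spline
wavelet (collaborative-filtering denoisers such as an external BM3D can
be registered as plug-ins with the same channel signature).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from skimage.restoration import denoise_wavelet

__all__ = [
    "domain_color",
    "domain_uncolor",
    "denoise_complex",
    "register_denoiser",
    "available_denoisers",
]

# A channel denoiser maps one 2D float array (range roughly [0, 1]) to
# another of the same shape.
ChannelDenoiser = Callable[[np.ndarray], np.ndarray]


def domain_color(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Complex field -> (hue, saturation, value) channels + amplitude scale.

    hue = phase / 2 pi in [0, 1), saturation = 1, value = |T| / max |T|.
    """
    amp = np.abs(values)
    amp_max = float(amp.max())
    scale = amp_max if amp_max > 0 else 1.0
    # Centre the principal phase branch at hue 0.5 so that weak-phase
    # fields do not straddle the periodic wrap at hue 0.
    hue = (np.angle(values) + np.pi) / (2.0 * np.pi)
    sat = np.ones_like(hue)
    val = amp / scale
    return hue, sat, val, scale


def domain_uncolor(
    hue: np.ndarray, sat: np.ndarray, val: np.ndarray, scale: float
) -> np.ndarray:
    """Inverse of :func:`domain_color` (saturation is carried but unused)."""
    return (val * scale) * np.exp(1j * (2.0 * np.pi * hue - np.pi))


def _wavelet_channel(channel: np.ndarray) -> np.ndarray:
    # BayesShrink soft thresholding with a biorthogonal spline wavelet.
    # The wavelet is deliberately non-orthogonal (best shrinkage quality
    # at high noise); skimage flags that choice, so silence its warning.
    span = channel.max() - channel.min()
    if span == 0:
        return channel.copy()
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*orthogonal wavelet.*", category=UserWarning
        )
        return denoise_wavelet(
            channel, wavelet="bior2.2", mode="soft", method="BayesShrink",
            rescale_sigma=True,
        )


_REGISTRY: dict[str, ChannelDenoiser] = {
    "identity": lambda channel: channel.copy(),
    "wavelet": _wavelet_channel,
}


def register_denoiser(name: str, fn: ChannelDenoiser) -> None:
    """Register an external channel denoiser (e.g. a full BM3D binding)."""
    _REGISTRY[name] = fn


def available_denoisers() -> list[str]:
    return sorted(_REGISTRY)


def denoise_complex(values: np.ndarray, denoiser_id: str = "wavelet") -> np.ndarray:
    """Denoise a complex field channel-wise through domain coloring."""
    try:
        fn = _REGISTRY[denoiser_id]
    except KeyError:
        raise ValueError(
            f"unknown denoiser {denoiser_id!r}; available: {available_denoisers()}"
        ) from None
    hue, sat, val, scale = domain_color(values)
    return domain_uncolor(fn(hue), fn(sat), fn(val), scale)
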