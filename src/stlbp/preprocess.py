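"""Preprocessing operators: adaptive Wiener denoising, Gaussian pyramid,
temporal length normalization.

The Wiener filter is the classical local-adaptive estimator: with local mean
``mu`` and local variance ``v`` over a sliding window and noise variance
``nv``,

    out = mu + max(0, v - nv) / max(v, nv) * (pixel - mu)

so flat regions collapse to their mean while high-variance structure is kept.
When ``noise_variance`` is ``None`` the noise power is estimated as the mean
of the local variances (the standard automatic rule).

The Gaussian pyramid uses the canonical separable 5-tap binomial kernel
[1, 4, 6, 4, 1]/16 with reflective borders and factor-2 downsampling by
even-index sampling (level k+1 has ceil(n/2) samples per axis).  Every level
is then resized to a common target with bilinear interpolation so descriptor
block grids stay comparable across levels.

``temporal_resample`` normalizes a clip to a fixed frame count by per-voxel
linear interpolation along t — a plain stand-in for model-based temporal
interpolation, preserving the one property the descriptor pipeline needs
(fixed length) without overshooting per-pixel intensity bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.transform import resize

__all__ = [
    "WienerConfig",
    "PyramidConfig",
    "wiener_filter",
    "gaussian_pyramid",
    "pyramid_video",
    "temporal_resample",
]

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class WienerConfig:
    """Adaptive Wiener filter settings.

    ``window``: odd (rows, cols) of the local-statistics window.
    ``noise_variance``: fixed noise power, or ``None`` for the automatic
    mean-of-local-variances estimate.
    """

    window: tuple[int, int] = (3, 3)
    noise_variance: float | None = None

    def __post_init__(self) -> None:
        r, c = self.window
        if r < 1 or c < 1 or r % 2 == 0 or c % 2 == 0:
            raise ValueError(f"window dims must be odd positive, got {self.window}")
        if self.noise_variance is not None and self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


@dataclass(frozen=True)
class PyramidConfig:
    """Gaussian pyramid settings: level count and common output size."""

    levels: int = 4
    resize_to: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.resize_to is not None and min(self.resize_to) < 1:
            raise ValueError(f"resize target must be positive, got {self.resize_to}")


def wiener_filter(img: np.ndarray, cfg: WienerConfig = WienerConfig()) -> np.ndarray:
    """Local adaptive Wiener estimate of a 2-D image; same shape as input."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    if img.shape[0] < cfg.window[0] or img.shape[1] < cfg.window[1]:
        raise ValueError(
            f"window {cfg.window} larger than image of shape {img.shape}"
        )
    # local statistics with reflective borders, so flat inputs stay exactly
    # flat at the edges (zero-padded moving averages would not)
    mean = ndimage.uniform_filter(img, size=cfg.window, mode="reflect")
    sq_mean = ndimage.uniform_filter(img * img, size=cfg.window, mode="reflect")
    var = np.maximum(sq_mean - mean * mean, 0.0)
    noise = float(var.mean()) if cfg.noise_variance is None else cfg.noise_variance
    denom = np.maximum(np.maximum(var, noise), 1e-300)
    gain = np.maximum(var - noise, 0.0) / denom
    return mean + gain * (img - mean)


def _pyrdown(img: np.ndarray) -> np.ndarray:
    """Binomial smoothing (reflective borders) then even-index decimation."""
    sm = signal.sepfir2d(img, _BINOMIAL5, _BINOMIAL5)
    return sm[::2, ::2]


def gaussian_pyramid(img: np.ndarray, cfg: PyramidConfig) -> list[np.ndarray]:
    """Multi-level Gaussian pyramid of a 2-D image.

    Level 0 is the input; level k+1 is level k smoothed and downsampled by
    2.  When ``cfg.resize_to`` is set, every level is bilinearly resized to
    that common (height, width) before being returned.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    levels = [img]
    for _ in range(cfg.levels - 1):
        prev = levels[-1]
        if min(prev.shape) < 2:
            raise ValueError(
                f"image exhausted at shape {prev.shape} before reaching "
                f"{cfg.levels} pyramid levels"
            )
        levels.append(_pyrdown(prev))
    if cfg.resize_to is not None:
        levels = [
            resize(lv, cfg.resize_to, order=1, mode="reflect", anti_aliasing=False)
            for lv in levels
        ]
    return levels


def pyramid_video(video: np.ndarray, cfg: PyramidConfig) -> list[np.ndarray]:
    """Per-frame Gaussian pyramid of a (h, w, l) volume.

    Returns one volume per level, all of shape ``resize_to + (l,)`` when a
    resize target is set (required so levels stack into volumes when no
    target is given and shapes shrink).
    """
    video = np.asarray(video, dtype=float)
    if video.ndim != 3:
        raise ValueError(f"expected (h, w, l) volume, got shape {video.shape}")
    per_frame = [gaussian_pyramid(video[:, :, t], cfg) for t in range(video.shape[2])]
    return [
        np.stack([fr[k] for fr in per_frame], axis=2) for k in range(cfg.levels)
    ]


def temporal_resample(video: np.ndarray, target_length: int) -> np.ndarray:
    """Linearly resample a volume along t to ``target_length`` frames.

    Sample positions are uniform over [0, length-1]; the first and last
    frames are preserved exactly, and ``target_length == length`` returns an
    identical volume.
    """
    video = np.asarray(video, dtype=float)
    if video.ndim != 3:
        raise ValueError(f"expected (h, w, l) volume, got shape {video.shape}")
    l = video.shape[2]
    if l < 2:
        raise ValueError(f"need at least 2 frames to resample, got {l}")
    if target_length < 2:
        raise ValueError(f"target_length must be >= 2, got {target_length}")
    pos = np.linspace(0.0, l - 1.0, target_length)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, l - 1)
    frac = pos - lo
    return video[:, :, lo] * (1.0 - frac) + video[:, :, hi] * frac
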