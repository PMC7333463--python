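"""Frame preprocessing for neuron detection.

Denoises (Gaussian + median, small 3x3 kernels so small neurons are not
distorted), suppresses the diffuse background glow from out-of-focus deep
neurons by subtracting a wide spatial low-pass estimate, and stretches the
contrast to the full 8-bit range.  The preprocessed frame feeds *only* the
detector; signal extraction always reads the unpreprocessed motion-corrected
frame, so preprocessing cannot bias the extracted traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class PreprocConfig:
    gaussian_kernel: int = 3
    median_kernel: int = 3
    background_kernel: int = 31

    def __post_init__(self):
        for k in (self.gaussian_kernel, self.median_kernel,
                  self.background_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")


def normalize_minmax(frame: np.ndarray) -> np.ndarray:
    """(I - I_min) * 255 / (I_max - I_min) per pixel; a constant frame maps
    to all zeros (division-by-zero guard)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    lo = frame.min()
    hi = frame.max()
    if hi == lo:
        return np.zeros_like(frame)
    # ratio-first evaluation keeps the endpoints exactly at 0 and 255
    return (frame - lo) / (hi - lo) * 255.0


def _gaussian_sigma(kernel: int) -> float:
    # sigma consistent with a k x k truncated Gaussian kernel
    return 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8


def preprocess(frame: np.ndarray, config: PreprocConfig | None = None
               ) -> np.ndarray:
    """Gaussian smooth -> median filter -> background subtraction (clamped
    at 0) -> min-max normalization to [0, 255]."""
    config = config if config is not None else PreprocConfig()
    frame = np.asarray(frame, dtype=np.float64)
    if min(frame.shape) < config.background_kernel // 2 + 1:
        raise ValueError("frame smaller than the background kernel")
    r = (config.gaussian_kernel - 1) // 2
    out = ndimage.gaussian_filter(frame, _gaussian_sigma(config.gaussian_kernel),
                                  radius=r, mode="nearest")
    out = ndimage.median_filter(out, size=config.median_kernel,
                                mode="nearest")
    bg = ndimage.gaussian_filter(
        out, _gaussian_sigma(config.background_kernel),
        radius=(config.background_kernel - 1) // 2, mode="nearest")
    out = np.clip(out - bg, 0.0, None)
    return normalize_minmax(out)
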