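"""Per-neuron relative-intensity (dF/F) trace extraction.

For each detected neuron the region of interest is the circle from the
detection matrix.  The per-frame signal is beta[i] = (F_i - F0_i)/F0_i,
where F_i is the mean pixel value over the circle in the motion-corrected
frame and F0_i is a rolling baseline: the mean of the ROI means over the W
frames immediately preceding the current one, excluding frames whose ROI
mean exceeded 3x the window's running median (so calcium transients do not
inflate the baseline).  Below a small baseline floor the signal is defined
as 0 (divide-by-zero guard, and the natural value for a dark background).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np


def roi_mean(frame: np.ndarray, x: float, y: float, radius: float) -> float:
    """Mean intensity over pixels whose center lies within the circle
    (inclusive boundary).  A degenerate circle covering no pixel center
    falls back to the nearest pixel."""
    h, w = frame.shape
    if x + radius < 0 or x - radius > w - 1 or y + radius < 0 \
            or y - radius > h - 1:
        raise ValueError("ROI circle lies fully outside the frame")
    r = max(radius, 0.0)
    y0 = max(int(np.floor(y - r)), 0)
    y1 = min(int(np.ceil(y + r)) + 1, h)
    x0 = max(int(np.floor(x - r)), 0)
    x1 = min(int(np.ceil(x + r)) + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    if not inside.any():
        iy = int(np.clip(round(y), 0, h - 1))
        ix = int(np.clip(round(x), 0, w - 1))
        return float(frame[iy, ix])
    return float(np.asarray(frame, dtype=np.float64)[y0:y1, x0:x1][inside].mean())


@dataclass
class BaselineConfig:
    window: int = 50             # W: frames feeding the rolling baseline
    spike_exclude_factor: float = 3.0
    f0_floor: float = 1.0        # below this baseline, beta is defined as 0


@dataclass
class SignalExtractor:
    """Stateful dF/F extractor over a fixed-order neuron set.

    Neuron identity follows the detection matrix row order (training
    discovery order); the matrix may grow between firings during training,
    in which case new columns join with empty baselines (their signal is 0
    until their first activity fills the window).
    """
    config: BaselineConfig = field(default_factory=BaselineConfig)
    _windows: list[collections.deque] = field(default_factory=list)

    def extract(self, frame: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """One firing: returns beta, one entry per detection-matrix row."""
        delta = np.asarray(delta, dtype=np.float64).reshape(-1, 3)
        n = delta.shape[0]
        while len(self._windows) < n:
            self._windows.append(
                collections.deque(maxlen=self.config.window))
        beta = np.zeros(n, dtype=np.float64)
        for i in range(n):
            x, y, r = delta[i]
            f = roi_mean(frame, x, y, r)
            win = self._windows[i]
            if win:
                vals = np.asarray(win, dtype=np.float64)
                med = np.median(vals)
                keep = vals <= self.config.spike_exclude_factor * max(med, 1e-12)
                f0 = vals[keep].mean() if keep.any() else vals.mean()
                if f0 > self.config.f0_floor:
                    beta[i] = (f - f0) / f0
            win.append(f)
        return beta


def extract_table(frames, delta: np.ndarray,
                  config: BaselineConfig | None = None) -> np.ndarray:
    """Convenience: run the extractor over an iterable of frames with a
    fixed detection matrix; returns an (L, nu) signal table."""
    ex = SignalExtractor(config or BaselineConfig())
    rows = [ex.extract(f, delta) for f in frames]
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), -1)


def dff_trace(roi_means: np.ndarray, config: BaselineConfig | None = None,
              spike_exclusion: bool = True) -> np.ndarray:
    """dF/F for a precomputed ROI-mean time series (vectorizable helper for
    evaluation-side bulk computation; same baseline rule as the extractor,
    with the spike-exclusion step optional)."""
    cfg = config or BaselineConfig()
    x = np.asarray(roi_means, dtype=np.float64)
    out = np.zeros_like(x)
    win: collections.deque = collections.deque(maxlen=cfg.window)
    for t, f in enumerate(x):
        if win:
            vals = np.asarray(win)
            if spike_exclusion:
                med = np.median(vals)
                keep = vals <= cfg.spike_exclude_factor * max(med, 1e-12)
                f0 = vals[keep].mean() if keep.any() else vals.mean()
            else:
                f0 = vals.mean()
            if f0 > cfg.f0_floor:
                out[t] = (f - f0) / f0
        win.append(f)
    return out


def dff_table_plain(roi_means: np.ndarray, window: int = 50,
                    f0_floor: float = 1.0) -> np.ndarray:
    """Vectorized plain rolling-mean dF/F over many series at once.

    ``roi_means`` is (T, k); the baseline at frame t is the mean over the
    preceding ``window`` frames (no spike exclusion -- used for the random
    null regions, which contain no transients)."""
    x = np.asarray(roi_means, dtype=np.float64)
    T = x.shape[0]
    cs = np.cumsum(np.vstack([np.zeros((1,) + x.shape[1:]), x]), axis=0)
    out = np.zeros_like(x)
    t = np.arange(T)
    lo = np.maximum(t - window, 0)
    n = t - lo
    valid = n > 0
    f0 = np.zeros_like(x)
    f0[valid] = (cs[t[valid]] - cs[lo[valid]]) / n[valid, None]
    mask = valid[:, None] & (f0 > f0_floor)
    out[mask] = (x[mask] - f0[mask]) / f0[mask]
    return out
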