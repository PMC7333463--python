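"""Quantitative evaluation against simulator ground truth.

Covers the three surfaces the pipeline is scored on: motion-correction
accuracy (mean/max absolute x, y displacement and rotation errors over
successfully corrected frames, plus the failure rate), detection accuracy
(pixel-level precision/recall/F1 between matched detected circles and
ground-truth masks, and the matched-active detection rate), and the
signal-to-noise ratio of extracted traces against a random-region null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .signals import dff_table_plain


# ---------------------------------------------------------------------------
# motion-correction error
# ---------------------------------------------------------------------------

@dataclass
class MotionErrorReport:
    m_x: np.ndarray              # per-frame |dx| over non-failed frames
    m_y: np.ndarray
    m_rot: np.ndarray            # degrees
    rate_fail: float             # percent
    n_frames: int

    @property
    def mean_x(self) -> float:
        return float(self.m_x.mean()) if self.m_x.size else float("nan")

    @property
    def mean_y(self) -> float:
        return float(self.m_y.mean()) if self.m_y.size else float("nan")

    @property
    def mean_rot(self) -> float:
        return float(self.m_rot.mean()) if self.m_rot.size else float("nan")

    @property
    def max_x(self) -> float:
        return float(self.m_x.max()) if self.m_x.size else float("nan")

    @property
    def max_y(self) -> float:
        return float(self.m_y.max()) if self.m_y.size else float("nan")

    @property
    def max_rot(self) -> float:
        return float(self.m_rot.max()) if self.m_rot.size else float("nan")

    def summary(self) -> str:
        return (f"mean(Mx)={self.mean_x:.4f} max(Mx)={self.max_x:.4f} "
                f"mean(My)={self.mean_y:.4f} max(My)={self.max_y:.4f} "
                f"mean(Mrot)={self.mean_rot:.6f} max(Mrot)={self.max_rot:.4f} "
                f"Rfail(%)={self.rate_fail:.2f}")


def motion_error(estimated_track: np.ndarray, true_track: np.ndarray,
                 statuses: list[str] | np.ndarray) -> MotionErrorReport:
    """Per-frame absolute displacement/angle errors over non-failed frames.

    Failed frames are excluded from the error averages (they were not
    corrected) and counted into the failure rate.
    """
    est = np.asarray(estimated_track, dtype=np.float64).reshape(-1, 3)
    true = np.asarray(true_track, dtype=np.float64).reshape(-1, 3)
    statuses = np.asarray(statuses)
    if not est.shape[0] == true.shape[0] == statuses.shape[0]:
        raise ValueError("track/status length mismatch")
    ok = statuses != "failed"
    diff = np.abs(est[ok] - true[ok])
    rate_fail = 100.0 * float((~ok).sum()) / len(ok) if len(ok) else 0.0
    return MotionErrorReport(diff[:, 0], diff[:, 1], diff[:, 2], rate_fail,
                             len(ok))


# ---------------------------------------------------------------------------
# detection accuracy
# ---------------------------------------------------------------------------

@dataclass
class DetectionScore:
    precision: float
    recall: float
    f1: float
    matches: list[tuple[int, int]]       # (detection row, mask index)
    detection_rate: float                # matched active / active, percent
    n_detected: int
    n_truth: int

    def summary(self) -> str:
        return (f"precision={self.precision:.4f} recall={self.recall:.4f} "
                f"F1={self.f1:.4f} detection_rate(%)={self.detection_rate:.1f} "
                f"matched={len(self.matches)}/{self.n_truth}")


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2uv/(u+v); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _circle_pixels(x: float, y: float, r: float,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    y0 = max(int(np.floor(y - r)), 0)
    y1 = min(int(np.ceil(y + r)) + 1, h)
    x0 = max(int(np.floor(x - r)), 0)
    x1 = min(int(np.ceil(x + r)) + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    return yy[inside], xx[inside]


def match_detections(delta: np.ndarray, masks: np.ndarray
                     ) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected circles to truth masks.

    A detection is a candidate for a mask when its center lies inside the
    mask; candidates are consumed nearest-(center-to-centroid)-first.
    """
    delta = np.asarray(delta, dtype=np.float64).reshape(-1, 3)
    n_masks = masks.shape[0]
    centroids = np.zeros((n_masks, 2))
    for j in range(n_masks):
        ys, xs = np.nonzero(masks[j])
        centroids[j] = (xs.mean(), ys.mean())
    pairs = []
    h, w = masks.shape[1:]
    for i, (x, y, _r) in enumerate(delta):
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < h and 0 <= ix < w):
            continue
        for j in range(n_masks):
            if masks[j, iy, ix]:
                dist = np.hypot(x - centroids[j, 0], y - centroids[j, 1])
                pairs.append((dist, i, j))
    pairs.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    matches = []
    for _dist, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matches.append((i, j))
    return matches


def detection_score(delta: np.ndarray, masks: np.ndarray,
                    active: np.ndarray | None = None,
                    per_neuron: bool = False) -> DetectionScore:
    """Pixel-level precision/recall/F1 of detected circles vs truth masks.

    Precision pools matched pixels over all detected circles; recall pools
    them over all truth masks (``per_neuron=True`` averages the per-pair
    ratios instead).  ``active`` restricts the detection-rate denominator to
    the truly active neurons.
    """
    delta = np.asarray(delta, dtype=np.float64).reshape(-1, 3)
    matches = match_detections(delta, masks)
    shape = masks.shape[1:]
    inter_total = 0.0
    circle_total = 0.0
    mask_total = float(masks.sum())
    per_u, per_v = [], []
    for i, j in matches:
        x, y, r = delta[i]
        ys, xs = _circle_pixels(x, y, r, shape)
        inter = float(masks[j, ys, xs].sum())
        inter_total += inter
        if per_neuron:
            per_u.append(inter / max(len(ys), 1))
            per_v.append(inter / max(float(masks[j].sum()), 1.0))
    for i in range(delta.shape[0]):
        x, y, r = delta[i]
        ys, xs = _circle_pixels(x, y, r, shape)
        circle_total += len(ys)
    if per_neuron:
        u = float(np.mean(per_u)) if per_u else 0.0
        v = float(np.mean(per_v)) if per_v else 0.0
    else:
        u = inter_total / circle_total if circle_total else 0.0
        v = inter_total / mask_total if mask_total else 0.0
    if active is None:
        active = np.arange(masks.shape[0])
    active = np.asarray(active)
    matched_active = sum(1 for _i, j in matches if j in set(active.tolist()))
    rate = 100.0 * matched_active / len(active) if len(active) else 0.0
    return DetectionScore(u, v, f1_score(u, v), matches, rate,
                          delta.shape[0], masks.shape[0])


# ---------------------------------------------------------------------------
# signal-to-noise ratio
# ---------------------------------------------------------------------------

@dataclass
class SNRReport:
    r_s: float
    r_n: float
    snr_db: float
    n_neurons: int
    n_rep: int

    def summary(self) -> str:
        return (f"Rs={self.r_s:.4f} Rn={self.r_n:.6g} "
                f"SNR(dB)={self.snr_db:.2f}")


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (T, k) arrays."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    out = np.zeros(a.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def snr(signals: np.ndarray, spikes: np.ndarray, frames: np.ndarray,
        masks: np.ndarray, radii: np.ndarray, n_rep: int = 1000,
        rng: np.random.Generator | None = None,
        max_mask_overlap: float = 0.0, baseline_window: int = 50
        ) -> SNRReport:
    """Trace/spike-train SNR against a random-region null.

    R_s is the mean Pearson correlation between each neuron's extracted
    dF/F trace (``signals``: (T, nu)) and its ground-truth spike train.
    For the null, each repetition redraws for every neuron a random circle
    of that neuron's radius (overlapping any truth mask in at most
    ``max_mask_overlap`` of its pixels -- 0 by default: spike trains are
    correlated across the simulated network, so a region carrying even a
    sliver of another neuron's mask is not a genuine null), computes the
    region's dF/F and its correlation with that neuron's spike train; R_n
    is the grand mean over ``n_rep`` repetitions.  SNR = 10*log10(R_s/R_n).
    """
    rng = rng if rng is not None else np.random.default_rng()
    signals = np.asarray(signals, dtype=np.float64)
    spikes01 = np.asarray(spikes, dtype=np.float64).T  # (T, nu)
    if signals.shape != spikes01.shape:
        raise ValueError("signals and spike trains misaligned")
    T, nu = signals.shape
    r_s = float(_pearson_columns(signals, spikes01).mean())

    h, w = frames.shape[1:]
    union = masks.any(axis=0)
    r_sum = 0.0
    r_count = 0
    for radius in np.unique(np.round(radii).astype(int)):
        sel = np.flatnonzero(np.round(radii).astype(int) == radius)
        r = max(int(radius), 1)
        # disk-mean video: ROI mean at every center in one convolution
        dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
        disk = (dy * dy + dx * dx <= r * r).astype(np.float32)
        disk /= disk.sum()
        stack = np.empty(frames.shape, dtype=np.float32)
        for t in range(T):
            stack[t] = ndimage.convolve(
                np.asarray(frames[t], dtype=np.float32), disk,
                mode="constant")
        overlap = ndimage.convolve(union.astype(np.float32), disk,
                                   mode="constant")
        valid = overlap <= max_mask_overlap
        valid[:r, :] = valid[-r:, :] = False
        valid[:, :r] = valid[:, -r:] = False
        vy, vx = np.nonzero(valid)
        if len(vy) == 0:
            raise ValueError("no valid null-region centers available")
        n_draw = n_rep * len(sel)
        pick = rng.integers(0, len(vy), size=n_draw)
        train_idx = np.tile(sel, n_rep)
        # chunked so the (T x n_draw) trace block stays modest in memory
        chunk = max(20_000_000 // max(T, 1), 1)
        for lo in range(0, n_draw, chunk):
            hi = min(lo + chunk, n_draw)
            traces = stack[:, vy[pick[lo:hi]], vx[pick[lo:hi]]]
            dff = dff_table_plain(traces, window=baseline_window)
            trains = spikes01[:, train_idx[lo:hi]]
            r_sum += float(_pearson_columns(dff, trains).sum())
        r_count += n_draw
        del stack
    r_n = r_sum / r_count
    if r_n <= 0 or r_s <= 0:
        # the ratio is undefined; both components are still reported
        snr_db = float("nan")
    else:
        snr_db = 10.0 * np.log10(r_s / r_n)
    return SNRReport(r_s, r_n, snr_db, nu, n_rep)


def framewise_rmse(video_a: np.ndarray, video_b: np.ndarray) -> np.ndarray:
    """Root-mean-square pixel difference per frame."""
    a = np.asarray(video_a, dtype=np.float64)
    b = np.asarray(video_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("video shape mismatch")
    return np.sqrt(((a - b) ** 2).mean(axis=(1, 2)))
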