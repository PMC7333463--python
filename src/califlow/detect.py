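"""Multi-threshold blob detection and the training-mode detection matrix.

The detector binarizes the preprocessed frame at a ladder of intensity
thresholds, extracts connected components at each level, filters them by
area and shape (circularity, inertia ratio, convexity), and merges
surviving components across levels whose centers fall within a merge
distance.  Each merged group becomes one detected neuron: center = mean of
the grouped centers, radius = distance from the center to the furthest
pixel of the largest contributing component.

During the training phase, per-frame detections accumulate into a
persistent detection matrix: a new detection within ``d`` pixels (in both x
and y) of an already-known neuron is treated as a repeat sighting; anything
else is a newly discovered neuron and is appended.  In real-time mode the
matrix is frozen and emitted unchanged each firing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError



@dataclass
class BlobParams:
    min_threshold: float = 0.0
    max_threshold: float = 255.0
    threshold_step: float = 10.0
    a_min: float = 9.0
    a_max: float = 150.0
    circularity_min: float = 0.5
    inertia_min: float = 0.3
    convexity_min: float = 0.5
    min_dist: float = 10.0
    min_repeatability: int = 2
    use_shape_filters: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.min_threshold < self.max_threshold:
            raise ValueError("need 0 <= min_threshold < max_threshold")
        if self.threshold_step <= 0:
            raise ValueError("threshold_step must be > 0")
        if self.threshold_step > self.max_threshold - self.min_threshold:
            raise ValueError("threshold_step exceeds the threshold range")
        if not self.a_min < self.a_max:
            raise ValueError("need a_min < a_max")


@dataclass
class TrainingState:
    """Persistent detector state: the accumulated detection matrix and the
    repeat-proximity tolerance ``d`` (pixels, per axis)."""
    d: float = 2.0
    mode: str = "training"           # training | realtime
    delta_p: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.float64))
    accumulate_in_realtime: bool = False


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    return min(4.0 * np.pi * area / perimeter ** 2, 1.0)


_STRUCT8 = np.ones((3, 3), dtype=bool)


def _level_components(binary: np.ndarray, params: BlobParams,
                      oy: int = 0, ox: int = 0
                      ) -> list[tuple[float, float, float, float]]:
    """Connected components of one binarization level that pass the area
    and shape filters, as (x, y, radius, area) tuples in frame coordinates
    (``oy``/``ox`` offset window coordinates back to the frame)."""
    if not binary.any():
        return []
    labels, n_lab = ndimage.label(binary, structure=_STRUCT8)
    areas = np.bincount(labels.ravel())[1:]
    candidates = np.flatnonzero((areas >= params.a_min)
                                & (areas <= params.a_max)) + 1
    if candidates.size == 0:
        return []
    slices = ndimage.find_objects(labels)
    out: list[tuple[float, float, float, float]] = []
    for lab in candidates:
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        ys, xs = np.nonzero(sub)
        n_px = len(ys)
        area = float(n_px)
        my = float(np.add.reduce(ys)) / n_px
        mx = float(np.add.reduce(xs)) / n_px
        dy, dx = ys - my, xs - mx
        if params.use_shape_filters:
            circ = _circularity(area, _perimeter(sub, area))
            if circ < params.circularity_min:
                continue
            myy = float(np.add.reduce(dy * dy)) / n_px
            mxx = float(np.add.reduce(dx * dx)) / n_px
            mxy = float(np.add.reduce(dy * dx)) / n_px
            tr, det = myy + mxx, myy * mxx - mxy * mxy
            disc = max(tr * tr / 4 - det, 0.0) ** 0.5
            big, small = tr / 2 + disc, tr / 2 - disc
            inertia = (small / big) if big > 0 else 1.0
            if inertia < params.inertia_min:
                continue
            # near-circular components are necessarily near-convex; the
            # explicit hull test only runs for more irregular shapes
            if circ < 0.8 and _convexity(ys, xs, area) \
                    < params.convexity_min:
                continue
        cy = my + sl[0].start + oy
        cx = mx + sl[1].start + ox
        radius = float(np.sqrt((dy * dy + dx * dx).max()))
        out.append((float(cx), float(cy), radius, area))
    return out


def _perimeter(sub: np.ndarray, area: float) -> float:
    """City-block boundary length scaled by pi/4 to approximate the true
    perimeter (exact scaling for a circle)."""
    adj = np.count_nonzero(sub[:, 1:] & sub[:, :-1]) \
        + np.count_nonzero(sub[1:, :] & sub[:-1, :])
    return (4.0 * area - 2.0 * adj) * (np.pi / 4.0)


def _convexity(ys: np.ndarray, xs: np.ndarray, area: float) -> float:
    """Ratio of pixel area to (pixel-corrected) convex-hull area."""
    if area < 3:
        return 1.0
    pts = np.column_stack([xs, ys]).astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear pixel sets
        return 1.0
    # polygon area through pixel centers underestimates the pixelized hull;
    # Pick-style boundary correction keeps convex blobs at ratio ~1
    hull_area = hull.volume + hull.area / 2.0 + 1.0
    return min(area / hull_area, 1.0)


def detect_blobs(frame: np.ndarray, params: BlobParams) -> np.ndarray:
    """Detect blobs in a preprocessed frame.

    Returns an (n_d, 3) matrix with rows (x_center, y_center, radius),
    0-based sub-pixel coordinates (x = column, y = row).
    """
    params.validate()
    frame = np.asarray(frame, dtype=np.float64)
    thresholds = np.arange(params.min_threshold, params.max_threshold,
                           params.threshold_step)
    # candidate blobs per threshold level that pass area + shape filters
    level_blobs: list[tuple[float, float, float, float]] = []  # x, y, r, area
    # the two lowest levels run on the full frame (the lowest may contain a
    # huge speckled background component); components at every higher level
    # nest inside the second-level components, so those levels only need to
    # visit small masked windows around each second-level component.
    for thr in thresholds[:2]:
        level_blobs.extend(_level_components(frame >= thr, params))
    if len(thresholds) > 2:
        base = frame >= thresholds[1]
        labels, n_lab = ndimage.label(base, structure=_STRUCT8)
        slices = ndimage.find_objects(labels)
        h, w = frame.shape
        for lab in range(1, n_lab + 1):
            sl = slices[lab - 1]
            y0 = max(sl[0].start - 1, 0)
            y1 = min(sl[0].stop + 1, h)
            x0 = max(sl[1].start - 1, 0)
            x1 = min(sl[1].stop + 1, w)
            win = np.where(labels[y0:y1, x0:x1] == lab,
                           frame[y0:y1, x0:x1], -np.inf)
            win_max = win.max()
            prev_binary = None
            prev_blobs: list[tuple[float, float, float, float]] = []
            for thr in thresholds[2:]:
                if thr > win_max:
                    break
                binary = win >= thr
                if prev_binary is not None and \
                        np.array_equal(binary, prev_binary):
                    level_blobs.extend(prev_blobs)  # identical level
                    continue
                blobs = _level_components(binary, params, y0, x0)
                level_blobs.extend(blobs)
                prev_binary = binary
                prev_blobs = blobs
    if not level_blobs:
        return np.empty((0, 3), dtype=np.float64)
    # merge across levels: greedy clustering by center distance
    clusters: list[dict] = []
    for cx, cy, r, area in level_blobs:
        best = None
        for cl in clusters:
            mx, my = cl["sx"] / cl["n"], cl["sy"] / cl["n"]
            d2 = (mx - cx) ** 2 + (my - cy) ** 2
            if d2 <= params.min_dist ** 2 and (best is None or d2 < best[0]):
                best = (d2, cl)
        if best is None:
            clusters.append({"sx": cx, "sy": cy, "n": 1, "r": r,
                             "area": area})
        else:
            cl = best[1]
            cl["sx"] += cx
            cl["sy"] += cy
            cl["n"] += 1
            if area > cl["area"]:
                cl["area"] = area
                cl["r"] = r
    rows = [(cl["sx"] / cl["n"], cl["sy"] / cl["n"], cl["r"])
            for cl in clusters if cl["n"] >= params.min_repeatability]
    return np.asarray(rows, dtype=np.float64).reshape(-1, 3)


def training_update(eta: np.ndarray, state: TrainingState) -> np.ndarray:
    """Merge one firing's detections into the persistent matrix.

    A detection whose |dx| <= d AND |dy| <= d relative to some known neuron
    is a repeat and is dropped; the survivors are newly discovered neurons
    and are appended in input order.  Returns (and persists) the updated
    matrix.
    """
    if state.mode != "training" and not state.accumulate_in_realtime:
        raise ValueError("training_update called outside training mode")
    eta = np.asarray(eta, dtype=np.float64).reshape(-1, 3)
    for row in eta:
        if state.delta_p.shape[0]:
            dx = np.abs(state.delta_p[:, 0] - row[0])
            dy = np.abs(state.delta_p[:, 1] - row[1])
            if np.any((dx <= state.d) & (dy <= state.d)):
                continue
        state.delta_p = np.vstack([state.delta_p, row[None, :]])
    return state.delta_p


def fire_detection(frame: np.ndarray, state: TrainingState,
                   params: BlobParams, log=None) -> np.ndarray:
    """One firing of the Neuron Detection actor.

    Training mode: detect, fold into the persistent matrix, emit the
    cumulative matrix.  Real-time mode: per-frame detection still runs (its
    result is diagnostic only) but the emitted matrix is the frozen training
    result, so the neuron set and its ordering stay fixed.
    """
    eta = detect_blobs(frame, params)
    if state.mode == "training" or state.accumulate_in_realtime:
        return training_update(eta, state).copy()
    if state.delta_p.shape[0] == 0 and log is not None:
        log.message("realtime detection fired with empty training matrix")
    return state.delta_p.copy()


def scale_params(params: BlobParams, **overrides) -> BlobParams:
    return replace(params, **overrides)
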