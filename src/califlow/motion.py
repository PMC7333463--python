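"""Rigid motion correction with adaptive correlation gating.

The estimator recovers a rigid warp (translation, optionally plus rotation
about the image center) between a current frame and a running reference
frame by maximizing the enhanced correlation coefficient (ECC) -- a
zero-mean, norm-normalized similarity that is invariant to brightness and
contrast changes.  Estimation runs on downsampled copies of the frames for
speed; a bounded FFT cross-correlation (and, for the Euclidean model, a
coarse angle sweep) provides the initial guess, which the ECC iteration
then refines to sub-pixel / sub-degree accuracy.

The per-frame acceptance logic mirrors a translation-first design: a cheap
translation-only estimate is gated by an adaptive threshold tau_1 computed
from the recent history of accepted correlations (CoHisQ); only when that
gate fails is the costlier Euclidean estimate attempted, gated by a looser
threshold tau_2.  Frames failing both gates are logged and replaced by the
reference frame.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# rigid warps
# ---------------------------------------------------------------------------

def _rot_rc(theta_deg: float) -> np.ndarray:
    """Rotation matrix acting on (row, col) offsets from the image center."""
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def warp_frame(frame: np.ndarray, tx: float, ty: float, theta: float = 0.0,
               fill: float = 0.0, order: int = 1) -> np.ndarray:
    """Rotate ``frame`` by ``theta`` degrees about its center, then translate
    the content by (+tx columns, +ty rows).  Bilinear interpolation by
    default, out-of-frame pixels filled with ``fill``.
    """
    h, w = frame.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([ty, tx])
    minv = _rot_rc(-theta)
    offset = center - minv @ (center + shift)
    if frame.dtype not in (np.float32, np.float64):
        frame = frame.astype(np.float64)
    return ndimage.affine_transform(frame, minv, offset=offset, order=order,
                                    mode="constant", cval=fill)


def invert_warp(tx: float, ty: float, theta: float) -> tuple[float, float, float]:
    """Parameters of the inverse rigid motion (so that applying them with
    ``warp_frame`` undoes warp_frame(tx, ty, theta))."""
    minv = _rot_rc(-theta)
    t2 = -(minv @ np.array([ty, tx]))
    return float(t2[1]), float(t2[0]), -theta


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WarpParams:
    """Estimated rigid motion of the current frame relative to the reference.

    ``tx``/``ty`` are sub-pixel translations (columns / rows); ``theta`` is a
    rotation in degrees about the image center.  ``model`` is
    ``translation_only`` (theta fixed at 0) or ``euclidean``.
    """
    tx: float
    ty: float
    theta: float = 0.0
    model: str = "translation_only"
    converged: bool = True

    def __post_init__(self):
        if self.model == "translation_only" and self.theta != 0.0:
            raise ValueError("translation_only model implies theta = 0")


class CoHisQ:
    """Ring buffer of the 100 most recent accepted correlation values with
    incrementally maintained mean and standard deviation."""

    def __init__(self, maxlen: int = 100):
        self.maxlen = maxlen
        self._queue: collections.deque[float] = collections.deque()
        self._sum = 0.0
        self._sumsq = 0.0

    def __len__(self) -> int:
        return len(self._queue)

    def push(self, value: float) -> None:
        if len(self._queue) == self.maxlen:
            old = self._queue.popleft()
            self._sum -= old
            self._sumsq -= old * old
        self._queue.append(value)
        self._sum += value
        self._sumsq += value * value

    @property
    def mean(self) -> float:
        if not self._queue:
            raise ValueError("empty correlation history")
        return self._sum / len(self._queue)

    @property
    def std(self) -> float:
        if not self._queue:
            raise ValueError("empty correlation history")
        var = self._sumsq / len(self._queue) - self.mean ** 2
        return math.sqrt(max(var, 0.0))

    def recompute(self) -> tuple[float, float]:
        """From-scratch mean/std, for verifying the incremental bookkeeping."""
        arr = np.asarray(self._queue, dtype=float)
        return float(arr.mean()), float(arr.std())

    def values(self) -> list[float]:
        return list(self._queue)


def adaptive_threshold(cohisq: CoHisQ, p: float, warmup_min: int = 10,
                       warmup_floor: float = 0.3) -> float:
    """tau = mean(CoHisQ) - p * std(CoHisQ).

    Until the queue holds ``warmup_min`` values the gate falls back to a
    fixed floor (low end of the correlation range seen in practice).
    """
    if len(cohisq) < warmup_min:
        return warmup_floor
    return cohisq.mean - p * cohisq.std


@dataclass
class MCState:
    """Mutable state of the Motion Correction actor."""
    reference: np.ndarray | None = None
    cohisq: CoHisQ = field(default_factory=CoHisQ)
    p1: float = 2.0
    p2: float = 10.0
    downsample_factor: float = 2.0
    frame_index: int = 0
    warmup_min: int = 10
    # warm-up gate floors before the history fills: the translation gate
    # must already reject poorly corrected rotated frames (which can still
    # correlate ~0.4-0.5), while the Euclidean gate stays permissive
    warmup_floor_tau1: float = 0.6
    warmup_floor_tau2: float = 0.55
    motion_eps_px: float = 0.5
    motion_eps_deg: float = 0.05
    max_iterations: int = 50
    eps: float = 1e-4
    angle_search: float = 8.0
    angle_step: float = 1.5
    max_shift: float = 30.0     # admissible translation bound, full-res px

    def __post_init__(self):
        if self.p1 >= self.p2:
            raise ValueError("p1 must be < p2")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


@dataclass
class MCResult:
    corrected_frame: np.ndarray | None
    warp: WarpParams
    correlation: float
    status: str  # translation_ok | euclidean_ok | no_motion | failed
    tau1: float = float("nan")
    tau2: float = float("nan")


# ---------------------------------------------------------------------------
# correlation and ECC estimation
# ---------------------------------------------------------------------------

def frame_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized (Pearson) correlation over pixels.

    Defined as 0 when either frame is constant.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _downsample(frame: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return np.asarray(frame, dtype=np.float64)
    return ndimage.zoom(np.asarray(frame, dtype=np.float64), 1.0 / factor,
                        order=1)


def _ecc_refine(ref: np.ndarray, cur: np.ndarray, model: str,
                p0: np.ndarray, max_iterations: int, eps: float
                ) -> tuple[np.ndarray, float, bool]:
    """Iterative ECC maximization of corr(warp_frame(cur, p), ref).

    ``p`` is (tx, ty) or (tx, ty, theta_rad) in the working resolution.
    Returns (p, rho, converged).
    """
    ref = np.asarray(ref, dtype=np.float64)
    cur = np.asarray(cur, dtype=np.float64)
    h, w = ref.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    ones = np.ones_like(cur)
    p = p0.astype(np.float64).copy()
    n_params = p.size
    yy = xx = None
    if n_params == 3:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    rho_prev = -np.inf
    rho = -np.inf
    converged = False
    for _ in range(max_iterations):
        theta = p[2] if n_params == 3 else 0.0
        theta_deg = math.degrees(theta)
        gw = warp_frame(cur, p[0], p[1], theta_deg)
        if n_params == 2:
            # pure translation: the valid region is an axis-aligned sub-rect
            valid = np.zeros_like(gw, dtype=bool)
            y0 = max(0, int(math.ceil(p[1])))
            y1 = min(h, h + int(math.floor(p[1])))
            x0 = max(0, int(math.ceil(p[0])))
            x1 = min(w, w + int(math.floor(p[0])))
            if y1 <= y0 or x1 <= x0:
                break
            valid[y0:y1, x0:x1] = True
        else:
            valid = warp_frame(ones, p[0], p[1], theta_deg) > 0.999
        if valid.sum() < 16:
            break
        # gradient of the warped image approximates the warped gradient
        gyw, gxw = np.gradient(gw)
        # inverse coordinate map m(o) = R(-theta)(o - c - t) + c and its
        # parameter Jacobian; image Jacobian columns via the chain rule.
        minv = _rot_rc(-theta_deg)
        # d m / d tx = -minv @ [0,1]; d m / d ty = -minv @ [1,0]
        dmx_dtx, dmy_dtx = -minv[1, 1], -minv[0, 1]
        dmx_dty, dmy_dty = -minv[1, 0], -minv[0, 0]
        cols = [gxw * dmx_dtx + gyw * dmy_dtx,
                gxw * dmx_dty + gyw * dmy_dty]
        if n_params == 3:
            # d m / d theta = d R(-t)/d theta @ (o - c - t)
            ct, st = math.cos(theta), math.sin(theta)
            drot = np.array([[-st, ct], [-ct, -st]])  # d/dtheta of R(-theta)
            oy = yy - center[0] - p[1]
            ox = xx - center[1] - p[0]
            dmy = drot[0, 0] * oy + drot[0, 1] * ox
            dmx = drot[1, 0] * oy + drot[1, 1] * ox
            cols.append(gxw * dmx + gyw * dmy)
        v = valid.ravel()
        ir = ref.ravel()[v]
        ir = ir - ir.mean()
        g = gw.ravel()[v]
        g = g - g.mean()
        G = np.stack([c.ravel()[v] for c in cols], axis=1)
        G = G - G.mean(axis=0)
        norm_ir = np.linalg.norm(ir)
        norm_g = np.linalg.norm(g)
        if norm_ir == 0.0 or norm_g == 0.0:
            break
        rho = float(ir @ g / (norm_ir * norm_g))
        if abs(rho - rho_prev) < eps:
            converged = True
            break
        rho_prev = rho
        GtG = G.T @ G
        try:
            GtG_inv = np.linalg.inv(GtG)
        except np.linalg.LinAlgError:
            break
        Gt_g = G.T @ g
        Gt_ir = G.T @ ir
        num = norm_g ** 2 - Gt_g @ GtG_inv @ Gt_g
        den = ir @ g - Gt_ir @ GtG_inv @ Gt_g
        if den <= 0:
            # already at (or beyond) the correlation optimum
            converged = True
            break
        lam = num / den
        err = lam * ir - g
        dp = GtG_inv @ (G.T @ err)
        p = p + dp
        if np.max(np.abs(dp)) < 1e-8:
            converged = True
            break
    return p, rho, converged


def _xcorr_shift(ref: np.ndarray, mov: np.ndarray, max_shift: int,
                 n_peaks: int = 1) -> list[tuple[float, float]]:
    """Candidate registration shifts (dy, dx) to apply to ``mov`` to align
    it on ``ref``: the ``n_peaks`` strongest local maxima of the zero-mean
    circular cross-correlation surface, searched within |shift| <=
    max_shift, each with a three-point parabolic sub-pixel interpolation.
    Returning several candidates lets the caller disambiguate near-periodic
    content (similar blobs a few pixels apart) by actual correlation."""
    a = ref - ref.mean()
    b = mov - mov.mean()
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    cc = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    # cc[d] = sum_x a[x + d] * b[x] peaks at the registration shift;
    # restrict to the window of admissible shifts (wrap-around corners)
    m = max_shift
    win = np.empty((2 * m + 1, 2 * m + 1))
    win[m:, m:] = cc[:m + 1, :m + 1]
    win[:m, m:] = cc[-m:, :m + 1]
    win[m:, :m] = cc[:m + 1, -m:]
    win[:m, :m] = cc[-m:, -m:]

    def _para(c0, c1, c2):
        den = c0 - 2 * c1 + c2
        if den >= 0:
            return 0.0
        return float(np.clip(0.5 * (c0 - c2) / den, -0.5, 0.5))

    if n_peaks == 1:
        peaks = [np.unravel_index(np.argmax(win), win.shape)]
    else:
        local_max = win == ndimage.maximum_filter(win, size=5)
        py, px = np.nonzero(local_max)
        order = np.argsort(win[py, px])[::-1][:n_peaks]
        peaks = list(zip(py[order], px[order]))
    out = []
    for iy, ix in peaks:
        sy = iy - m + (_para(win[iy - 1, ix], win[iy, ix], win[iy + 1, ix])
                       if 0 < iy < 2 * m else 0.0)
        sx = ix - m + (_para(win[iy, ix - 1], win[iy, ix], win[iy, ix + 1])
                       if 0 < ix < 2 * m else 0.0)
        out.append((sy, sx))
    return out


def estimate_warp(current: np.ndarray, reference: np.ndarray, model: str,
                  downsample_factor: float = 2.0, max_iterations: int = 50,
                  eps: float = 1e-4, angle_search: float = 8.0,
                  angle_step: float = 1.5, max_shift: float = 30.0
                  ) -> WarpParams:
    """Estimate the rigid motion of ``current`` relative to ``reference``.

    Runs at a resolution downsampled by ``downsample_factor`` per axis;
    translation is rescaled to full resolution on return.  Estimation only:
    neither frame is modified.
    """
    if current.shape != reference.shape:
        raise ValueError("frames must share a shape")
    if model not in ("translation_only", "euclidean"):
        raise ValueError(f"unknown model {model!r}")
    ref_ds = _downsample(reference, downsample_factor)
    cur_ds = _downsample(current, downsample_factor)
    if ref_ds.std() == 0.0 or cur_ds.std() == 0.0:
        return WarpParams(0.0, 0.0, 0.0, model="translation_only",
                          converged=False)
    max_shift_ds = max(int(np.ceil(max_shift / downsample_factor)), 1)
    # translation initialization: windowed cross-correlation proposes
    # candidate shifts (the search is bounded so a spurious far-field blob
    # match cannot produce an absurd shift); with sparse blob content the
    # strongest surface peak can be a wrong correspondence, so the top few
    # peaks are disambiguated by the actual frame correlation.
    if model == "translation_only":
        cands = _xcorr_shift(ref_ds, cur_ds, max_shift_ds, n_peaks=3)
        best_q, best_c = None, -np.inf
        for dy, dx in cands:
            c = frame_correlation(warp_frame(cur_ds, dx, dy), ref_ds)
            if c > best_c:
                best_q, best_c = np.array([dx, dy]), c
        q, _, conv = _ecc_refine(ref_ds, cur_ds, model, best_q,
                                 max_iterations, eps)
        ctx, cty, cth = (q[0] * downsample_factor,
                         q[1] * downsample_factor, 0.0)
        mtx, mty, mth = invert_warp(ctx, cty, cth)
        return WarpParams(mtx, mty, 0.0, model=model, converged=conv)

    # euclidean: coarse sweep over candidate angles, each with its own
    # cross-correlation shift, scored by correlation; best candidate refined.
    best = None
    angles = np.arange(-angle_search, angle_search + 1e-9, angle_step)
    for ang in angles:
        rot = warp_frame(cur_ds, 0.0, 0.0, ang)
        sy, sx = _xcorr_shift(ref_ds, rot, max_shift_ds)[0]
        cand = warp_frame(cur_ds, sx, sy, ang)
        c = frame_correlation(cand, ref_ds)
        if best is None or c > best[0]:
            best = (c, np.array([sx, sy, math.radians(ang)]))
    q, _, conv = _ecc_refine(ref_ds, cur_ds, model, best[1],
                             max_iterations, eps)
    ctx = q[0] * downsample_factor
    cty = q[1] * downsample_factor
    cth = math.degrees(q[2])
    mtx, mty, mth = invert_warp(ctx, cty, cth)
    return WarpParams(mtx, mty, mth, model=model, converged=conv)


# ---------------------------------------------------------------------------
# per-frame correction
# ---------------------------------------------------------------------------

def apply_correction(frame: np.ndarray, warp: WarpParams) -> np.ndarray:
    """Warp ``frame`` by the inverse of the estimated motion (full
    resolution, bilinear, border fill 0)."""
    ctx, cty, cth = invert_warp(warp.tx, warp.ty, warp.theta)
    return warp_frame(np.asarray(frame, dtype=np.float64), ctx, cty, cth)


def motion_detected(warp: WarpParams, eps_px: float = 0.5,
                    eps_deg: float = 0.05) -> bool:
    return (abs(warp.tx) >= eps_px or abs(warp.ty) >= eps_px
            or abs(warp.theta) >= eps_deg)


def correct_frame(current: np.ndarray, state: MCState,
                  log=None) -> MCResult:
    """One firing of the Motion Correction actor.

    Translation-only estimate first; accept via the tau_1 gate.  On failure,
    Euclidean (translation + rotation) estimate gated by tau_2.  On double
    failure the frame is replaced by the reference and a diagnostic message
    is appended to the experiment log.  Accepted correlations (either gate)
    feed the correlation history; the reference frame is replaced by every
    accepted frame.
    """
    if state.reference is None:
        raise ValueError("motion-correction state has no reference frame")
    idx = state.frame_index
    state.frame_index += 1
    cur = np.asarray(current, dtype=np.float64)
    ref = state.reference
    # the adaptive thresholds are clamped from below by the warm-up floors:
    # with p2 = 10, mean - p*sigma can otherwise go negative once the
    # correlation history has any variance, and a gate below ~0.3 accepts
    # arbitrarily bad warps (the thresholds observed in successful operation
    # stay within [0.3, 0.95])
    tau1 = max(adaptive_threshold(state.cohisq, state.p1, state.warmup_min,
                                  state.warmup_floor_tau1),
               state.warmup_floor_tau1)
    tau2 = max(adaptive_threshold(state.cohisq, state.p2, state.warmup_min,
                                  state.warmup_floor_tau2),
               state.warmup_floor_tau2)

    warp_t = estimate_warp(cur, ref, "translation_only",
                           state.downsample_factor, state.max_iterations,
                           state.eps, max_shift=state.max_shift)
    moved = motion_detected(warp_t, state.motion_eps_px, state.motion_eps_deg)
    plausible_t = (abs(warp_t.tx) <= state.max_shift
                   and abs(warp_t.ty) <= state.max_shift)
    if moved:
        shifted = apply_correction(cur, warp_t)
        c1 = frame_correlation(shifted, ref)
    else:
        shifted = cur
        c1 = frame_correlation(cur, ref)
    if c1 >= tau1 and plausible_t:
        state.reference = shifted
        state.cohisq.push(c1)
        status = "translation_ok" if moved else "no_motion"
        warp = warp_t if moved else WarpParams(0.0, 0.0, 0.0,
                                               model="translation_only")
        if log is not None:
            _log_line(log, idx, status, c1, tau1, tau2, warp)
        return MCResult(shifted, warp, c1, status, tau1, tau2)

    warp_e = estimate_warp(cur, ref, "euclidean", state.downsample_factor,
                           state.max_iterations, state.eps,
                           state.angle_search, state.angle_step,
                           state.max_shift)
    plausible_e = (abs(warp_e.tx) <= state.max_shift
                   and abs(warp_e.ty) <= state.max_shift
                   and abs(warp_e.theta) <= state.angle_search + 1.0)
    if motion_detected(warp_e, state.motion_eps_px, state.motion_eps_deg):
        shifted_e = apply_correction(cur, warp_e)
        c2 = frame_correlation(shifted_e, ref)
    else:
        shifted_e = cur
        c2 = frame_correlation(cur, ref)
    if c2 >= tau2 and plausible_e:
        state.reference = shifted_e
        state.cohisq.push(c2)
        if log is not None:
            _log_line(log, idx, "euclidean_ok", c2, tau1, tau2, warp_e)
        return MCResult(shifted_e, warp_e, c2, "euclidean_ok", tau1, tau2)

    if log is not None:
        log.message(f"motion correction failed at frame {idx}", frame=idx)
        _log_line(log, idx, "failed", c2, tau1, tau2, warp_e)
    return MCResult(state.reference, warp_e, c2, "failed", tau1, tau2)


def _log_line(log, idx, status, corr, tau1, tau2, warp) -> None:
    log.message(
        f"frame={idx} status={status} corr={corr:.4f} tau1={tau1:.4f} "
        f"tau2={tau2:.4f} tx={warp.tx:.3f} ty={warp.ty:.3f} "
        f"theta={warp.theta:.4f}", frame=idx)
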