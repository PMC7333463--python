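"""Ground-truthed calcium-imaging video simulator.

A small network of leaky integrate-and-fire (LIF) neurons drives a
mask-based fluorescence renderer: a neuron's mask pixels jump to intensity
128 on a spike and decay exponentially with a configurable half-life
(default 8 frames, emulating a fast GCaMP indicator imaged at ~30 Hz).
Rigid global motion (uniform translation, occasional rotation, and several
drift regimes) and two additive noise fields (temporally white "shot" noise
and temporally autocorrelated "colored" noise) can then be injected.  The
simulator records full ground truth -- per-neuron binary masks, the spike
matrix, and the per-frame motion track -- so that motion correction,
detection, and signal extraction can be scored quantitatively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np

from .motion import warp_frame

SPIKE_INTENSITY = 128.0


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class LIFParams:
    """Leaky integrate-and-fire parameters (arbitrary units, frame steps).

    The membrane potential follows an Euler step of
    ``dV/dt = (V_rest - V)/lambda + theta*lambda*(-0.5)*eps`` with unit frame
    step, where eps is standard normal.  ``w`` is the synaptic weight added
    to a child's potential one frame after a parent spike; ``stim_rate`` is
    the per-frame probability of an external stimulus event (adding ``w``)
    for stimulus-driven neurons.
    """
    v_rest: float = 0.0
    lam: float = 10.0
    theta: float = 0.065
    v_threshold: float = 1.0
    refractory: int = 5
    w: float = 0.2
    stim_rate: float = 0.02

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("membrane time constant lambda must be > 0")
        if self.refractory < 1:
            raise ValueError("refractory must be >= 1 frame")
        if not 0 <= self.stim_rate <= 1:
            raise ValueError("stim_rate must be a probability")


@dataclass
class NetworkTopology:
    """Two-group feed-forward topology: group A neurons are driven by an
    external stimulus and have no parents; each group B neuron has one or
    two group A parents."""
    n_neurons: int
    group_a: list[int]
    group_b: list[int]
    parent_map: dict[int, list[int]]

    def __post_init__(self):
        if set(self.group_a) | set(self.group_b) != set(range(self.n_neurons)) \
                or set(self.group_a) & set(self.group_b):
            raise ValueError("groups A and B must partition the neuron set")
        for b in self.group_b:
            parents = self.parent_map.get(b, [])
            if not 1 <= len(parents) <= 2 or any(p not in self.group_a
                                                 for p in parents):
                raise ValueError(f"neuron {b} needs 1-2 group-A parents")

    @classmethod
    def random(cls, n_neurons: int = 100, frac_a: float = 0.4,
               rng: np.random.Generator | None = None) -> "NetworkTopology":
        rng = rng if rng is not None else np.random.default_rng()
        n_a = max(1, int(round(frac_a * n_neurons)))
        perm = rng.permutation(n_neurons)
        group_a = sorted(int(i) for i in perm[:n_a])
        group_b = sorted(int(i) for i in perm[n_a:])
        parent_map = {
            b: [int(p) for p in rng.choice(group_a, size=rng.integers(1, 3),
                                           replace=False)]
            for b in group_b}
        return cls(n_neurons, group_a, group_b, parent_map)


@dataclass
class MotionConfig:
    translation_range: float = 10.0
    p_rot: float = 0.0           # rotation occurrence probability, percent
    alpha_rot: float = 0.0       # rotation uniform in [-alpha, alpha] degrees
    drift_mode: str = "random"   # random | constant_trajectory | small | large

    def __post_init__(self):
        if not 0 <= self.p_rot <= 100:
            raise ValueError("p_rot is a percentage")
        if self.alpha_rot < 0:
            raise ValueError("alpha_rot must be >= 0")
        if self.drift_mode not in ("random", "constant_trajectory", "small",
                                   "large"):
            raise ValueError(f"unknown drift mode {self.drift_mode!r}")


@dataclass
class NoiseConfig:
    shot_level: float = 0.0      # multiplier on the base shot sigma (1.0)
    colored_level: float = 0.0   # multiplier on the base colored sigma (0.4)
    shot_sigma_base: float = 1.0
    colored_sigma_base: float = 0.4
    colored_ar_coeff: float = 0.8

    def __post_init__(self):
        if self.shot_level < 0 or self.colored_level < 0:
            raise ValueError("noise multipliers must be >= 0")

    @classmethod
    def from_label(cls, label: str) -> "NoiseConfig":
        """Parse a ``sNNcMM`` label: sNN = NN/10 x base shot sigma,
        cMM = MM/10 x base colored sigma (e.g. ``s03c05`` -> 0.3, 0.5)."""
        m = re.fullmatch(r"s(\d+)c(\d+)", label)
        if m is None:
            raise ValueError(f"bad noise label {label!r}")
        return cls(shot_level=int(m.group(1)) / 10.0,
                   colored_level=int(m.group(2)) / 10.0)

    @property
    def label(self) -> str:
        return (f"s{int(round(self.shot_level * 10)):02d}"
                f"c{int(round(self.colored_level * 10)):02d}")


@dataclass
class MaskSet:
    """Per-neuron binary masks on a common grid."""
    masks: np.ndarray            # (n, H, W) bool
    centroids: np.ndarray        # (n, 2) as (x, y)
    widths: np.ndarray           # (n,) bounding widths, pixels
    heights: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.masks.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.masks.shape[1:]

    def union(self) -> np.ndarray:
        return self.masks.any(axis=0)


@dataclass
class SimConfig:
    n_neurons: int = 100
    n_frames: int = 1800
    grid: tuple[int, int] = (400, 400)
    mean_width: float = 6.8387
    mean_height: float = 6.7634
    decay_half_life: float = 8.0
    lif: LIFParams = field(default_factory=LIFParams)
    motion: MotionConfig = field(default_factory=MotionConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    frac_a: float = 0.4
    n_silent: int = 0            # force exactly this many neurons silent
    burn_in: int = 100           # pre-roll frames so frame 0 is stationary

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationBundle:
    frames: np.ndarray           # (T, H, W) uint8, with motion + noise
    clean_frames: np.ndarray     # (T, H, W) uint8, motion- and noise-free
    spikes: np.ndarray           # (n, T) uint8
    masks: MaskSet
    motion_track: np.ndarray     # (T, 3) true (tx, ty, theta) per frame
    topology: NetworkTopology
    config: SimConfig
    seed: int

    @property
    def active_neurons(self) -> np.ndarray:
        return np.flatnonzero(self.spikes.any(axis=1))


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------

def simulate_spikes(topology: NetworkTopology, lif: LIFParams, n_frames: int,
                    rng: np.random.Generator,
                    silent: set[int] | frozenset[int] = frozenset()
                    ) -> np.ndarray:
    """Euler-step LIF simulation over ``n_frames`` unit frame steps.

    External stimulus events (Bernoulli per frame) drive group A; a parent
    spike at frame t adds ``w`` to each child's potential at frame t+1
    (additively for two co-firing parents).  Potentials reset to rest on
    firing and the neuron stays refractory for ``lif.refractory`` frames.
    Neurons listed in ``silent`` never fire (unreachable threshold).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = topology.n_neurons
    v = np.full(n, lif.v_rest, dtype=np.float64)
    refractory_until = np.zeros(n, dtype=np.int64)
    spikes = np.zeros((n, n_frames), dtype=np.uint8)
    is_a = np.zeros(n, dtype=bool)
    is_a[topology.group_a] = True
    silent_mask = np.zeros(n, dtype=bool)
    if silent:
        silent_mask[list(silent)] = True
    synaptic = np.zeros(n, dtype=np.float64)  # input arriving this frame
    noise_scale = lif.theta * lif.lam * 0.5
    for t in range(n_frames):
        eps = rng.standard_normal(n)
        v += (lif.v_rest - v) / lif.lam + noise_scale * (-1.0) * eps
        stim = (rng.random(n) < lif.stim_rate) & is_a
        v += lif.w * stim
        v += synaptic
        synaptic[:] = 0.0
        can_fire = (t >= refractory_until) & ~silent_mask
        fired = (v > lif.v_threshold) & can_fire
        if fired.any():
            idx = np.flatnonzero(fired)
            spikes[idx, t] = 1
            v[idx] = lif.v_rest
            refractory_until[idx] = t + 1 + lif.refractory
            fired_set = set(int(i) for i in idx)
            for b, parents in topology.parent_map.items():
                k = sum(1 for p in parents if p in fired_set)
                if k:
                    synaptic[b] += lif.w * k
    return spikes


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def generate_masks(n: int, grid: tuple[int, int],
                   mean_width: float, mean_height: float,
                   rng: np.random.Generator, min_spacing: float = 12.0,
                   margin: int = 12, size_jitter: float = 0.08
                   ) -> MaskSet:
    """Place ``n`` elliptical connected masks with bounding sizes scattered
    around the requested means.  Centers keep a minimum spacing (so distinct
    neurons remain separable) and no mask is wholly contained in another.
    """
    if n < 1:
        raise ValueError("need n >= 1 masks")
    h, w = grid
    centers: list[tuple[float, float]] = []
    max_tries = 20000
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"grid {grid} too small to place {n} masks "
                             f"with spacing {min_spacing}")
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_spacing ** 2
               for y, x in centers):
            centers.append((cy, cx))
    masks = np.zeros((n, h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    widths = np.empty(n)
    heights = np.empty(n)
    centroids = np.empty((n, 2))
    for i, (cy, cx) in enumerate(centers):
        bw = mean_width * (1 + size_jitter * rng.standard_normal())
        bh = mean_height * (1 + size_jitter * rng.standard_normal())
        bw = max(bw, 3.0)
        bh = max(bh, 3.0)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        dy, dx = yy - cy, xx - cx
        u = ca * dx + sa * dy
        q = -sa * dx + ca * dy
        ell = (u / (bw / 2)) ** 2 + (q / (bh / 2)) ** 2 <= 1.0
        if not ell.any():
            ell[int(round(cy)), int(round(cx))] = True
        masks[i] = ell
        ys, xs = np.nonzero(ell)
        widths[i] = xs.max() - xs.min() + 1
        heights[i] = ys.max() - ys.min() + 1
        centroids[i] = (xs.mean(), ys.mean())
    return MaskSet(masks, centroids, widths, heights)


# ---------------------------------------------------------------------------
# rendering, motion, noise
# ---------------------------------------------------------------------------

def render_frames(spikes: np.ndarray, masks: MaskSet,
                  decay_half_life: float = 8.0) -> np.ndarray:
    """Render the clean (motion- and noise-free) video.

    A neuron's trace is 128 at spike frames and decays by 2**(-1/half_life)
    per frame otherwise; overlapping masks combine with a per-pixel max.
    """
    if decay_half_life <= 0:
        raise ValueError("decay_half_life must be > 0")
    n, T = spikes.shape
    if n != masks.n_neurons:
        raise ValueError("spike matrix and mask set disagree on neuron count")
    h, w = masks.grid
    decay = 2.0 ** (-1.0 / decay_half_life)
    traces = np.zeros((n, T), dtype=np.float64)
    prev = np.zeros(n)
    for t in range(T):
        prev = np.where(spikes[:, t] == 1, SPIKE_INTENSITY, prev * decay)
        traces[:, t] = prev
    # flat pixel index / owning-neuron arrays make the per-frame fill a
    # single max-scatter instead of a per-neuron loop
    flat_idx_parts, owner_parts = [], []
    for i in range(n):
        ys, xs = np.nonzero(masks.masks[i])
        flat_idx_parts.append(ys.astype(np.int64) * w + xs.astype(np.int64))
        owner_parts.append(np.full(len(ys), i, dtype=np.int64))
    flat_idx = np.concatenate(flat_idx_parts)
    owner = np.concatenate(owner_parts)
    frames = np.zeros((T, h * w), dtype=np.float32)
    vals = traces[owner, :].astype(np.float32)  # (n_pixels, T)
    # pixels owned by a single neuron scatter in one vectorized assignment;
    # the (rare) shared pixels take the max over their owners
    uniq, first, counts = np.unique(flat_idx, return_index=True,
                                    return_counts=True)
    single = counts == 1
    frames[:, uniq[single]] = vals[first[single], :].T
    for px in uniq[~single]:
        owners = owner[flat_idx == px]
        frames[:, px] = traces[owners, :].max(axis=0)
    frames = frames.reshape(T, h, w)
    np.clip(frames, 0.0, 255.0, out=frames)
    return frames


def _constant_trajectory(T: int, bound: float = 10.0) -> np.ndarray:
    """Rectangular-spiral drift path, 1 px/frame, within +/-``bound`` px of
    the ground-truth position, starting at (0, 0) and moving along +x."""
    pos = np.zeros((T, 2))
    x = y = 0.0
    # leg lengths grow in a rectangular spiral: R, U, L, L, D, D, R, R, ...
    directions = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    d = 0
    leg = bound
    step_in_leg = 0
    for t in range(1, T):
        dx, dy = directions[d % 4]
        nx, ny = x + dx, y + dy
        if abs(nx) > bound or abs(ny) > bound:
            d += 1
            step_in_leg = 0
            dx, dy = directions[d % 4]
            nx, ny = x + dx, y + dy
            nx = float(np.clip(nx, -bound, bound))
            ny = float(np.clip(ny, -bound, bound))
        x, y = nx, ny
        step_in_leg += 1
        if step_in_leg >= 2 * leg:
            d += 1
            step_in_leg = 0
        pos[t] = (x, y)
    return pos


def sample_motion_track(T: int, cfg: MotionConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw the per-frame ground-truth (tx, ty, theta) track.

    Frame 0 is left at the ground-truth pose (0, 0, 0): the correction
    reference is initialized from the first frame, so displacement estimates
    are only comparable to the injected truth when the initial reference is
    unmoved.
    """
    track = np.zeros((T, 3))
    if cfg.drift_mode == "constant_trajectory":
        track[:, :2] = _constant_trajectory(T, min(cfg.translation_range, 10.0))
    else:
        if cfg.drift_mode == "random":
            t = rng.uniform(-cfg.translation_range, cfg.translation_range,
                            size=(T, 2))
        elif cfg.drift_mode == "small":
            t = rng.uniform(-3.0, 3.0, size=(T, 2))
        else:  # large
            mag = rng.uniform(7.0, 10.0, size=(T, 2))
            sign = rng.choice([-1.0, 1.0], size=(T, 2))
            t = mag * sign
        t[0] = 0.0
        track[:, :2] = t
    if cfg.p_rot > 0 and cfg.alpha_rot > 0:
        occur = rng.random(T) < cfg.p_rot / 100.0
        angles = rng.uniform(-cfg.alpha_rot, cfg.alpha_rot, size=T)
        occur[0] = False
        track[:, 2] = np.where(occur, angles, 0.0)
    return track


def inject_motion(clean: np.ndarray, cfg: MotionConfig,
                  rng: np.random.Generator,
                  track: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-frame rigid motion to the clean video.

    Rotation (when it occurs) pivots about the image center with bilinear
    interpolation; out-of-frame pixels fill with 0.  Returns the moved video
    and the ground-truth track.
    """
    T = clean.shape[0]
    if track is None:
        track = sample_motion_track(T, cfg, rng)
    moved = np.empty_like(clean, dtype=np.float32)
    for t in range(T):
        tx, ty, th = track[t]
        if tx == 0.0 and ty == 0.0 and th == 0.0:
            moved[t] = clean[t]
        else:
            moved[t] = warp_frame(np.asarray(clean[t], dtype=np.float32),
                                  tx, ty, th)
    return moved, track


def add_noise(video: np.ndarray, cfg: NoiseConfig,
              rng: np.random.Generator, clamp: bool = True,
              copy: bool = True) -> np.ndarray:
    """Add zero-mean white shot noise (std shot_level x 1.0, i.i.d. per
    pixel and frame) and a per-pixel AR(1) colored field with marginal std
    colored_level x 0.4; clamp to [0, 255] for 8-bit output.
    ``copy=False`` mutates a float32 input in place (large videos)."""
    video = np.asarray(video, dtype=np.float32)
    T, h, w = video.shape
    out = video.copy() if copy else video
    shot_sigma = cfg.shot_level * cfg.shot_sigma_base
    col_sigma = cfg.colored_level * cfg.colored_sigma_base
    if shot_sigma == 0.0 and col_sigma == 0.0:
        return out
    phi = cfg.colored_ar_coeff
    innov = col_sigma * np.sqrt(1.0 - phi * phi)
    colored = None
    if col_sigma > 0:
        colored = col_sigma * rng.standard_normal((h, w), dtype=np.float32)
    for t in range(T):
        if shot_sigma > 0:
            out[t] += shot_sigma * rng.standard_normal((h, w),
                                                       dtype=np.float32)
        if colored is not None:
            if t > 0:
                colored = phi * colored + innov * rng.standard_normal(
                    (h, w), dtype=np.float32)
            out[t] += colored
    if clamp:
        np.clip(out, 0.0, 255.0, out=out)
    return out


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig, seed: int) -> SimulationBundle:
    """Generate a complete ground-truthed dataset, bit-exactly reproducible
    from (config, seed)."""
    ss = np.random.SeedSequence(seed)
    rng_topo, rng_mask, rng_spk, rng_mot, rng_noise, rng_sil = (
        np.random.default_rng(s) for s in ss.spawn(6))
    topo = NetworkTopology.random(config.n_neurons, config.frac_a, rng_topo)
    masks = generate_masks(config.n_neurons, config.grid, config.mean_width,
                           config.mean_height, rng_mask)
    silent: frozenset[int] = frozenset()
    if config.n_silent > 0:
        silent = frozenset(int(i) for i in rng_sil.choice(
            config.n_neurons, size=config.n_silent, replace=False))
    # burn-in pre-roll: the LIF network and fluorescence decay reach their
    # stationary regime before the first recorded frame, as in a recording
    # that starts mid-activity
    spikes_full = simulate_spikes(topo, config.lif,
                                  config.n_frames + config.burn_in, rng_spk,
                                  silent)
    if config.n_silent > 0:
        # inactive-neuron control: the forced-silent set defines the
        # inactive neurons exactly, so every other neuron must be active in
        # the recorded window; a neuron that happened never to fire gets one
        # spike at a random recorded frame
        for i in range(config.n_neurons):
            if i in silent or spikes_full[i, config.burn_in:].any():
                continue
            t = int(rng_sil.integers(config.burn_in,
                                     config.burn_in + config.n_frames))
            spikes_full[i, t] = 1
    clean_full = render_frames(spikes_full, masks, config.decay_half_life)
    spikes = spikes_full[:, config.burn_in:]
    # the stored clean reference is 8-bit (the acquisition scale); float
    # renders remain available through render_frames for exact-trace work
    clean8 = np.clip(np.rint(clean_full[config.burn_in:]), 0,
                     255).astype(np.uint8)
    moved, track = inject_motion(clean_full[config.burn_in:], config.motion,
                                 rng_mot)
    del clean_full
    noisy = add_noise(moved, config.noise, rng_noise, copy=False)
    np.rint(noisy, out=noisy)
    np.clip(noisy, 0, 255, out=noisy)
    frames = noisy.astype(np.uint8)
    return SimulationBundle(frames=frames, clean_frames=clean8,
                            spikes=spikes, masks=masks, motion_track=track,
                            topology=topo, config=config, seed=seed)
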