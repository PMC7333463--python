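"""Progressive-loosening calibration of the blob detector (SetParams).

Starting from pre-initialized size/threshold parameters (derived from the
image size and a rough neuron radius), detection runs over a set of
training frames; while the cumulative number of distinct detected neurons
stays below a target count T_n, the filtering constraints are loosened one
multiplicative step at a time (shrink the minimum area, grow the maximum
area, shrink the threshold step).  Loosening, rather than tightening, is
the calibration direction: tightening from loose constraints lets early
false positives into the persistent matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detect import BlobParams, TrainingState, detect_blobs, training_update


def preinit_blob_params(rough_radius: float,
                        threshold_step: float = 10.0) -> BlobParams:
    """Pre-initialization heuristic from a user-supplied rough neuron
    radius: a_min = pi*(r/2)^2, a_max = pi*(2r)^2."""
    if rough_radius <= 0:
        raise ValueError("rough_radius must be > 0")
    return BlobParams(a_min=math.pi * (0.5 * rough_radius) ** 2,
                      a_max=math.pi * (2.0 * rough_radius) ** 2,
                      threshold_step=threshold_step)


@dataclass
class AdaptConfig:
    target_neurons: int = 5
    initial_params: BlobParams = field(
        default_factory=lambda: preinit_blob_params(3.4))
    a_min_factor: float = 0.8
    a_max_factor: float = 1.25
    step_factor: float = 0.8
    step_floor: float = 1.0
    max_iterations: int = 20
    d: float = 2.0               # proximity tolerance when counting uniques

    def __post_init__(self):
        if self.target_neurons < 1:
            raise ValueError("target_neurons must be >= 1")
        if not (self.a_min_factor < 1 and self.a_max_factor > 1
                and self.step_factor <= 1):
            raise ValueError("relaxation factors must strictly loosen")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def count_distinct(frames: Sequence[np.ndarray], params: BlobParams,
                   d: float) -> int:
    """Cumulative distinct-neuron count over frames, using the training
    accumulation rule with proximity tolerance d."""
    state = TrainingState(d=d)
    for frame in frames:
        training_update(detect_blobs(frame, params), state)
    return state.delta_p.shape[0]


def loosen(params: BlobParams, cfg: AdaptConfig) -> BlobParams:
    return replace(params,
                   a_min=params.a_min * cfg.a_min_factor,
                   a_max=params.a_max * cfg.a_max_factor,
                   threshold_step=max(params.threshold_step * cfg.step_factor,
                                      cfg.step_floor))


def adapt_params(training_frames: Sequence[np.ndarray],
                 cfg: AdaptConfig | None = None, log=None) -> BlobParams:
    """Loosen the blob filters until the cumulative detected-neuron count
    over the training frames reaches the target; after ``max_iterations``
    the loosest parameters are returned with a warning."""
    cfg = cfg if cfg is not None else AdaptConfig()
    frames = list(training_frames)
    if not frames:
        raise ValueError("need at least one training frame")
    params = cfg.initial_params
    for _ in range(cfg.max_iterations):
        if count_distinct(frames, params, cfg.d) >= cfg.target_neurons:
            return params
        params = loosen(params, cfg)
    if log is not None:
        log.message(
            f"parameter adaptation hit max_iterations={cfg.max_iterations} "
            f"without reaching target_neurons={cfg.target_neurons}")
    return params
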