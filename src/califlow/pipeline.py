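"""System assembly: the processing actors wired into a PSDF graph pair.

The body graph implements the per-frame processing chain

    ImgSrc -> MotionCorrection -> Fork1 -> Preprocessing -> NeuronDetection
                                     \\                          |
                                      \\                        Fork2
                                       \\                      /     \\
                                        SignalExtraction <---+       DetSink
                                              |
                                           SigSink

Signal extraction consumes the *unpreprocessed* motion-corrected frame
together with the detection matrix.  The subinit graph holds the SetParams
actor, which calibrates the blob-detector size/threshold parameters on the
training frames; its outputs reach the Neuron Detection actor exclusively
through PSDF parameter bindings.

Two run modes mirror the platform's operating phases: initialization
(subinit calibration followed by training-mode body iterations that
accumulate the persistent detection matrix) and real-time (body iterations
only, detection matrix frozen, one signal vector emitted per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import adapt, detect, motion, preprocess, signals
from .dataflow import (Actor, ForkActor, Graph, ParamBinding, PSDFGraph,
                       RunLog, SinkActor, SourceActor)


@dataclass
class PipelineConfig:
    preproc: preprocess.PreprocConfig = field(
        default_factory=preprocess.PreprocConfig)
    blob: detect.BlobParams = field(default_factory=detect.BlobParams)
    adapt: adapt.AdaptConfig = field(default_factory=adapt.AdaptConfig)
    baseline: signals.BaselineConfig = field(
        default_factory=signals.BaselineConfig)
    d: float = 2.0                     # repeat-detection tolerance, px
    motion_correction: bool = True
    mc_p1: float = 2.0
    mc_p2: float = 10.0
    mc_downsample: float = 2.0


# ---------------------------------------------------------------------------
# actors
# ---------------------------------------------------------------------------

class MotionCorrectionActor(Actor):
    inputs = {"in": 1}
    outputs = {"out": 1}

    def __init__(self, name: str, p1: float = 2.0, p2: float = 10.0,
                 downsample: float = 2.0, enabled: bool = True,
                 log: RunLog | None = None):
        super().__init__(name)
        self.state = motion.MCState(p1=p1, p2=p2, downsample_factor=downsample)
        self.params["enabled"] = enabled
        self.log = log
        self.results: list[motion.MCResult] = []

    def fire(self, inputs):
        frame = inputs["in"][0]
        if not self.params.get("enabled", True):
            return {"out": [frame]}
        if self.state.reference is None:
            self.state.reference = np.asarray(frame, dtype=np.float64)
            self.state.frame_index += 1
            res = motion.MCResult(self.state.reference,
                                  motion.WarpParams(0.0, 0.0, 0.0),
                                  1.0, "no_motion")
            self.results.append(_slim(res))
            return {"out": [self.state.reference]}
        res = motion.correct_frame(frame, self.state, self.log)
        # retain only the per-frame record, never the pixel data (a long
        # run would otherwise pin every corrected frame in memory)
        self.results.append(_slim(res))
        return {"out": [res.corrected_frame]}

    def estimated_track(self) -> np.ndarray:
        return np.array([[r.warp.tx, r.warp.ty, r.warp.theta]
                         for r in self.results])

    def statuses(self) -> list[str]:
        return [r.status for r in self.results]


def _slim(res: motion.MCResult) -> motion.MCResult:
    return motion.MCResult(None, res.warp, res.correlation, res.status,
                           res.tau1, res.tau2)


class PreprocessingActor(Actor):
    inputs = {"in": 1}
    outputs = {"out": 1}

    def __init__(self, name: str, config: preprocess.PreprocConfig):
        super().__init__(name)
        self.config = config

    def fire(self, inputs):
        return {"out": [preprocess.preprocess(inputs["in"][0], self.config)]}


class NeuronDetectionActor(Actor):
    inputs = {"in": 1}
    outputs = {"out": 1}

    def __init__(self, name: str, blob: detect.BlobParams, d: float = 2.0,
                 mode: str = "training", log: RunLog | None = None):
        super().__init__(name)
        self.blob = blob
        self.state = detect.TrainingState(d=d, mode=mode)
        self.log = log
        self.params.update(a_min=blob.a_min, a_max=blob.a_max,
                           threshold_step=blob.threshold_step, mode=mode)

    def on_param(self, key, value):
        if key in ("a_min", "a_max", "threshold_step"):
            self.blob = replace(self.blob, **{key: value})
        elif key == "mode":
            self.state.mode = value

    def fire(self, inputs):
        delta = detect.fire_detection(inputs["in"][0], self.state, self.blob,
                                      self.log)
        return {"out": [delta]}


class SignalExtractionActor(Actor):
    inputs = {"frame": 1, "delta": 1}
    outputs = {"out": 1}

    def __init__(self, name: str, baseline: signals.BaselineConfig):
        super().__init__(name)
        self.extractor = signals.SignalExtractor(baseline)

    def fire(self, inputs):
        beta = self.extractor.extract(inputs["frame"][0], inputs["delta"][0])
        return {"out": [beta]}


class SetParamsActor(Actor):
    """Subinit actor: calibrates blob parameters on the training frames."""

    inputs: dict[str, int] = {}
    outputs = {"a_min": 1, "a_max": 1, "threshold_step": 1}

    def __init__(self, name: str, training_frames: Sequence[np.ndarray],
                 cfg: adapt.AdaptConfig, preproc: preprocess.PreprocConfig,
                 log: RunLog | None = None):
        super().__init__(name)
        self.training_frames = training_frames
        self.cfg = cfg
        self.preproc = preproc
        self.log = log
        self.result: detect.BlobParams | None = None
        self._fired = False

    def ready(self) -> bool:
        return not self._fired

    def fire(self, inputs):
        frames = [preprocess.preprocess(f, self.preproc)
                  for f in self.training_frames]
        self.result = adapt.adapt_params(frames, self.cfg, self.log)
        self._fired = True
        return {"a_min": [self.result.a_min], "a_max": [self.result.a_max],
                "threshold_step": [self.result.threshold_step]}


# ---------------------------------------------------------------------------
# graph assembly and run modes
# ---------------------------------------------------------------------------

@dataclass
class SystemHandles:
    psdf: PSDFGraph
    img_src: SourceActor
    mc: MotionCorrectionActor
    det: NeuronDetectionActor
    sig: SignalExtractionActor
    det_sink: SinkActor
    sig_sink: SinkActor
    set_params: SetParamsActor | None
    log: RunLog


def build_system(frames: Iterable[np.ndarray], config: PipelineConfig,
                 training_frames: Sequence[np.ndarray] | None = None,
                 mode: str = "training",
                 delta_p: np.ndarray | None = None) -> SystemHandles:
    """Wire the full PSDF graph pair for one run.

    ``training_frames`` enables the subinit (SetParams) graph; without it
    the subinit is a stub that re-emits the configured blob parameters.
    ``delta_p`` seeds the detector's persistent matrix (real-time mode).
    """
    log = RunLog()
    body = Graph("body")
    img = body.add(SourceActor("ImgSrc", frames))
    mc = body.add(MotionCorrectionActor(
        "MotionCorrection", config.mc_p1, config.mc_p2, config.mc_downsample,
        enabled=config.motion_correction, log=log))
    fork1 = body.add(ForkActor("Fork1", 2))
    pre = body.add(PreprocessingActor("Preprocessing", config.preproc))
    det = body.add(NeuronDetectionActor("NeuronDetection", config.blob,
                                        config.d, mode, log))
    if delta_p is not None:
        det.state.delta_p = np.asarray(delta_p, dtype=np.float64).copy()
    fork2 = body.add(ForkActor("Fork2", 2))
    sig = body.add(SignalExtractionActor("SignalExtraction", config.baseline))
    det_sink = body.add(SinkActor("DetectionSink"))
    sig_sink = body.add(SinkActor("SignalSink"))
    body.connect(img, "out", mc, "in")
    body.connect(mc, "out", fork1, "in")
    body.connect(fork1, "out0", pre, "in")
    body.connect(fork1, "out1", sig, "frame")
    body.connect(pre, "out", det, "in")
    body.connect(det, "out", fork2, "in")
    body.connect(fork2, "out0", sig, "delta")
    body.connect(fork2, "out1", det_sink, "in")
    body.connect(sig, "out", sig_sink, "in")

    subinit = Graph("subinit")
    set_params = None
    if training_frames is not None:
        set_params = subinit.add(SetParamsActor(
            "SetParams", training_frames, config.adapt, config.preproc, log))
        bindings = [
            ParamBinding("SetParams.a_min", [("NeuronDetection", "a_min")]),
            ParamBinding("SetParams.a_max", [("NeuronDetection", "a_max")]),
            ParamBinding("SetParams.threshold_step",
                         [("NeuronDetection", "threshold_step")]),
        ]
    else:
        bindings = []
    psdf = PSDFGraph(body, subinit, bindings)
    return SystemHandles(psdf, img, mc, det, sig, det_sink, sig_sink,
                         set_params, log)


@dataclass
class RunResult:
    delta_p: np.ndarray
    blob_params: detect.BlobParams
    signal_table: np.ndarray
    estimated_track: np.ndarray
    statuses: list[str]
    corrected_frames: list[np.ndarray] | None
    log: RunLog


def run_initialization(frames: Sequence[np.ndarray], config: PipelineConfig,
                       n_training_frames: int | None = None,
                       keep_frames: bool = False) -> RunResult:
    """Initialization mode: SetParams calibration on the leading training
    frames, then training-mode body iterations over all supplied frames,
    accumulating the persistent detection matrix."""
    frames = list(frames)
    n_train = min(n_training_frames or len(frames), len(frames))
    handles = build_system(iter(frames), config,
                           training_frames=frames[:n_train],
                           mode="training")
    if keep_frames:
        tap = _tap_corrected(handles)
    handles.psdf.run(len(frames), handles.log)
    blob = handles.det.blob
    return RunResult(handles.det.state.delta_p.copy(), blob,
                     _stack_signals(handles.sig_sink.collected),
                     handles.mc.estimated_track(), handles.mc.statuses(),
                     tap if keep_frames else None, handles.log)


def run_realtime(frames: Sequence[np.ndarray], config: PipelineConfig,
                 delta_p: np.ndarray,
                 blob_params: detect.BlobParams | None = None,
                 keep_frames: bool = False) -> RunResult:
    """Real-time mode: the body graph iterates once per analysis frame with
    the detection matrix frozen (the subinit graph is effectively disabled
    for the duration of the run)."""
    frames = list(frames)
    if blob_params is not None:
        config = replace(config, blob=blob_params)
    handles = build_system(iter(frames), config, training_frames=None,
                           mode="realtime", delta_p=delta_p)
    if keep_frames:
        tap = _tap_corrected(handles)
    handles.psdf.run(len(frames), handles.log)
    return RunResult(handles.det.state.delta_p.copy(), handles.det.blob,
                     _stack_signals(handles.sig_sink.collected),
                     handles.mc.estimated_track(), handles.mc.statuses(),
                     tap if keep_frames else None, handles.log)


def _tap_corrected(handles: SystemHandles) -> list[np.ndarray]:
    collected: list[np.ndarray] = []
    original = handles.mc.fire

    def wrapper(inputs):
        out = original(inputs)
        frame = np.asarray(out["out"][0])
        if frame.dtype != np.uint8:  # store 8-bit so long runs stay small
            frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        collected.append(frame)
        return out

    handles.mc.fire = wrapper  # type: ignore[method-assign]
    return collected


def _stack_signals(rows: list[np.ndarray]) -> np.ndarray:
    if not rows:
        return np.empty((0, 0))
    nu = max(len(r) for r in rows)
    table = np.zeros((len(rows), nu))
    for i, r in enumerate(rows):
        table[i, :len(r)] = r          # columns appear at discovery; earlier
    return table                       # frames carry 0 for late neurons
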