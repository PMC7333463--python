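"""Minimal dataflow runtime for streaming image analysis.

Actors are computational tasks with declared per-port token rates; edges are
FIFO buffers holding references to images/matrices (tokens are never deep
copies of pixel data).  A demand-driven single-threaded scheduler fires the
most downstream enabled actor.  A parameterized (PSDF-style) pair of graphs
-- a *subinit* graph that computes parameter values and a *body* graph that
does the per-frame processing -- is supported through explicit parameter
bindings: each captured subinit output port is associated with one or more
(actor, parameter) targets in the body graph.
"""

from __future__ import annotations

import collections
from typing import Any, Iterable


class DataflowError(Exception):
    """Base class for runtime errors in the dataflow graph."""


class StructuralError(DataflowError):
    """Graph is malformed (unknown actor, unconnected port, bad binding)."""


class SchedulingError(DataflowError):
    """An actor was fired while not enabled."""


class DeadlockError(DataflowError):
    """No actor is enabled before the current graph iteration completed."""


class Token:
    """A unit of communicated data; holds a reference, never a pixel copy."""

    __slots__ = ("payload",)

    def __init__(self, payload: Any):
        self.payload = payload


class Edge:
    """FIFO buffer between two actor ports, with optional initial tokens."""

    def __init__(self, source: tuple[str, str], sink: tuple[str, str],
                 delay: int = 0, initial_payloads: Iterable[Any] | None = None,
                 watermark: int = 10_000):
        if delay < 0:
            raise StructuralError(f"negative delay on edge {source}->{sink}")
        self.source = source
        self.sink = sink
        self.delay = delay
        self.watermark = watermark
        self.queue: collections.deque[Token] = collections.deque()
        self.enqueued = 0
        self.dequeued = 0
        payloads = list(initial_payloads) if initial_payloads is not None else [None] * delay
        if len(payloads) != delay:
            raise StructuralError("initial payload count must equal delay")
        for p in payloads:
            self.queue.append(Token(p))

    @property
    def occupancy(self) -> int:
        return len(self.queue)

    def conserved(self) -> bool:
        """Token conservation: enqueued - dequeued + delay == occupancy."""
        return self.enqueued - self.dequeued + self.delay == len(self.queue)

    def push(self, token: Token) -> None:
        self.queue.append(token)
        self.enqueued += 1

    def pop(self) -> Token:
        self.dequeued += 1
        return self.queue.popleft()


class Actor:
    """Base actor: subclasses declare port rates and implement ``fire``.

    ``inputs`` / ``outputs`` map port name -> tokens consumed/produced per
    firing.  ``params`` holds named parameters that may be rebound between
    graph iterations (PSDF); ``state`` is whatever the subclass keeps across
    firings (equivalent to a self-loop edge).
    """

    inputs: dict[str, int] = {}
    outputs: dict[str, int] = {}

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, Any] = {}

    def set_param(self, key: str, value: Any) -> None:
        self.params[key] = value
        self.on_param(key, value)

    def on_param(self, key: str, value: Any) -> None:
        """Hook called when a parameter is (re)bound."""

    def ready(self) -> bool:
        """Extra firing condition beyond buffer state (e.g. stream not ended)."""
        return True

    def fire(self, inputs: dict[str, list[Any]]) -> dict[str, list[Any]]:
        raise NotImplementedError


class RunLog:
    """Chronological record of firings, bindings, and diagnostic messages."""

    def __init__(self):
        self.events: list[dict[str, Any]] = []

    def firing(self, actor: str) -> None:
        self.events.append({"kind": "firing", "actor": actor})

    def binding(self, port: str, actor: str, param: str, value: Any) -> None:
        self.events.append({"kind": "binding", "port": port, "actor": actor,
                            "param": param, "value": value})

    def message(self, text: str, frame: int | None = None) -> None:
        self.events.append({"kind": "message", "frame": frame, "text": text})

    def firings(self) -> list[str]:
        return [e["actor"] for e in self.events if e["kind"] == "firing"]

    def messages(self) -> list[dict[str, Any]]:
        return [e for e in self.events if e["kind"] == "message"]

    def bindings(self) -> list[dict[str, Any]]:
        return [e for e in self.events if e["kind"] == "binding"]

    def dump(self) -> str:
        lines = []
        for e in self.events:
            if e["kind"] == "firing":
                lines.append(f"fire {e['actor']}")
            elif e["kind"] == "binding":
                lines.append(f"bind {e['port']} -> {e['actor']}.{e['param']} = {e['value']}")
            else:
                frame = "" if e["frame"] is None else f"frame={e['frame']} "
                lines.append(f"msg {frame}{e['text']}")
        return "\n".join(lines)


class Graph:
    """A directed dataflow graph of actors and FIFO edges."""

    def __init__(self, kind: str = "body"):
        self.kind = kind
        self.actors: dict[str, Actor] = {}
        self.edges: list[Edge] = []
        self._in: dict[tuple[str, str], Edge] = {}
        self._out: dict[tuple[str, str], Edge] = {}

    def add(self, actor: Actor) -> Actor:
        if actor.name in self.actors:
            raise StructuralError(f"duplicate actor name {actor.name!r}")
        self.actors[actor.name] = actor
        return actor

    def connect(self, src: Actor | str, src_port: str, dst: Actor | str,
                dst_port: str, delay: int = 0,
                initial_payloads: Iterable[Any] | None = None) -> Edge:
        src_name = src if isinstance(src, str) else src.name
        dst_name = dst if isinstance(dst, str) else dst.name
        for name in (src_name, dst_name):
            if name not in self.actors:
                raise StructuralError(f"unknown actor {name!r}")
        if src_port not in self.actors[src_name].outputs:
            raise StructuralError(f"{src_name} has no output port {src_port!r}")
        if dst_port not in self.actors[dst_name].inputs:
            raise StructuralError(f"{dst_name} has no input port {dst_port!r}")
        edge = Edge((src_name, src_port), (dst_name, dst_port), delay,
                    initial_payloads)
        self.edges.append(edge)
        self._out[(src_name, src_port)] = edge
        self._in[(dst_name, dst_port)] = edge
        return edge

    def in_edges(self, actor: Actor) -> dict[str, Edge | None]:
        return {p: self._in.get((actor.name, p)) for p in actor.inputs}

    def out_edges(self, actor: Actor) -> dict[str, Edge | None]:
        return {p: self._out.get((actor.name, p)) for p in actor.outputs}

    def enabled(self, actor: Actor | str) -> bool:
        """True iff every input edge holds >= its declared consumption.

        Output capacity is logically unbounded, so output space never blocks
        a firing (a watermark warning is recorded at drain time instead).
        """
        if isinstance(actor, str):
            if actor not in self.actors:
                raise StructuralError(f"unknown actor {actor!r}")
            actor = self.actors[actor]
        elif actor.name not in self.actors or self.actors[actor.name] is not actor:
            raise StructuralError(f"actor {actor.name!r} not in graph")
        if not actor.ready():
            return False
        for port, rate in actor.inputs.items():
            edge = self._in.get((actor.name, port))
            if edge is None:
                raise StructuralError(f"unconnected input port {actor.name}.{port}")
            if edge.occupancy < rate:
                return False
        return True

    def fire(self, actor: Actor | str, log: RunLog | None = None) -> None:
        """Fire one actor: consume/produce the declared token counts."""
        if isinstance(actor, str):
            actor = self.actors[actor]
        if not self.enabled(actor):
            raise SchedulingError(f"actor {actor.name!r} fired while not enabled")
        inputs: dict[str, list[Any]] = {}
        for port, rate in actor.inputs.items():
            edge = self._in[(actor.name, port)]
            inputs[port] = [edge.pop().payload for _ in range(rate)]
        outputs = actor.fire(inputs) or {}
        for port, rate in actor.outputs.items():
            produced = outputs.get(port, [])
            if len(produced) != rate:
                raise SchedulingError(
                    f"{actor.name}.{port} produced {len(produced)} tokens, "
                    f"declared {rate}")
            edge = self._out.get((actor.name, port))
            if edge is None:
                continue  # unconnected output: tokens are dropped
            for payload in produced:
                edge.push(Token(payload))
            if edge.occupancy > edge.watermark and log is not None:
                log.message(f"watermark exceeded on edge {edge.source}->{edge.sink}")
        for edge in self.edges:
            if not edge.conserved():
                raise DataflowError(
                    f"token conservation violated on {edge.source}->{edge.sink}")
        if log is not None:
            log.firing(actor.name)

    # -- scheduling ------------------------------------------------------

    def topological_order(self) -> list[str]:
        indeg = {name: 0 for name in self.actors}
        for e in self.edges:
            if e.delay == 0:  # delayed edges break dependency cycles
                indeg[e.sink[0]] += 1
        order, queue = [], collections.deque(
            n for n in self.actors if indeg[n] == 0)
        succ: dict[str, list[str]] = {n: [] for n in self.actors}
        for e in self.edges:
            if e.delay == 0:
                succ[e.source[0]].append(e.sink[0])
        while queue:
            n = queue.popleft()
            order.append(n)
            for m in succ[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
        if len(order) != len(self.actors):
            raise StructuralError("zero-delay cycle in graph")
        return order

    def sources(self) -> list[str]:
        return [n for n, a in self.actors.items() if not a.inputs]

    def drain(self, log: RunLog | None = None) -> int:
        """Fire the most downstream enabled non-source actor until quiescent."""
        order = self.topological_order()
        rank = {n: i for i, n in enumerate(order)}
        srcs = set(self.sources())
        count = 0
        while True:
            candidates = [n for n in self.actors
                          if n not in srcs and self.enabled(n)]
            if not candidates:
                return count
            name = max(candidates, key=lambda n: rank[n])
            self.fire(name, log)
            count += 1

    def run_iteration(self, log: RunLog | None = None) -> bool:
        """One graph iteration: fire each source once, then drain downstream.

        Returns False (without firing anything) if some source cannot fire,
        e.g. its input stream has ended.
        """
        srcs = self.sources()
        if not all(self.enabled(s) for s in srcs):
            return False
        for s in srcs:
            self.fire(s, log)
        fired = self.drain(log)
        if srcs and fired == 0 and any(
                e.occupancy > 0 for e in self.edges):
            raise DeadlockError(
                "no actor enabled mid-iteration; buffer state: "
                + ", ".join(f"{e.source}->{e.sink}:{e.occupancy}"
                            for e in self.edges))
        return True


class ParamBinding:
    """Associates a captured subinit output port with body actor parameters."""

    def __init__(self, port: str, targets: list[tuple[str, str]]):
        self.port = port  # "<actor>.<output port>" in the subinit graph
        self.targets = targets  # [(body actor name, parameter name), ...]


class PSDFGraph:
    """A PSDF pair: subinit graph computing parameters for a body graph."""

    def __init__(self, body: Graph, subinit: Graph,
                 bindings: list[ParamBinding]):
        self.body = body
        self.subinit = subinit
        self.bindings = bindings
        for b in bindings:
            actor, port = b.port.split(".")
            if actor not in subinit.actors:
                raise StructuralError(f"binding source actor {actor!r} missing")
            if port not in subinit.actors[actor].outputs:
                raise StructuralError(f"binding port {b.port!r} missing")
            for tgt_actor, _ in b.targets:
                if tgt_actor not in body.actors:
                    raise StructuralError(
                        f"binding target actor {tgt_actor!r} not in body graph")
        # capture sinks collect the most recent token on each bound port
        self._captures: dict[str, "_Capture"] = {}
        for b in bindings:
            if b.port in self._captures:
                continue
            actor, port = b.port.split(".")
            cap = _Capture(f"__capture_{actor}_{port}")
            subinit.add(cap)
            subinit.connect(actor, port, cap, "in")
            self._captures[b.port] = cap

    def run(self, n_body_iterations: int, log: RunLog | None = None) -> RunLog:
        """Run the subinit once, push bound parameters, run the body n times.

        In real-time operation ``n_body_iterations`` equals the number of
        analysis frames, so the subinit graph is effectively disabled for the
        duration of the run.
        """
        if n_body_iterations < 0:
            raise ValueError("n_body_iterations must be >= 0")
        log = log if log is not None else RunLog()
        # one subinit iteration (sources + drain until quiescent)
        while self.subinit.run_iteration(log):
            if all(c.value is not _UNSET for c in self._captures.values()):
                break
        for b in self.bindings:
            cap = self._captures[b.port]
            if cap.value is _UNSET:
                raise DataflowError(f"subinit produced no value on {b.port}")
            for tgt_actor, param in b.targets:
                self.body.actors[tgt_actor].set_param(param, cap.value)
                log.binding(b.port, tgt_actor, param, cap.value)
        for _ in range(n_body_iterations):
            if not self.body.run_iteration(log):
                break
        return log


_UNSET = object()


class _Capture(Actor):
    inputs = {"in": 1}
    outputs: dict[str, int] = {}

    def __init__(self, name: str):
        super().__init__(name)
        self.value: Any = _UNSET

    def fire(self, inputs):
        self.value = inputs["in"][0]
        return {}


# -- small generic actors used across graphs -----------------------------

class SourceActor(Actor):
    """Emits successive items of an iterable, one per firing (ImgSrc body)."""

    inputs: dict[str, int] = {}
    outputs = {"out": 1}

    def __init__(self, name: str, items: Iterable[Any]):
        super().__init__(name)
        self._items = iter(items)
        self._next: Any = _UNSET
        self._advance()
        self.index = 0

    def _advance(self) -> None:
        try:
            self._next = next(self._items)
        except StopIteration:
            self._next = _UNSET

    def ready(self) -> bool:
        return self._next is not _UNSET

    def fire(self, inputs):
        item = self._next
        self._advance()
        self.index += 1
        return {"out": [item]}


class ForkActor(Actor):
    """Consumes one token, produces the identical payload reference on each
    of its outputs (fan-out fixed at construction time)."""

    inputs = {"in": 1}

    def __init__(self, name: str, fanout: int = 2):
        super().__init__(name)
        self.outputs = {f"out{i}": 1 for i in range(fanout)}

    def fire(self, inputs):
        payload = inputs["in"][0]
        return {port: [payload] for port in self.outputs}


class FunctionActor(Actor):
    """Wraps a unary function as a 1-in/1-out actor."""

    inputs = {"in": 1}
    outputs = {"out": 1}

    def __init__(self, name: str, fn):
        super().__init__(name)
        self.fn = fn

    def fire(self, inputs):
        return {"out": [self.fn(inputs["in"][0])]}


class SinkActor(Actor):
    """Collects every consumed payload (reference) in arrival order."""

    inputs = {"in": 1}
    outputs: dict[str, int] = {}

    def __init__(self, name: str):
        super().__init__(name)
        self.collected: list[Any] = []

    def fire(self, inputs):
        self.collected.append(inputs["in"][0])
        return {}
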