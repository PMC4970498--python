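"""Configuration-driven chaining of reduction operations over an event stream.

A chain is described in an INI file: each section is one stage, with a
reserved ``operation`` key naming a registered operation, ``input`` (comma
separated) binding the stage to earlier results, an optional ``condition``
naming a boolean result that gates execution, and the remaining keys passed
through as parameters.  Stages are topologically ordered before execution,
so the file order is irrelevant; cycles and references to undefined results
are configuration errors.

Per event, every stage runs at most once and its result is immutable for the
rest of that event (single-event consistency).  Conditional stages — and any
stage missing one of its inputs because an upstream stage was skipped — are
skipped for that event.  Accumulating stages (running averages, the powder
pattern, the hit-rate window, multi-event export) update exactly once per
event when their gate allows, and finalize after the stream ends.  A stage
failure skips the event with a logged reason and processing continues.
Execution is single-threaded and fully deterministic for a fixed
configuration and input stream.
"""

from __future__ import annotations

import ast
import configparser
import graphlib
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import darkcal as _darkcal
from . import peakfind as _peakfind
from . import radial as _radial
from .accumulators import RunningAverage
from .io_formats import OutputItem, write_multi_event_h5

logger = logging.getLogger(__name__)

__all__ = ["ChainConfig", "Stage", "ChainConfigError", "load_config", "run_chain",
           "available_operations"]

#: result names every event stream provides implicitly
_STREAM_INPUTS = ("frame", "event_id")


class ChainConfigError(ValueError):
    """Invalid chain configuration (unknown op, cycle, undefined input)."""


@dataclass(frozen=True)
class Stage:
    name: str
    operation: str
    inputs: tuple[str, ...]
    params: dict = field(default_factory=dict)
    condition: str | None = None


@dataclass
class ChainConfig:
    stages: list[Stage]

    @property
    def order(self) -> list[Stage]:
        """Stages in dependency (topological) order, stable in declaration order."""
        by_name = {s.name: s for s in self.stages}
        ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
        for s in self.stages:
            deps = [i for i in s.inputs if i in by_name]
            if s.condition and s.condition in by_name:
                deps.append(s.condition)
            ts.add(s.name, *deps)
        try:
            ordered = list(ts.static_order())
        except graphlib.CycleError as exc:
            raise ChainConfigError(f"stage cycle detected: {exc.args[1]}") from exc
        # static_order is stable only per insertion; enforce declaration order
        # among independent stages for reproducibility
        rank = {name: i for i, name in enumerate(ordered)}
        return sorted(self.stages, key=lambda s: rank[s.name])


# ---------------------------------------------------------------------------
# operation registry

@dataclass(frozen=True)
class _OpSpec:
    kind: str  # "event" | "accumulate" | "constant"
    make: object  # factory: (stage, resources) -> callable / accumulator


class _PowderAccumulator:
    def __init__(self) -> None:
        self.avg = RunningAverage()

    def add(self, inputs: dict, params: dict) -> None:
        self.avg.add(inputs["value"])

    def finalize(self):
        return self.avg.mean


class _AverageAccumulator(_PowderAccumulator):
    pass


class _HitRateAccumulator:
    def __init__(self, window: int = 2400) -> None:
        self.flags: deque = deque(maxlen=int(window))

    def add(self, inputs: dict, params: dict) -> None:
        self.flags.append(bool(inputs["value"]))

    def finalize(self):
        if not self.flags:
            return float("nan")
        return sum(self.flags) / len(self.flags)


class _MultiEventH5Accumulator:
    """Collects selected per-event results; writes one multi-event file at the end."""

    def __init__(self, path: str, names: tuple[str, ...], group: str = "data",
                 compress: bool = False) -> None:
        self.path = path
        self.names = names
        self.group = group
        self.compress = compress
        self.events: list[tuple[int, dict]] = []

    def add(self, inputs: dict, params: dict) -> None:
        self.events.append((int(inputs["event_id"]),
                            {n: np.asarray(inputs[n]) for n in self.names}))

    def finalize(self):
        items = [OutputItem(source_name=n, group_path=self.group) for n in self.names]
        write_multi_event_h5(self.events, items, self.path, compress=self.compress)
        return self.path


def _op_constant(stage: Stage, resources: dict):
    value = stage.params.get("value")

    def run(inputs: dict) -> object:
        return value

    return run


def _op_dark_correct(stage: Stage, resources: dict):
    cal = resources[stage.params.get("calibration", "calibration")]
    dialect = stage.params.get("dialect", "crystfel")

    def run(inputs: dict):
        return _darkcal.apply_correction(inputs[stage.inputs[0]], cal, dialect=dialect)

    return run


def _op_find_peaks(stage: Stage, resources: dict):
    keys = ("pixel_threshold", "box_half_width", "snr_background", "snr_peak",
            "min_npix", "saturation_threshold")
    params = {k: stage.params[k] for k in keys if k in stage.params}
    pf = _peakfind.PeakFinderParams(**params)
    mask = resources.get(stage.params.get("mask", "mask"))

    def run(inputs: dict):
        return _peakfind.find_peaks(inputs[stage.inputs[0]], pf, mask=mask)

    return run


def _op_count_peaks(stage: Stage, resources: dict):
    def run(inputs: dict):
        return _peakfind.count_peaks(inputs[stage.inputs[0]])

    return run


def _op_is_hit(stage: Stage, resources: dict):
    lo = stage.params.get("lower", 1)
    hi = stage.params.get("upper", float("inf"))

    def run(inputs: dict):
        return _peakfind.is_hit(inputs[stage.inputs[0]], (lo, hi))

    return run


def _op_radial_average(stage: Stage, resources: dict):
    geom = resources[stage.params.get("geometry", "geometry")]
    beam = resources[stage.params.get("beam", "beam")]
    mask = resources.get(stage.params.get("mask", "mask"))
    nbins = int(stage.params.get("nbins", 100))
    q_range = stage.params.get("q_range")

    def run(inputs: dict):
        prof = _radial.radial_average(inputs[stage.inputs[0]], geom, beam,
                                      mask=mask, nbins=nbins, q_range=q_range)
        return prof.values

    return run


_REGISTRY: dict[str, _OpSpec] = {
    "constant": _OpSpec("constant", _op_constant),
    "dark_correct": _OpSpec("event", _op_dark_correct),
    "find_peaks": _OpSpec("event", _op_find_peaks),
    "count_peaks": _OpSpec("event", _op_count_peaks),
    "is_hit": _OpSpec("event", _op_is_hit),
    "radial_average": _OpSpec("event", _op_radial_average),
    "powder": _OpSpec("accumulate", lambda stage, res: _PowderAccumulator()),
    "average": _OpSpec("accumulate", lambda stage, res: _AverageAccumulator()),
    "hit_rate": _OpSpec(
        "accumulate",
        lambda stage, res: _HitRateAccumulator(window=int(stage.params.get("window", 2400))),
    ),
    "write_multi_h5": _OpSpec(
        "accumulate",
        lambda stage, res: _MultiEventH5Accumulator(
            path=str(stage.params["path"]),
            names=tuple(stage.inputs),
            group=str(stage.params.get("group", "data")),
            compress=bool(stage.params.get("compress", False)),
        ),
    ),
}


def available_operations() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# configuration

_RESERVED_KEYS = {"operation", "input", "inputs", "condition"}


def _parse_value(raw: str):
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw


def load_config(source) -> ChainConfig:
    """Parse an INI chain description (path or text) into a :class:`ChainConfig`.

    Validates operation names, input references (against earlier stages and
    the implicit stream inputs) and acyclicity.
    """
    parser = configparser.ConfigParser()
    text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists() else str(source)
    parser.read_string(text)

    stages: list[Stage] = []
    for section in parser.sections():
        body = dict(parser.items(section))
        if "operation" not in body:
            raise ChainConfigError(f"stage [{section}] has no 'operation' key")
        op = body["operation"].strip()
        if op not in _REGISTRY:
            raise ChainConfigError(
                f"stage [{section}]: unknown operation {op!r}; "
                f"available: {', '.join(available_operations())}"
            )
        raw_inputs = body.get("inputs", body.get("input", ""))
        inputs = tuple(s.strip() for s in raw_inputs.split(",") if s.strip())
        condition = body.get("condition", "").strip() or None
        params = {k: _parse_value(v) for k, v in body.items() if k not in _RESERVED_KEYS}
        stages.append(Stage(name=section, operation=op, inputs=inputs,
                            params=params, condition=condition))

    known = set(_STREAM_INPUTS)
    names = {s.name for s in stages}
    for s in stages:
        for inp in s.inputs:
            if inp not in known and inp not in names:
                raise ChainConfigError(
                    f"stage [{s.name}] references undefined result {inp!r}"
                )
        if s.condition and s.condition not in names and s.condition not in known:
            raise ChainConfigError(
                f"stage [{s.name}] condition references undefined result {s.condition!r}"
            )
    config = ChainConfig(stages=stages)
    config.order  # raises on cycles
    return config


def run_chain(config: ChainConfig, frames, resources: dict | None = None):
    """Execute a chain over an event stream.

    ``frames`` yields ``(event_id, frame)`` pairs (a :class:`FrameStack`
    iterates this way).  ``resources`` supplies constant objects referenced
    by stage parameters (calibration, geometry, beam, mask...).

    Returns ``(records, accumulated)``: one dict of per-event stage results
    per event (skipped stages absent), and the finalized accumulator values
    keyed by stage name.
    """
    resources = resources or {}
    ordered = config.order

    runners: dict[str, object] = {}
    accumulators: dict[str, object] = {}
    for s in ordered:
        spec = _REGISTRY[s.operation]
        made = spec.make(s, resources)
        if spec.kind == "accumulate":
            accumulators[s.name] = made
        else:
            runners[s.name] = made

    records: list[dict] = []
    for event_id, frame in frames:
        results: dict = {"frame": frame, "event_id": event_id}
        failed = False
        for s in ordered:
            if s.condition is not None:
                if s.condition not in results or not results[s.condition]:
                    continue
            if any(i not in results for i in s.inputs):
                continue  # upstream stage skipped for this event
            try:
                if s.name in accumulators:
                    acc = accumulators[s.name]
                    acc.add({**{i: results[i] for i in s.inputs},
                             "value": results[s.inputs[0]] if s.inputs else None,
                             "event_id": event_id}, s.params)
                else:
                    results[s.name] = runners[s.name](results)
            except Exception:
                logger.exception("event %s: stage [%s] failed; skipping event",
                                 event_id, s.name)
                failed = True
                break
        if failed:
            continue
        records.append({k: v for k, v in results.items()
                        if k not in ("frame",) and k not in accumulators})

    accumulated = {name: acc.finalize() for name, acc in accumulators.items()}
    return records, accumulated
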