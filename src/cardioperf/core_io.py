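"""Domain types and delimited-text I/O for perfusion recordings.

The atomic unit of the pipeline is a :class:`Recording` — a contraction
frequency time series in contractions/min on a minutes-from-registration
time axis — together with a :class:`ProtocolSpec` describing the perfusion
timeline (which solution flowed when, plus optional bolus pulses).

Time convention: minutes from registration start, 0-based.  Perfusion
segments are half-open intervals ``[t_start, t_end)``; any preincubation
before registration is not part of the axis.
"""

from __future__ import annotations

import csv
import io
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CardioperfError",
    "ParseError",
    "ValidationError",
    "Segment",
    "Pulse",
    "ProtocolSpec",
    "RecordingMeta",
    "Recording",
    "Trace",
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_protocol",
    "write_protocol",
    "read_trace",
    "write_trace",
    "write_report",
    "fmt6",
]

logger = logging.getLogger("cardioperf")

_TOL = 1e-9

#: default compound window for the continuous-perfusion variant (minutes)
DEFAULT_EXPOSURE_WINDOW = (4.0, 13.5)
#: default bolus time for the pulse-application variant (minutes)
DEFAULT_PULSE_TIME = 8.0
#: default registration length (minutes)
DEFAULT_DURATION = 22.0


class CardioperfError(Exception):
    """Base class for all package errors."""


class ParseError(CardioperfError):
    """A delimited-text or config file could not be interpreted."""


class ValidationError(CardioperfError):
    """A domain object violates its invariants."""


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One perfusion stretch ``[t_start, t_end)`` with a single solution."""

    t_start: float
    t_end: float
    solution_id: str
    concentration: float = 0.0  # mol/L; 0 for plain saline


@dataclass(frozen=True)
class Pulse:
    """A single bolus injected into the perfusion line at ``t_apply``."""

    t_apply: float
    solution_id: str
    concentration: float  # mol/L of the injected solution
    bolus_volume_fraction: float = 1.0  # dilution into chamber volume


@dataclass(frozen=True)
class ProtocolSpec:
    """Validated perfusion timeline shared by the simulator and the metrics.

    Segments must be ordered, contiguous and cover ``[0, total_duration]``
    exactly; gaps and overlaps are rejected, never repaired.
    """

    total_duration: float
    segments: tuple[Segment, ...]
    pulses: tuple[Pulse, ...] = ()
    flow_rate: float | None = None  # µL/min, metadata only

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValidationError(f"total_duration must be > 0, got {self.total_duration}")
        if not self.segments:
            raise ValidationError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "pulses", tuple(self.pulses))
        cursor = 0.0
        for i, seg in enumerate(self.segments):
            if seg.t_end <= seg.t_start:
                raise ValidationError(f"segment {i} ({seg.solution_id}): empty or reversed interval [{seg.t_start}, {seg.t_end})")
            if abs(seg.t_start - cursor) > _TOL:
                kind = "gap" if seg.t_start > cursor else "overlap"
                raise ValidationError(f"segment {i} ({seg.solution_id}): {kind} at t={cursor:g} min (segment starts at {seg.t_start:g})")
            if seg.concentration < 0:
                raise ValidationError(f"segment {i} ({seg.solution_id}): negative concentration {seg.concentration}")
            cursor = seg.t_end
        if abs(cursor - self.total_duration) > _TOL:
            raise ValidationError(f"segments end at {cursor:g} min but total_duration is {self.total_duration:g}")
        for j, p in enumerate(self.pulses):
            if not (0.0 <= p.t_apply <= self.total_duration):
                raise ValidationError(f"pulse {j} ({p.solution_id}): t_apply={p.t_apply:g} outside [0, {self.total_duration:g}]")
            if p.concentration < 0:
                raise ValidationError(f"pulse {j} ({p.solution_id}): negative concentration")
            if not (0 < p.bolus_volume_fraction <= 1):
                raise ValidationError(f"pulse {j} ({p.solution_id}): bolus_volume_fraction must be in (0, 1]")

    # -- queries -----------------------------------------------------------

    def segment_at(self, t: float) -> Segment:
        """Segment active at time ``t`` (last segment is closed at its end)."""
        if not (-_TOL <= t <= self.total_duration + _TOL):
            raise ValidationError(f"t={t:g} outside protocol span")
        for seg in self.segments:
            if seg.t_start - _TOL <= t < seg.t_end - _TOL:
                return seg
        return self.segments[-1]

    @property
    def solution_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            if seg.concentration > 0:
                seen.setdefault(seg.solution_id)
        for p in self.pulses:
            seen.setdefault(p.solution_id)
        return tuple(seen)

    def exposure_window(self) -> tuple[float, float]:
        """(onset, end) of drug exposure: span of non-zero-concentration
        segments, or the pulse time(s) if only pulses carry drug."""
        active = [s for s in self.segments if s.concentration > 0]
        if active:
            return (min(s.t_start for s in active), max(s.t_end for s in active))
        if self.pulses:
            return (min(p.t_apply for p in self.pulses), self.total_duration)
        raise ValidationError("protocol has no drug exposure (all saline, no pulses)")

    @property
    def has_exposure(self) -> bool:
        return any(s.concentration > 0 for s in self.segments) or bool(self.pulses)


def saline_protocol(total_duration: float = DEFAULT_DURATION) -> ProtocolSpec:
    """Control protocol: plain saline for the whole registration."""
    return ProtocolSpec(total_duration, (Segment(0.0, total_duration, "saline", 0.0),))


def continuous_protocol(
    treatment: Mapping[str, float],
    window: tuple[float, float] = DEFAULT_EXPOSURE_WINDOW,
    total_duration: float = DEFAULT_DURATION,
) -> ProtocolSpec:
    """Variant A: saline, then compound(s) perfused on ``window``, then
    saline again.  ``treatment`` maps solution id → mol/L.

    A multi-compound treatment becomes a single segment with the composite
    solution id ``"a+b"`` and the summed concentration; the per-compound
    composition is declared to the simulator via ``PDParams.solutions``.
    """
    t0, t1 = window
    if not treatment:
        raise ValidationError("continuous_protocol needs at least one compound")
    items = list(treatment.items())
    if len(items) == 1:
        sid, conc = items[0]
    else:
        sid = "+".join(k for k, _ in items)
        conc = sum(v for _, v in items)
    segs: list[Segment] = []
    if t0 > 0:
        segs.append(Segment(0.0, t0, "saline", 0.0))
    segs.append(Segment(t0, t1, sid, conc))
    if t1 < total_duration:
        segs.append(Segment(t1, total_duration, "saline", 0.0))
    return ProtocolSpec(total_duration, tuple(segs))


def pulse_protocol(
    carrier: Mapping[str, float],
    pulse_solution: str,
    pulse_concentration: float,
    t_pulse: float = DEFAULT_PULSE_TIME,
    bolus_volume_fraction: float = 1.0,
    window: tuple[float, float] = DEFAULT_EXPOSURE_WINDOW,
    total_duration: float = DEFAULT_DURATION,
) -> ProtocolSpec:
    """Variant B: continuous perfusion with ``carrier`` plus one bolus."""
    base = continuous_protocol(carrier, window, total_duration)
    return replace(base, pulses=(Pulse(t_pulse, pulse_solution, pulse_concentration, bolus_volume_fraction),))


# ---------------------------------------------------------------------------
# recording / trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecordingMeta:
    preparation_id: str = "prep"
    compound_ids: tuple[str, ...] = ()
    concentrations: tuple[float, ...] = ()
    variant: str = "control"  # control | A_continuous | B_pulse
    protocol: ProtocolSpec | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("control", "A_continuous", "B_pulse"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if len(self.compound_ids) != len(self.concentrations):
            raise ValidationError("compound_ids and concentrations differ in length")


@dataclass(frozen=True)
class Recording:
    """A contraction-frequency time series (contractions/min vs minutes)."""

    times: np.ndarray
    frequencies: np.ndarray
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "frequencies", f)
        if t.ndim != 1 or f.ndim != 1 or t.shape != f.shape:
            raise ValidationError("times and frequencies must be 1-D and equally long")
        # single-point recordings are tolerated for coarse bins (one value
        # per registration); everything below 1 point is meaningless
        if t.size < 1:
            raise ValidationError("recording needs at least one sample")
        if np.any(np.diff(t) <= 0):
            bad = t[1:][np.diff(t) <= 0][0]
            raise ValidationError(f"times must be strictly increasing (violated near t={bad:g})")
        if np.any(f < 0):
            raise ValidationError("negative contraction frequency")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Trace:
    """Raw optical-density signal (arbitrary units), uniformly sampled."""

    sample_rate: float  # samples/s
    values: np.ndarray
    duration: float  # s
    ground_truth_beats: np.ndarray | None = None  # s, simulator only

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        expected = round(self.duration * self.sample_rate)
        if v.size != expected:
            raise ValidationError(f"values has {v.size} samples, expected round(duration*sample_rate) = {expected}")
        if self.ground_truth_beats is not None:
            object.__setattr__(self, "ground_truth_beats", np.asarray(self.ground_truth_beats, dtype=float))


@dataclass(frozen=True)
class RunConfig:
    """Analysis knobs shared across stages."""

    baseline_window: tuple[float, float] = (0.0, 1.0)
    binning: float = 0.5  # minutes per frequency bin
    smoothing: float | None = None  # moving-mean width (minutes), None = off
    half_time_method: str = "interp"  # interp | fit
    classification_delta: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_window[1] <= self.baseline_window[0]:
            raise ValidationError("empty baseline window")
        if self.binning <= 0:
            raise ValidationError("binning must be > 0")
        if self.classification_delta < 0:
            raise ValidationError("classification tolerance must be >= 0")
        if self.half_time_method not in ("interp", "fit"):
            raise ValidationError(f"unknown half_time_method {self.half_time_method!r}")


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

_TIME_FACTORS = {"min": 1.0, "minute": 1.0, "minutes": 1.0, "s": 1.0 / 60.0, "sec": 1.0 / 60.0}
_FREQ_FACTORS = {"cpm": 1.0, "contractions_per_min": 1.0, "per_min": 1.0, "hz": 60.0}


def _parse_header_block(path: Path) -> tuple[dict[str, str], str]:
    """Split leading ``# key: value`` comment lines from the table body."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    k, _, v = stripped.partition(":")
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _sniff_delimiter(body: str) -> str:
    first = body.splitlines()[0] if body.splitlines() else ""
    if "\t" in first:
        return "\t"
    if ";" in first and "," not in first:
        return ";"
    return ","


def _meta_from_header(header: Mapping[str, str], prep_id: str) -> RecordingMeta:
    compounds = tuple(c for c in header.get("compound_ids", "").split() if c)
    concs = tuple(float(c) for c in header.get("concentrations", "").split() if c)
    if compounds and not concs:
        concs = (0.0,) * len(compounds)
    return RecordingMeta(
        preparation_id=header.get("preparation_id", prep_id),
        compound_ids=compounds,
        concentrations=concs,
        variant=header.get("variant", "control"),
    )


def read_recording(path: str | Path, fmt: str = "auto") -> list[Recording]:
    """Read one or more recordings from a delimited-text file.

    Two layouts are understood: *tidy-long* (columns ``time_min``, ``freq``
    and optionally ``preparation_id``) and *wide-matrix* (a time column
    followed by one column per preparation).  Comment lines ``# key: value``
    at the top declare units and metadata (``time_unit``, ``freq_unit``,
    ``compound_ids``, ``concentrations``, ``variant``).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    header, body = _parse_header_block(path)
    if not body.strip():
        raise ParseError(f"{path}: no data rows")
    delim = _sniff_delimiter(body)
    reader = csv.reader(io.StringIO(body), delimiter=delim)
    rows = [r for r in reader if any(cell.strip() for cell in r)]
    columns = [c.strip() for c in rows[0]]
    data_rows = rows[1:]
    if not data_rows:
        raise ParseError(f"{path}: header only, no data rows")

    t_factor = _TIME_FACTORS.get(header.get("time_unit", "min").lower())
    f_factor = _FREQ_FACTORS.get(header.get("freq_unit", "cpm").lower())
    if t_factor is None:
        raise ParseError(f"{path}: unknown time_unit {header.get('time_unit')!r}")
    if f_factor is None:
        raise ParseError(f"{path}: unknown freq_unit {header.get('freq_unit')!r}")

    lower = [c.lower() for c in columns]
    if fmt == "auto":
        fmt = "tidy" if any(c in ("freq", "frequency") for c in lower) else "wide"

    def parse_float(cell: str, row_no: int, col: str) -> float:
        try:
            return float(cell)
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_no}: bad number {cell!r} in column {col!r}") from exc

    recordings: list[Recording] = []
    if fmt == "tidy":
        try:
            t_idx = next(i for i, c in enumerate(lower) if c.startswith("time"))
            f_idx = next(i for i, c in enumerate(lower) if c in ("freq", "frequency"))
        except StopIteration as exc:
            raise ParseError(f"{path}: tidy layout needs time* and freq columns, got {columns}") from exc
        g_idx = next((i for i, c in enumerate(lower) if c in ("preparation_id", "prep", "preparation")), None)
        groups: dict[str, list[tuple[float, float]]] = {}
        for row_no, row in enumerate(data_rows, start=2):
            key = row[g_idx].strip() if g_idx is not None else header.get("preparation_id", "prep")
            t = parse_float(row[t_idx], row_no, columns[t_idx]) * t_factor
            f = parse_float(row[f_idx], row_no, columns[f_idx]) * f_factor
            groups.setdefault(key, []).append((t, f))
        for key, pts in groups.items():
            times = [p[0] for p in pts]
            seen: set[float] = set()
            for t in times:
                if t in seen:
                    raise ParseError(f"{path}: duplicate time point t={t:g} for preparation {key!r}")
                seen.add(t)
            order = np.argsort(times)
            arr_t = np.asarray(times, float)[order]
            arr_f = np.asarray([p[1] for p in pts], float)[order]
            if np.any(arr_f < 0):
                bad = arr_t[arr_f < 0][0]
                raise ValidationError(f"{path}: negative frequency at t={bad:g} for preparation {key!r}")
            recordings.append(Recording(arr_t, arr_f, _meta_from_header(header, key)))
    elif fmt == "wide":
        t_col = columns[0]
        times: list[float] = []
        matrix: list[list[float]] = []
        for row_no, row in enumerate(data_rows, start=2):
            t = parse_float(row[0], row_no, t_col) * t_factor
            if t in times:
                raise ParseError(f"{path}: duplicate time point t={t:g}")
            times.append(t)
            matrix.append([parse_float(cell, row_no, columns[j + 1]) * f_factor for j, cell in enumerate(row[1:])])
        arr_t = np.asarray(times, float)
        order = np.argsort(arr_t)
        arr = np.asarray(matrix, float)[order]
        arr_t = arr_t[order]
        for j, prep in enumerate(columns[1:]):
            col = arr[:, j]
            if np.any(col < 0):
                raise ValidationError(f"{path}: negative frequency in column {prep!r}")
            recordings.append(Recording(arr_t, col, _meta_from_header(header, prep)))
    else:
        raise ParseError(f"unknown format {fmt!r}")
    return recordings


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write one recording as tidy CSV with a metadata header block.

    Numbers use ``repr`` so a read-back round-trips to full precision.
    """
    path = Path(path)
    m = rec.meta
    lines = [
        "# time_unit: min",
        "# freq_unit: cpm",
        f"# preparation_id: {m.preparation_id}",
        f"# variant: {m.variant}",
    ]
    if m.compound_ids:
        lines.append("# compound_ids: " + " ".join(m.compound_ids))
        lines.append("# concentrations: " + " ".join(repr(float(c)) for c in m.concentrations))
    lines.append("time_min,freq")
    for t, f in zip(rec.times, rec.frequencies):
        lines.append(f"{float(t)!r},{float(f)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_trace(trace: Trace, path: str | Path) -> None:
    """Raw trace as CSV (``t_s,value``) with sampling metadata up top."""
    path = Path(path)
    lines = [f"# sample_rate: {trace.sample_rate!r}", f"# duration: {trace.duration!r}", "t_s,value"]
    dt = 1.0 / trace.sample_rate
    for i, v in enumerate(trace.values):
        lines.append(f"{i * dt:.6f},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    header, body = _parse_header_block(path)
    if "sample_rate" not in header:
        raise ParseError(f"{path}: trace file must declare '# sample_rate: <Hz>'")
    sample_rate = float(header["sample_rate"])
    rows = body.strip().splitlines()
    if not rows or not rows[0].lower().startswith("t_s"):
        raise ParseError(f"{path}: expected a 't_s,value' header row")
    values = np.asarray([float(r.split(",")[1]) for r in rows[1:]], dtype=float)
    duration = float(header.get("duration", values.size / sample_rate))
    return Trace(sample_rate=sample_rate, values=values, duration=duration)


# ---------------------------------------------------------------------------
# protocol I/O (flat YAML)
# ---------------------------------------------------------------------------


def read_protocol(path: str | Path) -> ProtocolSpec:
    """Load a :class:`ProtocolSpec` from a YAML file.

    Schema::

        total_duration: 22
        flow_rate: 300            # optional
        segments:
          - {start: 0, end: 4, solution: saline, concentration: 0}
          - {start: 4, end: 13.5, solution: ver, concentration: 3.0e-5}
          - {start: 13.5, end: 22, solution: saline, concentration: 0}
        pulses:                   # optional
          - {time: 8, solution: sol, concentration: 1.0e-5, bolus_fraction: 1.0}
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return protocol_from_dict(doc, where=str(path))


def protocol_from_dict(doc: Mapping, where: str = "<config>") -> ProtocolSpec:
    try:
        total = float(doc["total_duration"])
        segs = tuple(
            Segment(float(s["start"]), float(s["end"]), str(s["solution"]), float(s.get("concentration", 0.0)))
            for s in doc.get("segments", [])
        )
        pulses = tuple(
            Pulse(float(p["time"]), str(p["solution"]), float(p["concentration"]), float(p.get("bolus_fraction", 1.0)))
            for p in doc.get("pulses", [])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{where}: malformed protocol entry: {exc!r}") from exc
    flow = doc.get("flow_rate")
    return ProtocolSpec(total, segs, pulses, None if flow is None else float(flow))


def protocol_to_dict(proto: ProtocolSpec) -> dict:
    doc: dict = {
        "total_duration": proto.total_duration,
        "segments": [
            {"start": s.t_start, "end": s.t_end, "solution": s.solution_id, "concentration": s.concentration}
            for s in proto.segments
        ],
    }
    if proto.pulses:
        doc["pulses"] = [
            {"time": p.t_apply, "solution": p.solution_id, "concentration": p.concentration, "bolus_fraction": p.bolus_volume_fraction}
            for p in proto.pulses
        ]
    if proto.flow_rate is not None:
        doc["flow_rate"] = proto.flow_rate
    return doc


def write_protocol(proto: ProtocolSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(proto), sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def fmt6(x: object) -> str:
    """Render a number with 6 significant digits (deterministic output)."""
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    xf = float(x)
    if np.isnan(xf):
        return "nan"
    return f"{xf:.6g}"


def write_report(
    summaries: Sequence[Mapping[str, object]],
    path: str | Path,
    interactions: Sequence[Mapping[str, object]] = (),
    config_echo: Mapping[str, object] | None = None,
) -> tuple[Path, Path]:
    """Write the machine-readable summary table and a human-readable report.

    ``path`` is the stem: ``<path>.csv`` (deterministic, 6 significant
    digits) and ``<path>.txt``.  Identical inputs + config give
    byte-identical CSV output.
    """
    if not summaries:
        raise ValidationError("no results to report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    cols: list[str] = []
    for row in summaries:
        for key in row:
            if key not in cols:
                cols.append(key)
    csv_path = path.with_suffix(".csv")
    lines = [",".join(cols)]
    for row in summaries:
        lines.append(",".join(fmt6(row.get(c)) if not isinstance(row.get(c), str) else str(row.get(c)) for c in cols))
    csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    txt_path = path.with_suffix(".txt")
    out = ["cardioperf run report", "====================", ""]
    if config_echo:
        out.append("configuration:")
        for k, v in config_echo.items():
            out.append(f"  {k}: {v}")
        out.append("")
    out.append(f"python: {sys.version.split()[0]}  numpy: {np.__version__}")
    out.append(f"recordings summarised: {len(summaries)}")
    if interactions:
        out.append("")
        out.append("interaction results:")
        for row in interactions:
            out.append("  " + ", ".join(f"{k}={fmt6(v) if not isinstance(v, str) else v}" for k, v in row.items()))
    txt_path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return csv_path, txt_path
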