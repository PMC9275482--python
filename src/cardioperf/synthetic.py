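"""Synthetic perfusion recordings and densitometric traces.

Generates contraction-frequency series and raw optical traces with the
structure the analysis stack assumes: a stable baseline rhythm, reversible
concentration-dependent bradycardia with first-order onset/washout
kinetics, and configurable additive/antagonistic mixture behaviour.  Every
downstream stage can therefore be tested against known ground truth.

Model
-----
Chamber concentration is a step function over perfusion segments
(perfusion treated as instantaneous medium exchange); a bolus pulse adds an
instantaneous rise followed by exponential clearance at ``pulse_decay``.
The equilibrium percent-change effect of a single inhibitor follows a Hill
curve ``E_eq(C) = E_max * C^h / (C^h + EC50^h)``.  The realised effect
state relaxes toward equilibrium with separate deepening and recovery
rates::

    dE/dt = k_on  * (E_eq - E)   if E_eq <= E   (effect deepening)
    dE/dt = k_off * (E_eq - E)   otherwise      (washout / recovery)

Instantaneous frequency is ``f0 * (1 + E/100)`` plus linear drift and
additive Gaussian noise, truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    ProtocolSpec,
    Recording,
    RecordingMeta,
    Trace,
    ValidationError,
)

__all__ = [
    "CompoundPD",
    "PDParams",
    "concentration_trajectory",
    "equilibrium_effect",
    "effect_state",
    "simulate_frequency_series",
    "simulate_cohort",
    "simulate_trace",
]

INTERACTION_MODES = ("independent", "additive", "antagonistic")

# default noise profile reproducing the reference assay's control stability
# (per-minute drift of the saline-perfused heart stays inside +-3%)
DEFAULT_NOISE_SD_FREQ = 0.5  # contractions/min per sample
DEFAULT_BASELINE_DRIFT_SD = 0.5  # % of f0 over a full recording


@dataclass(frozen=True)
class CompoundPD:
    """Equilibrium concentration-effect parameters of one inhibitor."""

    e_max: float  # maximal % change, in [-100, 0] for inhibitors
    ec50: float  # mol/L
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (-100.0 <= self.e_max <= 0.0):
            raise ValidationError(f"e_max must be in [-100, 0], got {self.e_max}")
        if self.ec50 <= 0:
            raise ValidationError("ec50 must be > 0")
        if self.hill <= 0:
            raise ValidationError("hill must be > 0")


@dataclass(frozen=True)
class PDParams:
    """Full parameter set of the generator.

    ``potency`` maps compound ids to their Hill parameters.  ``solutions``
    optionally maps composite solution labels (e.g. ``"ver+sol"``) to a
    per-compound concentration breakdown, letting a single perfusion
    segment deliver a mixture.
    """

    potency: Mapping[str, CompoundPD] = field(default_factory=dict)
    f0: float = 60.0  # contractions/min; placeholder default, no published value exists
    k_on: float = 1.0  # 1/min
    k_off: float = 0.5  # 1/min
    pulse_decay: float = 1.0  # 1/min
    noise_sd_freq: float = 0.0  # contractions/min, per output sample
    baseline_drift_sd: float = 0.0  # % of f0 over the full recording
    interaction_mode: str = "independent"
    antagonism_lambda: float = 1.0  # scales the additive joint effect
    solutions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValidationError("f0 must be > 0")
        for name, rate in (("k_on", self.k_on), ("k_off", self.k_off), ("pulse_decay", self.pulse_decay)):
            if rate <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.noise_sd_freq < 0 or self.baseline_drift_sd < 0:
            raise ValidationError("noise terms must be >= 0")
        if self.interaction_mode not in INTERACTION_MODES:
            raise ValidationError(f"interaction_mode must be one of {INTERACTION_MODES}")
        if not (0.0 <= self.antagonism_lambda <= 1.0):
            raise ValidationError("antagonism_lambda must be in [0, 1]")

    def with_mixture(self, label: str, composition: Mapping[str, float]) -> "PDParams":
        sols = dict(self.solutions)
        sols[label] = dict(composition)
        return replace(self, solutions=sols)


# ---------------------------------------------------------------------------
# chamber concentrations
# ---------------------------------------------------------------------------


def _resolve_solution(params: PDParams, solution_id: str, concentration: float) -> dict[str, float]:
    """Per-compound mol/L delivered by one solution at the given strength."""
    if solution_id in params.solutions:
        return dict(params.solutions[solution_id])
    if solution_id in params.potency:
        return {solution_id: concentration}
    return {}  # saline or any solution without pharmacology


def concentration_trajectory(
    protocol: ProtocolSpec, params: PDParams, dt: float = 0.5
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Chamber concentration of each known compound on a uniform grid.

    Returns ``(times, {compound_id: mol/L array})``.  Within a segment the
    concentration is the segment's (step model); each pulse adds a bolus
    that decays exponentially at ``params.pulse_decay``.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    n = int(round(protocol.total_duration / dt))
    times = np.arange(n + 1) * dt
    times[-1] = min(times[-1], protocol.total_duration)
    concs: dict[str, np.ndarray] = {cid: np.zeros_like(times) for cid in params.potency}
    for seg in protocol.segments:
        mask = (times >= seg.t_start - 1e-12) & (times < seg.t_end - 1e-12)
        if seg is protocol.segments[-1]:
            mask |= times >= seg.t_end - 1e-12  # close the final segment
        for cid, c in _resolve_solution(params, seg.solution_id, seg.concentration).items():
            if cid in concs:
                concs[cid][mask] = c
    for p in protocol.pulses:
        for cid, c in _resolve_solution(params, p.solution_id, p.concentration).items():
            if cid not in concs:
                continue
            after = times >= p.t_apply - 1e-12
            concs[cid][after] += c * p.bolus_volume_fraction * np.exp(-params.pulse_decay * (times[after] - p.t_apply))
    return times, concs


# ---------------------------------------------------------------------------
# equilibrium effect
# ---------------------------------------------------------------------------


def _hill(c: np.ndarray | float, pd: CompoundPD) -> np.ndarray | float:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative concentration")
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.power(c, pd.hill)
        out = pd.e_max * num / (num + pd.ec50**pd.hill)
    return np.where(c > 0, out, 0.0)


def equilibrium_effect(conc: Mapping[str, float | np.ndarray] | float, params: PDParams) -> np.ndarray | float:
    """Steady-state percent change for the given chamber concentration(s).

    A scalar is accepted when exactly one compound is parameterised.  Joint
    effects of several compounds combine according to
    ``params.interaction_mode``:

    * ``independent`` — multiplicative survival of relative frequency:
      ``100 * (prod_i (1 + e_i/100) - 1)``
    * ``additive`` — ``sum_i e_i`` floored at −100
    * ``antagonistic`` — ``lambda * additive``, lambda in [0, 1]
    """
    if not isinstance(conc, Mapping):
        if len(params.potency) != 1:
            raise ValidationError("scalar concentration is ambiguous with several compounds")
        (pd,) = params.potency.values()
        return _hill(conc, pd)
    effects = []
    for cid, c in conc.items():
        if cid not in params.potency:
            raise ValidationError(f"no potency parameters for compound {cid!r}")
        effects.append(np.asarray(_hill(c, params.potency[cid]), dtype=float))
    if not effects:
        return 0.0
    if len(effects) == 1:
        out = effects[0]
    elif params.interaction_mode == "independent":
        surv = np.ones_like(effects[0])
        for e in effects:
            surv = surv * (1.0 + e / 100.0)
        out = 100.0 * (surv - 1.0)
    else:
        out = np.maximum(sum(effects), -100.0)
        if params.interaction_mode == "antagonistic":
            out = params.antagonism_lambda * out
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def effect_state(protocol: ProtocolSpec, params: PDParams, dt: float = 0.5, substeps: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic effect trajectory E(t) on the output grid.

    Integrates the asymmetric first-order relaxation with explicit Euler on
    an internal grid no coarser than 0.01 min, then returns every
    ``substeps``-th point so the output lands exactly on multiples of
    ``dt``.
    """
    if substeps is None:
        substeps = max(1, int(math.ceil(dt / 0.01)))
    dti = dt / substeps
    times_fine, concs = concentration_trajectory(protocol, params, dti)
    if params.potency:
        e_eq = np.asarray(equilibrium_effect(concs, params), dtype=float)
    else:
        e_eq = np.zeros_like(times_fine)
    e = np.empty_like(e_eq)
    e[0] = 0.0
    state = 0.0
    k_on, k_off = params.k_on, params.k_off
    for i in range(1, e_eq.size):
        target = e_eq[i - 1]
        k = k_on if target <= state else k_off
        state += dti * k * (target - state)
        state = max(state, -100.0)
        e[i] = state
    return times_fine[::substeps], e[::substeps]


def _variant_of(protocol: ProtocolSpec) -> str:
    if protocol.pulses:
        return "B_pulse"
    return "A_continuous" if any(s.concentration > 0 for s in protocol.segments) else "control"


def _meta_for(protocol: ProtocolSpec, params: PDParams, preparation_id: str) -> RecordingMeta:
    exposure: dict[str, float] = {}
    for seg in protocol.segments:
        for cid, c in _resolve_solution(params, seg.solution_id, seg.concentration).items():
            exposure[cid] = max(exposure.get(cid, 0.0), c)
    for p in protocol.pulses:
        for cid, c in _resolve_solution(params, p.solution_id, p.concentration).items():
            exposure[cid] = max(exposure.get(cid, 0.0), c * p.bolus_volume_fraction)
    cids = tuple(sorted(exposure))
    return RecordingMeta(
        preparation_id=preparation_id,
        compound_ids=cids,
        concentrations=tuple(exposure[c] for c in cids),
        variant=_variant_of(protocol),
        protocol=protocol,
    )


def simulate_frequency_series(
    protocol: ProtocolSpec,
    params: PDParams,
    seed: int | np.random.Generator = 0,
    dt: float = 0.5,
    preparation_id: str = "sim",
) -> Recording:
    """One synthetic frequency recording sampled every ``dt`` minutes.

    Identical ``(protocol, params, seed, dt)`` give identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times, e = effect_state(protocol, params, dt)
    f = params.f0 * (1.0 + e / 100.0)
    drift_slope = rng.normal(0.0, params.baseline_drift_sd) if params.baseline_drift_sd > 0 else 0.0
    f = f + params.f0 * (drift_slope / 100.0) * (times / protocol.total_duration)
    if params.noise_sd_freq > 0:
        f = f + rng.normal(0.0, params.noise_sd_freq, size=times.size)
    f = np.clip(f, 0.0, None)
    return Recording(times, f, _meta_for(protocol, params, preparation_id))


def simulate_cohort(
    protocol: ProtocolSpec,
    params: PDParams,
    n: int,
    seed: int = 0,
    dt: float = 0.5,
    prefix: str = "prep",
) -> list[Recording]:
    """``n`` preparations under one protocol; the deterministic effect
    trajectory is integrated once and only the noise differs per animal."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    times, e = effect_state(protocol, params, dt)
    base = params.f0 * (1.0 + e / 100.0)
    meta_proto = _meta_for(protocol, params, prefix)
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        f = base.copy()
        if params.baseline_drift_sd > 0:
            f = f + params.f0 * (rng.normal(0.0, params.baseline_drift_sd) / 100.0) * (times / protocol.total_duration)
        if params.noise_sd_freq > 0:
            f = f + rng.normal(0.0, params.noise_sd_freq, size=times.size)
        meta = replace(meta_proto, preparation_id=f"{prefix}{i + 1:02d}")
        recs.append(Recording(times, np.clip(f, 0.0, None), meta))
    return recs


# ---------------------------------------------------------------------------
# raw trace
# ---------------------------------------------------------------------------


def simulate_trace(
    protocol: ProtocolSpec,
    params: PDParams,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 50.0,
    waveform_width: float = 0.25,
    waveform_amplitude: float = 1.0,
    noise_sd: float = 0.0,
) -> Trace:
    """Synthetic densitometric trace with known beat times.

    Beats are produced by integrate-and-fire on the instantaneous rate
    (the phase integral reaching successive integers emits a beat); each
    beat is stamped as a raised-cosine pulse of ``waveform_width`` seconds
    centred on the beat time, on top of additive Gaussian noise.
    """
    if sample_rate < 20.0 * params.f0 / 60.0:
        raise ValidationError(f"sample_rate {sample_rate} too low for f0={params.f0} contractions/min (need >= {20 * params.f0 / 60:g})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt_s = 1.0 / sample_rate
    duration_s = protocol.total_duration * 60.0
    n = round(duration_s * sample_rate)
    t_s = np.arange(n) * dt_s

    # instantaneous rate in Hz from the deterministic effect state
    tm, e = effect_state(protocol, params, dt=protocol.total_duration / max(1, int(protocol.total_duration / 0.01)))
    rate_hz = np.interp(t_s / 60.0, tm, params.f0 * (1.0 + e / 100.0)) / 60.0

    # start mid-cycle so the first and last beats sit clear of the trace
    # edges and every stamped waveform fits inside the record
    phase = 0.5 + np.cumsum(rate_hz) * dt_s
    n_beats = int(np.floor(phase[-1]))
    beats = np.interp(np.arange(1, n_beats + 1), phase, t_s)

    if beats.size >= 2:
        min_ibi = float(np.min(np.diff(beats)))
        if waveform_width >= min_ibi:
            raise ValidationError(f"waveform_width {waveform_width}s >= shortest inter-beat interval {min_ibi:.3f}s: beats would fuse")

    values = np.zeros(n)
    half = waveform_width / 2.0
    for tb in beats:
        i0 = max(0, int(np.ceil((tb - half) * sample_rate)))
        i1 = min(n - 1, int(np.floor((tb + half) * sample_rate)))
        if i1 < i0:
            continue
        tt = t_s[i0 : i1 + 1] - tb
        values[i0 : i1 + 1] += waveform_amplitude * 0.5 * (1.0 + np.cos(2.0 * np.pi * tt / waveform_width))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return Trace(sample_rate=sample_rate, values=values, duration=duration_s, ground_truth_beats=beats)
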