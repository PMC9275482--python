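"""Two-compound mixture analysis: toxic index, toxic units, classification.

For a mixture effect ``E_mix`` and single-agent effects ``E_a`` and
``E_b`` (all on the signed percent-change scale and sharing direction)::

    TI = E_mix / (E_a + E_b)
    TU = E_mix / E_a + E_mix / E_b

An exactly additive mixture gives ``TI = 1`` and
``TU = (E_a + E_b)/E_a + (E_a + E_b)/E_b`` (the additive reference, always
>= 4 for same-sign effects).  Values below the reference indicate
antagonism, above it synergism.  The identity ``TU = TI * TU_ref`` holds
algebraically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import ProtocolSpec, Recording, ValidationError
from .pd_metrics import PercentChangeSeries, _sample_at, percent_change

__all__ = [
    "InteractionResult",
    "toxic_index",
    "toxic_units",
    "tu_additive_reference",
    "classify_ti",
    "classify_tu",
    "evaluate_interaction",
    "interaction_pipeline",
    "ARM_MIX",
    "ARM_A",
    "ARM_B",
]

ARM_A = "compound_a"
ARM_B = "compound_b"
ARM_MIX = "mixture"

DEFAULT_DELTA = 0.05  # reporting convention only, not a scientific claim


@dataclass(frozen=True)
class InteractionResult:
    e_mix: float
    e_a: float
    e_b: float
    ti: float
    tu: float
    tu_additive_ref: float
    label_ti: str
    label_tu: str
    evaluation_minute: float
    delta: float = DEFAULT_DELTA
    n_per_arm: Mapping[str, int] | None = None


def _check_signs(e_mix: float, e_a: float, e_b: float) -> None:
    effects = (e_mix, e_a, e_b)
    if any(e > 0 for e in effects) and any(e < 0 for e in effects):
        raise ValidationError(
            "mixed-sign effects: the toxic index/unit framework assumes all effects act in the same direction"
        )


def toxic_index(e_mix: float, e_a: float, e_b: float) -> float:
    """``TI = E_mix / (E_a + E_b)`` on signed effects (the sign cancels)."""
    _check_signs(e_mix, e_a, e_b)
    if e_a + e_b == 0:
        raise ValidationError("sum of single-agent effects is zero; TI undefined")
    return e_mix / (e_a + e_b)


def toxic_units(e_mix: float, e_a: float, e_b: float) -> float:
    """``TU = E_mix/E_a + E_mix/E_b``."""
    _check_signs(e_mix, e_a, e_b)
    if e_a == 0 or e_b == 0:
        raise ValidationError(
            "a single-agent effect is zero; TU is undefined — measure a non-zero effect for each compound alone"
        )
    return e_mix / e_a + e_mix / e_b


def tu_additive_reference(e_a: float, e_b: float) -> float:
    """TU of an exactly additive mixture; >= 4 for same-sign effects."""
    if e_a == 0 or e_b == 0:
        raise ValidationError("zero single-agent effect; additive reference undefined")
    s = e_a + e_b
    return s / e_a + s / e_b


def classify_ti(ti: float, delta: float = DEFAULT_DELTA) -> str:
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    if abs(ti - 1.0) <= delta:
        return "additive"
    return "antagonism" if ti < 1.0 - delta else "synergism"


def classify_tu(tu: float, tu_ref: float, delta: float = DEFAULT_DELTA) -> str:
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    if abs(tu - tu_ref) <= delta * tu_ref:
        return "additive"
    return "antagonism" if tu < tu_ref else "synergism"


def evaluate_interaction(
    e_mix: float,
    e_a: float,
    e_b: float,
    evaluation_minute: float = math.nan,
    delta: float = DEFAULT_DELTA,
    n_per_arm: Mapping[str, int] | None = None,
) -> InteractionResult:
    """Full TI/TU computation with classification for one evaluation point."""
    ti = toxic_index(e_mix, e_a, e_b)
    tu = toxic_units(e_mix, e_a, e_b)
    ref = tu_additive_reference(e_a, e_b)
    return InteractionResult(
        e_mix=e_mix,
        e_a=e_a,
        e_b=e_b,
        ti=ti,
        tu=tu,
        tu_additive_ref=ref,
        label_ti=classify_ti(ti, delta),
        label_tu=classify_tu(tu, ref, delta),
        evaluation_minute=evaluation_minute,
        delta=delta,
        n_per_arm=dict(n_per_arm) if n_per_arm else None,
    )


def _arm_mean_effect(recordings: Sequence[Recording], minute: float, baseline_window: tuple[float, float]) -> float:
    values = []
    for rec in recordings:
        pcs: PercentChangeSeries = percent_change(rec, baseline_window)
        values.append(_sample_at(pcs, minute))
    return float(np.mean(values))


def interaction_pipeline(
    arms: Mapping[str, Sequence[Recording]],
    protocol: ProtocolSpec,
    evaluation_minutes: Sequence[float] | None = None,
    baseline_window: tuple[float, float] = (0.0, 1.0),
    delta: float = DEFAULT_DELTA,
) -> list[InteractionResult]:
    """Group-level interaction analysis over three experimental arms.

    ``arms`` must provide ``compound_a``, ``compound_b`` and ``mixture``
    (each a non-empty list of recordings).  Effects enter as the group
    mean of percent change at each evaluation minute.  Defaults: minute 13
    for continuous mixtures, minutes 9 and 13 for pulse protocols.
    """
    for name in (ARM_A, ARM_B, ARM_MIX):
        if name not in arms or not arms[name]:
            raise ValidationError(f"missing or empty arm: {name!r}")
    if evaluation_minutes is None:
        evaluation_minutes = (9.0, 13.0) if protocol.pulses else (13.0,)
    results = []
    n_per_arm = {name: len(arms[name]) for name in (ARM_A, ARM_B, ARM_MIX)}
    for minute in evaluation_minutes:
        e_a = _arm_mean_effect(arms[ARM_A], minute, baseline_window)
        e_b = _arm_mean_effect(arms[ARM_B], minute, baseline_window)
        e_mix = _arm_mean_effect(arms[ARM_MIX], minute, baseline_window)
        results.append(evaluate_interaction(e_mix, e_a, e_b, float(minute), delta, n_per_arm))
    return results
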