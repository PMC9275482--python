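"""Shared builders used by several test modules."""

import numpy as np

import cardioperf as cp


def make_plateau_recording(
    e_plateau: float,
    f0: float = 60.0,
    dt: float = 0.5,
    window: tuple[float, float] = (4.0, 13.5),
    total: float = 22.0,
    ramp: float = 1.0,
    recovery: float = 2.0,
    prep_id: str = "prep",
) -> cp.Recording:
    """Deterministic trapezoid percent-change trajectory hitting
    ``e_plateau`` exactly between ``window[0] + ramp`` and ``window[1]``."""
    t = np.arange(int(round(total / dt)) + 1) * dt
    on, off = window
    y = np.zeros_like(t)
    rising = (t > on) & (t < on + ramp)
    y[rising] = e_plateau * (t[rising] - on) / ramp
    y[(t >= on + ramp) & (t < off)] = e_plateau
    rec_mask = (t >= off) & (t < off + recovery)
    y[rec_mask] = e_plateau * (1.0 - (t[rec_mask] - off) / recovery)
    return cp.Recording(t, f0 * (1.0 + y / 100.0), cp.RecordingMeta(prep_id, ("x",), (1e-5,), "A_continuous"))
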