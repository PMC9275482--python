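"""Experiment orchestration: config-driven runs, fixtures, manifests.

``run_experiment`` drives simulate → metrics → dose-response → interaction
as one reproducible run.  All randomness descends from a single seed via
``numpy.random.SeedSequence`` spawning, so identical config + seed
reproduce every machine-readable output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .core_io import (
    DEFAULT_DURATION,
    DEFAULT_EXPOSURE_WINDOW,
    DEFAULT_PULSE_TIME,
    ProtocolSpec,
    Pulse,
    Recording,
    RecordingMeta,
    ValidationError,
    continuous_protocol,
    fmt6,
    protocol_from_dict,
    read_protocol,
    read_recording,
    saline_protocol,
    write_report,
)
from .interaction import ARM_A, ARM_B, ARM_MIX, interaction_pipeline
from .pd_metrics import (
    ec,
    effect_summary,
    fit_dose_response,
    percent_change,
)
from .synthetic import CompoundPD, PDParams, simulate_cohort

logger = logging.getLogger("cardioperf")

__all__ = ["run_experiment", "make_fixtures", "load_config", "build_arm_protocol", "build_params"]


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return doc


def build_params(cfg: Mapping, treatment: Mapping[str, float] | None = None) -> PDParams:
    pd_cfg = dict(cfg.get("pd", {}))
    potency = {
        cid: CompoundPD(float(spec["e_max"]), float(spec["ec50"]), float(spec.get("hill", 1.0)))
        for cid, spec in cfg.get("compounds", {}).items()
    }
    params = PDParams(potency=potency, **pd_cfg)
    if treatment and len(treatment) > 1:
        label = "+".join(treatment)
        params = params.with_mixture(label, treatment)
    return params


def build_arm_protocol(arm: Mapping, cfg: Mapping) -> ProtocolSpec:
    total = float(cfg.get("total_duration", DEFAULT_DURATION))
    window = tuple(cfg.get("exposure_window", DEFAULT_EXPOSURE_WINDOW))
    if "protocol" in arm:
        doc = arm["protocol"]
        return protocol_from_dict(doc) if isinstance(doc, Mapping) else read_protocol(doc)
    variant = str(arm.get("variant", "A")).upper()
    treatment = dict(arm.get("treatment", {}))
    if variant in ("CONTROL", "C") or not treatment:
        return saline_protocol(total)
    proto = continuous_protocol(treatment, window, total)
    if variant == "B":
        p = dict(arm.get("pulse", {}))
        if not p:
            raise ValidationError(f"arm {arm.get('name')!r}: variant B needs a 'pulse' entry")
        pulse = Pulse(
            float(p.get("time", DEFAULT_PULSE_TIME)),
            str(p["solution"]),
            float(p["concentration"]),
            float(p.get("bolus_fraction", 1.0)),
        )
        proto = replace(proto, pulses=(pulse,))
    return proto


def _last_exposure_effect(rec: Recording, protocol: ProtocolSpec, baseline_window: tuple[float, float]) -> float:
    """Percent change at the last sample inside the exposure window."""
    pcs = percent_change(rec, baseline_window)
    _, end = protocol.exposure_window()
    inside = pcs.times < end - 1e-9
    if not np.any(inside):
        raise ValidationError("no samples inside the exposure window")
    return float(pcs.pct_change[inside][-1])


def _summarise_arm(
    name: str,
    recordings: Sequence[Recording],
    protocol: ProtocolSpec,
    cfg: Mapping,
) -> list[dict]:
    baseline = tuple(cfg.get("baseline_window", (0.0, 1.0)))
    minutes = list(cfg.get("report_minutes", (9.0, 13.0)))
    method = str(cfg.get("half_time_method", "interp"))
    rows = []
    for rec in recordings:
        pcs = percent_change(rec, baseline)
        row: dict = {
            "arm": name,
            "preparation": rec.meta.preparation_id,
            "compounds": "+".join(rec.meta.compound_ids) or "saline",
            "concentrations": ";".join(fmt6(c) for c in rec.meta.concentrations),
            "variant": rec.meta.variant,
        }
        if protocol.has_exposure:
            summ = effect_summary(pcs, protocol, minutes, method=method)
            row.update(
                e_max=summ.e_max,
                t_max=summ.t_max,
                t50=summ.t50,
                rt50=summ.rt50,
                rt50_censored=summ.rt50_censored,
                arrested=summ.arrested,
            )
            for m in minutes:
                row[f"e_at_{fmt6(m)}"] = summ.e_at[float(m)]
        else:
            i = int(np.argmax(np.abs(pcs.pct_change)))
            row.update(e_max=float(pcs.pct_change[i]), t_max=float(pcs.times[i]), t50=math.nan, rt50=math.nan, rt50_censored=False, arrested=False)
        rows.append(row)
    return rows


def _write_cohort(recordings: Sequence[Recording], path: Path) -> None:
    """All preparations of one arm as a single tidy CSV."""
    m = recordings[0].meta
    lines = ["# time_unit: min", "# freq_unit: cpm", f"# variant: {m.variant}"]
    if m.compound_ids:
        lines.append("# compound_ids: " + " ".join(m.compound_ids))
        lines.append("# concentrations: " + " ".join(repr(float(c)) for c in m.concentrations))
    lines.append("time_min,freq,preparation_id")
    for rec in recordings:
        for t, f in zip(rec.times, rec.frequencies):
            lines.append(f"{float(t)!r},{float(f)!r},{rec.meta.preparation_id}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_experiment(config: Mapping | str | Path, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute a full configured run; returns the output directory.

    On any stage failure the partial outputs are kept and a ``.failed``
    marker naming the stage is left in the directory.
    """
    cfg = dict(load_config(config)) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = _run_experiment(cfg, out, seed)
    except Exception as exc:
        (out / ".failed").write_text(f"{type(exc).__name__}: {exc}\n", encoding="utf-8")
        raise
    failed = out / ".failed"
    if failed.exists():
        failed.unlink()
    return result


def _run_experiment(cfg: dict, out: Path, seed: int | None) -> Path:
    master_seed = int(cfg.get("seed", 0) if seed is None else seed)
    arms_cfg = list(cfg.get("arms", []))
    if not arms_cfg:
        raise ValidationError("nothing to run: config declares no arms")
    dt = float(cfg.get("dt", 0.5))
    baseline = tuple(cfg.get("baseline_window", (0.0, 1.0)))
    timings: dict[str, float] = {}
    input_hashes: dict[str, str] = {}

    ss = np.random.SeedSequence(master_seed)
    arm_seeds = ss.generate_state(len(arms_cfg))

    arms: dict[str, list[Recording]] = {}
    protocols: dict[str, ProtocolSpec] = {}
    summaries: list[dict] = []
    (out / "recordings").mkdir(exist_ok=True)

    t0 = time.perf_counter()
    for i, arm in enumerate(arms_cfg):
        name = str(arm.get("name", f"arm{i}"))
        proto = build_arm_protocol(arm, cfg)
        protocols[name] = proto
        if "recordings" in arm:
            rec_path = Path(arm["recordings"])
            input_hashes[str(rec_path)] = hashlib.sha256(rec_path.read_bytes()).hexdigest()
            recs = read_recording(rec_path)
        else:
            params = build_params(cfg, arm.get("treatment"))
            recs = simulate_cohort(proto, params, int(arm.get("n", 1)), seed=int(arm_seeds[i]), dt=dt, prefix=f"{name}_p")
            _write_cohort(recs, out / "recordings" / f"{name}.csv")
        arms[name] = recs
        logger.info("arm %s: %d recordings, variant %s", name, len(recs), recs[0].meta.variant)
        summaries.extend(_summarise_arm(name, recs, proto, cfg))
    timings["simulate_and_summarise"] = time.perf_counter() - t0

    # dose-response blocks
    t0 = time.perf_counter()
    dr_rows: list[dict] = []
    for block in cfg.get("dose_response", []):
        compound = str(block["compound"])
        doses, effects = [], []
        for arm_name in block["arms"]:
            if arm_name not in arms:
                raise ValidationError(f"dose_response references unknown arm {arm_name!r}")
            proto = protocols[arm_name]
            per_prep = [_last_exposure_effect(r, proto, baseline) for r in arms[arm_name]]
            meta = arms[arm_name][0].meta
            try:
                dose = meta.concentrations[meta.compound_ids.index(compound)]
            except ValueError as exc:
                raise ValidationError(f"arm {arm_name!r} does not expose compound {compound!r}") from exc
            doses.append(dose)
            effects.append(float(np.mean(per_prep)))
        fit = fit_dose_response(doses, effects, e_bottom=block.get("e_bottom"))
        row = {
            "compound": compound,
            "ic50": fit.ic50,
            "hill_slope": fit.hill_slope,
            "e_bottom": fit.e_bottom,
            "sse": fit.residual_sse,
            "extrapolated": fit.extrapolated,
        }
        try:
            row["ec75"] = ec(fit, 0.75)
        except ValidationError:
            row["ec75"] = math.nan
        dr_rows.append(row)
        logger.info("dose-response %s: IC50=%s", compound, fmt6(fit.ic50))
    timings["dose_response"] = time.perf_counter() - t0

    # interaction blocks
    t0 = time.perf_counter()
    inter_rows: list[dict] = []
    for block in cfg.get("interactions", []):
        mapping = {ARM_A: block["a"], ARM_B: block["b"], ARM_MIX: block["mix"]}
        for role, arm_name in mapping.items():
            if arm_name not in arms:
                raise ValidationError(f"interaction {block.get('name')!r}: unknown arm {arm_name!r} for {role}")
        proto = protocols[mapping[ARM_MIX]]
        results = interaction_pipeline(
            {role: arms[arm_name] for role, arm_name in mapping.items()},
            proto,
            evaluation_minutes=block.get("minutes"),
            baseline_window=baseline,
            delta=float(cfg.get("delta", 0.05)),
        )
        for res in results:
            inter_rows.append(
                {
                    "name": str(block.get("name", mapping[ARM_MIX])),
                    "minute": res.evaluation_minute,
                    "e_a": res.e_a,
                    "e_b": res.e_b,
                    "e_mix": res.e_mix,
                    "ti": round(res.ti, 2),
                    "tu": round(res.tu, 2),
                    "tu_additive_ref": round(res.tu_additive_ref, 2),
                    "label_ti": res.label_ti,
                    "label_tu": res.label_tu,
                }
            )
    timings["interaction"] = time.perf_counter() - t0

    config_echo = {"seed": master_seed, "dt": dt, "baseline_window": list(baseline), "version": __version__}
    write_report(summaries, out / "summary", inter_rows, config_echo)
    if dr_rows:
        write_report(dr_rows, out / "dose_response")
    if inter_rows:
        write_report(inter_rows, out / "interactions")

    manifest = {
        "version": __version__,
        "seed": master_seed,
        "config": cfg,
        "input_hashes": input_hashes,
        "n_arms": len(arms_cfg),
    }
    canonical = json.dumps(manifest, sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(canonical.encode()).hexdigest()
    manifest["stage_timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _piecewise_recording(
    e_plateau: float,
    prep_id: str,
    compound_ids: tuple[str, ...] = (),
    concentrations: tuple[float, ...] = (),
    f0: float = 60.0,
    dt: float = 0.5,
    window: tuple[float, float] = DEFAULT_EXPOSURE_WINDOW,
    total: float = DEFAULT_DURATION,
    ramp: float = 1.0,
    recovery: float = 2.0,
    variant: str = "A_continuous",
) -> Recording:
    """Deterministic trapezoid trajectory hitting ``e_plateau`` exactly."""
    t = np.arange(int(round(total / dt)) + 1) * dt
    on, off = window
    y = np.zeros_like(t)
    rising = (t > on) & (t < on + ramp)
    y[rising] = e_plateau * (t[rising] - on) / ramp
    y[(t >= on + ramp) & (t < off)] = e_plateau
    rec_mask = (t >= off) & (t < off + recovery)
    y[rec_mask] = e_plateau * (1.0 - (t[rec_mask] - off) / recovery)
    freqs = f0 * (1.0 + y / 100.0)
    meta = RecordingMeta(prep_id, compound_ids, concentrations, variant)
    return Recording(t, freqs, meta)


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the worked-example fixture set used in docs and tests.

    * plateau recordings carrying the group-mean effects of the reference
      experiment (-77.9, -25.3, -66.7, -28.3, -72.3 %)
    * analytic ramp recordings for the half-time estimators
    * one seeded noisy cohort
    """
    from .core_io import write_protocol, write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    plateaus = {
        "ver": (-77.9, ("ver",), (3e-5,)),
        "sol": (-25.3, ("sol",), (1e-5,)),
        "ver_sol_mix": (-66.7, ("ver", "sol"), (3e-5, 1e-5)),
        "chac": (-28.3, ("chac",), (1e-5,)),
        "ver_chac_mix": (-72.3, ("ver", "chac"), (3e-5, 1e-5)),
    }
    for name, (e, cids, concs) in plateaus.items():
        rec = _piecewise_recording(e, name, cids, concs)
        p = out / f"plateau_{name}.csv"
        write_recording(rec, p)
        paths[f"plateau_{name}"] = p

    # linear ramp 0 -> -100% over minutes 4..6, recovery -100 -> 0 over 13.5..15.5
    ramp = _piecewise_recording(-100.0, "ramp", ("x",), (1e-5,), ramp=2.0, recovery=2.0)
    paths["ramp"] = out / "ramp.csv"
    write_recording(ramp, paths["ramp"])

    proto = continuous_protocol({"x": 1e-5})
    paths["protocol_variant_a"] = out / "protocol_variant_a.yaml"
    write_protocol(proto, paths["protocol_variant_a"])
    paths["protocol_control"] = out / "protocol_control.yaml"
    write_protocol(saline_protocol(), paths["protocol_control"])

    params = PDParams(
        potency={"x": CompoundPD(-80.0, 1e-6, 1.5)},
        k_on=1.2,
        k_off=0.4,
        noise_sd_freq=0.6,
        baseline_drift_sd=0.5,
    )
    cohort = simulate_cohort(proto, params, n=15, seed=seed, prefix="noisy_p")
    paths["noisy_cohort"] = out / "noisy_cohort.csv"
    _write_cohort(cohort, paths["noisy_cohort"])
    return paths
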