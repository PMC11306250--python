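"""End-to-end orchestration: simulate, detect, fit, report.

A :class:`RunConfig` fully determines a run; the global seed spawns one
independent stream per stage through ``numpy.random.SeedSequence``
(stage index = position in ``STAGES``), so each stage is reproducible
on its own.  Every run writes its resolved configuration next to the
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__, crossbridge
from .detection import DetectionConfig, detect_events
from .dwells import (classify_rates, cumulative_dwell_fit,
                     displacement_gaussian_fit, working_stroke_estimate)
from .ensemble import ensemble_stiffness
from .loadkin import fit_bell
from .params import Conditions, CycleRates, MechanicalParams, variant
from .synthetics import (SimConfig, crossbridge_load, simulate_state_sequence,
                         simulate_trap_trace)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("dwell_kinetics", "stroke", "stiffness", "bell")


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name."""


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one full analysis run."""

    variant: str = "S267E"
    seed: int = 0
    out_dir: str = "actotrap_run"
    atp_levels: tuple = (0.01, 0.1)
    n_dwell_events: int = 2000
    n_stroke_events: int = 120
    n_stiffness_events: int = 40
    bell_offsets: tuple = (40.0, 0.0, -40.0, -80.0)
    n_bell_events: int = 200
    detection: DetectionConfig = dataclasses.field(
        default_factory=DetectionConfig)
    rates: CycleRates | None = None
    mech: MechanicalParams | None = None

    def resolve(self) -> "RunConfig":
        v = variant(self.variant)
        out = dataclasses.replace(
            self,
            rates=self.rates or v.rates,
            mech=self.mech or v.mech,
        )
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "detection" in raw:
            raw["detection"] = DetectionConfig(**raw["detection"])
        if "rates" in raw:
            raw["rates"] = CycleRates(**raw["rates"])
        if "mech" in raw:
            raw["mech"] = MechanicalParams(**raw["mech"])
        for key in ("atp_levels", "bell_offsets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, STAGES.index(stage)])


def _dwell_kinetics(cfg: RunConfig, rng_seq) -> dict:
    children = rng_seq.spawn(len(cfg.atp_levels))
    fits = []
    for child, atp in zip(children, cfg.atp_levels):
        cond = Conditions(atp=atp)
        duration = cfg.n_dwell_events * (
            1.0 / cfg.rates.k_att + 1.0 / cfg.rates.k1_0
            + 1.0 / (cfg.rates.k2_0 * atp)) * 1.1
        # zero-load kinetics: the table constants are the ground truth
        traj = simulate_state_sequence(cfg.rates, cond, duration, child)
        fits.append(cumulative_dwell_fit(traj.attached_dwells(),
                                         n_boot=40, seed=child.spawn(1)[0]))
    cls = classify_rates(fits, list(cfg.atp_levels))
    return {"k1": cls.k1_0, "k1_se": cls.k1_se,
            "k2": cls.k2_0, "k2_se": cls.k2_se,
            "fits": [dataclasses.asdict(f) for f in fits]}


def _stroke(cfg: RunConfig, rng_seq) -> dict:
    # 10 uM ATP keeps the per-event displacement distribution tight
    cond = Conditions(atp=0.01)
    t_cycle = (1.0 / cfg.rates.k_att + 1.0 / cfg.rates.k1_0
               + 1.0 / (cfg.rates.k2_0 * cond.atp))
    duration = cfg.n_stroke_events * t_cycle * 1.15
    c1, c2 = rng_seq.spawn(2)
    traj = simulate_state_sequence(cfg.rates, cond, duration, c1,
                                   mech=cfg.mech)
    sim = SimConfig(duration=duration, seed=int(c2.generate_state(1)[0] % 2**31),
                    forcing_amp=0.0)
    trace = simulate_trap_trace(traj, cfg.mech, sim, rates=cfg.rates,
                                cond=cond)
    events = detect_events(trace, cfg.detection)
    disp = [e.displacement for e in events]
    gfit = displacement_gaussian_fit(disp)
    ws = working_stroke_estimate(gfit, trace)
    ws_se = gfit.stderr["xc"] / trace.metadata["stroke_recovery_factor"]
    return {"ws": ws, "ws_se": ws_se, "n_events": len(events),
            "xc_bead": gfit.xc}


def _stiffness(cfg: RunConfig, rng_seq) -> dict:
    cond = Conditions(atp=0.1)
    t_cycle = (1.0 / cfg.rates.k_att + 1.0 / cfg.rates.k1_0
               + 1.0 / (cfg.rates.k2_0 * cond.atp))
    duration = cfg.n_stiffness_events * t_cycle * 1.15
    c1, c2 = rng_seq.spawn(2)
    traj = simulate_state_sequence(cfg.rates, cond, duration, c1,
                                   mech=cfg.mech)
    sim = SimConfig(duration=duration, seed=int(c2.generate_state(1)[0] % 2**31),
                    forcing_amp=100.0)
    trace = simulate_trap_trace(traj, cfg.mech, sim, rates=cfg.rates,
                                cond=cond)
    events = detect_events(trace, cfg.detection)
    tc = ensemble_stiffness(trace, events, atp=cond.atp,
                            min_events=min(30, max(5, len(events) // 2)))
    return {"kappa_pre": tc.plateau_pre, "kappa_rigor": tc.plateau_rigor,
            "single_plateau": tc.single_plateau,
            "k1_stiff": tc.k1_stiff, "k2_stiff": tc.k2_stiff,
            "n_events": tc.n_events}


def _bell(cfg: RunConfig, rng_seq) -> dict:
    cond = Conditions(atp=0.1)
    children = rng_seq.spawn(len(cfg.bell_offsets))
    F1, F2, k1s, k2s, k1e, k2e = [], [], [], [], [], []
    for child, offset in zip(children, cfg.bell_offsets):
        loads = {st: crossbridge_load(cfg.mech, st, offset)
                 for st in ("post1_ADP", "rigor")}
        t_cycle = (1.0 / cfg.rates.k_att
                   + 1.0 / crossbridge.k1_at(
                       cfg.rates, cond.with_load(loads["post1_ADP"]))
                   + 1.0 / (crossbridge.k2_at(
                       cfg.rates, cond.with_load(loads["rigor"])) * cond.atp))
        duration = cfg.n_bell_events * t_cycle * 1.1
        traj = simulate_state_sequence(cfg.rates, cond, duration, child,
                                       mech=cfg.mech, static_offset=offset)
        fit = cumulative_dwell_fit(traj.attached_dwells(), n_boot=30,
                                   seed=child.spawn(1)[0])
        # at 100 uM ATP and resisting load the ATP branch is the slower
        # component throughout (d2 > d1)
        F1.append(loads["post1_ADP"])
        F2.append(loads["rigor"])
        k1s.append(fit.k2_obs)
        k1e.append(fit.stderr["k2_obs"])
        k2s.append(fit.k1 / cond.atp)
        k2e.append(fit.stderr["k1"] / cond.atp)
    bell1 = fit_bell(F1, k1s, k1e)
    bell2 = fit_bell(F2, k2s, k2e)
    return {"d1": bell1.d, "d1_se": bell1.d_se, "k1_0": bell1.k0,
            "d2": bell2.d, "d2_se": bell2.d_se, "k2_0": bell2.k0}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and emit a report.

    Returns a dict with one entry per stage plus a flat summary row
    mirroring the per-variant rate/stiffness table.  Partial outputs
    are written to ``config.out_dir`` as stages complete; a stage
    failure raises :class:`PipelineError` naming the stage.
    """
    cfg = config.resolve()
    os.makedirs(cfg.out_dir, exist_ok=True)
    with open(os.path.join(cfg.out_dir, "config.json"), "w") as fh:
        json.dump({"package_version": __version__, **cfg.to_dict()}, fh,
                  indent=1, default=str)

    report: dict = {"variant": cfg.variant, "seed": cfg.seed,
                    "package_version": __version__}
    runners = {"dwell_kinetics": _dwell_kinetics, "stroke": _stroke,
               "stiffness": _stiffness, "bell": _bell}
    for stage in STAGES:
        try:
            report[stage] = runners[stage](cfg, _stage_seed(cfg.seed, stage))
        except Exception as exc:
            with open(os.path.join(cfg.out_dir, "report_partial.json"),
                      "w") as fh:
                json.dump(report, fh, indent=1, default=str)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        with open(os.path.join(cfg.out_dir, "report_partial.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=str)

    cond = Conditions(atp=0.1)
    summary = {
        "variant": cfg.variant,
        "k1_s": report["dwell_kinetics"]["k1"],
        "k2_mM_s": report["dwell_kinetics"]["k2"],
        "ws_nm": report["stroke"]["ws"],
        "kappa_pre_pN_nm": report["stiffness"]["kappa_pre"],
        "kappa_rigor_pN_nm": report["stiffness"]["kappa_rigor"],
        "d1_nm": report["bell"]["d1"],
        "d2_nm": report["bell"]["d2"],
        "duty_0p1mM": crossbridge.apparent_duty_ratio(cfg.rates, cond),
        "stall_force_pN": crossbridge.stall_force(cfg.mech, "rigor"),
    }
    report["summary"] = summary
    pd.DataFrame([summary]).to_csv(
        os.path.join(cfg.out_dir, "report.tsv"), sep="\t", index=False)
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
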