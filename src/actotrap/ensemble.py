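"""Ensemble-averaged mechanics of attachment events.

Events are synchronised at their start or end, resampled to the trace
grid, and averaged pointwise.  Events shorter than the averaging span
are extended with the mean of their last (start alignment) or first
(end alignment) twenty samples, so every grid point averages the full
event count.  Crossbridge stiffness is estimated per forcing cycle by
synchronous detection of the 100-Hz phasors of both beads.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize

from .detection import BindingEvent
from .params import ParameterError
from .synthetics import TrapTrace

__all__ = [
    "EnsembleAverage",
    "StiffnessTimecourse",
    "align_and_average",
    "fit_single_exponential",
    "demodulate_stiffness",
    "ensemble_stiffness",
]

PAD_POINTS = 20  # samples used for the short-event extension rule


@dataclasses.dataclass
class EnsembleAverage:
    """Synchronised pointwise mean of event time courses."""

    alignment: str              # "start" | "end"
    time: np.ndarray            # s, relative to the alignment point
    mean: np.ndarray
    n: np.ndarray               # contributing events per point
    n_events: int


@dataclasses.dataclass
class StiffnessTimecourse:
    """Start-aligned ensemble stiffness with plateau and transition fits."""

    time: np.ndarray
    kappa: np.ndarray           # pN/nm
    plateau_pre: float
    plateau_rigor: float
    single_plateau: bool
    k1_stiff: float | None      # s^-1 (start-aligned transition)
    k1_stiff_se: float | None
    k2_stiff: float | None      # mM^-1 s^-1 (end-aligned, scaled by [ATP])
    k2_stiff_se: float | None
    n_events: int


def _event_baseline(x: np.ndarray, events: list[BindingEvent], idx: int,
                    sample_rate: float, span: float,
                    margin: int) -> float:
    """Mean of detached samples flanking event ``idx`` within ``span`` s."""
    n = x.size
    mask = np.zeros(n, dtype=bool)
    e = events[idx]
    i0, i1 = int(e.t_start * sample_rate), int(e.t_end * sample_rate)
    lo, hi = max(0, i0 - int(span * sample_rate)), min(n, i1 + int(span * sample_rate))
    mask[lo:hi] = True
    for other in events:
        j0 = max(0, int(other.t_start * sample_rate) - margin)
        j1 = min(n, int(other.t_end * sample_rate) + margin)
        mask[j0:j1] = False
    if not mask.any():
        raise ParameterError(f"no detached baseline around event {idx}")
    return float(x[mask].mean())


def align_and_average(trace: TrapTrace, events: list[BindingEvent],
                      alignment: str = "start",
                      span: float | None = None,
                      min_events: int = 20) -> EnsembleAverage:
    """Start/end-synchronised ensemble average of event displacements.

    Each event contributes its baseline-subtracted dumbbell position
    (mean of both channels).  ``span`` is the averaged window length in
    seconds (default: the 90th percentile of event durations).  Events
    shorter than the extension rule's 20 samples are excluded with a
    warning.
    """
    if alignment not in ("start", "end"):
        raise ParameterError("alignment must be 'start' or 'end'")
    if len(events) < min_events:
        raise ParameterError(f"need >= {min_events} events")
    sr = trace.sample_rate
    x = 0.5 * (np.asarray(trace.x_driven, float)
               + np.asarray(trace.x_passive, float))
    sim = trace.metadata.get("sim_config", {})
    if sim.get("forcing_amp", 0.0) and sim.get("forcing_freq", 0.0):
        from .detection import remove_forcing
        x = remove_forcing(x, sr, sim["forcing_freq"])

    if span is None:
        span = float(np.quantile([e.dwell for e in events], 0.9))
    n_grid = max(int(round(span * sr)), 2)
    margin = PAD_POINTS

    rows = []
    for idx, e in enumerate(events):
        i0, i1 = int(round(e.t_start * sr)), int(round(e.t_end * sr))
        seg = x[i0:i1]
        if seg.size < PAD_POINTS:
            warnings.warn(f"event {idx} shorter than {PAD_POINTS} samples; "
                          "excluded", stacklevel=2)
            continue
        base = _event_baseline(x, events, idx, sr, span=0.5, margin=margin)
        seg = seg - base
        if alignment == "start":
            if seg.size >= n_grid:
                row = seg[:n_grid]
            else:
                pad = seg[-PAD_POINTS:].mean()
                row = np.concatenate([seg, np.full(n_grid - seg.size, pad)])
        else:
            if seg.size >= n_grid:
                row = seg[-n_grid:]
            else:
                pad = seg[:PAD_POINTS].mean()
                row = np.concatenate([np.full(n_grid - seg.size, pad), seg])
        rows.append(row)
    if len(rows) < min_events:
        raise ParameterError("too few usable events after exclusion")
    arr = np.asarray(rows)
    mean = arr.mean(axis=0)
    n = np.full(n_grid, arr.shape[0])
    if alignment == "start":
        time = np.arange(n_grid) / sr
    else:
        time = (np.arange(n_grid) - n_grid + 1) / sr
    return EnsembleAverage(alignment=alignment, time=time, mean=mean,
                           n=n, n_events=arr.shape[0])


def fit_single_exponential(avg: EnsembleAverage,
                           min_points: int = 30,
                           skip: int = 0) -> dict:
    """Least-squares fit A*exp(-k*x) + y0 to an ensemble average.

    ``x`` is the unsigned time from the alignment point.  ``skip``
    drops that many grid points nearest the alignment point, where the
    mechanical attachment/detachment transient contaminates the
    average.  Returns the parameters with their standard errors; ``k``
    is constrained positive.
    """
    if avg.time.size < min_points:
        raise ParameterError(f"need >= {min_points} grid points")
    x = np.abs(avg.time - avg.time[0 if avg.alignment == "start" else -1])
    if avg.alignment == "end":
        x = x[::-1]
        y = avg.mean[::-1]
    else:
        y = avg.mean
    if skip:
        x, y = x[skip:], y[skip:]

    span = y[-1] - y[0]
    k0 = 1.0 / max(x[-1] / 3.0, 1e-9)
    p0 = [-span if span != 0 else -1.0, k0, y[-1]]

    def model(x_, A, k, y0):
        return A * np.exp(-k * x_) + y0

    try:
        popt, pcov = optimize.curve_fit(
            model, x, y, p0=p0,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except RuntimeError as exc:
        raise ParameterError(f"exponential fit failed: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return {"A": float(popt[0]), "k": float(popt[1]), "y0": float(popt[2]),
            "A_se": float(se[0]), "k_se": float(se[1]), "y0_se": float(se[2])}


def demodulate_stiffness(trace: TrapTrace, event: BindingEvent | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-forcing-cycle crossbridge stiffness over an event (or trace).

    Synchronous detection extracts the complex 100-Hz phasors X_d, X_p
    of both beads per cycle.  With the rod position inferred from the
    passive bead, X_a = X_p (kt+kl)/kl, force balance on the rod +
    passive bead gives the force carried by the crossbridge, so

        kappa = Re[(kl (X_d - X_a) - kt X_p) / X_a]

    which is ~0 for detached segments (the numerator is then purely
    viscous/imaginary).  Returns cycle-centre times and kappa values.
    """
    sim = trace.metadata.get("sim_config", {})
    amp, freq = sim.get("forcing_amp", 0.0), sim.get("forcing_freq", 0.0)
    if not amp or not freq:
        raise ParameterError("trace has no forcing; cannot demodulate")
    mech = trace.metadata.get("mech", {})
    kt, kl = mech["kappa_trap"], mech["kappa_link"]
    sr = trace.sample_rate
    m = int(round(sr / freq))

    if event is None:
        c0, c1 = 0, trace.n_samples // m
    else:
        c0 = int(np.ceil(event.t_start * sr / m))
        c1 = int(np.floor(event.t_end * sr / m))
    if c1 <= c0:
        return np.empty(0), np.empty(0)

    idx = np.arange(c0 * m, c1 * m)
    phase = 2.0 * np.pi * freq * idx / sr
    s, c = np.sin(phase), np.cos(phase)
    n_cyc = c1 - c0

    def phasor(x):
        blocks = (x[c0 * m:c1 * m]).reshape(n_cyc, m)
        sb = s.reshape(n_cyc, m)
        cb = c.reshape(n_cyc, m)
        return ((blocks * sb).mean(axis=1) * 2.0
                + 1j * (blocks * cb).mean(axis=1) * 2.0)

    Xd = phasor(np.asarray(trace.x_driven, float))
    Xp = phasor(np.asarray(trace.x_passive, float))
    Xa = Xp * (kt + kl) / kl
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.real((kl * (Xd - Xa) - kt * Xp) / Xa)
    t_centers = (np.arange(c0, c1) + 0.5) * m / sr
    return t_centers, kappa


def ensemble_stiffness(trace: TrapTrace, events: list[BindingEvent],
                       atp: float | None = None,
                       min_events: int = 30,
                       plateau_gap: float = 0.04,
                       pad_cycles: int = 2) -> StiffnessTimecourse:
    """Start-aligned ensemble stiffness with plateaus and transition rates.

    Per-event stiffness series are aligned at the event start, padded
    with the mean of the last ``pad_cycles`` values, and averaged.
    Plateaus are medians of the first/last quartile of the averaged
    span.  If the plateaus differ by less than ``plateau_gap`` pN/nm
    the record is flagged single-plateau and no transition is fitted;
    otherwise single exponentials to the start- and end-aligned
    averages give the transition rates (the end-aligned one scaled by
    [ATP] to a second-order constant).
    """
    sim = trace.metadata.get("sim_config", {})
    if atp is None:
        atp = trace.metadata.get("conditions", {}).get("atp")
    if len(events) < min_events:
        raise ParameterError(f"need >= {min_events} events with forcing")

    series = []
    for e in events:
        _, kap = demodulate_stiffness(trace, e)
        if kap.size >= 2:
            series.append(kap)
    if len(series) < min_events:
        raise ParameterError("too few events with >= 2 forcing cycles")

    n_grid = int(np.quantile([len(s) for s in series], 0.9))
    n_grid = max(n_grid, 4)

    def aligned(which):
        rows = []
        for kap in series:
            if which == "start":
                if kap.size >= n_grid:
                    row = kap[:n_grid]
                else:
                    pad = kap[-min(pad_cycles, kap.size):].mean()
                    row = np.concatenate(
                        [kap, np.full(n_grid - kap.size, pad)])
            else:
                if kap.size >= n_grid:
                    row = kap[-n_grid:]
                else:
                    pad = kap[:min(pad_cycles, kap.size)].mean()
                    row = np.concatenate(
                        [np.full(n_grid - kap.size, pad), kap])
            rows.append(row)
        return np.asarray(rows).mean(axis=0)

    freq = sim["forcing_freq"]
    cycle = 1.0 / freq
    kap_start = aligned("start")
    kap_end = aligned("end")
    time = (np.arange(n_grid) + 0.5) * cycle

    # fit the rise first: its t=0 intercept is the pre-rigor plateau,
    # which is only a few forcing cycles wide when ADP release is fast
    avg1 = EnsembleAverage("start", time, kap_start,
                           np.full(n_grid, len(series)), len(series))
    try:
        fit1 = fit_single_exponential(avg1, min_points=4)
    except ParameterError:
        fit1 = None
    resolved = (fit1 is not None and abs(fit1["A"]) >= plateau_gap
                and fit1["k"] * time[-1] > 1.0
                and fit1["k_se"] < fit1["k"])
    if not resolved:
        # per-cycle estimates are skewed, so pool means, not medians
        level = float(np.concatenate(series).mean())
        return StiffnessTimecourse(
            time=time, kappa=kap_start, plateau_pre=level,
            plateau_rigor=level, single_plateau=True,
            k1_stiff=None, k1_stiff_se=None, k2_stiff=None,
            k2_stiff_se=None, n_events=len(series))

    plateau_pre = float(fit1["A"] + fit1["y0"])
    # rigor plateau: pool every real cycle after the transition has
    # settled (3 / fitted rate), cycle-weighted across events
    i_cut = int(np.ceil(3.0 / (fit1["k"] * cycle)))
    settled = [kap[i_cut:] for kap in series if kap.size > i_cut]
    if settled:
        plateau_rigor = float(np.concatenate(settled).mean())
    else:
        q = max(n_grid // 4, 1)
        plateau_rigor = float(np.mean(kap_start[-q:]))
    avg2 = EnsembleAverage("end", time - time[-1], kap_end,
                           np.full(n_grid, len(series)), len(series))
    fit2 = fit_single_exponential(avg2, min_points=4)
    k2_stiff = fit2["k"] / atp if atp else None
    k2_se = fit2["k_se"] / atp if atp else None
    return StiffnessTimecourse(
        time=time, kappa=kap_start, plateau_pre=plateau_pre,
        plateau_rigor=plateau_rigor, single_plateau=False,
        k1_stiff=fit1["k"], k1_stiff_se=fit1["k_se"],
        k2_stiff=k2_stiff, k2_stiff_se=k2_se, n_events=len(series))
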