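"""Variance-based detection of actin-binding events in bead traces.

Attachment stiffens the mechanical network and suppresses the thermal
motion of the beads, so binding shows up as a drop in the rolling
variance of the passive-bead position.  Detection therefore runs a
dual-threshold hysteresis machine on the log rolling variance, with
thresholds placed automatically between the two modes of its
distribution (Otsu split).  The 100-Hz forcing component, when
present, is removed per forcing cycle before any variance is taken.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .params import ParameterError
from .synthetics import TrapTrace

__all__ = [
    "DetectionConfig",
    "BindingEvent",
    "NoAttachedPopulationError",
    "remove_forcing",
    "rolling_variance",
    "detect_events",
    "event_table",
    "events_from_table",
]


class NoAttachedPopulationError(RuntimeError):
    """Variance histogram is unimodal: nothing to detect in auto mode."""


@dataclasses.dataclass(frozen=True)
class DetectionConfig:
    """Tuning knobs of the variance detector (times in ms / s as noted)."""

    window: float = 20.0           # rolling-variance window, ms
    threshold_mode: str = "auto"   # "auto" | "manual"
    manual_thresholds: tuple[float, float] | None = None  # (low, high) log-var
    hysteresis_frac: float = 0.2
    min_duration: float = 10.0     # ms
    baseline_span: float = 0.5     # s of flanking detached data
    channel: str = "passive"       # variance channel
    min_trace_duration: float = 10.0  # s
    min_mode_separation: float = 0.4  # log-variance units, auto mode
    min_mode_dprime: float = 4.0   # separation / within-class SD, auto mode
    refine_frac: float = 0.15      # edge refinement threshold, frac of sep
                                   # below the detached mode (0 disables)

    def __post_init__(self) -> None:
        if not 0.0 < self.hysteresis_frac < 1.0:
            raise ParameterError("hysteresis_frac must be in (0, 1)")
        if self.window <= 0 or self.min_duration <= 0:
            raise ParameterError("window and min_duration must be > 0")

    def window_samples(self, sample_rate: float) -> int:
        n = int(round(self.window * 1e-3 * sample_rate))
        if n < 5:
            raise ParameterError("window must cover >= 5 samples")
        return n


@dataclasses.dataclass(frozen=True)
class BindingEvent:
    """One detected attachment."""

    t_start: float
    t_end: float
    dwell: float
    displacement: float     # nm, working-stroke direction positive
    mean_load: float        # pN, resisting positive (NaN if no kappa_trap)
    var_attached: float     # nm^2
    var_detached: float     # nm^2


def remove_forcing(x: np.ndarray, sample_rate: float,
                   freq: float) -> np.ndarray:
    """Subtract the phase-locked sinusoidal component per forcing cycle.

    Each full cycle is least-squares projected onto sin/cos at the
    forcing frequency and that component removed; the cycle mean is
    kept, so displacements are unaffected.  Adapting per cycle tracks
    the amplitude change between attached and detached periods.
    """
    x = np.asarray(x, dtype=float)
    m = int(round(sample_rate / freq))
    if abs(sample_rate / freq - m) > 1e-6:
        raise ParameterError("sample_rate must be an integer multiple of freq")
    n_cyc = x.size // m
    out = x.copy()
    if n_cyc == 0:
        return out
    phase = 2.0 * np.pi * freq * np.arange(m) / sample_rate
    s, c = np.sin(phase), np.cos(phase)
    blocks = out[: n_cyc * m].reshape(n_cyc, m)
    a = blocks @ s * (2.0 / m)
    b = blocks @ c * (2.0 / m)
    blocks -= np.outer(a, s) + np.outer(b, c)
    tail = out[n_cyc * m:]
    if tail.size:
        ph = 2.0 * np.pi * freq * np.arange(n_cyc * m, x.size) / sample_rate
        tail -= a[-1] * np.sin(ph) + b[-1] * np.cos(ph)
    return out


def rolling_variance(channel: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling variance (ddof=1) of a 1-d signal."""
    x = np.asarray(channel, dtype=float)
    if x.size <= window:
        raise ParameterError("window longer than trace")
    mu = uniform_filter1d(x, window, mode="nearest")
    mu2 = uniform_filter1d(x * x, window, mode="nearest")
    v = (mu2 - mu * mu) * (window / (window - 1.0))
    return np.clip(v, 0.0, None)


def _otsu_split(lv: np.ndarray) -> tuple[float, float, float, float]:
    """Two-class split of log-variance values.

    Returns (threshold, low mean, high mean, pooled within-class SD)
    maximising the between-class variance over a 256-bin histogram.
    The pooled SD lets callers test whether the split reflects real
    bimodality (Otsu always returns *some* split).
    """
    hist, edges = np.histogram(lv, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    tot = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    w0 = cum_w[:-1]
    w1 = tot - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_m[:-1] / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (cum_m[-1] - cum_m[:-1]) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    i = int(np.argmax(between))
    thr = centers[i]
    lo, hi = lv[lv <= thr], lv[lv > thr]
    n0, n1 = lo.size, hi.size
    pooled = np.sqrt((n0 * lo.var() + n1 * hi.var()) / max(n0 + n1, 1))
    return thr, mu0[i], mu1[i], float(pooled)


def _detached_mask(n: int, segments: list[tuple[int, int]]) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for i0, i1 in segments:
        mask[i0:i1] = False
    return mask


def detect_events(trace: TrapTrace, cfg: DetectionConfig | None = None
                  ) -> list[BindingEvent]:
    """Detect binding events on a trace.

    Auto thresholding requires a bimodal log-variance distribution;
    events shorter than ``min_duration`` or touching the trace
    boundaries are discarded.  Displacement is the mean attached
    dumbbell position (average of both channels, half-window margins
    trimmed) minus the flanking detached baseline; ``mean_load`` is the
    trap-derived force ``kappa_trap * (delta_driven + delta_passive)``.
    """
    cfg = cfg or DetectionConfig()
    if trace.duration < cfg.min_trace_duration:
        raise ParameterError(
            f"trace of {trace.duration:.2f} s is shorter than "
            f"min_trace_duration = {cfg.min_trace_duration} s")
    sr = trace.sample_rate
    w = cfg.window_samples(sr)

    xd = np.asarray(trace.x_driven, dtype=float)
    xp = np.asarray(trace.x_passive, dtype=float)
    sim = trace.metadata.get("sim_config", {})
    famp = sim.get("forcing_amp", 0.0)
    ffreq = sim.get("forcing_freq", 0.0)
    if famp and ffreq:
        xd = remove_forcing(xd, sr, ffreq)
        xp = remove_forcing(xp, sr, ffreq)
    var_chan = xp if cfg.channel == "passive" else xd

    v = rolling_variance(var_chan, w)
    lv = np.log(np.clip(v, 1e-12, None))

    refine_thr = None
    if cfg.threshold_mode == "manual":
        if cfg.manual_thresholds is None:
            raise ParameterError("manual mode requires manual_thresholds")
        thr_lo, thr_hi = cfg.manual_thresholds
    else:
        _, m_att, m_det, pooled_sd = _otsu_split(lv)
        sep = m_det - m_att
        dprime = sep / max(pooled_sd, 1e-12)
        if sep < cfg.min_mode_separation or dprime < cfg.min_mode_dprime:
            raise NoAttachedPopulationError(
                f"log-variance split (sep {sep:.3f}, d' {dprime:.1f}) "
                "does not show an attached population")
        mid = 0.5 * (m_att + m_det)
        thr_lo = mid - cfg.hysteresis_frac * sep / 2.0
        thr_hi = mid + cfg.hysteresis_frac * sep / 2.0
        if cfg.refine_frac > 0:
            refine_thr = m_det - cfg.refine_frac * sep

    # dual-threshold hysteresis scan
    below = lv < thr_lo
    above = lv > thr_hi
    segments: list[tuple[int, int]] = []
    attached = False
    start = 0
    for i in range(lv.size):
        if not attached and below[i]:
            attached, start = True, i
        elif attached and above[i]:
            segments.append((start, i))
            attached = False
    if attached:
        segments.append((start, lv.size))  # boundary; dropped below

    if refine_thr is not None and segments:
        # hysteresis thresholds sit deep in the attached mode, which
        # shortens events by ~half a window per edge; walk each edge
        # outward to a crossing near the detached mode
        refined = []
        for j, (i0, i1) in enumerate(segments):
            lo_lim = segments[j - 1][1] if j > 0 else 0
            hi_lim = segments[j + 1][0] if j + 1 < len(segments) else lv.size
            while i0 > lo_lim and lv[i0 - 1] < refine_thr:
                i0 -= 1
            while i1 < hi_lim and lv[i1] < refine_thr:
                i1 += 1
            refined.append((i0, i1))
        segments = refined

    min_n = int(round(cfg.min_duration * 1e-3 * sr))
    kept = [(i0, i1) for i0, i1 in segments
            if i1 - i0 >= min_n and i0 > 0 and i1 < lv.size]
    det_mask = _detached_mask(lv.size, segments)

    kappa_trap = trace.metadata.get("mech", {}).get("kappa_trap")
    span_n = int(round(cfg.baseline_span * sr))
    margin = w // 2
    dumbbell = 0.5 * (xd + xp)

    events: list[BindingEvent] = []
    for i0, i1 in kept:
        core0, core1 = i0 + margin, i1 - margin
        if core1 - core0 < 2:
            core0, core1 = i0, i1
        lo = max(0, i0 - span_n)
        hi = min(lv.size, i1 + span_n)
        base = det_mask.copy()
        base[:lo] = False
        base[hi:] = False
        base[max(0, i0 - margin):min(lv.size, i1 + margin)] = False
        if not base.any():
            continue
        disp = dumbbell[core0:core1].mean() - dumbbell[base].mean()
        if kappa_trap is not None:
            dd = xd[core0:core1].mean() - xd[base].mean()
            dp = xp[core0:core1].mean() - xp[base].mean()
            load = kappa_trap * (dd + dp)
        else:
            load = float("nan")
        events.append(BindingEvent(
            t_start=i0 / sr,
            t_end=i1 / sr,
            dwell=(i1 - i0) / sr,
            displacement=float(disp),
            mean_load=float(load),
            var_attached=float(v[core0:core1].mean()),
            var_detached=float(v[base].mean()),
        ))
    return events


_COLUMNS = ["t_start", "t_end", "dwell", "displacement", "mean_load",
            "var_attached", "var_detached"]


def event_table(events: list[BindingEvent]) -> pd.DataFrame:
    """Lossless tabular form of a BindingEvent list."""
    if not events:
        return pd.DataFrame(columns=_COLUMNS)
    return pd.DataFrame([dataclasses.asdict(e) for e in events],
                        columns=_COLUMNS)


def events_from_table(table: pd.DataFrame) -> list[BindingEvent]:
    return [BindingEvent(**{c: float(row[c]) for c in _COLUMNS})
            for _, row in table.iterrows()]
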