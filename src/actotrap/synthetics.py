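"""Synthetic data with the stochastic structure the estimators assume.

Three generators live here:

* :func:`simulate_state_sequence` -- a Markov jump process over the
  three-state cycle detached -> post1_ADP -> rigor -> detached with
  load-dependent exit rates.
* :func:`simulate_trap_trace` -- an overdamped-Langevin realisation of
  the two trapped beads and the actin rod coupled to that state
  sequence, with an optional sinusoidal forcing on the driven bead.
* :func:`simulate_stopped_flow` -- single-exponential fluorescence
  transients with additive Gaussian noise.

The mechanical network is linear (three coordinates: driven bead,
passive bead, actin rod), so within each constant-state segment the
dynamics is a multivariate Ornstein-Uhlenbeck process with sinusoidal
drive.  It is integrated with the *exact* discretisation: transform to
the modal coordinates of Gamma^-1/2 K Gamma^-1/2, where every mode is
an independent 1-d OU process whose transition kernel and sinusoidal
response are known in closed form.  The update is exact for any step
size and reproduces equipartition statistics to machine precision; a
plain Euler-Maruyama backend (``method="euler"``) is kept for
cross-checks and refuses to run when its stability criterion
``kappa_max * dt / gamma >= 0.1`` is violated.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate, signal

from .crossbridge import k1_at, k2_at
from .params import Conditions, CycleRates, MechanicalParams, ParameterError

__all__ = [
    "SimConfig",
    "StateInterval",
    "StateTrajectory",
    "TrapTrace",
    "Transient",
    "UnstableIntegrationError",
    "crossbridge_load",
    "simulate_state_sequence",
    "simulate_trap_trace",
    "simulate_stopped_flow",
    "stiffness_matrix",
    "equilibrium_positions",
    "equipartition_covariance",
    "sampled_covariance",
    "transfer_response",
    "expected_event_displacement",
    "bead_level_displacement",
]

STATES = ("detached", "post1_ADP", "rigor")
_NEXT = {"detached": "post1_ADP", "post1_ADP": "rigor", "rigor": "detached"}


class UnstableIntegrationError(RuntimeError):
    """Euler integration refused: step too large for the stiffest mode."""


# --------------------------------------------------------------------------
# configuration and containers


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Trace-simulation configuration.

    ``forcing_amp`` is the peak-to-peak amplitude of the 100-Hz
    sinusoid applied to the driven trap; ``static_offset`` shifts both
    trap centres (nm) to impose a net load on the attached crossbridge.
    """

    duration: float
    seed: int
    sample_rate: float = 5000.0
    internal_step: float = 2.0e-5
    forcing_freq: float = 100.0
    forcing_amp: float = 100.0
    static_offset: float = 0.0
    kT: float = 4.07

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.internal_step > 1.0 / (2.0 * self.sample_rate):
            raise ParameterError(
                "internal_step must be <= 1/(2*sample_rate)")
        if self.forcing_amp < 0:
            raise ParameterError("forcing_amp must be >= 0")
        ratio = 1.0 / (self.sample_rate * self.internal_step)
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                "1/sample_rate must be an integer multiple of internal_step")

    @property
    def decimation(self) -> int:
        return int(round(1.0 / (self.sample_rate * self.internal_step)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class StateInterval:
    state: str
    t_start: float
    t_end: float
    load_at_entry: float  # pN, resisting positive


class StateTrajectory:
    """Ordered, contiguous sequence of cycle-state intervals."""

    def __init__(self, intervals: Sequence[StateInterval]):
        intervals = list(intervals)
        if not intervals:
            raise ParameterError("empty trajectory")
        for a, b in zip(intervals, intervals[1:]):
            if not math.isclose(a.t_end, b.t_start, abs_tol=1e-12):
                raise ParameterError("intervals must be contiguous")
            if _NEXT[a.state] != b.state:
                raise ParameterError(
                    f"illegal transition {a.state} -> {b.state}")
        self.intervals = intervals

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)

    @property
    def duration(self) -> float:
        return self.intervals[-1].t_end - self.intervals[0].t_start

    def attached_dwells(self, complete_only: bool = True) -> np.ndarray:
        """Durations of attached periods (post1_ADP entry to detachment)."""
        dwells, t0 = [], None
        for iv in self.intervals:
            if iv.state == "post1_ADP" and t0 is None:
                t0 = iv.t_start
            elif iv.state == "detached" and t0 is not None:
                dwells.append(iv.t_start - t0)
                t0 = None
        if t0 is not None and not complete_only:
            dwells.append(self.intervals[-1].t_end - t0)
        return np.asarray(dwells)

    def detached_dwells(self) -> np.ndarray:
        out = [iv.t_end - iv.t_start for iv in self.intervals[1:-1]
               if iv.state == "detached"]
        return np.asarray(out)

    def attached_periods(self) -> list[tuple[float, float]]:
        """(t_start, t_end) of each complete attached period."""
        out, t0 = [], None
        for iv in self.intervals:
            if iv.state == "post1_ADP" and t0 is None:
                t0 = iv.t_start
            elif iv.state == "detached" and t0 is not None:
                out.append((t0, iv.t_start))
                t0 = None
        return out

    def to_records(self) -> list[dict]:
        return [dataclasses.asdict(iv) for iv in self.intervals]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "StateTrajectory":
        return cls([StateInterval(**r) for r in records])


@dataclasses.dataclass
class TrapTrace:
    """Sampled two-bead position record with full provenance metadata."""

    x_driven: np.ndarray
    x_passive: np.ndarray
    sample_rate: float
    metadata: dict
    truth: StateTrajectory | None = None

    def __post_init__(self) -> None:
        self.x_driven = np.asarray(self.x_driven, dtype=float)
        self.x_passive = np.asarray(self.x_passive, dtype=float)
        if self.x_driven.shape != self.x_passive.shape:
            raise ParameterError("channel lengths differ")
        if self.metadata is None:
            raise ParameterError("metadata is mandatory")

    @property
    def n_samples(self) -> int:
        return self.x_driven.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclasses.dataclass
class Transient:
    """Stopped-flow fluorescence transient."""

    time: np.ndarray
    signal: np.ndarray
    truth_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 50:
            raise ParameterError("transient needs >= 50 points")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")


# --------------------------------------------------------------------------
# load bookkeeping and state sequence


def crossbridge_load(mech: MechanicalParams, state: str,
                     static_offset: float = 0.0) -> float:
    """Quasi-static load on the attached crossbridge (pN, resisting > 0).

    Force balance of the linear network with both trap centres at
    ``static_offset`` and the motor anchor at the state's stroke
    offset s gives ``F = 2*ks*km*(s - c0) / (2*ks + km)`` with ks the
    trap+link series stiffness.  This is also the cycle average under
    sinusoidal forcing, which averages to zero.
    """
    km = mech.kappa_state(state)
    if km == 0.0:
        return 0.0
    ks = mech.kappa_series
    s = mech.stroke_offset(state)
    return 2.0 * ks * km * (s - static_offset) / (2.0 * ks + km)


def simulate_state_sequence(rates: CycleRates, cond: Conditions,
                            duration: float, seed,
                            mech: MechanicalParams | None = None,
                            static_offset: float = 0.0) -> StateTrajectory:
    """Gillespie draw of the three-state cycle over ``duration`` seconds.

    If ``mech`` is given, the load entering the Bell factors is the
    quasi-static crossbridge load of each attached state (including the
    ``static_offset`` contribution), evaluated at state entry; otherwise
    ``cond.load`` is used for every attached state.
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if cond.atp <= 0:
        raise ParameterError("atp must be > 0")
    rng = np.random.default_rng(seed)
    intervals: list[StateInterval] = []
    t, state = 0.0, "detached"
    while t < duration:
        if state == "detached":
            load, rate = 0.0, rates.k_att
        else:
            if mech is not None:
                load = crossbridge_load(mech, state, static_offset)
            else:
                load = cond.load
            c = cond.with_load(load)
            if state == "post1_ADP":
                rate = k1_at(rates, c)
            else:
                rate = k2_at(rates, c) * cond.atp
        dwell = rng.exponential(1.0 / rate)
        t_end = min(t + dwell, duration)
        intervals.append(StateInterval(state, t, t_end, load))
        t = t_end
        state = _NEXT[state]
    return StateTrajectory(intervals)


# --------------------------------------------------------------------------
# linear-network algebra (oracles reused by the property tests)

_COORDS = ("driven", "passive", "actin")


def _drag_matrix(mech: MechanicalParams) -> np.ndarray:
    return np.diag([mech.drag_bead, mech.drag_bead, mech.drag_actin])


def stiffness_matrix(mech: MechanicalParams, state: str) -> np.ndarray:
    """3x3 stiffness matrix K of (driven bead, passive bead, actin rod)."""
    kt, kl = mech.kappa_trap, mech.kappa_link
    km = mech.kappa_state(state)
    return np.array([
        [kt + kl, 0.0, -kl],
        [0.0, kt + kl, -kl],
        [-kl, -kl, 2.0 * kl + km],
    ])


def _force_const(mech: MechanicalParams, state: str,
                 static_offset: float) -> np.ndarray:
    """Constant part of the force vector (trap centres + motor anchor)."""
    kt = mech.kappa_trap
    km = mech.kappa_state(state)
    s = mech.stroke_offset(state)
    return np.array([kt * static_offset, kt * static_offset, km * s])


def equilibrium_positions(mech: MechanicalParams, state: str,
                          static_offset: float = 0.0) -> np.ndarray:
    """Mean coordinates of the network in the given state (nm)."""
    K = stiffness_matrix(mech, state)
    return np.linalg.solve(K, _force_const(mech, state, static_offset))


def equipartition_covariance(mech: MechanicalParams, state: str,
                             kT: float = 4.07) -> np.ndarray:
    """Stationary covariance kT * K^-1 of the instantaneous coordinates."""
    return kT * np.linalg.inv(stiffness_matrix(mech, state))


def _modal(mech: MechanicalParams, state: str):
    """Eigendecomposition of Gamma^-1/2 K Gamma^-1/2 (symmetric, PD)."""
    G = _drag_matrix(mech)
    g_isqrt = 1.0 / np.sqrt(np.diag(G))
    S = (g_isqrt[:, None] * stiffness_matrix(mech, state)) * g_isqrt[None, :]
    lam, V = np.linalg.eigh(S)
    return lam, V, g_isqrt


def sampled_covariance(mech: MechanicalParams, state: str,
                       cfg: SimConfig) -> np.ndarray:
    """Stationary covariance of the block-averaged (decimated) output.

    Decimation averages ``m`` consecutive internal samples, which
    attenuates the fast modes; the closed form below is the covariance
    actually expected of a :class:`TrapTrace` channel.
    """
    lam, V, g_isqrt = _modal(mech, state)
    h, m = cfg.internal_step, cfg.decimation
    e = np.exp(-lam * h)
    var_mode = cfg.kT / lam
    j = np.arange(1, m)
    acc = np.array([(m + 2.0 * np.sum((m - j) * ei ** j)) / m ** 2 for ei in e])
    var_block = var_mode * acc
    B = (g_isqrt[:, None] * V)
    return B @ np.diag(var_block) @ B.T


def transfer_response(mech: MechanicalParams, state: str, freq: float,
                      amp: float) -> np.ndarray:
    """Complex steady-state response of the coordinates to the forcing.

    The driven trap centre moves as ``Im[amp * exp(i w t)]`` (``amp`` =
    half the peak-to-peak amplitude); returns the complex amplitudes X
    such that ``x_k(t) = Im[X_k exp(i w t)]``,
    ``X = (K + i w Gamma)^-1 f`` with ``f = (kappa_trap*amp, 0, 0)``.
    """
    w = 2.0 * math.pi * freq
    K = stiffness_matrix(mech, state)
    G = _drag_matrix(mech)
    f = np.array([mech.kappa_trap * amp, 0.0, 0.0], dtype=complex)
    return np.linalg.solve(K + 1j * w * G, f)


# --------------------------------------------------------------------------
# exact trace integration


def _segment_exact(x0: np.ndarray, n: int, t0: float, mech: MechanicalParams,
                   state: str, cfg: SimConfig, rng: np.random.Generator):
    """Exact OU propagation over n internal steps; returns (3, n) array."""
    h = cfg.internal_step
    lam, V, g_isqrt = _modal(mech, state)
    g_sqrt = 1.0 / g_isqrt
    # modal drive: constant + sinusoid
    f0 = _force_const(mech, state, cfg.static_offset)
    u0 = V.T @ (g_isqrt * f0)
    zpart_const = u0 / lam
    w = 2.0 * math.pi * cfg.forcing_freq
    amp = 0.5 * cfg.forcing_amp
    t = t0 + h * np.arange(1, n + 1)
    if amp > 0.0:
        fph = np.array([mech.kappa_trap * amp, 0.0, 0.0])
        U = V.T @ (g_isqrt * fph)
        denom = lam + 1j * w
        zpart = zpart_const[:, None] + np.imag(
            (U / denom)[:, None] * np.exp(1j * w * t)[None, :])
        zpart_t0 = zpart_const + np.imag(U / denom * np.exp(1j * w * t0))
    else:
        zpart = np.repeat(zpart_const[:, None], n, axis=1)
        zpart_t0 = zpart_const
    z0 = V.T @ (g_sqrt * x0)
    decay = np.exp(-lam[:, None] * (t - t0)[None, :])
    z_det = zpart + (z0 - zpart_t0)[:, None] * decay
    # stochastic part: AR(1) per mode started at zero
    e = np.exp(-lam * h)
    sd = np.sqrt(cfg.kT / lam * (1.0 - e ** 2))
    xi = rng.standard_normal((3, n)) * sd[:, None]
    z_noise = np.empty_like(xi)
    for i in range(3):
        z_noise[i] = signal.lfilter([1.0], [1.0, -e[i]], xi[i])
    z = z_det + z_noise
    return g_isqrt[:, None] * (V @ z)


def _segment_euler(x0: np.ndarray, n: int, t0: float, mech: MechanicalParams,
                   state: str, cfg: SimConfig, rng: np.random.Generator):
    """Euler-Maruyama propagation; refuses unstable steps."""
    h = cfg.internal_step
    G = np.array([mech.drag_bead, mech.drag_bead, mech.drag_actin])
    K = stiffness_matrix(mech, state)
    kmax_over_g = np.max(np.sum(np.abs(K), axis=1) / G)
    if kmax_over_g * h >= 0.1:
        raise UnstableIntegrationError(
            f"kappa_max*dt/gamma = {kmax_over_g * h:.3g} >= 0.1; "
            "reduce internal_step or use method='exact'")
    f0 = _force_const(mech, state, cfg.static_offset)
    w = 2.0 * math.pi * cfg.forcing_freq
    amp = 0.5 * cfg.forcing_amp
    sd = np.sqrt(2.0 * cfg.kT * h / G)
    out = np.empty((3, n))
    x = x0.copy()
    for k in range(n):
        t = t0 + k * h
        f = f0.copy()
        f[0] += mech.kappa_trap * amp * math.sin(w * t)
        x = x + h / G * (f - K @ x) + sd * rng.standard_normal(3)
        out[:, k] = x
    return out


class _Decimator:
    """Streaming block-average decimation of internal-rate samples."""

    def __init__(self, factor: int):
        self.factor = factor
        self.carry = np.empty((3, 0))
        self.blocks: list[np.ndarray] = []

    def push(self, seg: np.ndarray) -> None:
        buf = np.concatenate([self.carry, seg], axis=1)
        n_full = (buf.shape[1] // self.factor) * self.factor
        if n_full:
            b = buf[:, :n_full].reshape(3, -1, self.factor).mean(axis=2)
            self.blocks.append(b)
        self.carry = buf[:, n_full:]

    def result(self) -> np.ndarray:
        if not self.blocks:
            return np.empty((3, 0))
        return np.concatenate(self.blocks, axis=1)


def simulate_trap_trace(traj: StateTrajectory, mech: MechanicalParams,
                        cfg: SimConfig, rates: CycleRates | None = None,
                        cond: Conditions | None = None,
                        method: str = "exact") -> TrapTrace:
    """Integrate the bead/rod network along a state trajectory.

    Piecewise-constant stiffness per state; within each segment the
    linear SDE is propagated exactly (default) or by Euler-Maruyama.
    Output is block-averaged down to ``cfg.sample_rate``.  The returned
    metadata records every parameter plus derived calibration numbers
    (series-compliance factors, expected event displacement).
    """
    if traj.duration < cfg.duration - 1e-9:
        raise ParameterError("trajectory shorter than requested duration")
    if method not in ("exact", "euler"):
        raise ParameterError(f"unknown method {method!r}")
    rng = np.random.default_rng(np.random.PCG64(
        np.random.SeedSequence([cfg.seed, 0xACE])))
    prop = _segment_exact if method == "exact" else _segment_euler

    first = traj.intervals[0].state
    x = equilibrium_positions(mech, first, cfg.static_offset)
    C0 = equipartition_covariance(mech, first, cfg.kT)
    x = x + np.linalg.cholesky(C0) @ rng.standard_normal(3)

    h = cfg.internal_step
    n_total = int(round(cfg.duration / h))
    dec = _Decimator(cfg.decimation)
    pos = 0
    for iv in traj:
        end = min(int(round(iv.t_end / h)), n_total)
        n = end - pos
        if n <= 0:
            continue
        seg = prop(x, n, pos * h, mech, iv.state, cfg, rng)
        x = seg[:, -1].copy()
        dec.push(seg)
        pos = end
        if pos >= n_total:
            break
    out = dec.result()

    meta = {
        "sim_config": cfg.to_dict(),
        "mech": mech.to_dict(),
        "kT": cfg.kT,
        "method": method,
        "seed": cfg.seed,
    }
    if rates is not None:
        meta["rates"] = rates.to_dict()
    if cond is not None:
        meta["conditions"] = cond.to_dict()
    ks = mech.kappa_series
    beta = mech.kappa_link / (mech.kappa_trap + mech.kappa_link)
    meta["kappa_series"] = ks
    meta["bead_coupling"] = beta
    meta["state_levels"] = {
        st: bead_level_displacement(mech, st, cfg.static_offset)
        for st in ("post1_ADP", "rigor")}
    meta["state_loads"] = {
        st: crossbridge_load(mech, st, cfg.static_offset)
        for st in ("post1_ADP", "rigor")}
    if rates is not None and cond is not None:
        disp = expected_event_displacement(rates, mech, cond,
                                           cfg.static_offset)
        meta["truth_mean_displacement"] = disp
        meta["stroke_recovery_factor"] = disp / mech.ws_total
    return TrapTrace(out[0], out[1], cfg.sample_rate, meta, truth=traj)


# --------------------------------------------------------------------------
# calibration helpers


def bead_level_displacement(mech: MechanicalParams, state: str,
                            static_offset: float = 0.0) -> float:
    """Mean bead displacement (attached minus detached baseline) in nm.

    Static force balance: the rod settles at
    ``x_a - c0 = km (s - c0) / (2 ks + km)`` and each bead follows with
    coupling ``kl / (kt + kl)``.
    """
    km = mech.kappa_state(state)
    if km == 0.0:
        return 0.0
    ks = mech.kappa_series
    beta = mech.kappa_link / (mech.kappa_trap + mech.kappa_link)
    s = mech.stroke_offset(state)
    return beta * km * (s - static_offset) / (2.0 * ks + km)


def expected_event_displacement(rates: CycleRates, mech: MechanicalParams,
                                cond: Conditions,
                                static_offset: float = 0.0) -> float:
    """Expected event-mean bead displacement E[(T1 l1 + T2 l2)/(T1+T2)].

    T1, T2 are the exponential dwells of the two attached states at
    their quasi-static loads and l1, l2 the bead-level displacement of
    each state.  This is the unambiguous ground truth for working-
    stroke recovery; dividing by ``ws_total`` gives the series-
    compliance recovery factor stored in trace metadata.
    """
    l1 = bead_level_displacement(mech, "post1_ADP", static_offset)
    l2 = bead_level_displacement(mech, "rigor", static_offset)
    a1 = k1_at(rates, cond.with_load(
        crossbridge_load(mech, "post1_ADP", static_offset)))
    a2 = k2_at(rates, cond.with_load(
        crossbridge_load(mech, "rigor", static_offset))) * cond.atp
    if math.isclose(a1, a2, rel_tol=1e-12):
        frac1 = 0.5
    else:
        # U = T1/(T1+T2) has density a1*a2 / (a2 + (a1-a2) u)^2 on (0,1)
        def dens(u):
            return u * a1 * a2 / (a2 + (a1 - a2) * u) ** 2
        frac1, _ = integrate.quad(dens, 0.0, 1.0)
    return l2 + (l1 - l2) * frac1


# --------------------------------------------------------------------------
# stopped flow


def simulate_stopped_flow(k_obs: float, amplitude: float, y0: float,
                          noise_sd: float, duration: float, n_points: int,
                          seed) -> Transient:
    """Single-exponential transient y0 + A*(1 - exp(-k t)) + noise."""
    if k_obs <= 0:
        raise ParameterError("k_obs must be > 0")
    if duration < 5.0 / k_obs:
        raise ParameterError("duration must be >= 5/k_obs")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    y = y0 + amplitude * (1.0 - np.exp(-k_obs * t))
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n_points)
    return Transient(t, y, truth_rate=k_obs)
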