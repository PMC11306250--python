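"""Closed-form chemo-mechanics of the single-headed ATPase cycle.

The attached phase of the cycle is two sequential exponential steps:
ADP release (rate ``k1``) completing the working stroke, then
ATP-induced detachment (pseudo-first-order rate ``k2 * [ATP]``).  Both
exit rates depend on the load F on the crossbridge through
``k(F) = k0 * exp(-F * d / kT)`` with resisting load positive.
"""

from __future__ import annotations

import math

from .params import Conditions, CycleRates, MechanicalParams, ParameterError

__all__ = [
    "load_rate",
    "k1_at",
    "k2_at",
    "mean_attached_time",
    "apparent_duty_ratio",
    "predicted_gliding_velocity",
    "stall_force",
    "rigor_occupancy",
]


def load_rate(k0: float, d: float, cond: Conditions) -> float:
    """Exponential load dependence of a transition rate.

    Returns ``k0 * exp(-F * d / kT)`` where F is ``cond.load`` (pN,
    resisting positive).  ``log k`` is affine in F with slope ``-d/kT``.
    """
    if k0 <= 0:
        raise ParameterError("k0 must be > 0")
    if d < 0:
        raise ParameterError("d must be >= 0")
    return k0 * math.exp(-cond.load * d / cond.kT)


def k1_at(rates: CycleRates, cond: Conditions) -> float:
    """ADP-release rate at the given load (s^-1)."""
    return load_rate(rates.k1_0, rates.d1, cond)


def k2_at(rates: CycleRates, cond: Conditions) -> float:
    """Second-order ATP-binding constant at the given load (mM^-1 s^-1)."""
    return load_rate(rates.k2_0, rates.d2, cond)


def mean_attached_time(rates: CycleRates, cond: Conditions,
                       zero_atp: str = "error") -> float:
    """Mean actin-attached time t_on = 1/k1(F) + 1/(k2(F)*[ATP]) in s.

    With ``zero_atp="error"`` (default) an ATP concentration of zero
    raises; with ``zero_atp="inf"`` it returns ``math.inf``.
    """
    if cond.atp == 0:
        if zero_atp == "inf":
            return math.inf
        raise ParameterError("atp must be > 0 (detachment requires ATP)")
    return 1.0 / k1_at(rates, cond) + 1.0 / (k2_at(rates, cond) * cond.atp)


def apparent_duty_ratio(rates: CycleRates, cond: Conditions) -> float:
    """Fraction of the cycle spent attached, t_on / (t_on + 1/k_att)."""
    t_on = mean_attached_time(rates, cond)
    t_off = 1.0 / rates.k_att
    return t_on / (t_on + t_off)


def predicted_gliding_velocity(mech: MechanicalParams, rates: CycleRates,
                               cond: Conditions) -> float:
    """Single-attached-head translocation speed, ws_total / t_on (nm/s).

    This is an upper bound on the measured gliding speed; only the
    ratio between variants is a quantitative prediction.
    """
    if mech.ws_total == 0:
        return 0.0
    return mech.ws_total / mean_attached_time(rates, cond)


def stall_force(mech: MechanicalParams, state: str = "rigor") -> float:
    """Stall force ws_total * kappa(state) in pN.

    ``state`` selects which crossbridge stiffness applies ("pre" for
    the ADP-bound states, "rigor" for the nucleotide-free state).
    """
    if state == "pre":
        kappa = mech.kappa_pre
    elif state == "rigor":
        kappa = mech.kappa_rigor
    else:
        raise ParameterError(f"unknown stiffness state {state!r}")
    return mech.ws_total * kappa


def rigor_occupancy(rates: CycleRates, cond: Conditions) -> float:
    """Fraction of the attached time spent nucleotide-free.

    Equals ``(1/(k2(F)*atp)) / t_on``; the complement is the occupancy
    of the ADP-bound (pre-rigor) state, and the two sum to one exactly.
    """
    t_on = mean_attached_time(rates, cond)
    t_rigor = 1.0 / (k2_at(rates, cond) * cond.atp)
    return t_rigor / t_on
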