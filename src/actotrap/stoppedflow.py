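"""Solution kinetics: single-exponential transients and ATP titrations."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .params import ParameterError
from .synthetics import Transient

__all__ = ["TransientFit", "fit_transient", "second_order_rate"]


@dataclasses.dataclass(frozen=True)
class TransientFit:
    """Single-exponential fit of a stopped-flow transient."""

    k_obs: float
    amplitude: float
    y0: float
    stderr: dict
    lag_flag: bool      # early-time residuals fail a runs test


def _runs_test_p(signs: np.ndarray) -> float:
    """Two-sided p-value of the Wald-Wolfowitz runs test on a sign array."""
    signs = signs[signs != 0]
    n = signs.size
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0 or n < 10:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = (2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n)
           / (n ** 2 * (n - 1.0)))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def fit_transient(transient: Transient, dead_time: float = 1e-3,
                  lag_alpha: float = 0.01) -> TransientFit:
    """Least-squares single exponential y0 + A*(1 - exp(-k t)).

    The first ``dead_time`` seconds are discarded (mixing dead time;
    set 0 to disable).  ``lag_flag`` is set when the residuals of the
    first decade of the reaction (t <= ln(10)/k_obs) fail a runs test
    at significance ``lag_alpha`` -- the signature of a lag phase.
    """
    mask = transient.time >= dead_time
    t = transient.time[mask] - dead_time
    y = transient.signal[mask]
    if t.size < 50:
        raise ParameterError("need >= 50 points after dead-time truncation")

    span = y[-1] - y[0]
    k_guess = 1.0 / max(t[-1] / 5.0, 1e-12)
    p0 = [span if span != 0 else 1.0, k_guess, float(y[0])]

    def model(t_, A, k, y0):
        return y0 + A * (1.0 - np.exp(-k * t_))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except RuntimeError as exc:
        raise ParameterError(f"transient fit failed: {exc}") from exc
    A, k, y0 = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if t[-1] < 3.0 / k:
        raise ParameterError("transient spans less than 3/k_obs")

    resid = y - model(t, *popt)
    early = t <= np.log(10.0) / k
    p_runs = _runs_test_p(np.sign(resid[early]))
    return TransientFit(k_obs=float(k), amplitude=float(A), y0=float(y0),
                        stderr={"amplitude": float(se[0]),
                                "k_obs": float(se[1]),
                                "y0": float(se[2])},
                        lag_flag=bool(p_runs < lag_alpha))


def second_order_rate(points, k_se=None) -> dict:
    """Weighted linear regression of k_obs against [ATP].

    ``points`` is a list of (atp mM, k_obs s^-1) pairs at >= 3 ATP
    levels (replicates allowed).  The slope is the apparent
    second-order rate constant (mM^-1 s^-1); the intercept is free and
    reported.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be (atp, k_obs) pairs")
    atp, k = pts[:, 0], pts[:, 1]
    if np.unique(atp).size < 3:
        raise ParameterError("need >= 3 distinct ATP levels")
    if k_se is not None:
        se = np.asarray(k_se, dtype=float)
        w = np.where(np.isfinite(se) & (se > 0), 1.0 / se ** 2, 0.0)
        if not np.any(w > 0):
            w = np.ones_like(k)
    else:
        w = np.ones_like(k)
    X = np.stack([np.ones_like(atp), atp], axis=1)
    A = X.T @ (X * w[:, None])
    beta = np.linalg.solve(A, X.T @ (w * k))
    cov = np.linalg.inv(A)
    resid = k - X @ beta
    dof = max(k.size - 2, 1)
    scale = float(resid @ (w * resid)) / dof
    if k_se is None:
        cov = cov * scale
    se_beta = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return {"slope": float(beta[1]), "intercept": float(beta[0]),
            "slope_se": float(se_beta[1]), "intercept_se": float(se_beta[0])}
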