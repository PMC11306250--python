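"""Load-resolved kinetics: bin events by load and fit the Bell relation.

The Bell relation ``k = k0 * exp(-F d / kT)`` is linear in log space,
so the fit is a weighted linear regression of log k on F; the slope is
``-d/kT`` and the intercept ``log k0``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .detection import BindingEvent
from .params import KT_DEFAULT, ParameterError

__all__ = ["BellFit", "bin_events_by_load", "fit_bell"]


@dataclasses.dataclass(frozen=True)
class BellFit:
    """Fitted zero-load rate and load-sensitivity distance."""

    k0: float           # s^-1 (or mM^-1 s^-1 for second-order rates)
    d: float            # nm; resisting load positive
    k0_se: float
    d_se: float
    n_bins: int
    bins: tuple         # ((F, k, k_se), ...) records actually fitted


def bin_events_by_load(events: list[BindingEvent],
                       bin_edges,
                       min_per_bin: int = 10) -> list[list[BindingEvent]]:
    """Partition events by ``mean_load`` into the given bins.

    Bins with fewer than ``min_per_bin`` events are dropped with a
    warning; an error is raised if nothing survives.
    """
    if not events:
        raise ParameterError("empty event list")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin_edges must be increasing with >= 2 values")
    loads = np.asarray([e.mean_load for e in events])
    if np.any(~np.isfinite(loads)):
        raise ParameterError("events must carry finite mean_load")
    which = np.digitize(loads, edges) - 1
    out = []
    for b in range(edges.size - 1):
        members = [e for e, w in zip(events, which) if w == b]
        if 0 < len(members) < min_per_bin:
            warnings.warn(f"bin {b} has only {len(members)} events; dropped",
                          stacklevel=2)
            continue
        if members:
            out.append(members)
    if not out:
        raise ParameterError("all load bins underpopulated")
    return out


def fit_bell(loads, rates, rate_se=None, kT: float = KT_DEFAULT) -> BellFit:
    """Weighted least squares of log k against F.

    ``rate_se`` (per-point rate standard errors) sets the weights via
    error propagation ``se(log k) = se(k)/k``; omitted, all points
    weigh equally.  Needs at least 3 (F, k) points and positive rates.
    """
    F = np.asarray(loads, dtype=float)
    k = np.asarray(rates, dtype=float)
    if F.size != k.size or F.size < 3:
        raise ParameterError("need >= 3 (F, k) points")
    if np.any(k <= 0):
        raise ParameterError("rates must be positive")
    y = np.log(k)
    if rate_se is not None:
        se = np.asarray(rate_se, dtype=float)
        sigma = np.where(np.isfinite(se) & (se > 0), se / k, np.nan)
        if np.all(np.isnan(sigma)):
            sigma = np.ones_like(y)
        else:
            fill = np.nanmax(sigma) * 10.0
            sigma = np.where(np.isnan(sigma), fill, sigma)
    else:
        sigma = np.ones_like(y)
        se = np.full_like(y, np.nan)
    w = 1.0 / sigma ** 2

    X = np.stack([np.ones_like(F), -F / kT], axis=1)
    WX = X * w[:, None]
    A = X.T @ WX
    b = WX.T @ y
    try:
        beta = np.linalg.solve(A, b)
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("singular Bell design (degenerate loads)") from exc
    resid = y - X @ beta
    dof = max(F.size - 2, 1)
    if rate_se is None:
        cov = cov * float(resid @ (w * resid)) / dof
    logk0, d = beta
    se_beta = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    k0 = float(np.exp(logk0))
    recs = tuple((float(f), float(kk), float(s))
                 for f, kk, s in zip(F, k, se))
    return BellFit(k0=k0, d=float(d), k0_se=float(k0 * se_beta[0]),
                   d_se=float(se_beta[1]), n_bins=int(F.size), bins=recs)
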