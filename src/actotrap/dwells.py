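"""Event-statistics estimators: dwell kinetics, working stroke, duty ratio.

The attached-time survival function is fitted with a free-amplitude
double exponential ``A1 exp(-k1 t) + A2 exp(-k2 t) (+ y0)``.  For the
sequential two-step attached phase this family contains the true
(hypoexponential) survival exactly -- one amplitude comes out
negative -- so the estimator is consistent; components are labelled
afterwards by their ATP dependence, never by magnitude.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats

from .detection import BindingEvent
from .params import ParameterError

__all__ = [
    "DwellFit",
    "GaussianFit",
    "ClassifiedRates",
    "FitError",
    "ClassificationError",
    "cumulative_dwell_fit",
    "classify_rates",
    "displacement_gaussian_fit",
    "working_stroke_estimate",
    "apparent_duty_and_onrate",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last residual norm."""


class ClassificationError(RuntimeError):
    """No dwell component is ATP-invariant within tolerance."""


@dataclasses.dataclass(frozen=True)
class DwellFit:
    """Double-exponential survival fit, components ordered k1 < k2_obs."""

    A1: float
    k1: float
    A2: float
    k2_obs: float
    y0: float
    stderr: dict
    n_events: int
    R2: float

    def components(self) -> list[tuple[float, float]]:
        """[(rate, stderr), ...] in record order (slow first)."""
        return [(self.k1, self.stderr["k1"]),
                (self.k2_obs, self.stderr["k2_obs"])]


@dataclasses.dataclass(frozen=True)
class GaussianFit:
    """Single-Gaussian displacement fit; xc is the working stroke."""

    xc: float
    w: float    # width; the Gaussian sigma is w/2
    A: float    # area
    stderr: dict


@dataclasses.dataclass(frozen=True)
class ClassifiedRates:
    """ATP-classified kinetics: zero-load k1 (s^-1) and k2 (mM^-1 s^-1)."""

    k1_0: float
    k1_se: float
    k2_0: float
    k2_se: float


def _survival_points(dwells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.sort(np.asarray(dwells, dtype=float))
    n = t.size
    s = 1.0 - (np.arange(1, n + 1) - 0.5) / n
    return t, s


def _double_exp_design(t: np.ndarray, ka: float, kb: float,
                       free_y0: bool) -> np.ndarray:
    cols = [np.exp(-ka * t), np.exp(-kb * t)]
    if free_y0:
        cols.append(np.ones_like(t))
    return np.stack(cols, axis=1)


def cumulative_dwell_fit(dwells, free_y0: bool = False,
                         weighted: bool = True,
                         min_events: int = 50,
                         n_boot: int = 0, seed=0) -> DwellFit:
    """Fit the unbinned empirical survival with a double exponential.

    Uses variable projection: the rates are optimised by multistart
    nonlinear least squares while the amplitudes are solved linearly
    at each step, which makes the fit robust to poor starting values.
    ``weighted=True`` (default) applies binomial ECDF variance weights
    ``n / (S (1-S))``, which markedly reduces the bias of the weakly
    identified component; ``weighted=False`` gives the plain
    unweighted fit.  Parameter standard errors come from the Jacobian
    at the optimum, or from ``n_boot`` bootstrap resamples when
    requested (survival points are serially correlated, so the
    bootstrap errors are the honest ones).
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < min_events:
        raise ParameterError(
            f"need >= {min_events} dwells, got {dwells.size}")
    if np.any(dwells <= 0):
        raise ParameterError("dwells must be positive")
    t, s = _survival_points(dwells)
    if weighted:
        wts = np.sqrt(t.size / np.clip(s * (1.0 - s), 1e-4, None))
    else:
        wts = np.ones_like(s)

    def amplitudes(logk):
        X = _double_exp_design(t, np.exp(logk[0]), np.exp(logk[1]), free_y0)
        coef, *_ = np.linalg.lstsq(X * wts[:, None], s * wts, rcond=None)
        return coef, X

    def resid(logk):
        coef, X = amplitudes(logk)
        return (X @ coef - s) * wts

    k_mean = 1.0 / t.mean()
    best = None
    for fa, fb in ((0.3, 3.0), (1.0, 8.0), (0.1, 1.0), (0.5, 1.5),
                   (0.2, 20.0)):
        p0 = np.log([k_mean * fa, k_mean * fb])
        try:
            res = optimize.least_squares(resid, p0, method="trf",
                                         bounds=([-10, -10], [10, 10]),
                                         max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        last = float("nan") if best is None else float(np.sqrt(2 * best.cost))
        raise FitError(f"survival fit did not converge (residual {last:.3g})")

    ka, kb = np.exp(best.x)
    coef, X = amplitudes(best.x)
    fitted = X @ coef
    ss_res = float(np.sum(((s - fitted) * wts) ** 2))
    ss_plain = float(np.sum((s - fitted) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_plain / ss_tot if ss_tot > 0 else 1.0

    # full-parameter covariance at the optimum
    if free_y0:
        amp_a, amp_b, y0 = coef
    else:
        amp_a, amp_b = coef
        y0 = 0.0

    def model(params):
        a1, lka, a2, lkb = params[:4]
        out = a1 * np.exp(-np.exp(lka) * t) + a2 * np.exp(-np.exp(lkb) * t)
        if free_y0:
            out = out + params[4]
        return out

    p_opt = [amp_a, math_log(ka), amp_b, math_log(kb)]
    if free_y0:
        p_opt.append(y0)
    p_opt = np.asarray(p_opt)
    J = _num_jac(model, p_opt) * wts[:, None]
    dof = max(t.size - p_opt.size, 1)
    sigma2 = ss_res / dof
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p_opt.size, np.inf)
    # translate log-rate errors to rate errors
    se_ka = se[1] * ka
    se_kb = se[3] * kb

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            sample = rng.choice(dwells, size=dwells.size, replace=True)
            try:
                f = cumulative_dwell_fit(sample, free_y0=free_y0,
                                         weighted=weighted,
                                         min_events=min_events)
                boots.append(sorted([f.k1, f.k2_obs]))
            except (FitError, ParameterError):
                continue
        if len(boots) >= max(10, n_boot // 2):
            arr = np.asarray(boots)
            se_sorted = arr.std(axis=0, ddof=1)
            if ka < kb:
                se_ka, se_kb = se_sorted
            else:
                se_kb, se_ka = se_sorted

    comp = [(amp_a, se[0], ka, se_ka), (amp_b, se[2], kb, se_kb)]
    comp.sort(key=lambda c: c[2])
    (A1, sA1, K1, s1), (A2, sA2, K2, s2) = comp
    if A1 > 0 and A2 > 0 and not (0.5 < (A1 + A2 + y0) < 1.5):
        warnings.warn("double-exponential amplitudes look pathological",
                      stacklevel=2)
    return DwellFit(A1=float(A1), k1=float(K1), A2=float(A2),
                    k2_obs=float(K2), y0=float(y0),
                    stderr={"A1": float(sA1), "k1": float(s1),
                            "A2": float(sA2), "k2_obs": float(s2),
                            "y0": float(se[4]) if free_y0 else 0.0},
                    n_events=int(dwells.size), R2=float(r2))


def math_log(x: float) -> float:
    return float(np.log(x))


def _num_jac(f, p, eps=1e-6):
    f0 = f(p)
    J = np.empty((f0.size, p.size))
    for i in range(p.size):
        dp = p.copy()
        step = eps * max(1.0, abs(p[i]))
        dp[i] += step
        J[:, i] = (f(dp) - f0) / step
    return J


def _finite_weight(se: float) -> float:
    if se is None or not np.isfinite(se) or se <= 0:
        return 0.0
    return 1.0 / se ** 2


def classify_rates(fits: list[DwellFit], atps: list[float],
                   alpha: float = 0.01) -> ClassifiedRates:
    """Label dwell components by ATP dependence across concentrations.

    The component whose rate is invariant across ATP levels is the
    ADP-release rate k1; the other is regressed through the origin
    against [ATP] to give the second-order k2.  The assignment is the
    one minimising the joint inverse-variance-weighted misfit of both
    roles, and a chi-square consistency test at significance ``alpha``
    rejects classifications where no component is ATP-invariant.  All
    averages are inverse-variance weighted, so a level where the fit
    is degenerate (huge stderr) contributes nothing.  Invariant to
    permuting component order inside each fit.
    """
    if len(fits) != len(atps) or len(fits) < 2:
        raise ParameterError("need fits at >= 2 ATP concentrations")
    comps = []
    for f in fits:
        pair = f.components()
        # a fit whose two rates are not separated by at least 2x is
        # unresolved: component identity is ambiguous within the gap,
        # so widen both errors by half the gap (in quadrature)
        if f.k2_obs < 2.0 * f.k1:
            gap = 0.5 * (f.k2_obs - f.k1)
            pair = [(k, float(np.hypot(se, gap))) for k, se in pair]
        comps.append(pair)

    best = None
    for mask in range(2 ** len(fits)):
        inv = [comps[i][(mask >> i) & 1] for i in range(len(fits))]
        var = [comps[i][1 - ((mask >> i) & 1)] for i in range(len(fits))]
        wsum = sum(_finite_weight(se) for _, se in inv)
        if wsum == 0:
            continue
        k_bar = sum(k * _finite_weight(se) for k, se in inv) / wsum
        q_inv = sum(_finite_weight(se) * (k - k_bar) ** 2 for k, se in inv)
        # the complementary component must lie on a line through the origin
        num = sum(_finite_weight(se) * a * k
                  for (k, se), a in zip(var, atps))
        den = sum(_finite_weight(se) * a * a
                  for (_, se), a in zip(var, atps))
        if den == 0:
            continue
        slope = num / den
        q_var = sum(_finite_weight(se) * (k - slope * a) ** 2
                    for (k, se), a in zip(var, atps))
        q = q_inv + q_var
        if best is None or q < best[0]:
            best = (q, inv, var, k_bar, wsum)
    if best is None:
        raise ClassificationError("no usable component errors")
    q, inv, var, k_bar, wsum = best

    q_inv = sum(_finite_weight(se) * (k - k_bar) ** 2 for k, se in inv)
    n_used = sum(1 for _, se in inv if _finite_weight(se) > 0)
    if n_used >= 2 and q_inv > stats.chi2.ppf(1.0 - alpha, n_used - 1):
        raise ClassificationError(
            f"no ATP-invariant component: consistency chi2 = {q_inv:.2f} "
            f"exceeds the {1 - alpha:.2%} quantile for {n_used - 1} dof")

    k1_0 = k_bar
    k1_se = wsum ** -0.5

    num = sum(_finite_weight(se) * a * k for (k, se), a in zip(var, atps))
    den = sum(_finite_weight(se) * a * a for (_, se), a in zip(var, atps))
    if den == 0:
        raise ClassificationError("ATP-dependent component has no usable errors")
    k2_0 = num / den
    k2_se = den ** -0.5
    return ClassifiedRates(k1_0=float(k1_0), k1_se=float(k1_se),
                           k2_0=float(k2_0), k2_se=float(k2_se))


def _gauss(x, A, xc, w):
    return A / (w * np.sqrt(np.pi / 2.0)) * np.exp(-2.0 * ((x - xc) / w) ** 2)


def displacement_gaussian_fit(displacements, bin_width: float = 2.0,
                              min_events: int = 100) -> GaussianFit:
    """Binned least-squares single-Gaussian fit of event displacements.

    The stated ``bin_width`` (2 nm default) is narrowed automatically
    when the sample is so tight that fewer than eight bins would be
    populated.  A crude bimodality screen (Sarle's coefficient) emits a
    warning but the fit is still returned.
    """
    x = np.asarray(displacements, dtype=float)
    if x.size < min_events:
        raise ParameterError(f"need >= {min_events} displacements")
    span = x.max() - x.min()
    bw = bin_width
    if span / bw < 8:
        bw = max(span / 12.0, 1e-6)
    edges = np.arange(x.min() - bw, x.max() + 2 * bw, bw)
    hist, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = hist / (x.size * bw)

    n = x.size
    skew = stats.skew(x)
    kurt = stats.kurtosis(x, fisher=False)
    sarle = (skew ** 2 + 1.0) / (
        kurt + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)) - 3.0) \
        if n > 3 else 0.0
    if sarle > 0.7:
        warnings.warn("displacement distribution looks bimodal", stacklevel=2)

    p0 = [1.0, float(x.mean()), float(2.0 * x.std())]
    try:
        popt, pcov = optimize.curve_fit(_gauss, centers, dens, p0=p0,
                                        maxfev=5000)
    except RuntimeError as exc:
        raise FitError(str(exc)) from exc
    A, xc, w = popt
    w = abs(w)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return GaussianFit(xc=float(xc), w=float(w), A=float(A),
                       stderr={"A": float(se[0]), "xc": float(se[1]),
                               "w": float(se[2])})


def working_stroke_estimate(fit: GaussianFit, trace) -> float:
    """Convert a bead-level displacement centre to a working stroke.

    Divides by the series-compliance recovery factor recorded in the
    trace metadata (expected event-mean bead displacement per nm of
    working stroke).
    """
    factor = trace.metadata.get("stroke_recovery_factor")
    if not factor:
        raise ParameterError("trace metadata lacks stroke_recovery_factor")
    return fit.xc / factor


def apparent_duty_and_onrate(events: list[BindingEvent],
                             total_time: float,
                             min_events: int = 20) -> dict:
    """Apparent duty ratio and real on-rate from an event list.

    duty = sum(dwell)/total_time; on_rate = n_events / total detached
    time.
    """
    if len(events) < min_events:
        raise ParameterError(f"need >= {min_events} events")
    t_on = float(sum(e.dwell for e in events))
    if t_on > total_time:
        raise ParameterError("events exceed total_time")
    detached = total_time - t_on
    if detached <= 0:
        raise ParameterError("zero detached time")
    return {"duty": t_on / total_time,
            "on_rate": len(events) / detached}
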