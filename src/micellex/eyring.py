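"""Modified Eyring kinetics for micelle exchange relaxation.

The tagged-fraction relaxation F(t) of chains exchanging between a micelle
and the bulk is described by a three-parameter rate equation

    dF/dt = -k1 * exp(F/eps) - k2 + (k1 + k2) * exp(-F/eps)

which reduces to the classic Eyring barrier-hopping equation
``dF/dt = -2 k1 sinh(F/eps)`` when k2 -> 0.  ``k1`` sets the kinetics of the
initial and logarithmic regimes, ``k2`` the observable exponential regime and
``eps`` (~1e-2) is the crossover value of the correlation function.  The
stationary state is F = 0, i.e. complete mixing of tagged and untagged
chains.

In the variable ``y = exp(F/eps)`` the equation is a constant-coefficient
Riccati equation

    eps * dy/dt = -k1 y^2 - k2 y + (k1 + k2) = -k1 (y - 1)(y + 1 + 1/gamma)

with ``gamma = k1/k2``, which is solved in closed form.  Rescaling
``t = a t*`` and ``y e^{-1/eps} = b y*`` with ``a = eps/k2`` and
``b = e^{-1/eps}/gamma`` removes all parameters from the transport part:

    dy*/dt* = -y*^2 - y*     (exact up to the gamma(1+gamma) source term,
                              whose fixed point sits at y* = gamma)

so curves from different systems collapse onto a master curve.  The
logarithmic regime appears as a slope of -1 in a log-log plot of y* against
t*, is established after ``tau1 = (eps/k1) exp(-1/eps)`` and, for type-b
dynamics (gamma < 1), crosses over near t* ~ 1 to a universal second
exponential regime.  Type-a dynamics (gamma > 1) instead reach the terminal
exponential decay directly.

Everything involving ``exp(1/eps)`` is evaluated in log space; the public
functions are safe down to eps ~ 2e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .series import CorrelationSeries, ScaledCurve

__all__ = [
    "EyringParams",
    "EyringDerived",
    "EyringFit",
    "FitError",
    "RegimeError",
    "eyring_rhs",
    "eyring_solution",
    "scale_transform",
    "inverse_scale_transform",
    "asymptotics",
    "fit",
    "classify_and_collapse",
]

#: data must reach at least this scaled time for k2 to be considered reliable
K2_RELIABLE_TSTAR = 0.1


class FitError(RuntimeError):
    """Raised for degenerate input curves or non-converged fits."""


class RegimeError(ValueError):
    """Raised when an asymptotic regime is requested outside its class."""


@dataclass(frozen=True)
class EyringParams:
    """The three kinetic parameters (all positive).

    eps : dimensionless crossover value of the correlation function (~1e-2)
    k1  : kinetic constant of the initial/logarithmic regimes (1/s)
    k2  : kinetic constant of the observable exponential regime (1/s)
    """

    eps: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.eps > 0 and self.k1 > 0 and self.k2 > 0):
            raise ValueError("eps, k1, k2 must all be positive")

    @property
    def gamma(self) -> float:
        return self.k1 / self.k2

    def derived(self) -> "EyringDerived":
        eps, k1, k2 = self.eps, self.k1, self.k2
        gamma = k1 / k2
        tau1 = (eps / k1) * np.exp(-1.0 / eps)
        tau2 = eps / (2.0 * k1 + k2)
        a = eps / k2
        log_b = -1.0 / eps - np.log(gamma)
        return EyringDerived(gamma, tau1, tau2, a, log_b)


@dataclass(frozen=True)
class EyringDerived:
    """Quantities derived from (eps, k1, k2).

    gamma : k1/k2, the dynamic-class parameter (type a: >1, type b: <1)
    tau1  : (eps/k1) e^{-1/eps}, onset time of the logarithmic regime (s)
    tau2  : eps/(2 k1 + k2), terminal relaxation time of the exact solution (s)
    a     : time scale factor of the master transform, t* = t/a, a = eps/k2 (s)
    log_b : natural log of the y-scale factor b = e^{-1/eps}/gamma
    """

    gamma: float
    tau1: float
    tau2: float
    a: float
    log_b: float

    @property
    def b(self) -> float:
        return float(np.exp(self.log_b))


def eyring_rhs(F, p: EyringParams):
    """Right-hand side dF/dt of the modified Eyring equation (1/s)."""
    F = np.asarray(F, dtype=float)
    x = F / p.eps
    out = -p.k1 * np.exp(x) - p.k2 + (p.k1 + p.k2) * np.exp(-x)
    return out if out.ndim else float(out)


def eyring_solution(t, p: EyringParams, F0: float = 1.0):
    """Closed-form solution F(t) with F(0) = F0 (default 1).

    Uses the Riccati root transform u = (y+ - y-)/(y - y-) with roots
    y+ = 1 and y- = -(1 + 1/gamma); u relaxes as
    ``u(t) = 1 - (1 - u0) e^{-t/tau2}`` which is evaluated with ``expm1`` so
    the solution is accurate from t << tau1 through t >> tau2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    eps = p.eps
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _solution_core(t, p, F0, eps)


def _solution_core(t, p, F0, eps):
    inv_gamma = p.k2 / p.k1
    span = 2.0 + inv_gamma  # y+ - y-
    lam = (2.0 * p.k1 + p.k2) / eps  # 1/tau2
    # u0 = span / (y0 + 1 + 1/gamma) with y0 = e^{F0/eps}; the complement is
    # computed from the cancellation-free identity 1 - u0 = (y0 - 1)/(y0 + 1 + 1/gamma).
    if F0 / eps < 700.0:
        y0 = np.exp(F0 / eps)
        denom = y0 + 1.0 + inv_gamma
        u0 = span / denom
        one_minus_u0 = (y0 - 1.0) / denom
    else:  # y0 overflows double precision; u0 is zero to machine accuracy
        u0 = np.exp(np.log(span) - F0 / eps)
        one_minus_u0 = 1.0
    decay = np.exp(-lam * t)
    v = one_minus_u0 * decay  # v = 1 - u, accurate at late times
    u = -np.expm1(-lam * t) + u0 * decay  # accurate at early times
    # Using span - (1 + 1/gamma) = 1 exactly: y = (1 + (1+1/gamma) v) / (1 - v),
    # so ln y = log1p((1+1/gamma) v) - ln u, with ln u taken from whichever of
    # the two complementary forms is well conditioned.
    with np.errstate(divide="ignore"):
        log_u = np.where(v > 0.5, np.log(u), np.log1p(-v))
    log_y = np.log1p((1.0 + inv_gamma) * v) - log_u
    out = eps * log_y
    return out if out.ndim else float(out)


def scale_transform(curve: CorrelationSeries, p: EyringParams, label: str = "") -> ScaledCurve:
    """Map a relaxation curve onto the universal (t*, y*) coordinates.

    t* = t k2/eps and ln y* = ln(gamma) + F/eps; the transform is a bijection
    and :func:`inverse_scale_transform` round-trips it exactly.
    """
    if curve.domain != "seconds":
        raise ValueError("curve must be in the seconds domain")
    d = p.derived()
    log_y_star = np.log(d.gamma) + curve.F / p.eps
    return ScaledCurve(curve.times / d.a, np.exp(log_y_star), log_y_star, label=label)


def inverse_scale_transform(scaled: ScaledCurve, p: EyringParams) -> CorrelationSeries:
    d = p.derived()
    F = p.eps * (scaled.log_y_star - np.log(d.gamma))
    return CorrelationSeries(scaled.t_star * d.a, F)


def _log_approximant(p: EyringParams) -> Callable[[np.ndarray], np.ndarray]:
    tau1 = p.derived().tau1

    def F_log(t):
        return 1.0 - p.eps * np.log1p(np.asarray(t, dtype=float) / tau1)

    return F_log


def _type_b_exact(p: EyringParams) -> Callable[[np.ndarray], np.ndarray]:
    # Exact solution of dy*/dt* = -y*^2 - y* from y*(0) = 1/q, q = e^{-1/eps}/gamma:
    #   y*(t*) = 1 / ((1+q) e^{t*} - 1)
    # mapped back to F = eps (ln y* - ln gamma).
    d = p.derived()
    q = np.exp(-1.0 / p.eps) / d.gamma

    def F_b(t):
        t_star = np.asarray(t, dtype=float) / d.a
        log_y_star = -np.log(np.expm1(t_star) + q * np.exp(t_star))
        return p.eps * (log_y_star - np.log(d.gamma))

    return F_b


def _type_a_terminal(p: EyringParams) -> Callable[[np.ndarray], np.ndarray]:
    # Matched form: terminal exponential with the slowly varying logarithmic
    # amplitude, F(t) = [1 - eps ln(1 + t/tau1)] e^{-t/tau2}.
    d = p.derived()

    def F_a(t):
        t = np.asarray(t, dtype=float)
        return (1.0 - p.eps * np.log1p(t / d.tau1)) * np.exp(-t / d.tau2)

    return F_a


def asymptotics(p: EyringParams, regime: str) -> Callable[[np.ndarray], np.ndarray]:
    """Return a callable F(t) approximant for one asymptotic regime.

    regime:
      * ``"logarithmic"``        F = 1 - eps ln(1 + t/tau1); valid for
                                 tau1 << t and before the class-dependent
                                 crossover (t* << 1 for type b, t* << 1/gamma
                                 for type a).
      * ``"terminal"``           type a (gamma > 1) terminal exponential with
                                 matched logarithmic amplitude.
      * ``"second-intermediate"``type b (gamma < 1) universal regime from the
                                 exact parameter-free master solution.
      * ``"matched"``            global type-b form, accurate for gamma << 1
                                 over the whole observable range (while the
                                 neglected gamma source term is small, i.e.
                                 down to F of order eps).
    """
    gamma = p.gamma
    if regime == "logarithmic":
        return _log_approximant(p)
    if regime == "terminal":
        if gamma <= 1.0:
            raise RegimeError("terminal asymptotics require type-a dynamics (gamma > 1)")
        return _type_a_terminal(p)
    if regime in ("second-intermediate", "matched"):
        if gamma >= 1.0:
            raise RegimeError(f"{regime} asymptotics require type-b dynamics (gamma < 1)")
        return _type_b_exact(p)
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# fitting


def _log_time_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoidal weights uniform in ln t (so every decade counts equally)."""
    lt = np.log(times)
    w = np.empty_like(lt)
    w[1:-1] = 0.5 * (lt[2:] - lt[:-2])
    w[0] = lt[1] - lt[0]
    w[-1] = lt[-1] - lt[-2]
    w /= w.mean()
    return np.sqrt(w)


def _initial_guess(times: np.ndarray, F: np.ndarray) -> tuple[float, float, float]:
    """Heuristic (eps, k1, k2) from the straightest lin-log window and the tail."""
    lt = np.log(times)
    n = times.size
    win = max(6, n // 3)
    best = (np.inf, 0.02, 1.0)  # (sse, slope, intercept)
    for i0 in range(0, n - win + 1, max(1, win // 4)):
        x, y = lt[i0 : i0 + win], F[i0 : i0 + win]
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(res[0]) if res.size else 0.0
        if coef[0] < 0 and sse < best[0]:
            best = (sse, coef[0], coef[1])
    slope, intercept = best[1], best[2]
    eps0 = float(np.clip(-slope, 1e-3, 0.5))
    # log regime: F = 1 - eps ln(t/tau1)  =>  intercept = 1 + eps ln tau1
    log_tau1 = (intercept - 1.0) / eps0
    log_tau1 = float(np.clip(log_tau1, np.log(times[0]) - 60.0, np.log(times[-1])))
    k10 = eps0 * np.exp(-1.0 / eps0 - log_tau1)
    # tail rate from the last decade of data (F roughly linear in t there)
    tail = times >= times[-1] / 10.0
    if np.count_nonzero(tail) >= 2:
        tt, Ft = times[tail], F[tail]
        k20 = max((Ft[0] - Ft[-1]) / (tt[-1] - tt[0]), 0.0)
    else:
        k20 = 0.0
    if not np.isfinite(k20) or k20 <= 0:
        k20 = eps0 / times[-1]
    k10 = float(np.clip(k10, 1e-300, 1e300))
    return eps0, k10, float(k20)


@dataclass
class EyringFit:
    """Result of fitting the modified Eyring solution to a relaxation curve."""

    params: EyringParams
    r2: float
    residuals: np.ndarray
    covariance: np.ndarray | None  # covariance of (ln eps, ln k1, ln k2)
    n_points: int
    k2_reliable: bool
    dynamic_class: str  # "a", "b" or "boundary"

    @property
    def gamma(self) -> float:
        return self.params.gamma

    @property
    def derived(self) -> EyringDerived:
        return self.params.derived()

    def report(self) -> dict:
        d = self.derived
        return {
            "eps": self.params.eps,
            "k1": self.params.k1,
            "k2": self.params.k2,
            "gamma": d.gamma,
            "tau1": d.tau1,
            "tau2": d.tau2,
            "r2": self.r2,
            "k2_reliable": self.k2_reliable,
            "class": self.dynamic_class,
            "n_points": self.n_points,
        }


def classify_gamma(gamma: float) -> str:
    if gamma > 1.0:
        return "a"
    if gamma < 1.0:
        return "b"
    return "boundary"


def fit(
    curve: CorrelationSeries,
    init: EyringParams | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> EyringFit:
    """Nonlinear least-squares fit of the modified Eyring solution to F(t).

    Residuals are taken in F with weights uniform per decade of time;
    positivity of (eps, k1, k2) is enforced by fitting their logarithms.
    ``n_starts`` multiplicative jitters of the initial guess guard against
    local minima.  Raises :class:`FitError` for flat curves, for curves with
    fewer than 10 positive-time points or spanning under two time decades,
    and when no start converges.
    """
    if curve.domain != "seconds":
        raise ValueError("fit expects a seconds-domain curve")
    mask = curve.times > 0
    times, F = curve.times[mask], curve.F[mask]
    if times.size < 10:
        raise FitError("need at least 10 positive-time points")
    if times[-1] / times[0] < 100.0:
        raise FitError("curve must span at least two decades in time")
    if float(np.ptp(F)) < 0.02:
        raise FitError("curve is flat; kinetic parameters are not identifiable")

    w = _log_time_weights(times)
    if init is not None:
        theta0 = np.log([init.eps, init.k1, init.k2])
    else:
        theta0 = np.log(_initial_guess(times, F))

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            eps, k1, k2 = np.exp(np.clip(theta, -700.0, 700.0))
            model = eyring_solution(times, EyringParams(eps, k1, k2))
            out = w * (model - F)
        return np.where(np.isfinite(out), out, 1e6)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, [0.2, 2.0, 1.0])
        try:
            sol = least_squares(resid, start, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no fit converged within the multi-start budget")

    eps, k1, k2 = np.exp(best.x)
    params = EyringParams(float(eps), float(k1), float(k2))
    res = best.fun
    ss_res = float(res @ res)
    ybar = float(np.average(F, weights=w**2))
    ss_tot = float(((w * (F - ybar)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    dof = times.size - 3
    cov = None
    if dof > 0:
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * ss_res / dof
        except np.linalg.LinAlgError:
            cov = None

    t_star_max = times[-1] / params.derived().a
    return EyringFit(
        params=params,
        r2=r2,
        residuals=res / w,
        covariance=cov,
        n_points=int(times.size),
        k2_reliable=bool(t_star_max >= K2_RELIABLE_TSTAR),
        dynamic_class=classify_gamma(params.gamma),
    )


@dataclass
class ClassifiedCurve:
    label: str
    dynamic_class: str
    gamma: float
    k2_reliable: bool
    scaled: ScaledCurve


def classify_and_collapse(
    fits: Sequence[tuple[CorrelationSeries, EyringParams]] | Sequence[tuple[CorrelationSeries, EyringParams, str]],
) -> list[ClassifiedCurve]:
    """Label each fitted curve type a / type b and emit its scaled form.

    Curves whose data never leave the logarithmic window (last point below
    t* = 0.1) carry ``k2_reliable=False``: the crossover that determines k2
    was not observed.  A gamma of exactly 1 is labelled "boundary".
    """
    out: list[ClassifiedCurve] = []
    for item in fits:
        curve, params = item[0], item[1]
        label = item[2] if len(item) > 2 else f"curve{len(out)}"
        d = params.derived()
        cls = classify_gamma(d.gamma)
        reliable = bool(curve.times[-1] / d.a >= K2_RELIABLE_TSTAR)
        out.append(
            ClassifiedCurve(
                label=label,
                dynamic_class=cls,
                gamma=d.gamma,
                k2_reliable=reliable,
                scaled=scale_transform(curve, params, label=label),
            )
        )
    return out
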