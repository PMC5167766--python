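"""Growth-irradiance response fitting.

Growth rate versus growth light is described either by the Eilers-Peeters
photoinhibition curve

    mu(I) = I / (a I^2 + b I + c)

whose maximum has the closed form mu_max = 1/(b + 2 sqrt(a c)) at the optimum
irradiance I_opt = sqrt(c/a), or — when the response is monotone — by an
ordinary linear regression that is only *reported* when its slope differs
significantly from zero (two-sided t-test, alpha = 0.05).

``select_response_model`` fits both and prefers Eilers-Peeters when the
photoinhibition coefficient ``a`` is significantly positive (its 95 % CI
excludes zero), i.e. when the data support a rise-then-fall response.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LightResponseError",
    "LightResponseFit",
    "eilers_peeters_mu",
    "mu_max_closed_form",
    "fit_eilers_peeters",
    "fit_linear_gated",
    "select_response_model",
]


class LightResponseError(ValueError):
    """Raised for unusable inputs to light-response fitting."""


@dataclass
class LightResponseFit:
    model: str  # "eilers_peeters" | "linear" | "none"
    a: float = float("nan")
    b: float = float("nan")
    c: float = float("nan")
    mu_max: float = float("nan")
    i_opt: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    slope_p: float = float("nan")
    r2: float = float("nan")
    ci95: dict = field(default_factory=dict)
    n: int = 0
    flags: tuple = ()
    alternatives: dict = field(default_factory=dict, repr=False, compare=False)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model == "eilers_peeters":
            return eilers_peeters_mu(x, self.a, self.b, self.c)
        if self.model == "linear":
            return self.slope * x + self.intercept
        raise LightResponseError("no model selected")


def eilers_peeters_mu(I, a, b, c):
    """mu(I) = I / (a I^2 + b I + c); the denominator is clipped away from 0."""
    I = np.asarray(I, dtype=float)
    den = a * I * I + b * I + c
    return I / np.where(den > 1e-12, den, 1e-12)


def mu_max_closed_form(a: float, b: float, c: float) -> float:
    """Maximum of the Eilers-Peeters curve: 1/(b + 2 sqrt(a c))."""
    den = b + 2.0 * math.sqrt(max(a, 0.0) * max(c, 0.0))
    if den <= 0:
        return float("inf")
    return 1.0 / den


def _validate_points(I, mu, min_points):
    I = np.asarray(I, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if I.shape != mu.shape or I.ndim != 1:
        raise LightResponseError("I and mu must be 1-D arrays of equal length")
    if len(I) < min_points:
        raise LightResponseError(f"need >= {min_points} points, got {len(I)}")
    return I, mu


def fit_eilers_peeters(I, mu) -> LightResponseFit:
    """Least-squares Eilers-Peeters fit with linearized 95 % CIs.

    Requires >= 4 points with >= 3 distinct positive irradiances.  With
    exactly 3 distinct light levels and no replicates the 3-parameter fit is
    exactly identified, so no residual degrees of freedom remain: the fit is
    flagged ``exact_fit_no_ci``.  A non-positive fitted ``c`` cannot occur
    (bounded below); non-convergence returns ``model="none"`` with flags.
    """
    I, mu = _validate_points(I, mu, 4)
    if np.any(I <= 0):
        raise LightResponseError("irradiances must be > 0")
    if len(np.unique(I)) < 3:
        raise LightResponseError("need >= 3 distinct irradiances")

    order = np.argsort(I)
    i1, m1 = I[order[0]], max(mu[order[0]], 1e-9)
    c0 = i1 / m1
    mu_top = max(np.max(mu), 1e-9)

    def resid(x):
        return eilers_peeters_mu(I, *x) - mu

    lo = [0.0, -np.inf, 1e-9]
    hi = [1.0, np.inf, np.inf]
    best = None
    for a0 in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1):
        b0 = 1.0 / mu_top - 2.0 * math.sqrt(a0 * c0)
        try:
            res = optimize.least_squares(
                resid, [a0, b0, c0], bounds=(lo, hi), method="trf",
                x_scale=[max(a0, 1e-6), max(abs(b0), 1e-3), max(c0, 1e-3)],
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or best.status <= 0:
        return LightResponseFit(model="none", n=len(I), flags=("ep_fit_failed",))

    a, b, c = (float(v) for v in best.x)
    n = len(I)
    dof = n - 3
    rss = 2.0 * best.cost
    sst = float(np.sum((mu - np.mean(mu)) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")
    flags: list[str] = []
    ci95: dict = {}
    if dof > 0:
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            tcrit = stats.t.ppf(0.975, dof)
            for name, val, var in zip("abc", (a, b, c), np.diag(cov)):
                se = math.sqrt(max(var, 0.0))
                ci95[name] = (val - tcrit * se, val + tcrit * se)
        except np.linalg.LinAlgError:
            flags.append("singular_covariance")
    else:
        flags.append("exact_fit_no_ci")

    mu_max = mu_max_closed_form(a, b, c)
    if not math.isfinite(mu_max):
        flags.append("unbounded_mu_max")
    i_opt = math.sqrt(c / a) if a > 0 else float("inf")
    return LightResponseFit(
        model="eilers_peeters", a=a, b=b, c=c, mu_max=mu_max, i_opt=i_opt,
        r2=r2, ci95=ci95, n=n, flags=tuple(flags),
    )


def fit_linear_gated(x, y, alpha: float = 0.05) -> LightResponseFit:
    """OLS fit reported only when the slope is significantly non-zero.

    Returns ``model="linear"`` when the two-sided p-value of slope = 0 falls
    below ``alpha``, otherwise ``model="none"`` (fit retained in the fields
    for inspection either way).  Fewer than 3 points or zero x-variance are
    rejected — there would be no residual degrees of freedom for the test.
    """
    x, y = _validate_points(x, y, 3)
    if np.ptp(x) == 0:
        raise LightResponseError("all x identical: slope is unidentifiable")
    res = stats.linregress(x, y)
    n = len(x)
    dof = n - 2
    tcrit = stats.t.ppf(0.975, dof)
    ci95 = {
        "slope": (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr),
        "intercept": (
            res.intercept - tcrit * res.intercept_stderr,
            res.intercept + tcrit * res.intercept_stderr,
        ),
    }
    significant = bool(res.pvalue < alpha)
    return LightResponseFit(
        model="linear" if significant else "none",
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_p=float(res.pvalue),
        r2=float(res.rvalue**2),
        ci95=ci95,
        n=n,
        flags=() if significant else ("slope_not_significant",),
    )


def select_response_model(I, mu, alpha: float = 0.05) -> LightResponseFit:
    """Fit both candidate models and pick one.

    Eilers-Peeters is preferred when it converges with a photoinhibition
    coefficient significantly above zero (95 % CI excludes 0), i.e. the data
    are demonstrably non-monotone; otherwise the slope-gated linear fit is
    used.  Both fits are recorded under ``alternatives``.
    """
    I, mu = _validate_points(I, mu, 3)
    alternatives: dict = {}
    ep = None
    if len(np.unique(I)) >= 3 and len(I) >= 4 and np.all(I > 0):
        try:
            ep = fit_eilers_peeters(I, mu)
            alternatives["eilers_peeters"] = ep
        except LightResponseError:
            ep = None
    lin = None
    try:
        lin = fit_linear_gated(I, mu, alpha)
        alternatives["linear"] = lin
    except LightResponseError:
        lin = None

    chosen = None
    if ep is not None and ep.model == "eilers_peeters" and ep.a > 0:
        a_ci = ep.ci95.get("a")
        if a_ci is not None and a_ci[0] > 0:
            chosen = ep
    if chosen is None and lin is not None:
        chosen = lin
    if chosen is None:
        chosen = LightResponseFit(model="none", n=len(I), flags=("no_model",))
    chosen.alternatives = alternatives
    return chosen
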