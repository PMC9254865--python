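"""Parametric survival curves for right-censored time-to-event data.

Implements the six distribution families conventionally used to extrapolate
oncology trial endpoints in health-technology assessment (exponential,
Weibull, Gompertz, generalized gamma, log-logistic, log-normal), maximum
likelihood fitting to right-censored individual patient data, AIC/BIC model
selection, and proportional-hazards shifting of a baseline curve.

Parameterizations
-----------------
exponential   S(t) = exp(-rate * t)
weibull       S(t) = exp(-(t / scale) ** shape)
gompertz      S(t) = exp(-(rate / shape) * (exp(shape * t) - 1)); shape may be
              negative, in which case the curve plateaus (improper survival)
loglogistic   S(t) = 1 / (1 + (t / scale) ** shape)
lognormal     S(t) = 1 - Phi((ln t - mu) / sigma)
gengamma      three-parameter (mu, sigma, q) log-time form; q -> 0 recovers
              the log-normal, q = 1 the Weibull.

Times are in the unit declared by ``time_unit`` ("months" by default, the
trial scale); conversion to model years happens at the engine boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SurvivalFunction",
    "ProportionalHazards",
    "ParametricFit",
    "survival_at",
    "apply_hazard_ratio",
    "fit_parametric",
    "fit_all_families",
    "select_distribution",
]

#: canonical family order, also the fixed tie-break order in selection
FAMILIES: tuple[str, ...] = (
    "exponential",
    "weibull",
    "gompertz",
    "gengamma",
    "loglogistic",
    "lognormal",
)

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "gengamma": ("mu", "sigma", "q"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
}

#: parameters that must be strictly positive (fitted on the log scale)
_POSITIVE: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("rate",),
    "gengamma": ("sigma",),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("sigma",),
}

_GG_Q_EPS = 1e-5  # |q| below this: generalized gamma -> log-normal limit


class CurveError(ValueError):
    """Invalid survival-curve specification or argument."""


class FitError(RuntimeError):
    """Parametric fitting cannot proceed (e.g. no events)."""


class SelectionError(RuntimeError):
    """No usable fit to select from."""


def _validate_params(family: str, params: Mapping[str, float]) -> None:
    if family not in FAMILIES:
        raise CurveError(f"unknown family {family!r}; expected one of {FAMILIES}")
    expected = set(PARAM_NAMES[family])
    got = set(params)
    if got != expected:
        raise CurveError(f"{family} expects parameters {sorted(expected)}, got {sorted(got)}")
    for name in _POSITIVE[family]:
        if not params[name] > 0:
            raise CurveError(f"{family} parameter {name!r} must be > 0, got {params[name]}")
    for name, value in params.items():
        if not np.isfinite(value):
            raise CurveError(f"{family} parameter {name!r} is not finite")


@dataclass(frozen=True)
class SurvivalFunction:
    """A parametric survival curve, evaluable at any nonnegative time."""

    family: str
    params: Mapping[str, float]
    time_unit: str = "months"

    def __post_init__(self) -> None:
        _validate_params(self.family, self.params)
        if self.time_unit not in ("months", "years"):
            raise CurveError(f"time_unit must be 'months' or 'years', got {self.time_unit!r}")
        object.__setattr__(self, "params", dict(self.params))

    # -- evaluation ----------------------------------------------------

    def survival(self, t):
        """S(t); vectorized, clipped to [0, 1]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise CurveError("survival requires t >= 0")
        p = self.params
        fam = self.family
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if fam == "exponential":
                s = np.exp(-p["rate"] * t)
            elif fam == "weibull":
                s = np.exp(-((t / p["scale"]) ** p["shape"]))
            elif fam == "gompertz":
                a, b = p["shape"], p["rate"]
                if abs(a) < 1e-12:
                    s = np.exp(-b * t)
                else:
                    s = np.exp(-(b / a) * np.expm1(a * t))
            elif fam == "loglogistic":
                s = 1.0 / (1.0 + (t / p["scale"]) ** p["shape"])
            elif fam == "lognormal":
                s = _lognormal_sf(t, p["mu"], p["sigma"])
            else:  # gengamma
                s = _gengamma_sf(t, p["mu"], p["sigma"], p["q"])
        return np.clip(np.where(t == 0.0, 1.0, s), 0.0, 1.0)

    def cumulative_hazard(self, t):
        s = np.clip(self.survival(t), 1e-300, 1.0)
        return -np.log(s)

    def log_density(self, t):
        """log f(t) for t > 0 (used by the censored likelihood)."""
        t = np.asarray(t, dtype=float)
        p = self.params
        fam = self.family
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if fam == "exponential":
                lam = p["rate"]
                out = math.log(lam) - lam * t
            elif fam == "weibull":
                k, s0 = p["shape"], p["scale"]
                out = math.log(k / s0) + (k - 1) * np.log(t / s0) - (t / s0) ** k
            elif fam == "gompertz":
                a, b = p["shape"], p["rate"]
                if abs(a) < 1e-12:
                    out = math.log(b) - b * t
                else:
                    out = math.log(b) + a * t - (b / a) * np.expm1(a * t)
            elif fam == "loglogistic":
                al, be = p["scale"], p["shape"]
                z = (t / al) ** be
                out = math.log(be / al) + (be - 1) * np.log(t / al) - 2 * np.log1p(z)
            elif fam == "lognormal":
                mu, sg = p["mu"], p["sigma"]
                out = stats.norm.logpdf((np.log(t) - mu) / sg) - np.log(sg * t)
            else:  # gengamma, Prentice log-time form
                mu, sg, q = p["mu"], p["sigma"], p["q"]
                if abs(q) < _GG_Q_EPS:
                    out = stats.norm.logpdf((np.log(t) - mu) / sg) - np.log(sg * t)
                else:
                    z = (np.log(t) - mu) / sg
                    a = q ** -2
                    out = (
                        math.log(abs(q))
                        + a * math.log(a)
                        - special.gammaln(a)
                        - np.log(sg * t)
                        + a * (q * z - np.exp(np.clip(q * z, None, 700.0)))
                    )
        return out

    def inverse_survival(self, u):
        """Smallest t with S(t) = u, for u in (0, 1]; inf if never reached."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u > 1)):
            raise CurveError("inverse_survival requires u in (0, 1]")
        p = self.params
        fam = self.family
        with np.errstate(divide="ignore", invalid="ignore"):
            if fam == "exponential":
                t = -np.log(u) / p["rate"]
            elif fam == "weibull":
                t = p["scale"] * (-np.log(u)) ** (1.0 / p["shape"])
            elif fam == "gompertz":
                a, b = p["shape"], p["rate"]
                if abs(a) < 1e-12:
                    t = -np.log(u) / b
                else:
                    arg = 1.0 - (a / b) * np.log(u)
                    t = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / a, np.inf)
            elif fam == "loglogistic":
                t = p["scale"] * (1.0 / u - 1.0) ** (1.0 / p["shape"])
            elif fam == "lognormal":
                t = np.exp(p["mu"] + p["sigma"] * special.ndtri(1.0 - u))
            else:  # gengamma
                mu, sg, q = p["mu"], p["sigma"], p["q"]
                if abs(q) < _GG_Q_EPS:
                    t = np.exp(mu + sg * special.ndtri(1.0 - u))
                else:
                    a = q ** -2
                    y = special.gammainccinv(a, u) if q > 0 else special.gammaincinv(a, u)
                    z = np.log(y / a) / q
                    t = np.exp(mu + sg * z)
        return np.where(u == 1.0, 0.0, t)


def _lognormal_sf(t, mu, sigma):
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    out[pos] = stats.norm.sf((np.log(t[pos]) - mu) / sigma)
    return out


def _gengamma_sf(t, mu, sigma, q):
    if abs(q) < _GG_Q_EPS:
        return _lognormal_sf(t, mu, sigma)
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    z = (np.log(t[pos]) - mu) / sigma
    a = q ** -2
    u = a * np.exp(np.clip(q * z, None, 700.0))
    out[pos] = special.gammaincc(a, u) if q > 0 else special.gammainc(a, u)
    return out


@dataclass(frozen=True)
class ProportionalHazards:
    """A baseline curve shifted by a hazard ratio: S'(t) = S(t) ** hr.

    The cumulative-hazard ratio against the baseline equals ``hr`` at every
    time by construction, which is the identity used for subgroup analyses.
    """

    baseline: "SurvivalFunction | ProportionalHazards"
    hr: float

    def __post_init__(self) -> None:
        if not self.hr > 0:
            raise CurveError(f"hazard ratio must be > 0, got {self.hr}")

    @property
    def time_unit(self) -> str:
        return self.baseline.time_unit

    def survival(self, t):
        return np.clip(self.baseline.survival(t) ** self.hr, 0.0, 1.0)

    def cumulative_hazard(self, t):
        return self.hr * self.baseline.cumulative_hazard(t)

    def inverse_survival(self, u):
        u = np.asarray(u, dtype=float)
        return self.baseline.inverse_survival(u ** (1.0 / self.hr))


def survival_at(fn, t: float) -> float:
    """Evaluate a survival curve at a single nonnegative time."""
    if t < 0:
        raise CurveError(f"t must be >= 0, got {t}")
    return float(fn.survival(np.asarray(t, dtype=float)))


def apply_hazard_ratio(fn, hr: float) -> ProportionalHazards:
    """Shift a curve by a hazard ratio under proportional hazards."""
    return ProportionalHazards(baseline=fn, hr=float(hr))


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class ParametricFit:
    """A fitted parametric curve with its information criteria.

    aic = 2k - 2 loglik, bic = k ln(n_obs) - 2 loglik with k free parameters.
    """

    function: SurvivalFunction
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_events: int
    converged: bool

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.function.family])


def _coerce_ipd(ipd) -> tuple[np.ndarray, np.ndarray]:
    """Accept a PseudoIPD/SimulatedIPD-like object, DataFrame, or pair."""
    if hasattr(ipd, "time") and hasattr(ipd, "event"):
        time, event = ipd.time, ipd.event
    elif hasattr(ipd, "columns"):
        tcol = "time_months" if "time_months" in ipd.columns else "time"
        time, event = ipd[tcol], ipd["event"]
    else:
        time, event = ipd
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise CurveError("time and event must have the same length")
    if np.any(time <= 0):
        raise CurveError("all times must be > 0 for parametric fitting")
    if not set(np.unique(event)) <= {0, 1}:
        raise CurveError("event indicator must be 0/1")
    return time, event


def _pack(family: str, params: dict[str, float]) -> np.ndarray:
    pos = _POSITIVE[family]
    return np.array(
        [math.log(params[n]) if n in pos else params[n] for n in PARAM_NAMES[family]]
    )


def _unpack(family: str, theta: np.ndarray) -> dict[str, float]:
    pos = _POSITIVE[family]
    return {
        n: (math.exp(v) if n in pos else float(v))
        for n, v in zip(PARAM_NAMES[family], theta)
    }


def _starts(family: str, time: np.ndarray, event: np.ndarray) -> list[dict[str, float]]:
    """Deterministic multi-start values from crude data moments."""
    rate0 = max(event.sum(), 1) / time.sum()
    logt = np.log(time)
    mu0, sg0 = float(np.mean(logt)), max(float(np.std(logt)), 0.2)
    med0 = float(np.median(time))
    if family == "exponential":
        return [{"rate": rate0}, {"rate": rate0 * 2}, {"rate": rate0 / 2}]
    if family == "weibull":
        return [
            {"shape": s, "scale": med0 / math.log(2) ** (1 / s)} for s in (1.0, 0.7, 1.5)
        ]
    if family == "gompertz":
        return [
            {"shape": a, "rate": rate0} for a in (1e-3, 0.05, -0.05)
        ]
    if family == "loglogistic":
        return [{"scale": med0, "shape": s} for s in (1.0, 1.5, 2.5)]
    if family == "lognormal":
        return [{"mu": mu0, "sigma": sg0}, {"mu": mu0, "sigma": sg0 * 2}]
    return [  # gengamma
        {"mu": mu0, "sigma": sg0, "q": q} for q in (1.0, 0.5, -0.5)
    ]


def _neg_loglik(theta: np.ndarray, family: str, time, event) -> float:
    try:
        fn = SurvivalFunction(family, _unpack(family, theta))
    except (CurveError, OverflowError):
        return 1e12
    with np.errstate(all="ignore"):
        logf = fn.log_density(time)
        s = np.clip(fn.survival(time), 1e-300, 1.0)
        ll = np.where(event == 1, logf, np.log(s)).sum()
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def fit_parametric(ipd, family: str) -> ParametricFit:
    """Fit one family to right-censored data by maximum likelihood.

    The censored log-likelihood sum(event * ln f(t) + (1-event) * ln S(t)) is
    maximized over a transformed parameter scale (log for positive
    parameters) with deterministic multi-start; convergence is flagged from
    the gradient norm at the optimum, never raised.
    """
    time, event = _coerce_ipd(ipd)
    if time.size < 2:
        raise FitError("need at least 2 records")
    if event.sum() < 1:
        raise FitError("need at least 1 event (likelihood unbounded otherwise)")
    if family not in FAMILIES:
        raise CurveError(f"unknown family {family!r}")

    best_theta, best_nll = None, np.inf
    for start in _starts(family, time, event):
        theta0 = _pack(family, start)
        try:
            res = optimize.minimize(
                _neg_loglik, theta0, args=(family, time, event), method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
            )
            res = optimize.minimize(
                _neg_loglik, res.x, args=(family, time, event), method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
        except Exception:
            continue
        if res.fun < best_nll:
            best_nll, best_theta = float(res.fun), np.asarray(res.x)

    if best_theta is None or not np.isfinite(best_nll) or best_nll >= 1e11:
        raise FitError(f"all starts failed for family {family!r}")

    grad = optimize.approx_fprime(best_theta, _neg_loglik, 1e-7, family, time, event)
    converged = bool(np.max(np.abs(grad)) <= 1e-6 * max(1.0, abs(best_nll)) * 100)

    fn = SurvivalFunction(family, _unpack(family, best_theta))
    k = len(PARAM_NAMES[family])
    loglik = -best_nll
    return ParametricFit(
        function=fn,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(time.size) - 2 * loglik,
        n_obs=int(time.size),
        n_events=int(event.sum()),
        converged=converged,
    )


def fit_all_families(ipd, families: Sequence[str] = FAMILIES) -> list[ParametricFit]:
    """Fit every requested family; families whose fit errors are skipped."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric(ipd, fam))
        except FitError:
            continue
    if not fits:
        raise FitError("no family could be fitted")
    return fits


def select_distribution(fits: Iterable[ParametricFit], criterion: str = "aic") -> ParametricFit:
    """Pick the minimum-AIC/BIC fit.

    Converged fits are preferred over non-converged ones; exact criterion
    ties break on fewer parameters, then on the fixed family order.
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    fits = list(fits)
    if not fits:
        raise SelectionError("empty fit list")
    pool = [f for f in fits if f.converged] or []
    if not pool:
        raise SelectionError("all fits non-converged")
    return min(
        pool,
        key=lambda f: (
            getattr(f, criterion),
            f.n_params,
            FAMILIES.index(f.function.family),
        ),
    )
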