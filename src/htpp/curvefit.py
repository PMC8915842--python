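"""Concentration-response modeling: model family, ML fitting, AIC selection, BMC inversion.

The engine fits a registry of ten curve shapes (constant, Hill, gain-loss,
polynomials, power, exponentials) to well-level responses by maximum
likelihood under Student-t errors with 4 degrees of freedom and a fitted log
error scale ``er``.  Heavy-tailed errors damp the influence of outlying wells
relative to least squares.  The best model is chosen by lowest AIC (with
``er`` counted as a free parameter), and the benchmark concentration (BMC) is
the smallest positive concentration at which the fitted curve crosses the
benchmark response (BMR), in closed form where the model admits one and by
bracketed root finding otherwise.

Model formulas (response as a function of concentration x):

========  =====================================================
constant  0
hill      tp / (1 + (ga/x)^p)
gnls      tp / [(1 + (ga/x)^p) (1 + (x/la)^q)]
poly1     a*x
poly2     a*(x/b + x^2/b^2)
power     a*x^p
exp2      a*(exp(x/b) - 1)
exp3      a*(exp((x/b)^p) - 1)
exp4      tp*(1 - 2^(-x/ga))
exp5      tp*(1 - 2^(-(x/ga)^p))
========  =====================================================

``tp`` is the top (asymptotic effect), ``ga`` the gain AC50, ``p``/``q`` gain
and loss powers, ``la`` the loss AC50, ``a`` a response scale and ``b`` a dose
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "MODEL_NAMES",
    "MODEL_PARAMS",
    "CRFit",
    "BMCResult",
    "BMCStatus",
    "eval_model",
    "fit_model",
    "fit_constant",
    "fit_family",
    "select_model",
    "invert_bmc",
    "NotFittableError",
    "nmad",
]

_T_DF = 4.0
_T_CONST = float(gammaln((_T_DF + 1) / 2) - gammaln(_T_DF / 2) - 0.5 * np.log(_T_DF * np.pi))

_EXP_CLIP = 700.0  # exp() overflow guard


def nmad(x, axis=None):
    """Normalized median absolute deviation: 1.4826 * median(|x - median(x)|).

    Gaussian-consistent robust spread estimate, used for every "nMAD" in the
    pipeline (cell-level normalization, well-level scaling, benchmark
    responses).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=axis, keepdims=axis is not None)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


# ---------------------------------------------------------------------------
# model registry

def _f_constant(x):
    return np.zeros_like(np.asarray(x, dtype=float))


def _f_hill(x, tp, ga, p):
    x = np.asarray(x, dtype=float)
    return tp / (1.0 + (ga / x) ** p)


def _f_gnls(x, tp, ga, p, la, q):
    x = np.asarray(x, dtype=float)
    return tp / ((1.0 + (ga / x) ** p) * (1.0 + (x / la) ** q))


def _f_poly1(x, a):
    return a * np.asarray(x, dtype=float)


def _f_poly2(x, a, b):
    x = np.asarray(x, dtype=float) / b
    return a * (x + x * x)


def _f_power(x, a, p):
    return a * np.asarray(x, dtype=float) ** p


def _f_exp2(x, a, b):
    z = np.clip(np.asarray(x, dtype=float) / b, None, _EXP_CLIP)
    return a * (np.exp(z) - 1.0)


def _f_exp3(x, a, b, p):
    z = np.clip((np.asarray(x, dtype=float) / b) ** p, None, _EXP_CLIP)
    return a * (np.exp(z) - 1.0)


def _f_exp4(x, tp, ga):
    x = np.asarray(x, dtype=float)
    return tp * (1.0 - 2.0 ** (-x / ga))


def _f_exp5(x, tp, ga, p):
    x = np.asarray(x, dtype=float)
    return tp * (1.0 - 2.0 ** (-((x / ga) ** p)))


_MODEL_FNS: dict[str, Callable] = {
    "constant": _f_constant,
    "hill": _f_hill,
    "gnls": _f_gnls,
    "poly1": _f_poly1,
    "poly2": _f_poly2,
    "power": _f_power,
    "exp2": _f_exp2,
    "exp3": _f_exp3,
    "exp4": _f_exp4,
    "exp5": _f_exp5,
}

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "constant": (),
    "hill": ("tp", "ga", "p"),
    "gnls": ("tp", "ga", "p", "la", "q"),
    "poly1": ("a",),
    "poly2": ("a", "b"),
    "power": ("a", "p"),
    "exp2": ("a", "b"),
    "exp3": ("a", "b", "p"),
    "exp4": ("tp", "ga"),
    "exp5": ("tp", "ga", "p"),
}

#: registry order, also the model-selection tie-break order
MODEL_NAMES: tuple[str, ...] = tuple(MODEL_PARAMS)

#: subfamilies used by the viability and profiling stages
CV_COUNT_MODELS = ("constant", "hill")
CV_CYTO_MODELS = ("constant", "hill", "gnls")
PROFILING_MODELS = ("constant", "hill", "poly1", "poly2", "power", "exp2", "exp3", "exp4", "exp5")


class NotFittableError(ValueError):
    """Raised when the data cannot support the requested model."""


def eval_model(model: str, params: dict[str, float] | Sequence[float], conc):
    """Evaluate a registered model at positive concentration(s)."""
    if model not in _MODEL_FNS:
        raise KeyError(f"unknown model {model!r}; registry: {MODEL_NAMES}")
    names = MODEL_PARAMS[model]
    if isinstance(params, dict):
        args = [params[n] for n in names]
    else:
        args = list(params)[: len(names)]
    return _MODEL_FNS[model](conc, *args)


# ---------------------------------------------------------------------------
# likelihood

def _negll(x, fn, conc, resp):
    with np.errstate(over="ignore", invalid="ignore"):
        mu = fn(conc, *x[:-1])
        er = x[-1]
        z = np.clip((resp - mu) * np.exp(-er), -1e120, 1e120)
        ll = np.sum(_T_CONST - er - 0.5 * (_T_DF + 1) * np.log1p(z * z / _T_DF))
    return -ll if np.isfinite(ll) else 1e300


def _model_grad(model: str, x, params) -> np.ndarray:
    """d mu / d theta, one row per model parameter, columns over concentrations."""
    if model == "hill":
        tp, ga, p = params
        t = (ga / x) ** p
        u = 1.0 / (1.0 + t)
        return np.array([u, -tp * u * u * p * t / ga, -tp * u * u * t * np.log(ga / x)])
    if model == "gnls":
        tp, ga, p, la, q = params
        t = (ga / x) ** p
        u = 1.0 / (1.0 + t)
        s = (x / la) ** q
        v = 1.0 / (1.0 + s)
        return np.array([
            u * v,
            -tp * v * u * u * p * t / ga,
            -tp * v * u * u * t * np.log(ga / x),
            tp * u * v * v * q * s / la,
            -tp * u * v * v * s * np.log(x / la),
        ])
    if model == "poly1":
        return np.array([x])
    if model == "poly2":
        a, b = params
        y = x / b
        return np.array([y + y * y, -a * (1.0 + 2.0 * y) * y / b])
    if model == "power":
        a, p = params
        xp = x**p
        return np.array([xp, a * xp * np.log(x)])
    if model == "exp2":
        a, b = params
        y = np.clip(x / b, None, 300.0)
        ey = np.exp(y)
        return np.array([ey - 1.0, -a * ey * y / b])
    if model == "exp3":
        a, b, p = params
        y = np.clip((x / b) ** p, None, 300.0)
        ey = np.exp(y)
        return np.array([ey - 1.0, -a * ey * p * y / b, a * ey * y * np.log(x / b)])
    if model == "exp4":
        tp, ga = params
        w = 2.0 ** (-x / ga)
        return np.array([1.0 - w, -tp * w * np.log(2.0) * x / ga**2])
    if model == "exp5":
        tp, ga, p = params
        h = (x / ga) ** p
        w = 2.0 ** (-h)
        dmu_dh = tp * w * np.log(2.0)
        return np.array([1.0 - w, dmu_dh * (-p * h / ga), dmu_dh * h * np.log(x / ga)])
    raise KeyError(model)


def _negll_and_grad(x, model, fn, conc, resp):
    """Objective and analytic gradient for L-BFGS-B."""
    with np.errstate(over="ignore", invalid="ignore"):
        theta, er = x[:-1], x[-1]
        mu = fn(conc, *theta)
        inv_s = np.exp(-er)
        z = np.clip((resp - mu) * inv_s, -1e120, 1e120)
        den = 1.0 + z * z / _T_DF
        ll = np.sum(_T_CONST - er - 0.5 * (_T_DF + 1) * np.log(den))
        if not np.isfinite(ll):
            return 1e300, np.zeros_like(x)
        w = (_T_DF + 1) / _T_DF * z / den * inv_s  # d ll_i / d mu_i
        g_theta = -(_model_grad(model, conc, theta) @ w) if len(theta) else np.empty(0)
        g_er = -np.sum(-1.0 + (_T_DF + 1) / _T_DF * z * z / den)
        grad = np.concatenate([g_theta, [g_er]])
        if not np.all(np.isfinite(grad)):
            return 1e300, np.zeros_like(x)
    return -ll, grad


def t4_loglik(resid, er: float) -> float:
    """Student-t(4) log-likelihood of residuals with log error scale ``er``."""
    z = np.asarray(resid, dtype=float) * np.exp(-er)
    return float(np.sum(_T_CONST - er - 0.5 * (_T_DF + 1) * np.log1p(z * z / _T_DF)))


@dataclass(frozen=True)
class CRFit:
    """One fitted concentration-response model."""

    model: str
    params: dict[str, float]  # includes the fitted log error scale "er"
    loglik: float
    aic: float
    n_obs: int

    @property
    def n_free_params(self) -> int:
        return len(MODEL_PARAMS[self.model]) + 1  # + er

    def predict(self, conc):
        return eval_model(self.model, self.params, conc)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
        }


# ---------------------------------------------------------------------------
# bounds and starting points

def _data_stats(conc, resp):
    cmin, cmax = float(np.min(conc)), float(np.max(conc))
    mmax = max(float(np.max(np.abs(resp))), 1e-8)
    at_top = resp[conc == cmax]
    s = float(np.sign(np.mean(at_top))) if at_top.size else 0.0
    if s == 0.0:
        s = float(np.sign(np.sum(resp))) or 1.0
    resp_mad = nmad(resp)
    er0 = math.log(max(resp_mad, 1e-4 * mmax))
    return cmin, cmax, mmax, s, er0


def _bounds(model: str, cmin, cmax, mmax, er0):
    tp_b = (-1.2 * mmax, 1.2 * mmax)
    conc_b = (cmin / 10.0, cmax * 10.0)
    pow_b = (0.3, 8.0)
    a_b = (-1.2 * mmax / cmin, 1.2 * mmax / cmin)
    # dose scale b is kept above cmax/100: smaller values make the exponential
    # models numerically step-like, a regime the hill model already covers
    per = {"tp": tp_b, "ga": conc_b, "la": conc_b, "p": pow_b, "q": pow_b,
           "a": a_b, "b": (cmax / 100.0, cmax * 10.0)}
    bl = [per[n] for n in MODEL_PARAMS[model]]
    bl.append((er0 - 18.0, er0 + 5.0))
    return bl


def _inits(model: str, cmin, cmax, mmax, s, er0) -> list[list[float]]:
    gmid = math.sqrt(cmin * cmax)
    t = s * mmax
    e = math.e
    starts: dict[str, list[list[float]]] = {
        "constant": [[]],
        "hill": [[t, cmin, 1.2], [t, gmid, 1.2], [t, cmax, 1.2],
                 [t / 2, gmid, 3.0], [0.0, gmid, 1.0]],
        "gnls": [[t, cmin, 1.2, cmax * 10, 1.2], [t, gmid, 1.2, cmax * 10, 1.2],
                 [t, cmax, 1.2, cmax * 10, 1.2], [1.2 * t, gmid, 1.2, cmax, 2.0],
                 [0.0, gmid, 1.0, cmax * 10, 1.0]],
        "poly1": [[t / cmax], [t / (10 * cmax)], [0.0]],
        "poly2": [[t / 2, cmax], [t / 2, cmax / 3], [t / 6, cmax / 10], [0.0, cmax]],
        "power": [[t / cmax, 1.0], [t / math.sqrt(cmax), 0.5], [t / cmax**2, 2.0], [0.0, 1.0]],
        "exp2": [[t / (e - 1), cmax], [t / (math.exp(3) - 1), cmax / 3], [0.0, cmax]],
        "exp3": [[t / (e - 1), cmax, 1.2], [t / (math.exp(3) - 1), cmax / 3, 1.2], [0.0, cmax, 1.0]],
        "exp4": [[t, cmin], [t, gmid], [t, cmax], [0.0, gmid]],
        "exp5": [[t, cmin, 1.2], [t, gmid, 1.2], [t, cmax, 1.2], [t, gmid, 3.0], [0.0, gmid, 1.0]],
    }
    return [x + [er0] for x in starts[model]]


def _clip_to_bounds(x, bounds):
    return [min(max(v, lo), hi) for v, (lo, hi) in zip(x, bounds)]


def fit_constant(conc, resp) -> CRFit:
    """ML fit of the zero-effect model: only the t4 error scale is estimated."""
    conc, resp = _canonical(conc, resp)
    *_, er0 = _data_stats(conc, resp)
    res = optimize.minimize_scalar(
        lambda er: -t4_loglik(resp, er), bounds=(er0 - 18.0, er0 + 5.0), method="bounded",
        options={"xatol": 1e-10},
    )
    ll = -float(res.fun)
    return CRFit("constant", {"er": float(res.x)}, ll, 2 * 1 - 2 * ll, len(resp))


def _canonical(conc, resp):
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("conc and resp must be 1-D vectors of equal length")
    if not np.all(np.isfinite(resp)) or not np.all(np.isfinite(conc)):
        raise ValueError("non-finite input")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    # canonical ordering makes the fit invariant to permutation of the pairs
    order = np.lexsort((resp, conc))
    return conc[order], resp[order]


def fit_model(conc, resp, model: str, extra_inits: Sequence[Sequence[float]] = ()) -> CRFit:
    """Maximum-likelihood t4 fit of one model, multi-start from deterministic seeds.

    A least-squares polish of the best deterministic start is added as a
    further start, which pins down noiseless data exactly.  ``extra_inits``
    lets callers cascade solutions from nested models.
    """
    if model not in _MODEL_FNS:
        raise KeyError(f"unknown model {model!r}")
    conc, resp = _canonical(conc, resp)
    if model == "constant":
        return fit_constant(conc, resp)
    if np.unique(conc).size < 2:
        raise NotFittableError(f"{model} needs >= 2 distinct concentrations")

    fn = _MODEL_FNS[model]
    cmin, cmax, mmax, s, er0 = _data_stats(conc, resp)
    bounds = _bounds(model, cmin, cmax, mmax, er0)
    starts = _inits(model, cmin, cmax, mmax, s, er0)
    for ei in extra_inits:
        ei = list(ei)
        if len(ei) == len(bounds) - 1:
            ei = ei + [er0]
        if len(ei) == len(bounds):
            starts.append(ei)
    starts = [_clip_to_bounds(x0, bounds) for x0 in starts]

    best_x, best_nll = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            _negll_and_grad, x0, args=(model, fn, conc, resp), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 150, "ftol": 1e-11, "gtol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_x = float(res.fun), res.x.copy()

    # least-squares polish: exact on noiseless data, and a good extra basin
    try:
        p_bounds = list(zip(*bounds[:-1]))
        ls = optimize.least_squares(
            lambda th: fn(conc, *th) - resp, best_x[:-1],
            bounds=(list(p_bounds[0]), list(p_bounds[1])), xtol=1e-13, ftol=1e-13, gtol=1e-13,
            max_nfev=400,
        )
        r_mad = nmad(ls.fun)
        er_ls = math.log(max(r_mad, math.exp(bounds[-1][0])))
        x0 = _clip_to_bounds(list(ls.x) + [er_ls], bounds)
        res = optimize.minimize(
            _negll_and_grad, x0, args=(model, fn, conc, resp), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 150, "ftol": 1e-11, "gtol": 1e-8},
        )
        for cand in (np.asarray(x0), res.x):
            v = _negll(cand, fn, conc, resp)
            if np.isfinite(v) and v < best_nll:
                best_nll, best_x = float(v), np.asarray(cand, dtype=float).copy()
    except Exception:
        pass

    if best_x is None:
        raise NotFittableError(f"{model}: no start converged")
    names = MODEL_PARAMS[model] + ("er",)
    params = {n: float(v) for n, v in zip(names, best_x)}
    ll = -best_nll
    k = len(names)
    return CRFit(model, params, ll, 2 * k - 2 * ll, len(resp))


def fit_family(conc, resp, models: Sequence[str] = MODEL_NAMES) -> list[CRFit]:
    """Fit a family of models on the same data, cascading nested solutions.

    The constant fit's error scale seeds every sloped model's zero-effect
    start, and simpler gain models seed their gain-loss / power-augmented
    extensions, so log-likelihood is nondecreasing along nesting chains.
    """
    conc_c, resp_c = _canonical(conc, resp)
    fits: dict[str, CRFit] = {}
    cmax = float(np.max(conc_c))
    for m in MODEL_NAMES:  # registry order guarantees parents fit first
        if m not in models:
            continue
        if m == "constant":
            fits[m] = fit_constant(conc_c, resp_c)
            continue
        extras: list[list[float]] = []
        const = fits.get("constant")
        if const is not None:
            extras.append([0.0] * len(MODEL_PARAMS[m]) + [const.params["er"]])
        parent = {"gnls": "hill", "exp5": "exp4", "exp3": "exp2", "poly2": "poly1"}.get(m)
        if parent in fits:
            pp = fits[parent].params
            if m == "gnls":
                # loss term (x/la)^q with la = 10*cmax and q at its upper bound
                # is negligible over the tested range: reduces to the hill fit
                extras.append([pp["tp"], pp["ga"], pp["p"], cmax * 10, 8.0, pp["er"]])
            elif m == "exp5":
                extras.append([pp["tp"], pp["ga"], 1.0, pp["er"]])
            elif m == "exp3":
                extras.append([pp["a"], pp["b"], 1.0, pp["er"]])
            elif m == "poly2":
                extras.append([pp["a"] * cmax / 2.0, cmax, pp["er"]])
        try:
            fits[m] = fit_model(conc_c, resp_c, m, extra_inits=extras)
        except NotFittableError:
            continue
    return [fits[m] for m in MODEL_NAMES if m in fits]


def select_model(fits: Sequence[CRFit]) -> CRFit:
    """Lowest-AIC fit; ties broken toward fewer parameters, then registry order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.n_free_params, MODEL_NAMES.index(f.model)))


# ---------------------------------------------------------------------------
# benchmark-concentration inversion

class BMCStatus(str, Enum):
    ESTIMATED = "estimated"
    ABOVE_TOP_CENSORED = "above_top_censored"
    NOT_CALCULABLE = "not_calculable"


@dataclass(frozen=True)
class BMCResult:
    """Benchmark concentration with censoring status."""

    bmc_uM: float | None
    bmr: float
    status: BMCStatus
    direction: str  # "up" or "down"
    below_range: bool = False

    @property
    def is_estimated(self) -> bool:
        return self.status is BMCStatus.ESTIMATED

    def display(self, top_tested: float | None = None) -> str:
        if self.status is BMCStatus.NOT_CALCULABLE:
            return "—"
        if self.status is BMCStatus.ABOVE_TOP_CENSORED:
            return f">{top_tested:g}" if top_tested is not None else ">top"
        return f"{self.bmc_uM:.2E}"

    def to_dict(self) -> dict:
        return {
            "bmc_uM": self.bmc_uM, "bmr": self.bmr, "status": self.status.value,
            "direction": self.direction, "below_range": self.below_range,
        }


NOT_CALCULABLE = BMCResult(None, float("nan"), BMCStatus.NOT_CALCULABLE, "up")


def _censored(bmr, direction):
    return BMCResult(None, float(bmr), BMCStatus.ABOVE_TOP_CENSORED, direction)


def invert_bmc(
    fit: CRFit,
    bmr: float,
    top_tested: float,
    min_tested: float | None = None,
    require_direction: str | None = None,
) -> BMCResult:
    """Smallest positive concentration where |fitted response| crosses |bmr|.

    The crossing is taken in the direction of the fitted top.  Closed forms
    are used for hill/exp4/exp5/poly1/power; poly2/exp2/exp3/gnls fall back to
    a log-grid scan plus Brent refinement.  A constant selected model, or a
    curve that never reaches the BMR within (0, top_tested], is censored as
    ">top".  Crossings below ``min_tested`` are still estimates but flagged
    ``below_range``.  One-sided endpoints (e.g. a distance from the null,
    where only increases are meaningful) may pass ``require_direction``: a
    fit pointing the other way is censored.
    """
    if bmr == 0:
        raise ValueError("bmr must be nonzero")
    if top_tested <= 0:
        raise ValueError("top_tested must be positive")
    b = abs(float(bmr))
    p = fit.params
    model = fit.model

    if model == "constant":
        return _censored(bmr, "up")

    f_top = float(np.asarray(fit.predict(top_tested)))
    if model == "gnls":
        direction = "up" if p["tp"] > 0 else "down"
    else:
        direction = "up" if f_top > 0 else ("down" if f_top < 0 else "up")
        if f_top == 0.0:
            return _censored(bmr, direction)
    if require_direction is not None and direction != require_direction:
        return _censored(bmr, direction)

    bmc: float | None = None
    if model in ("hill", "exp4", "exp5"):
        tp = abs(p["tp"])
        if tp > b:
            if model == "hill":
                bmc = p["ga"] * (tp / b - 1.0) ** (-1.0 / p["p"])
            elif model == "exp4":
                bmc = -p["ga"] * math.log2(1.0 - b / tp)
            else:
                bmc = p["ga"] * (-math.log2(1.0 - b / tp)) ** (1.0 / p["p"])
    elif model == "poly1":
        bmc = b / abs(p["a"]) if p["a"] != 0 else None
    elif model == "power":
        bmc = (b / abs(p["a"])) ** (1.0 / p["p"]) if p["a"] != 0 else None
    else:
        # grid scan on log scale for the first |f| = b crossing, then Brent
        lo = (min_tested if min_tested is not None else top_tested * 1e-6) * 1e-4
        grid = np.geomspace(lo, top_tested, 600)
        vals = np.abs(np.asarray(fit.predict(grid), dtype=float)) - b
        idx = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
        if idx.size:
            i = int(idx[0])
            bmc = float(optimize.brentq(
                lambda x: abs(float(np.asarray(fit.predict(x)))) - b,
                grid[i], grid[i + 1], xtol=1e-300, rtol=1e-13,
            ))
        elif vals[0] >= 0:  # already past the BMR at the bottom of the grid
            bmc = float(grid[0])

    if bmc is None or not np.isfinite(bmc) or bmc > top_tested:
        return _censored(bmr, direction)
    below = bool(min_tested is not None and bmc < min_tested)
    if below and abs(float(np.asarray(fit.predict(min_tested)))) < b:
        # the exceedance lives entirely below the tested range (a non-monotone
        # fit spiking where there is no data): not a defensible estimate
        return _censored(bmr, direction)
    return BMCResult(float(bmc), float(bmr), BMCStatus.ESTIMATED, direction, below)
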