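"""Quantal (dichotomous) benchmark-dose modeling of DEG-count profiles.

The per-dose count of differentially expressed genes, expressed as a
fraction of the total unique DEG count, is treated as incidence data and
modeled with the standard quantal suite at a benchmark response of 10%
extra risk, [P(d) - P(0)] / [1 - P(0)] = 0.10.

Model forms (g = background, all fitted by binomial maximum likelihood,
with the conventional shape restrictions):

* logistic        P(d) = 1 / (1 + exp(-(a + b d)))
* probit          P(d) = Phi(a + b d)
* log_logistic    P(d) = g + (1-g) / (1 + exp(-(a + b ln d))),  b >= 1
* quantal_linear  P(d) = g + (1-g)(1 - exp(-b d))
* multistage2     P(d) = g + (1-g)(1 - exp(-(b1 d + b2 d^2))),  b >= 0
* multistage3     ... + b3 d^3,                                 b >= 0
* weibull         P(d) = g + (1-g)(1 - exp(-b d^a)),            a >= 1
* gamma           P(d) = g + (1-g) GammaCDF(b d; a),            a >= 1

Selection follows the published rule: lowest AIC among models with Pearson
goodness-of-fit p > 0.1, with a divergence flag when candidate BMDs span a
>= 3-fold range.  When no model reaches the fit threshold (common for very
large denominators, where even small lack-of-fit is overwhelming), the
selector falls back — flagged — to the lowest-AIC member of the multistage
family (quantal-linear is its degree-1 case), the conventional default
family for cancer-type incidence data.

BMDLs are one-sided profile-likelihood lower confidence limits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_formats import TxpodError
from .synthetic_data import DichotomousDataset

logger = logging.getLogger("txpod")

DICHOTOMOUS_MODELS = (
    "logistic", "probit", "log_logistic", "quantal_linear",
    "multistage2", "multistage3", "weibull", "gamma",
)
MULTISTAGE_FAMILY = ("quantal_linear", "multistage2", "multistage3")
_AIC_TIE = 1e-6
_PCLIP = 1e-12


@dataclass
class DichotomousFit:
    model_name: str
    params: np.ndarray
    param_names: tuple[str, ...]
    loglik: float
    aic: float
    gof_p: float
    bmd: float
    bmdl: float = float("nan")
    converged: bool = True
    data: DichotomousDataset = field(repr=False, default=None)

    def predict(self, d) -> np.ndarray:
        return _MODELS[self.model_name].prob(np.asarray(d, float), self.params)


class _ModelDef:
    def __init__(self, prob, bounds, names, starts, bmd_fn):
        self.prob = prob
        self.bounds = bounds
        self.names = names
        self.starts = starts
        self.bmd_fn = bmd_fn


def _logistic_p(d, th):
    a, b = th
    return 1.0 / (1.0 + np.exp(-(a + b * d)))


def _logistic_bmd(th, bmr):
    a, b = th
    p0 = 1.0 / (1.0 + math.exp(-a))
    pt = p0 + bmr * (1.0 - p0)
    return (math.log(pt / (1.0 - pt)) - a) / b


def _probit_p(d, th):
    a, b = th
    return stats.norm.cdf(a + b * d)


def _probit_bmd(th, bmr):
    a, b = th
    p0 = stats.norm.cdf(a)
    pt = p0 + bmr * (1.0 - p0)
    return (stats.norm.ppf(pt) - a) / b


def _loglogistic_p(d, th):
    g, a, b = th
    d = np.asarray(d, float)
    out = np.full(d.shape, g, dtype=float)
    pos = d > 0
    out[pos] = g + (1.0 - g) / (1.0 + np.exp(-(a + b * np.log(d[pos]))))
    return out


def _loglogistic_bmd(th, bmr):
    g, a, b = th
    return math.exp((math.log(bmr / (1.0 - bmr)) - a) / b)


def _ql_p(d, th):
    g, b = th
    return g + (1.0 - g) * (1.0 - np.exp(-b * np.asarray(d, float)))


def _ql_bmd(th, bmr):
    b = th[1]
    return -math.log(1.0 - bmr) / b if b > 0 else float("inf")


def _ms_p_factory(degree):
    def prob(d, th):
        d = np.asarray(d, float)
        g = th[0]
        poly = sum(th[i] * d**i for i in range(1, degree + 1))
        return g + (1.0 - g) * (1.0 - np.exp(-poly))
    return prob


def _ms_bmd_factory(degree):
    def bmd(th, bmr):
        c = -math.log(1.0 - bmr)
        coeffs = [th[i] for i in range(degree, 0, -1)] + [-c]
        roots = np.roots(coeffs)
        real = [r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 1e-12]
        return min(real) if real else float("inf")
    return bmd


def _weibull_p(d, th):
    g, a, b = th
    d = np.asarray(d, float)
    return g + (1.0 - g) * (1.0 - np.exp(-b * np.power(np.maximum(d, 0), a)))


def _weibull_bmd(th, bmr):
    g, a, b = th
    return (-math.log(1.0 - bmr) / b) ** (1.0 / a) if b > 0 else float("inf")


def _gamma_p(d, th):
    g, a, b = th
    d = np.asarray(d, float)
    return g + (1.0 - g) * special.gammainc(a, b * np.maximum(d, 0))


def _gamma_bmd(th, bmr):
    g, a, b = th
    return float(special.gammaincinv(a, bmr)) / b if b > 0 else float("inf")


_MODELS: dict[str, _ModelDef] = {
    "logistic": _ModelDef(
        _logistic_p, [(-50, 50), (1e-9, 50)], ("alpha", "beta"),
        [(-2.0, 0.3), (-1.0, 0.1), (-4.0, 1.0)], _logistic_bmd),
    "probit": _ModelDef(
        _probit_p, [(-20, 20), (1e-9, 20)], ("alpha", "beta"),
        [(-1.0, 0.2), (-2.0, 0.5), (-0.5, 0.1)], _probit_bmd),
    "log_logistic": _ModelDef(
        _loglogistic_p, [(0, 1 - 1e-9), (-50, 50), (1, 18)],
        ("background", "alpha", "beta"),
        [(0.01, -3.0, 1.5), (0.0, -1.0, 1.0), (0.05, -5.0, 3.0)],
        _loglogistic_bmd),
    "quantal_linear": _ModelDef(
        _ql_p, [(0, 1 - 1e-9), (1e-9, 50)], ("background", "beta"),
        [(0.01, 0.2), (0.0, 0.05), (0.05, 0.5)], _ql_bmd),
    "multistage2": _ModelDef(
        _ms_p_factory(2), [(0, 1 - 1e-9), (0, 50), (0, 50)],
        ("background", "beta1", "beta2"),
        [(0.01, 0.1, 0.01), (0.0, 0.02, 0.03), (0.0, 0.0, 0.05)],
        _ms_bmd_factory(2)),
    "multistage3": _ModelDef(
        _ms_p_factory(3), [(0, 1 - 1e-9), (0, 50), (0, 50), (0, 50)],
        ("background", "beta1", "beta2", "beta3"),
        [(0.01, 0.05, 0.005, 0.001), (0.0, 0.01, 0.001, 0.005),
         (0.0, 0.0, 0.0, 0.01), (0.01, 0.1, 0.01, 0.001)],
        _ms_bmd_factory(3)),
    "weibull": _ModelDef(
        _weibull_p, [(0, 1 - 1e-9), (1, 18), (1e-9, 50)],
        ("background", "power", "beta"),
        [(0.01, 1.5, 0.05), (0.0, 2.5, 0.01), (0.0, 1.0, 0.2)], _weibull_bmd),
    "gamma": _ModelDef(
        _gamma_p, [(0, 1 - 1e-9), (1, 18), (1e-9, 50)],
        ("background", "power", "beta"),
        [(0.01, 1.5, 0.3), (0.0, 3.0, 0.5), (0.0, 1.0, 0.1)], _gamma_bmd),
}


def binomial_loglik(p, n, k) -> float:
    """Binomial log-likelihood (without the combinatorial constant)."""
    p = np.clip(np.asarray(p, float), _PCLIP, 1.0 - _PCLIP)
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    return float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))


def _n_free_params(params: np.ndarray, bounds, tol: float = 1e-6) -> int:
    free = 0
    for v, (lo, hi) in zip(params, bounds):
        if v > lo + tol and v < hi - tol:
            free += 1
    return free


def fit_dichotomous(data: DichotomousDataset, model_name: str,
                    bmr: float = 0.10) -> DichotomousFit:
    """Fit one quantal model by binomial maximum likelihood.

    Deterministic multi-start bounded minimization; the Pearson chi-square
    goodness-of-fit uses df = (#dose groups) - (#parameters not stuck at a
    bound), with p = 1 when df <= 0.
    """
    if len(data.doses) < 3:
        raise TxpodError("need at least 3 dose groups")
    if model_name not in _MODELS:
        raise TxpodError(f"unknown dichotomous model {model_name!r}")
    mdef = _MODELS[model_name]
    d, k, n = data.doses, data.affected.astype(float), data.denominator.astype(float)

    def nll(th):
        return -binomial_loglik(mdef.prob(d, th), n, k)

    best = None
    for x0 in mdef.starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=mdef.bounds)
        if best is None or res.fun < best.fun:
            best = res
    th = np.asarray(best.x, float)
    ll = -float(best.fun)
    npar = len(th)
    aic = 2 * npar - 2 * ll
    phat = np.clip(mdef.prob(d, th), _PCLIP, 1 - _PCLIP)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((k - n * phat) ** 2 / (n * phat * (1 - phat))))
    df = len(d) - _n_free_params(th, mdef.bounds)
    gof_p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    bmd = bmd_extra_risk_params(model_name, th, bmr)
    converged = bool(best.success) and np.isfinite(ll)
    if k.sum() == 0:
        bmd = float("nan")  # background-only data: benchmark unreachable
    return DichotomousFit(
        model_name=model_name, params=th, param_names=mdef.names,
        loglik=ll, aic=aic, gof_p=gof_p, bmd=bmd, converged=converged,
        data=data)


def bmd_extra_risk_params(model_name: str, params, bmr: float = 0.10) -> float:
    """Dose at ``bmr`` extra risk (closed form per model)."""
    if not 0 < bmr < 1:
        return float("nan")
    val = _MODELS[model_name].bmd_fn(np.asarray(params, float), bmr)
    return float(val) if np.isfinite(val) and val > 0 else float("nan")


def bmd_extra_risk(fit: DichotomousFit, bmr: float = 0.10) -> float:
    return bmd_extra_risk_params(fit.model_name, fit.params, bmr)


def bmdl_profile_dichotomous(fit: DichotomousFit, bmr: float = 0.10,
                             confidence: float = 0.95) -> float:
    """One-sided profile-likelihood lower bound on the BMD.

    Bisection on candidate BMDL values; at each the likelihood is maximized
    subject to BMD(theta) = b (SLSQP with an equality constraint).
    """
    if not np.isfinite(fit.bmd):
        return float("nan")
    data = fit.data
    mdef = _MODELS[fit.model_name]
    d, k, n = data.doses, data.affected.astype(float), data.denominator.astype(float)
    offset = stats.chi2.ppf(2 * confidence - 1, 1) / 2.0
    target = fit.loglik - offset

    def profile_ll(b: float) -> float:
        def nll(th):
            return -binomial_loglik(mdef.prob(d, th), n, k)

        cons = [{"type": "eq",
                 "fun": lambda th: bmd_extra_risk_params(fit.model_name, th, bmr) - b}]
        # a near-feasible start: stretch the dose response so the BMD moves to b
        stretched = fit.params.copy()
        if fit.model_name in MULTISTAGE_FAMILY:
            for i in range(1, len(stretched)):
                stretched[i] *= (fit.bmd / b) ** i
        elif fit.model_name in ("weibull", "gamma"):
            stretched[2] *= (fit.bmd / b) ** (stretched[1] if fit.model_name == "weibull" else 1.0)
        best = None
        for x0 in (fit.params, stretched, np.asarray(mdef.starts[0], float)):
            try:
                res = optimize.minimize(
                    nll, x0, method="SLSQP", bounds=mdef.bounds,
                    constraints=cons,
                    options={"maxiter": 600, "ftol": 1e-11})
            except (ValueError, OverflowError):
                continue
            if res.success and (best is None or res.fun < best):
                best = float(res.fun)
        return -best if best is not None else -math.inf

    lo, hi = fit.bmd * 1e-3, fit.bmd
    for _ in range(6):
        if profile_ll(lo) < target:
            break
        lo /= 10.0
        if lo < fit.bmd * 1e-9:
            return float(lo)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if profile_ll(mid) >= target:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-4 * fit.bmd:
            break
    return float(hi)


def fit_dichotomous_suite(data: DichotomousDataset, bmr: float = 0.10,
                          models=DICHOTOMOUS_MODELS) -> list[DichotomousFit]:
    fits = []
    for m in models:
        try:
            fits.append(fit_dichotomous(data, m, bmr))
        except TxpodError:
            raise
        except Exception as exc:  # degenerate/separated data
            logger.warning("dichotomous model %s failed: %s", m, exc)
    return fits


def _aic_key(fit: DichotomousFit) -> tuple:
    return (round(fit.aic / _AIC_TIE) * _AIC_TIE, len(fit.params),
            DICHOTOMOUS_MODELS.index(fit.model_name))


def select_dichotomous(fits: list[DichotomousFit], gof_threshold: float = 0.1
                       ) -> tuple[DichotomousFit, dict]:
    """Lowest AIC among goodness-of-fit passers, with divergence bookkeeping.

    ``report['bmd_divergent']`` is set when the candidate BMDs span at least
    a 3-fold range.  With no passer the selection falls back to the
    lowest-AIC multistage-family fit and ``report['poor_fit_fallback']`` is
    set; selection fails only if nothing converged with a defined BMD.
    """
    report: dict = {"bmd_divergent": False, "poor_fit_fallback": False,
                    "candidates": []}
    usable = [f for f in fits if f.converged and np.isfinite(f.bmd)]
    if not usable:
        raise TxpodError("no converged dichotomous fit with a defined BMD")
    passing = [f for f in usable if f.gof_p > gof_threshold]
    if passing:
        pool = passing
    else:
        pool = [f for f in usable if f.model_name in MULTISTAGE_FAMILY]
        if not pool:
            pool = usable
        report["poor_fit_fallback"] = True
    bmds = [f.bmd for f in pool]
    if max(bmds) / min(bmds) >= 3.0:
        report["bmd_divergent"] = True
    report["candidates"] = [(f.model_name, f.bmd, f.gof_p) for f in pool]
    winner = min(pool, key=_aic_key)
    return winner, report


def run_deg_count_bmd(data: DichotomousDataset, bmr: float = 0.10,
                      confidence: float = 0.95) -> tuple[DichotomousFit, dict]:
    """Full quantal pipeline: fit suite, select, BMD, profile BMDL."""
    fits = fit_dichotomous_suite(data, bmr)
    winner, report = select_dichotomous(fits)
    winner.bmdl = bmdl_profile_dichotomous(winner, bmr, confidence)
    report["all_fits"] = [(f.model_name, f.aic, f.gof_p, f.bmd) for f in fits]
    return winner, report
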