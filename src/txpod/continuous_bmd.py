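"""Continuous dose-response modeling: Hill/power/linear/polynomial fits,
model selection, and BMD/BMDL at a benchmark response of 1.349 control SD.

Per gene, five mean functions are fitted under a constant-variance normal
likelihood (equivalently by least squares, with the MLE variance SSE/N):

* linear   f(d) = g + b1*d
* poly2    f(d) = g + b1*d + b2*d^2
* poly3    f(d) = g + b1*d + b2*d^2 + b3*d^3
* power    f(d) = g + b*d^delta,              delta >= 1
* hill     f(d) = g + v*d^n / (k^n + d^n),    n >= 1, k > 0

Selection follows the BMDExpress-style rule set: a nested chi-square test
(cutoff 0.05) picks among the polynomial family; the nested winner, power,
and Hill then compete on AIC among models with lack-of-fit p > 0.1.  A Hill
winner whose half-max parameter k falls below one third of the lowest
positive dose is flagged: the next-best model is used if its fit p > 0.05,
otherwise the Hill BMD is replaced by half the lowest positive dose.

The BMD solves |f(d) - f(0)| = bmr_sd * sigma_hat (first crossing); the BMDL
is a one-sided profile-likelihood lower confidence limit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_formats import DoseResponseSet, RunConfig, TxpodError

logger = logging.getLogger("txpod")

MODEL_ORDER = ("linear", "poly2", "poly3", "power", "hill")
# parameter counts include the variance parameter
N_PARAMS = {"linear": 3, "poly2": 4, "poly3": 5, "power": 4, "hill": 5}
_AIC_TIE = 1e-6
_SIGMA_FLOOR2 = 1e-24  # variance floor for exact (zero-residual) fits


def _chi2_sf(x: float, df: int) -> float:
    return float(special.chdtrc(df, x))


@dataclass
class GroupStats:
    """Sufficient statistics of one gene's replicated dose series."""

    doses: np.ndarray   # distinct doses, increasing
    n: np.ndarray       # replicates per dose
    means: np.ndarray   # group means
    ssw: float          # within-group sum of squares

    @classmethod
    def from_arrays(cls, dose_vec, values) -> "GroupStats":
        dose_vec = np.asarray(dose_vec, dtype=float)
        values = np.asarray(values, dtype=float)
        if dose_vec.shape != values.shape:
            raise TxpodError("doses and values must align")
        doses = np.unique(dose_vec)
        n = np.array([(dose_vec == d).sum() for d in doses])
        means = np.array([values[dose_vec == d].mean() for d in doses])
        ssw = float(sum(((values[dose_vec == d] - m) ** 2).sum()
                        for d, m in zip(doses, means)))
        return cls(doses=doses, n=n, means=means, ssw=ssw)

    @property
    def total_n(self) -> int:
        return int(self.n.sum())


@dataclass
class ContinuousFit:
    model_name: str
    params: dict[str, float]
    sigma_hat: float
    loglik: float
    aic: float
    gof_p: float
    n_params: int
    converged: bool
    stats: GroupStats = field(repr=False)

    def predict(self, d) -> np.ndarray:
        return _predict(self.model_name, self.params, d)


@dataclass
class BmdResult:
    gene: str
    model_name: str | None
    bmd: float
    bmdl: float
    hill_flagged: bool = False
    flag_action: str = "none"        # none | next_best | halved_substitute
    excluded_above_top: bool = False
    gof_p: float = float("nan")
    aic: float = float("nan")
    sigma_hat: float = float("nan")
    reason: str = ""


def _predict(model: str, p: dict[str, float], d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if model == "linear":
        return p["gamma"] + p["beta1"] * d
    if model == "poly2":
        return p["gamma"] + p["beta1"] * d + p["beta2"] * d**2
    if model == "poly3":
        return p["gamma"] + p["beta1"] * d + p["beta2"] * d**2 + p["beta3"] * d**3
    if model == "power":
        return p["gamma"] + p["beta"] * np.power(d, p["delta"])
    if model == "hill":
        k, n = p["k"], p["n"]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(d > 0, d**n / (k**n + d**n), 0.0)
        return p["gamma"] + p["nu"] * frac
    raise TxpodError(f"unknown continuous model {model!r}")


def _weighted_lstsq(X: np.ndarray, gs: GroupStats) -> tuple[np.ndarray, float]:
    """Least squares of group means on design X with replicate weights.

    Returns coefficients and the total SSE (within + lack-of-fit)."""
    w = np.sqrt(gs.n.astype(float))
    coef, *_ = np.linalg.lstsq(X * w[:, None], gs.means * w, rcond=None)
    resid = gs.means - X @ coef
    return coef, gs.ssw + float((gs.n * resid**2).sum())


def _loglik_from_sse(sse: float, n_total: int) -> tuple[float, float]:
    sigma2 = max(sse / n_total, _SIGMA_FLOOR2)
    ll = -0.5 * n_total * (math.log(2 * math.pi * sigma2) + 1.0)
    return ll, math.sqrt(sigma2)


def _poly_design(doses: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(doses, degree + 1, increasing=True)


def _fit_polynomial(gs: GroupStats, degree: int, model: str) -> ContinuousFit:
    if degree >= len(gs.doses):
        raise TxpodError(
            f"{model} needs at least {degree + 1} distinct doses")
    coef, sse = _weighted_lstsq(_poly_design(gs.doses, degree), gs)
    names = ["gamma", "beta1", "beta2", "beta3"][: degree + 1]
    params = dict(zip(names, map(float, coef)))
    return _finish_fit(model, params, sse, gs, converged=True)


def _profiled_sse(basis: np.ndarray, gs: GroupStats
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (intercept, amplitude) per candidate shape basis row.

    ``basis`` is (candidates x doses); returns (sse, gamma, amp) arrays with
    the within-group SS included in sse."""
    w = gs.n.astype(float)
    y = gs.means
    sw = w.sum()
    sy = float((w * y).sum())
    sx = basis @ w
    sxx = (basis**2) @ w
    sxy = basis @ (w * y)
    det = sw * sxx - sx**2
    safe = det > 1e-12 * np.maximum(sw * sxx, 1e-300)
    amp = np.where(safe, (sw * sxy - sx * sy) / np.where(safe, det, 1.0), 0.0)
    gamma = (sy - amp * sx) / sw
    resid = y[None, :] - gamma[:, None] - amp[:, None] * basis
    sse = gs.ssw + (resid**2) @ w
    return sse, gamma, amp


def _scalar_profiled_sse(basis: np.ndarray, gs: GroupStats
                         ) -> tuple[float, float, float]:
    """Fast scalar version of :func:`_profiled_sse` for one basis vector."""
    w = gs.n
    y = gs.means
    sw = w.sum()
    sy = (w * y).sum()
    sx = (w * basis).sum()
    sxx = (w * basis * basis).sum()
    sxy = (w * basis * y).sum()
    det = sw * sxx - sx * sx
    if det <= 1e-12 * max(sw * sxx, 1e-300):
        amp = 0.0
    else:
        amp = (sw * sxy - sx * sy) / det
    gamma = (sy - amp * sx) / sw
    resid = y - gamma - amp * basis
    return gs.ssw + float((w * resid * resid).sum()), float(gamma), float(amp)


def _fit_power(gs: GroupStats, max_iterations: int) -> ContinuousFit:
    d = gs.doses

    def basis_for(deltas: np.ndarray) -> np.ndarray:
        return np.power(d[None, :], deltas[:, None])

    grid = np.concatenate([[1.0], np.geomspace(1.01, 18.0, 60)])
    sse, _, _ = _profiled_sse(basis_for(grid), gs)
    i = int(np.argmin(sse))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: _scalar_profiled_sse(d**t, gs)[0],
            bounds=(lo, hi), method="bounded",
            options={"maxiter": max_iterations, "xatol": 1e-7})
        cand = [1.0, float(grid[i]), float(res.x)]
    else:
        cand = [1.0, float(grid[i])]
    fits = [(_scalar_profiled_sse(d**c, gs), c) for c in cand]
    (sse_j, gamma_j, amp_j), delta = min(fits, key=lambda t: t[0][0])
    # prefer the simplest shape (delta = 1) on numerical ties
    if fits[0][0][0] <= sse_j * (1 + 1e-9) + 1e-300:
        (sse_j, gamma_j, amp_j), delta = fits[0]
    params = {"gamma": gamma_j, "beta": amp_j, "delta": delta}
    return _finish_fit("power", params, sse_j, gs, converged=True)


def _hill_basis(d: np.ndarray, logk: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Hill fraction d^n / (k^n + d^n) for each (logk, n) pair (rows)."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        logd = np.where(d > 0, np.log(np.maximum(d, 1e-300)), -np.inf)
        z = n[:, None] * (logd[None, :] - logk[:, None])
        return np.where(np.isneginf(z), 0.0, 1.0 / (1.0 + np.exp(-z)))


def _fit_hill(gs: GroupStats, max_iterations: int) -> ContinuousFit:
    if len(gs.doses) < 4:
        raise TxpodError("hill needs at least 4 distinct doses")
    d = gs.doses
    top = float(d.max())
    lowpos = float(d[d > 0].min())
    logk_grid = np.log(np.geomspace(lowpos / 50.0, top * 10.0, 28))
    n_grid = np.array([1.0, 1.3, 1.7, 2.2, 2.8, 3.6, 4.6, 6.0, 8.0, 11.0, 15.0, 18.0])
    KK, NN = np.meshgrid(logk_grid, n_grid, indexing="ij")
    logk_all, n_all = KK.ravel(), NN.ravel()
    sse, _, _ = _profiled_sse(_hill_basis(d, logk_all, n_all), gs)
    i = int(np.argmin(sse))

    lo_k, hi_k = math.log(lowpos / 100.0), math.log(top * 30.0)
    logd_list = [math.log(v) if v > 0 else None for v in d.tolist()]
    w_list = gs.n.tolist()
    y_list = gs.means.tolist()
    sw = float(sum(w_list))
    sy = float(sum(wi * yi for wi, yi in zip(w_list, y_list)))

    def _basis_list(logk: float, n: float) -> list[float]:
        out = []
        for ld in logd_list:
            if ld is None:
                out.append(0.0)
                continue
            z = n * (ld - logk)
            if z > 35.0:
                out.append(1.0)
            elif z < -35.0:
                out.append(0.0)
            else:
                out.append(1.0 / (1.0 + math.exp(-z)))
        return out

    def _sse_of_basis(basis: list[float]) -> tuple[float, float, float]:
        sx = sxx = sxy = 0.0
        for wi, yi, bi in zip(w_list, y_list, basis):
            sx += wi * bi
            sxx += wi * bi * bi
            sxy += wi * bi * yi
        det = sw * sxx - sx * sx
        amp = 0.0 if det <= 1e-12 * max(sw * sxx, 1e-300) else (sw * sxy - sx * sy) / det
        gamma = (sy - amp * sx) / sw
        sse = gs.ssw
        for wi, yi, bi in zip(w_list, y_list, basis):
            r = yi - gamma - amp * bi
            sse += wi * r * r
        return sse, gamma, amp

    def scalar_basis(logk: float, n: float) -> np.ndarray:
        return np.asarray(_basis_list(logk, n))

    def sse_at(x) -> float:
        logk = min(max(float(x[0]), lo_k), hi_k)
        n = min(max(float(x[1]), 1.0), 18.0)
        return _sse_of_basis(_basis_list(logk, n))[0]

    res = optimize.minimize(
        sse_at, np.array([logk_all[i], n_all[i]]), method="Nelder-Mead",
        options={"maxiter": max_iterations, "xatol": 2e-5, "fatol": 1e-12})
    x = (min(max(res.x[0], lo_k), hi_k), min(max(res.x[1], 1.0), 18.0))
    if sse_at(x) > sse[i]:
        x = (float(logk_all[i]), float(n_all[i]))
    k, n = math.exp(x[0]), float(x[1])
    sse_b, gamma_b, amp_b = _scalar_profiled_sse(scalar_basis(x[0], n), gs)
    params = {"gamma": gamma_b, "nu": amp_b, "k": k, "n": n}
    return _finish_fit("hill", params, sse_b, gs, converged=True)


def _finish_fit(model: str, params: dict, sse: float, gs: GroupStats,
                converged: bool) -> ContinuousFit:
    ll, sigma = _loglik_from_sse(sse, gs.total_n)
    npar = N_PARAMS[model]
    return ContinuousFit(
        model_name=model, params=params, sigma_hat=sigma, loglik=ll,
        aic=2 * npar - 2 * ll, gof_p=float("nan"), n_params=npar,
        converged=converged, stats=gs,
    )


def fit_model(doses, values, model_name: str,
              max_iterations: int = 250) -> ContinuousFit:
    """Fit one mean function to a replicated dose series by maximum likelihood.

    ``doses`` gives the dose of each measurement in ``values``.  Hill and
    cubic fits require at least four distinct doses.
    """
    gs = GroupStats.from_arrays(doses, values)
    fit = _fit_from_stats(gs, model_name, max_iterations)
    fit.gof_p = goodness_of_fit(fit)
    return fit


def _fit_from_stats(gs: GroupStats, model_name: str,
                    max_iterations: int) -> ContinuousFit:
    if model_name == "linear":
        return _fit_polynomial(gs, 1, "linear")
    if model_name == "poly2":
        return _fit_polynomial(gs, 2, "poly2")
    if model_name == "poly3":
        return _fit_polynomial(gs, 3, "poly3")
    if model_name == "power":
        return _fit_power(gs, max_iterations)
    if model_name == "hill":
        return _fit_hill(gs, max_iterations)
    raise TxpodError(f"unknown continuous model {model_name!r}")


def goodness_of_fit(fit: ContinuousFit) -> float:
    """Likelihood-ratio lack-of-fit p against the saturated group-means model.

    Both models share the constant-variance structure; df is the number of
    dose groups minus the number of mean-function parameters (p = 1 when
    df <= 0, i.e. the mean function can interpolate the group means).
    """
    gs = fit.stats
    ll_sat, _ = _loglik_from_sse(gs.ssw, gs.total_n)
    lr = max(2.0 * (ll_sat - fit.loglik), 0.0)
    df = len(gs.doses) - (fit.n_params - 1)
    if df <= 0:
        return 1.0
    return _chi2_sf(lr, df)


def nested_linear_vs_poly(fits: dict[str, ContinuousFit],
                          cutoff: float = 0.05) -> ContinuousFit:
    """Step-up likelihood-ratio choice among linear / poly2 / poly3."""
    chain = [fits[m] for m in ("linear", "poly2", "poly3")
             if m in fits and fits[m] is not None and fits[m].converged]
    if not chain:
        raise TxpodError("no converged nested fits")
    current = chain[0]
    for nxt in chain[1:]:
        lr = 2.0 * (nxt.loglik - current.loglik)
        df = nxt.n_params - current.n_params
        if _chi2_sf(max(lr, 0.0), df) < cutoff:
            current = nxt
    return current


def _aic_key(fit: ContinuousFit) -> tuple:
    return (round(fit.aic / _AIC_TIE) * _AIC_TIE, fit.n_params,
            MODEL_ORDER.index(fit.model_name))


def select_best_model(
    fits: dict[str, ContinuousFit],
    gof_threshold: float = 0.1,
    lowest_positive_dose: float | None = None,
    nested_cutoff: float = 0.05,
    hill_flag_literal_halving: bool = False,
) -> tuple[ContinuousFit | None, dict]:
    """Apply the full selection rule; returns (winner, bookkeeping).

    Candidates are the nested-family winner, power, and Hill.  The lowest-AIC
    candidate with fit p > ``gof_threshold`` wins (ties: fewest parameters,
    then fixed model order).  A flagged Hill (k < lowest positive dose / 3)
    yields to the next-best candidate with fit p > 0.05; if none exists the
    Hill is kept and its BMD later replaced by half the lowest positive dose
    (or half its own BMD under the literal-halving switch).
    """
    info: dict = {"hill_flagged": False, "flag_action": "none", "reason": ""}
    for f in fits.values():
        if f is not None and math.isnan(f.gof_p):
            f.gof_p = goodness_of_fit(f)
    candidates: list[ContinuousFit] = []
    try:
        candidates.append(nested_linear_vs_poly(fits, nested_cutoff))
    except TxpodError:
        pass
    for name in ("power", "hill"):
        f = fits.get(name)
        if f is not None and f.converged:
            candidates.append(f)
    if not candidates:
        info["reason"] = "no converged fits"
        return None, info
    passing = [f for f in candidates if f.gof_p > gof_threshold]
    if not passing:
        info["reason"] = "no model with goodness-of-fit p > %g" % gof_threshold
        return None, info
    winner = min(passing, key=_aic_key)
    if winner.model_name == "hill" and lowest_positive_dose is not None:
        if winner.params["k"] < lowest_positive_dose / 3.0:
            info["hill_flagged"] = True
            alt = [f for f in candidates
                   if f is not winner and f.gof_p > 0.05]
            if alt:
                winner = min(alt, key=_aic_key)
                info["flag_action"] = "next_best"
            else:
                info["flag_action"] = "halved_substitute"
                info["halved_reference"] = (
                    "own_bmd" if hill_flag_literal_halving else "lowest_dose")
    return winner, info


def compute_bmd(fit: ContinuousFit, bmr_sd: float = 1.349) -> float:
    """Smallest positive dose with |f(d) - f(0)| = bmr_sd * sigma_hat.

    Closed-form for linear/power/Hill; first sign crossing (dense scan +
    Brent refinement) for polynomials.  NaN when the benchmark response is
    unreachable within 10x the top dose or sigma_hat is (numerically) zero.
    """
    if fit.sigma_hat <= 1e-10:
        return float("nan")
    band = bmr_sd * fit.sigma_hat
    p = fit.params
    top = float(fit.stats.doses.max())
    limit = 10.0 * top
    if fit.model_name == "linear":
        if p["beta1"] == 0:
            return float("nan")
        bmd = band / abs(p["beta1"])
        return bmd if bmd <= limit else float("nan")
    if fit.model_name == "power":
        if p["beta"] == 0:
            return float("nan")
        bmd = (band / abs(p["beta"])) ** (1.0 / p["delta"])
        return bmd if bmd <= limit else float("nan")
    if fit.model_name == "hill":
        if abs(p["nu"]) <= band:
            return float("nan")
        r = band / abs(p["nu"])
        bmd = p["k"] * (r / (1.0 - r)) ** (1.0 / p["n"])
        return bmd if bmd <= limit else float("nan")
    # polynomials: first crossing of the band (curves may be non-monotone)
    f0 = float(fit.predict(0.0))
    grid = np.linspace(0.0, limit, 8193)
    g = np.abs(fit.predict(grid) - f0) - band
    crossing = np.nonzero((g[:-1] < 0) & (g[1:] >= 0))[0]
    if len(crossing) == 0:
        return float("nan")
    i = int(crossing[0])
    lo, hi = grid[i], grid[i + 1]
    func = lambda d: abs(float(fit.predict(d)) - f0) - band
    if func(lo) == 0.0:
        return float(lo)
    return float(optimize.brentq(func, lo, hi, xtol=1e-10, rtol=1e-12))


# ---------------------------------------------------------------------------
# profile-likelihood BMDL

def _constrained_sse(model: str, gs: GroupStats, b: float, band_per_sigma: float,
                     sigma: float, shape: np.ndarray, sign: float) -> float:
    """SSE with the amplitude parameter eliminated by the BMR constraint
    |f(b) - f(0)| = band_per_sigma * sigma."""
    band = band_per_sigma * sigma
    d = gs.doses
    if model == "linear":
        beta1 = sign * band / b
        resid_basis = gs.means - beta1 * d
        X = np.ones((len(d), 1))
    elif model == "poly2":
        (beta2,) = shape
        beta1 = (sign * band - beta2 * b**2) / b
        resid_basis = gs.means - beta1 * d - beta2 * d**2
        X = np.ones((len(d), 1))
    elif model == "poly3":
        beta2, beta3 = shape
        beta1 = (sign * band - beta2 * b**2 - beta3 * b**3) / b
        resid_basis = gs.means - beta1 * d - beta2 * d**2 - beta3 * d**3
        X = np.ones((len(d), 1))
    elif model == "power":
        (delta,) = shape
        delta = min(max(delta, 1.0), 18.0)
        beta = sign * band / b**delta
        resid_basis = gs.means - beta * np.power(d, delta)
        X = np.ones((len(d), 1))
    elif model == "hill":
        logk, n = shape
        n = min(max(n, 1.0), 18.0)
        k = math.exp(logk)
        frac_b = b**n / (k**n + b**n)
        nu = sign * band / frac_b
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(d > 0, d**n / (k**n + d**n), 0.0)
        resid_basis = gs.means - nu * frac
        X = np.ones((len(d), 1))
    else:
        raise TxpodError(model)
    # optimal intercept is the weighted mean of the residual basis
    gamma = float((gs.n * resid_basis).sum() / gs.n.sum())
    return gs.ssw + float((gs.n * (resid_basis - gamma) ** 2).sum())


_SHAPE_DIM = {"linear": 0, "poly2": 1, "poly3": 2, "power": 1, "hill": 2}


def _profile_loglik(fit: ContinuousFit, b: float, bmr_sd: float) -> float:
    """Maximum log-likelihood subject to BMD = b (both sign branches)."""
    gs, model = fit.stats, fit.model_name
    N = gs.total_n
    p = fit.params
    if model == "linear":
        shape0 = np.array([])
    elif model == "poly2":
        shape0 = np.array([p["beta2"]])
    elif model == "poly3":
        shape0 = np.array([p["beta2"], p["beta3"]])
    elif model == "power":
        shape0 = np.array([p["delta"]])
    else:
        shape0 = np.array([math.log(p["k"]), p["n"]])
    amp = {"linear": p.get("beta1"), "poly2": p.get("beta1"),
           "poly3": p.get("beta1"), "power": p.get("beta"),
           "hill": p.get("nu")}[model]
    signs = (1.0, -1.0) if amp is None or amp == 0 else (math.copysign(1.0, amp), -math.copysign(1.0, amp))

    best = -math.inf
    for sign in signs:
        def nll(x):
            sigma = math.exp(x[-1])
            sse = _constrained_sse(model, gs, b, bmr_sd, sigma, x[:-1], sign)
            return 0.5 * N * math.log(2 * math.pi * sigma**2) + sse / (2 * sigma**2)

        x0 = np.append(shape0, math.log(max(fit.sigma_hat, 1e-6)))
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 400, "xatol": 1e-6,
                                         "fatol": 1e-9})
        best = max(best, -float(res.fun))
        if sign == signs[0] and best > -math.inf and model == "linear":
            break  # the opposite-sign branch cannot do better for a line
    return best


def compute_bmdl(fit: ContinuousFit, bmr_sd: float = 1.349,
                 confidence: float = 0.95) -> float:
    """One-sided profile-likelihood lower confidence limit on the BMD.

    The BMDL is the smallest b with constrained maximum log-likelihood within
    chi2_1(2*confidence - 1)/2 of the unconstrained maximum, located by
    bisection on (0, BMD].
    """
    bmd = compute_bmd(fit, bmr_sd)
    if not np.isfinite(bmd):
        return float("nan")
    offset = stats.chi2.ppf(2 * confidence - 1, 1) / 2.0
    target = fit.loglik - offset
    lo, hi = bmd / 50.0, bmd
    for _ in range(12):
        if _profile_loglik(fit, lo, bmr_sd) < target:
            break
        lo /= 8.0
        if lo < bmd * 1e-9:
            return float(lo)  # profile flat to numerical zero
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _profile_loglik(fit, mid, bmr_sd) >= target:
            hi = mid
        else:
            lo = mid
        if (hi - lo) < 1e-4 * bmd:
            break
    return float(hi)


# ---------------------------------------------------------------------------
# per-gene pipeline

def fit_all_models(doses, values, max_iterations: int = 250
                   ) -> dict[str, ContinuousFit]:
    gs = GroupStats.from_arrays(doses, values)
    return _fit_all_from_stats(gs, max_iterations)


def _fit_all_from_stats(gs: GroupStats, max_iterations: int
                        ) -> dict[str, ContinuousFit]:
    fits: dict[str, ContinuousFit] = {}
    for model in MODEL_ORDER:
        try:
            f = _fit_from_stats(gs, model, max_iterations)
            f.gof_p = goodness_of_fit(f)
            fits[model] = f
        except TxpodError as exc:
            logger.debug("model %s skipped: %s", model, exc)
    return fits


def run_gene_bmd(
    dset: DoseResponseSet,
    genes: list[str],
    cfg: RunConfig | None = None,
    with_bmdl: bool = True,
    hill_flag_literal_halving: bool = False,
) -> list[BmdResult]:
    """Fit-all / select / BMD / BMDL for every gene in ``genes``.

    Genes whose BMD exceeds the top dose are marked ``excluded_above_top``
    and should not feed pathway aggregation.  BMDL profiling is optional
    (``with_bmdl=False``) for bulk runs that only need BMD point estimates.
    """
    if not genes:
        raise TxpodError("empty gene list")
    cfg = cfg or RunConfig()
    log2 = dset.log2_values()
    dose_vec = dset.dose_vector
    top = float(max(dose_vec))
    lowpos = float(min(d for d in dset.doses if d > 0))
    results: list[BmdResult] = []
    for gene in genes:
        y = log2.loc[gene].to_numpy(dtype=float)
        gs = GroupStats.from_arrays(dose_vec, y)
        fits = _fit_all_from_stats(gs, cfg.max_iterations)
        winner, info = select_best_model(
            fits, gof_threshold=0.1, lowest_positive_dose=lowpos,
            hill_flag_literal_halving=hill_flag_literal_halving)
        if winner is None:
            results.append(BmdResult(gene=gene, model_name=None,
                                     bmd=float("nan"), bmdl=float("nan"),
                                     reason=info["reason"]))
            continue
        if info["flag_action"] == "halved_substitute":
            bmd = (0.5 * compute_bmd(winner, cfg.bmr_sd)
                   if info.get("halved_reference") == "own_bmd"
                   else 0.5 * lowpos)
        else:
            bmd = compute_bmd(winner, cfg.bmr_sd)
        if not np.isfinite(bmd):
            results.append(BmdResult(
                gene=gene, model_name=winner.model_name, bmd=float("nan"),
                bmdl=float("nan"), hill_flagged=info["hill_flagged"],
                flag_action=info["flag_action"], gof_p=winner.gof_p,
                aic=winner.aic, sigma_hat=winner.sigma_hat,
                reason="benchmark response unreachable"))
            continue
        excluded = bmd > top
        bmdl = float("nan")
        if with_bmdl and not excluded and info["flag_action"] != "halved_substitute":
            bmdl = compute_bmdl(winner, cfg.bmr_sd, cfg.confidence)
        results.append(BmdResult(
            gene=gene, model_name=winner.model_name, bmd=float(bmd),
            bmdl=bmdl, hill_flagged=info["hill_flagged"],
            flag_action=info["flag_action"], excluded_above_top=bool(excluded),
            gof_p=winner.gof_p, aic=winner.aic, sigma_hat=winner.sigma_hat))
    n_mod = sum(r.model_name is not None and np.isfinite(r.bmd)
                and not r.excluded_above_top for r in results)
    n_exc = sum(r.excluded_above_top for r in results)
    logger.info("continuous BMD: %d modeled, %d excluded above top dose, "
                "%d unmodeled", n_mod, n_exc, len(results) - n_mod - n_exc)
    return results
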