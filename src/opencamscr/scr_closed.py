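"""Maximum-likelihood closed-population SCR with sex-mixture models.

The observation model is a proximity detector with Bernoulli daily
detections: the per-day probability at distance ``d`` from an activity
centre is the half-normal ``g0 * exp(-d^2 / (2 sigma^2))``, and a
``u``-active-day occasion compounds to ``1 - (1 - p_day)^u``.  Density is
a homogeneous Poisson intensity ``D`` over the habitat mask and the fit
maximises the full (unconditional) likelihood with Poisson-distributed
number of detected individuals.  A partially observed sex covariate is
handled as a hybrid finite mixture whose mixing proportion ``pmix`` is
the sex ratio (probability female).  Competing model structures (null,
sex on sigma, sex on both detection parameters) are compared by AICc and
combined by Akaike-weight model averaging of density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp

from opencamscr.capture_data import ClosedSessionHistory
from opencamscr.statespace import StateSpaceMask

MODEL_IDS = ("M0", "sex_on_sigma", "sex_on_g0_sigma")


@dataclass
class ClosedModelSpec:
    """Closed-model structure: which detection parameters carry sex."""

    model_id: str = "M0"
    occasion_length: int = 5

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")

    @property
    def n_classes(self) -> int:
        return 1 if self.model_id == "M0" else 2

    @property
    def K(self) -> int:
        """Parameter count, including density and (for mixtures) pmix."""
        return {"M0": 3, "sex_on_sigma": 5, "sex_on_g0_sigma": 6}[self.model_id]


@dataclass
class ClosedFitResult:
    model_id: str
    estimates: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    loglik: float
    K: int
    n: int
    aicc_value: float
    converged: bool
    spatial_recaptures: int
    warnings: list[str] = field(default_factory=list)

    @property
    def density_per_100km2(self) -> float:
        return self.estimates["D"] * 100.0

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.estimates:
            lo, hi = self.ci[name]
            rows.append(
                {"parameter": name, "estimate": self.estimates[name],
                 "se": self.se[name], "lcl": lo, "ucl": hi}
            )
        return pd.DataFrame(rows)


def halfnormal_p(d, g0: float, sigma: float):
    """Half-normal detection probability ``g0 * exp(-d^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = g0 * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return float(out) if out.ndim == 0 else out


def _suff_stats(history: ClosedSessionHistory):
    """Group occasions by usage level u: counts C[j,u] and detections M[u][i,j]."""
    y, usage = history.y, history.usage
    levels = sorted(set(np.unique(usage)) - {0})
    C = {u: (usage == u).sum(axis=1) for u in levels}              # (J,)
    M = {u: (y * (usage == u)[None]).sum(axis=2) for u in levels}  # (n, J)
    return levels, C, M


def _class_weights(sexes: np.ndarray, pmix: float | None, n_classes: int) -> np.ndarray:
    """(n, n_classes) log membership weights; known sexes are degenerate."""
    n = sexes.shape[0]
    if n_classes == 1:
        return np.zeros((n, 1))
    with np.errstate(divide="ignore"):
        logw = np.log(np.array([pmix, 1.0 - pmix]))
    out = np.tile(logw, (n, 1))
    out[sexes == 0, 1] = -np.inf  # known female
    out[sexes == 1, 0] = -np.inf  # known male
    out[sexes == 0, 0] = logw[0]
    out[sexes == 1, 1] = logw[1]
    return out


def closed_loglik(
    history: ClosedSessionHistory,
    mask: StateSpaceMask,
    spec: ClosedModelSpec,
    params: dict,
) -> float:
    """Full closed-SCR log-likelihood over the habitat mask.

    ``params`` holds ``D`` (individuals per km^2), per-class ``g0`` and
    ``sigma`` (m) tuples, and ``pmix`` for mixture specs.  The likelihood
    is ``sum_i log(D a sum_c w_ic sum_x P_i(x, c)) - Lambda - log n!``
    with ``Lambda = D a sum_x sum_c w_c pdot_c(x)``, where ``a`` is the
    cell area, ``P_i`` the Bernoulli product of the individual's history
    and ``pdot`` the probability of at least one detection.  Individuals
    with no detections must be removed beforehand.
    """
    detected = history.detected_mask()
    if not detected.all():
        raise ValueError("history contains undetected individuals; drop them first")
    n = history.n_individuals
    if n == 0:
        raise ValueError("no detections to condition on")
    D = float(params["D"])
    ncls = spec.n_classes
    g0s = np.atleast_1d(np.asarray(params["g0"], dtype=float))
    sigs = np.atleast_1d(np.asarray(params["sigma"], dtype=float))
    if g0s.size == 1:
        g0s = np.repeat(g0s, ncls)
    if sigs.size == 1:
        sigs = np.repeat(sigs, ncls)
    pmix = params.get("pmix")
    if ncls == 2 and pmix is None:
        raise ValueError("mixture spec requires pmix")

    cells = mask.cell_centres
    a = mask.cell_area
    d2 = ((cells[:, None, :] - history.site_coords[None, :, :]) ** 2).sum(axis=2)
    levels, C, M = _suff_stats(history)

    logP = np.full((n, cells.shape[0], ncls), 0.0)      # log P_i(x, c)
    log1mpdot = np.zeros((cells.shape[0], ncls))
    for c in range(ncls):
        pday = g0s[c] * np.exp(-d2 / (2.0 * sigs[c] ** 2))  # (ncells, J)
        for u in levels:
            p_u = 1.0 - (1.0 - pday) ** u
            logp = np.log(np.clip(p_u, 1e-300, None))
            log1m = np.log1p(-np.clip(p_u, None, 1 - 1e-15))
            logP[:, :, c] += M[u] @ logp.T + (C[u][None, :] - M[u]) @ log1m.T
            log1mpdot[:, c] += log1m @ C[u]

    # marginal class weights for Lambda
    if ncls == 1:
        w_marg = np.array([1.0])
    else:
        w_marg = np.array([pmix, 1.0 - pmix])
    pdot = 1.0 - np.exp(log1mpdot)
    Lambda = D * a * float(np.sum(pdot @ w_marg))

    logw = _class_weights(history.sexes, pmix, ncls)     # (n, ncls)
    # log sum_x sum_c exp(logw_ic + logP_i(x,c))
    per_ind = logsumexp(
        logP + logw[:, None, :], axis=(1, 2)
    )
    if not np.all(np.isfinite(per_ind)):
        return -np.inf
    ll = float(np.sum(np.log(D) + np.log(a) + per_ind) - Lambda - gammaln(n + 1))
    return ll


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample AIC: ``-2 loglik + 2K + 2K(K+1)/(n-K-1)``."""
    if K > 0 and n <= K + 1:
        raise ValueError("AICc undefined for n <= K + 1")
    out = -2.0 * loglik + 2.0 * K
    if K > 0:
        out += 2.0 * K * (K + 1) / (n - K - 1)
    return out


# ---------------------------------------------------------------------- #
# fitting
# ---------------------------------------------------------------------- #

def _pack(spec: ClosedModelSpec, params: dict) -> np.ndarray:
    t = [math.log(params["D"])]
    if spec.model_id == "M0":
        t += [logit(params["g0"][0]), math.log(params["sigma"][0])]
    elif spec.model_id == "sex_on_sigma":
        t += [logit(params["g0"][0]),
              math.log(params["sigma"][0]), math.log(params["sigma"][1]),
              logit(params["pmix"])]
    else:
        t += [logit(params["g0"][0]), logit(params["g0"][1]),
              math.log(params["sigma"][0]), math.log(params["sigma"][1]),
              logit(params["pmix"])]
    return np.array(t, dtype=float)


def _unpack(spec: ClosedModelSpec, theta: np.ndarray) -> dict:
    D = math.exp(theta[0])
    if spec.model_id == "M0":
        return {"D": D, "g0": (expit(theta[1]),), "sigma": (math.exp(theta[2]),),
                "pmix": None}
    if spec.model_id == "sex_on_sigma":
        g0 = expit(theta[1])
        return {"D": D, "g0": (g0, g0),
                "sigma": (math.exp(theta[2]), math.exp(theta[3])),
                "pmix": expit(theta[4])}
    return {"D": D, "g0": (expit(theta[1]), expit(theta[2])),
            "sigma": (math.exp(theta[3]), math.exp(theta[4])),
            "pmix": expit(theta[5])}


def _numerical_hessian(fun, theta, h=1e-4):
    p = theta.size
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            hi = h * max(1.0, abs(theta[i]))
            hj = h * max(1.0, abs(theta[j]))
            if i == j:
                f0 = fun(theta)
                tp, tm = theta.copy(), theta.copy()
                tp[i] += hi
                tm[i] -= hi
                H[i, i] = (fun(tp) - 2 * f0 + fun(tm)) / hi ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [hi, hj]
                tpm[i] += hi
                tpm[j] -= hj
                tmp[i] -= hi
                tmp[j] += hj
                tmm[[i, j]] -= [hi, hj]
                H[i, j] = H[j, i] = (fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)) / (
                    4 * hi * hj
                )
    return H


def count_spatial_recaptures(history: ClosedSessionHistory) -> int:
    """Individuals detected at more than one distinct site."""
    sites_per_ind = (history.y.sum(axis=2) > 0).sum(axis=1)
    return int((sites_per_ind > 1).sum())


def _start_values(history: ClosedSessionHistory, mask: StateSpaceMask,
                  spec: ClosedModelSpec) -> dict:
    # sigma from RMS dispersion of each individual's detection sites
    disp = []
    for i in range(history.n_individuals):
        det_sites = np.flatnonzero(history.y[i].sum(axis=1) > 0)
        if det_sites.size > 1:
            xy = history.site_coords[det_sites]
            disp.append(np.sqrt(((xy - xy.mean(axis=0)) ** 2).sum(axis=1).mean()))
    sigma0 = float(np.mean(disp)) if disp else float(mask.spacing * 3)
    sigma0 = max(sigma0, mask.spacing)
    D0 = 2.0 * history.n_individuals / mask.total_area
    pm0 = 0.5
    return {"D": D0, "g0": (0.02, 0.02), "sigma": (sigma0, sigma0), "pmix": pm0}


def fit_closed(
    history: ClosedSessionHistory,
    mask: StateSpaceMask,
    spec: ClosedModelSpec | None = None,
) -> ClosedFitResult:
    """Maximise the closed-SCR likelihood; Wald intervals on link scales.

    Estimation is on transformed parameters (log D, logit g0, log sigma,
    logit pmix) by quasi-Newton search; standard errors come from the
    inverse numerical Hessian with delta-method back-transformation, and
    95% CIs are Wald intervals on the link scale, back-transformed.
    Non-convergence and absence of spatial recaptures (sigma then
    unidentifiable) are flagged, never silently ignored.
    """
    spec = spec or ClosedModelSpec()
    keep = history.detected_mask()
    if keep.sum() < 2:
        raise ValueError("need >= 2 detected individuals")
    hist = ClosedSessionHistory(
        y=history.y[keep], usage=history.usage, site_coords=history.site_coords,
        sexes=history.sexes[keep], days_per_occasion=history.days_per_occasion,
        individual_ids=[x for x, m in zip(history.individual_ids, keep) if m],
    )
    warnings_list: list[str] = []
    n_recap = count_spatial_recaptures(hist)
    if n_recap == 0:
        warnings_list.append("no spatial recaptures: sigma unidentifiable")

    def nll(theta):
        try:
            ll = closed_loglik(hist, mask, spec, _unpack(spec, theta))
        except (ValueError, FloatingPointError):
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    theta0 = _pack(spec, _start_values(hist, mask, spec))
    res = minimize(nll, theta0, method="L-BFGS-B")
    res2 = minimize(nll, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 1000})
    best = res2 if res2.fun <= res.fun else res
    theta = np.asarray(best.x, dtype=float)
    converged = bool(best.success) and best.fun < 1e9 and n_recap > 0

    H = _numerical_hessian(nll, theta)
    se_t = np.full(theta.size, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se_t = np.sqrt(d)
        else:
            converged = False
            warnings_list.append("non-positive-definite Hessian")
    except np.linalg.LinAlgError:
        converged = False
        warnings_list.append("singular Hessian")

    params = _unpack(spec, theta)
    names, values, links = _named_params(spec, theta)
    est, se, ci = {}, {}, {}
    z = 1.959963984540054
    for idx, (name, link) in enumerate(zip(names, links)):
        t, s = theta[idx], se_t[idx]
        lo_t, hi_t = t - z * s, t + z * s
        if link == "log":
            est[name] = math.exp(t)
            se[name] = est[name] * s
            ci[name] = (math.exp(lo_t), math.exp(hi_t))
        else:  # logit
            est[name] = float(expit(t))
            se[name] = float(expit(t) * (1 - expit(t)) * s)
            ci[name] = (float(expit(lo_t)), float(expit(hi_t)))

    ll = -best.fun
    n = hist.n_individuals
    if n > spec.K + 1:
        aicc_value = aicc(ll, spec.K, n)
    else:
        aicc_value = float("nan")
        warnings_list.append("AICc undefined (n <= K + 1)")
    return ClosedFitResult(
        model_id=spec.model_id, estimates=est, se=se, ci=ci, loglik=ll,
        K=spec.K, n=n, aicc_value=aicc_value, converged=converged,
        spatial_recaptures=n_recap, warnings=warnings_list,
    )


def _named_params(spec, theta):
    if spec.model_id == "M0":
        return ["D", "g0", "sigma"], theta, ["log", "logit", "log"]
    if spec.model_id == "sex_on_sigma":
        return (["D", "g0", "sigma_F", "sigma_M", "pmix"], theta,
                ["log", "logit", "log", "log", "logit"])
    return (["D", "g0_F", "g0_M", "sigma_F", "sigma_M", "pmix"], theta,
            ["log", "logit", "logit", "log", "log", "logit"])


# ---------------------------------------------------------------------- #
# model selection / averaging
# ---------------------------------------------------------------------- #

def selection_table(fits: list[ClosedFitResult]) -> pd.DataFrame:
    """AICc ranking with Akaike weights across all supplied fits."""
    df = pd.DataFrame(
        {
            "model": [f.model_id for f in fits],
            "K": [f.K for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": [f.aicc_value for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    w = np.exp(-0.5 * df["dAICc"])
    df["weight"] = w / w.sum()
    return df.sort_values("AICc", kind="stable").reset_index(drop=True)


@dataclass
class ModelAverageResult:
    density_per_100km2: float
    se_per_100km2: float
    table: pd.DataFrame
    retained: list[str]


def model_average(fits: list[ClosedFitResult]) -> ModelAverageResult:
    """Akaike-weight model averaging of density over models with dAICc < 2.

    Weights are renormalised over the retained set; the unconditional
    standard error combines within-model variance and between-model
    spread (Buckland et al. formula).
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to average")
    aiccs = np.array([f.aicc_value for f in ok])
    delta = aiccs - aiccs.min()
    kept = [f for f, d in zip(ok, delta) if d < 2.0]
    dk = np.array([f.aicc_value for f in kept]) - aiccs.min()
    w = np.exp(-0.5 * dk)
    w = w / w.sum()
    D = np.array([f.density_per_100km2 for f in kept])
    se = np.array([f.se["D"] * 100.0 for f in kept])
    D_bar = float(w @ D)
    se_bar = float(w @ np.sqrt(se ** 2 + (D - D_bar) ** 2))
    return ModelAverageResult(
        density_per_100km2=D_bar, se_per_100km2=se_bar,
        table=selection_table(ok), retained=[f.model_id for f in kept],
    )
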