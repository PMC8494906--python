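"""Bayesian open-population SCR via data augmentation.

The observed individuals are embedded in a super-population of size M
with latent inclusion indicators; each individual carries a latent sex,
a contiguous alive run across primary periods (single entry, single
exit — no revival), and a per-period activity centre following a
Markovian bivariate-normal relocation kernel over the habitat mask.
Detection is daily Bernoulli with a sex-specific half-normal function of
the distance to the current activity centre, masked by site-day effort.
Survival and per-capita recruitment are sex-specific and yearly;
abundance, density, realised growth rate and sex ratio are derived per
posterior draw.  Point estimates are posterior modes, intervals 95%
highest-posterior-density intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from opencamscr._open_kernel import run_chain
from opencamscr.capture_data import RobustDesignHistory
from opencamscr.statespace import StateSpaceMask

PARAM_NAMES = (
    "g0_F", "g0_M", "sigma_F", "sigma_M", "phi_F", "phi_M",
    "gamma_F", "gamma_M", "psi", "sigma_move", "psi1",
)

DEFAULT_PRIORS = {
    "g0_F": (0.0, 1.0), "g0_M": (0.0, 1.0),
    "sigma_F": (0.0, 20_000.0), "sigma_M": (0.0, 20_000.0),
    "phi_F": (0.0, 1.0), "phi_M": (0.0, 1.0),
    "gamma_F": (0.0, 1.0), "gamma_M": (0.0, 1.0),
    "psi": (0.0, 1.0), "sigma_move": (0.0, 30_000.0), "psi1": (0.0, 1.0),
}


@dataclass
class OpenModelConfig:
    """Sampler configuration.

    ``M`` is the augmented population size (must exceed the number of
    detected individuals; the survey-scale default is 400).  The default
    run is a desk-scale 3 chains x 20,000 iterations (burn-in 5,000,
    thin 5); :meth:`survey_preset` gives the 10 x 100,000 configuration
    used at full scale.  ``fixed`` pins named parameters at a value
    (their updates are skipped).
    """

    M: int = 400
    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    movement_type: str = "markov"
    seed: int = 0
    fixed: dict = field(default_factory=dict)
    allow_empty: bool = False

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.movement_type not in ("markov", "independent"):
            raise ValueError("movement_type must be 'markov' or 'independent'")
        for name in self.fixed:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r} in fixed")

    @classmethod
    def survey_preset(cls, **kwargs) -> "OpenModelConfig":
        """Full-scale preset: 10 chains of 100,000 iterations, M = 400."""
        defaults = dict(M=400, n_chains=10, n_iter=100_000, burn_in=20_000, thin=20)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class OpenPosterior:
    """Per-chain posterior draws and latent-state summaries."""

    params: dict[str, np.ndarray]   # name -> (chains, draws)
    N: np.ndarray                   # (chains, draws, L) total abundance
    N_female: np.ndarray            # (chains, draws, L)
    alive_mean: np.ndarray          # (M, L) posterior inclusion frequency
    sex_female_mean: np.ndarray     # (M,) posterior P(female)
    config: OpenModelConfig
    n_detected: int

    @property
    def n_primary(self) -> int:
        return self.N.shape[2]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].ravel()

    @property
    def N_male(self) -> np.ndarray:
        return self.N - self.N_female

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw (chains stacked), for CSV export."""
        cols = {"chain": np.repeat(np.arange(self.N.shape[0]), self.N.shape[1])}
        for name, d in self.params.items():
            cols[name] = d.ravel()
        for l in range(self.n_primary):
            cols[f"N[{l + 1}]"] = self.N[:, :, l].ravel()
            cols[f"N_F[{l + 1}]"] = self.N_female[:, :, l].ravel()
        return pd.DataFrame(cols)


@dataclass
class DerivedEstimates:
    """Posterior-mode + HPD summaries of derived demographic quantities."""

    abundance: pd.DataFrame     # period, group, mode, hpd_low, hpd_high
    density: pd.DataFrame       # per 100 km^2
    growth: pd.DataFrame        # lambda_t = N_{t+1} / N_t
    sex_ratio: pd.DataFrame     # P(female)
    area_km2: float


# ---------------------------------------------------------------------- #
# summaries
# ---------------------------------------------------------------------- #

def posterior_mode(samples: np.ndarray) -> float:
    """Histogram mode with Freedman-Diaconis bins; integer mode for counts.

    Falls back to the median (with a warning) below 100 draws.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        warnings.warn("fewer than 100 draws: falling back to median", stacklevel=2)
        return float(np.median(x))
    if np.all(x == x[0]):
        return float(x[0])
    if np.all(x == np.round(x)):
        vals, counts = np.unique(x.astype(np.int64), return_counts=True)
        return float(vals[np.argmax(counts)])
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    if width <= 0:
        return float(np.median(x))
    n_bins = max(1, int(np.ceil((x.max() - x.min()) / width)))
    counts, edges = np.histogram(x, bins=n_bins)
    b = int(np.argmax(counts))
    return float(0.5 * (edges[b] + edges[b + 1]))


def hpd_interval(samples: np.ndarray, mass: float = 0.95,
                 method: str = "hpd") -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` sorted draws.

    ``method='quantile'`` returns the equal-tailed interval at the
    (1-mass)/2 and (1+mass)/2 quantiles instead.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if method == "quantile":
        lo = (1.0 - mass) / 2.0
        return (float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo)))
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


# ---------------------------------------------------------------------- #
# initialisation and sampling
# ---------------------------------------------------------------------- #

def _site_period_stats(history: RobustDesignHistory):
    ndet = history.y.sum(axis=2).astype(np.float64)        # (n, J, L)
    U = history.usage.sum(axis=1).astype(np.float64)       # (J, L)
    return ndet, U


def init_state(
    history: RobustDesignHistory,
    mask: StateSpaceMask,
    config: OpenModelConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """Initial MCMC state for one chain.

    Detected individuals' alive runs span first-to-last detection period;
    activity centres start at the mean detection location (or uniform for
    augmented rows); latent sexes are drawn from the observed sex
    frequencies; scalar parameters are drawn overdispersed within their
    priors.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = history.n_individuals
    if n == 0 and not config.allow_empty:
        raise ValueError("empty history: nothing to fit (set allow_empty to override)")
    if config.M < n:
        raise ValueError(f"M={config.M} is below the {n} detected individuals")
    M, L = config.M, history.n_primary
    ndet, _ = _site_period_stats(history)
    per_period = ndet.sum(axis=1)                          # (n, L)

    first = np.full(M, -1, dtype=np.int64)
    last = np.full(M, -1, dtype=np.int64)
    zf = np.full(M, -1, dtype=np.int64)
    zl = np.full(M, -1, dtype=np.int64)
    sexobs = np.full(M, -1, dtype=np.int8)
    for i in range(n):
        det_l = np.flatnonzero(per_period[i] > 0)
        first[i], last[i] = det_l[0], det_l[-1]
        zf[i], zl[i] = det_l[0], det_l[-1]
        sexobs[i] = history.sexes[i]

    n_F = int((history.sexes == 0).sum())
    n_M = int((history.sexes == 1).sum())
    p_F = (n_F + 1.0) / (n_F + n_M + 2.0)
    sex0 = np.where(sexobs >= 0, sexobs, (rng.random(M) > p_F).astype(np.int8))
    sex0 = sex0.astype(np.int8)

    xmin, xmax, ymin, ymax = mask.bounds
    ac0 = np.column_stack(
        [rng.uniform(xmin, xmax, M * L), rng.uniform(ymin, ymax, M * L)]
    ).reshape(M, L, 2)
    for i in range(n):
        w = ndet[i].sum(axis=1)
        if w.sum() > 0:
            centre = (history.site_coords * w[:, None]).sum(axis=0) / w.sum()
            ac0[i, :, :] = centre
        for l in range(L):
            if ndet[i, :, l].sum() > 0:
                wl = ndet[i, :, l]
                ac0[i, l] = (history.site_coords * wl[:, None]).sum(axis=0) / wl.sum()

    pars0 = np.empty(11)
    pars0[0] = np.exp(rng.uniform(np.log(0.003), np.log(0.08)))
    pars0[1] = np.exp(rng.uniform(np.log(0.003), np.log(0.08)))
    pars0[2] = rng.uniform(2_000.0, 8_000.0)
    pars0[3] = rng.uniform(2_000.0, 8_000.0)
    pars0[4] = rng.uniform(0.5, 0.95)
    pars0[5] = rng.uniform(0.5, 0.95)
    pars0[6] = rng.uniform(0.02, 0.3)
    pars0[7] = rng.uniform(0.02, 0.3)
    pars0[8] = rng.uniform(0.3, 0.7)
    pars0[9] = rng.uniform(2_000.0, 8_000.0)
    pars0[10] = rng.uniform(0.1, 0.5)
    for name, value in config.fixed.items():
        pars0[PARAM_NAMES.index(name)] = value

    return {
        "pars0": pars0, "zf0": zf, "zl0": zl, "sex0": sex0, "ac0": ac0,
        "first": first, "last": last, "sexobs": sexobs,
    }


def run_mcmc(
    history: RobustDesignHistory,
    mask: StateSpaceMask,
    config: OpenModelConfig,
) -> OpenPosterior:
    """Run the Metropolis-within-Gibbs sampler; chains are independent
    given distinct sub-seeds derived from ``config.seed``."""
    n = history.n_individuals
    ndet_obs, U = _site_period_stats(history)
    M, L = config.M, history.n_primary
    ndet = np.zeros((M, ndet_obs.shape[1], L))
    ndet[:n] = ndet_obs

    lo = np.array([config.priors[p][0] for p in PARAM_NAMES])
    hi = np.array([config.priors[p][1] for p in PARAM_NAMES])
    fixed = np.zeros(11, dtype=np.uint8)
    for name in config.fixed:
        fixed[PARAM_NAMES.index(name)] = 1
    markov = 1 if (config.movement_type == "markov" and L > 1) else 0
    bounds = np.array(mask.bounds, dtype=float)
    sites = np.asarray(history.site_coords, dtype=float)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(config.n_chains)]

    all_draws, alive_sums, sexF_sums = [], [], []
    for c, cs in enumerate(chain_seeds):
        state = init_state(history, mask, config, rng=np.random.default_rng(cs))
        draws, alive_mean, sexF_mean, _ = run_chain(
            cs, config.n_iter, config.burn_in, config.thin,
            ndet, U, sites, bounds,
            state["sexobs"], state["first"], state["last"],
            lo, hi, fixed,
            state["pars0"], state["zf0"], state["zl0"], state["sex0"], state["ac0"],
            markov,
        )
        if not np.all(np.isfinite(draws)):
            raise FloatingPointError(f"non-finite draws in chain {c}")
        all_draws.append(draws)
        alive_sums.append(alive_mean)
        sexF_sums.append(sexF_mean)

    stacked = np.stack(all_draws)                      # (chains, draws, 11+2L)
    params = {name: stacked[:, :, p] for p, name in enumerate(PARAM_NAMES)}
    N = stacked[:, :, 11: 11 + L]
    NF = stacked[:, :, 11 + L: 11 + 2 * L]
    return OpenPosterior(
        params=params, N=N, N_female=NF,
        alive_mean=np.mean(alive_sums, axis=0),
        sex_female_mean=np.mean(sexF_sums, axis=0),
        config=config, n_detected=n,
    )


# ---------------------------------------------------------------------- #
# derived quantities
# ---------------------------------------------------------------------- #

def _summarize(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float, float]:
    mode = posterior_mode(draws.ravel())
    lo, hi = hpd_interval(draws.ravel(), mass)
    return mode, lo, hi


def derive_estimates(posterior: OpenPosterior, mask: StateSpaceMask) -> DerivedEstimates:
    """Density, growth rate and sex ratio as per-draw derived parameters.

    Per draw: ``D_t = N_t / area * 100`` (individuals per 100 km^2),
    ``lambda_t = N_{t+1} / N_t`` (flagged NaN when ``N_t = 0``) and
    ``sex_ratio_t = N_{F,t} / N_t`` (the probability that an individual
    is female); each series is summarised by posterior mode and 95% HPD.
    """
    area = mask.total_area
    if area <= 0:
        raise ValueError("state-space mask has zero area")
    L = posterior.n_primary
    groups = {"combined": posterior.N, "female": posterior.N_female,
              "male": posterior.N_male}

    ab_rows, d_rows, g_rows, r_rows = [], [], [], []
    for gname, Ng in groups.items():
        for l in range(L):
            mode, lo, hi = _summarize(Ng[:, :, l])
            ab_rows.append({"period": l + 1, "group": gname, "mode": mode,
                            "hpd_low": lo, "hpd_high": hi})
            mode, lo, hi = _summarize(Ng[:, :, l] / area * 100.0)
            d_rows.append({"period": l + 1, "group": gname, "mode": mode,
                           "hpd_low": lo, "hpd_high": hi})
        for l in range(L - 1):
            num, den = Ng[:, :, l + 1], Ng[:, :, l]
            with np.errstate(divide="ignore", invalid="ignore"):
                lam = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
            ok = np.isfinite(lam)
            if ok.sum() == 0:
                mode = lo = hi = np.nan
            else:
                mode, lo, hi = _summarize(lam[ok])
            g_rows.append({"period": l + 1, "group": gname, "mode": mode,
                           "hpd_low": lo, "hpd_high": hi,
                           "undefined_fraction": float(1.0 - ok.mean())})
    for l in range(L):
        den = posterior.N[:, :, l]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, posterior.N_female[:, :, l]
                             / np.where(den > 0, den, 1), np.nan)
        ok = np.isfinite(ratio)
        mode, lo, hi = _summarize(ratio[ok]) if ok.sum() else (np.nan,) * 3
        r_rows.append({"period": l + 1, "mode": mode, "hpd_low": lo, "hpd_high": hi})

    return DerivedEstimates(
        abundance=pd.DataFrame(ab_rows), density=pd.DataFrame(d_rows),
        growth=pd.DataFrame(g_rows), sex_ratio=pd.DataFrame(r_rows),
        area_km2=area,
    )


def parameter_summary(posterior: OpenPosterior, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mode and HPD per scalar parameter (pooled chains)."""
    rows = []
    for name in PARAM_NAMES:
        d = posterior.pooled(name)
        mode, lo, hi = _summarize(d, mass)
        rows.append({"parameter": name, "mode": mode, "hpd_low": lo, "hpd_high": hi})
    return pd.DataFrame(rows)
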