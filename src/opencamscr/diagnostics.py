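"""Gelman-Rubin convergence assessment for the open-model MCMC.

Implements the classic potential scale reduction factor (PSRF) with the
degrees-of-freedom adjustment and the 97.5% sampling-distribution upper
confidence limit, matching the construction used by the standard R
implementation (coda's ``gelman.diag``).  The pass rule is a 95% upper
limit below 1.1 for every reported parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

DEFAULT_THRESHOLD = 1.1


@dataclass
class ConvergenceReport:
    table: pd.DataFrame     # parameter, psrf, upper_limit, pass
    threshold: float
    passed: bool
    notes: list[str]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def gelman_rubin(chains: np.ndarray) -> tuple[float, float]:
    """PSRF point estimate and 97.5% upper limit from parallel chains.

    ``chains`` is (m, n): m >= 2 chains of n >= 100 post-burn-in draws.
    Returns ``(psrf, upper)``; a parameter constant across all draws is
    reported as exactly converged (1.0, 1.0).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError(
            "need >= 2 chains of equal length; for a single chain split it "
            "into halves first"
        )
    m, n = chains.shape
    if n < 100:
        raise ValueError("need >= 100 draws per chain")

    S2 = chains.var(axis=1, ddof=1)          # within-chain variances
    xbar = chains.mean(axis=1)
    W = S2.mean()
    B = n * xbar.var(ddof=1)
    if W <= 0:
        if B <= 0:
            return 1.0, 1.0                  # constant everywhere
        return np.inf, np.inf
    muhat = xbar.mean()
    var_w = S2.var(ddof=1) / m
    var_b = 2.0 * B ** 2 / (m - 1)
    cov_s2_x2 = np.cov(S2, xbar ** 2, ddof=1)[0, 1]
    cov_s2_x = np.cov(S2, xbar, ddof=1)[0, 1]
    cov_wb = (n / m) * (cov_s2_x2 - 2.0 * muhat * cov_s2_x)

    V = (n - 1) * W / n + (1.0 + 1.0 / m) * B / n
    var_V = (
        ((n - 1) ** 2) * var_w
        + ((1.0 + 1.0 / m) ** 2) * var_b
        + 2.0 * (n - 1) * (1.0 + 1.0 / m) * cov_wb
    ) / n ** 2
    if var_V <= 0:
        df_adj = 1.0
    else:
        df_V = 2.0 * V ** 2 / var_V
        df_adj = (df_V + 3.0) / (df_V + 1.0)

    B_df = m - 1
    W_df = 2.0 * W ** 2 / (var_w if var_w > 0 else np.inf)
    R2_fixed = (n - 1.0) / n
    R2_random = (1.0 + 1.0 / m) * B / (n * W)
    psrf = float(np.sqrt(df_adj * (R2_fixed + R2_random)))
    if np.isfinite(W_df) and W_df > 0:
        q = f_dist.ppf(0.975, B_df, W_df)
    else:
        q = 1.0
    upper = float(np.sqrt(df_adj * (R2_fixed + q * R2_random)))
    return psrf, upper


def convergence_report(posterior, threshold: float = DEFAULT_THRESHOLD) -> ConvergenceReport:
    """PSRF table for the open-model scalar parameters and abundance series.

    Latent per-individual indicators are excluded (only scalars and the
    derived N_t series are assessed).  The overall flag passes iff every
    upper limit is below ``threshold``.
    """
    names: list[str] = []
    series: list[np.ndarray] = []
    for name, draws in posterior.params.items():
        names.append(name)
        series.append(draws)
    L = posterior.N.shape[2]
    for l in range(L):
        names.append(f"N[{l + 1}]")
        series.append(posterior.N[:, :, l])

    rows, notes = [], []
    for name, draws in zip(names, series):
        if np.allclose(draws, draws.ravel()[0]):
            psrf, upper = 1.0, 1.0
            notes.append(f"{name}: zero variance across draws")
        else:
            psrf, upper = gelman_rubin(draws)
        rows.append(
            {"parameter": name, "psrf": psrf, "upper_limit": upper,
             "pass": upper < threshold}
        )
    table = pd.DataFrame(rows)
    return ConvergenceReport(
        table=table, threshold=threshold, passed=bool(table["pass"].all()),
        notes=notes,
    )
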