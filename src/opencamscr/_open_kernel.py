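"""Numba kernel for the data-augmented open-population SCR sampler.

One chain of Metropolis-within-Gibbs over:

* detection scalars (g0, sigma per sex) — random-walk Metropolis on
  logit/log scales with Jacobian correction under bounded-uniform priors;
* survival phi per sex and the inclusion probabilities (psi for sex,
  psi1 for initial-period entry) — conjugate Beta Gibbs draws;
* per-capita recruitment gamma per sex — exact grid draws from the 1-D
  conditional, refreshed both between and inside alive-state sweeps so
  entrant counts and rates equilibrate jointly;
* the movement scale — random-walk Metropolis on the log scale against
  a partially collapsed conditional (prior-resampled path segments are
  integrated out);
* per-individual alive-state sequences — exact categorical draws over the
  enumerable set of contiguous runs (entry, exit) consistent with the
  individual's detections, so the no-revival constraint holds at every
  iteration; entry probabilities over the never-yet-alive pool are
  calibrated so the expected number of entrants of sex s at t+1 equals
  gamma_s * N_t;
* latent sexes of unsexed individuals — conditional Bernoulli combining
  psi with the sex-specific observation and demographic terms;
* activity centres per individual-period — random-walk Metropolis under
  a rectangle-truncated bivariate-normal Markov kernel (exact erf-product
  normaliser), with a uniform prior in the first period.

Parameter vector layout (indices used throughout):
0 g0_F, 1 g0_M, 2 sigma_F, 3 sigma_M, 4 phi_F, 5 phi_M,
6 gamma_F, 7 gamma_M, 8 psi, 9 sigma_move, 10 psi1.

Sufficient statistics: daily Bernoulli detections within a primary period
are exchangeable given effort, so the observation likelihood depends only
on per-(individual, site, period) detection counts and per-(site, period)
active-day counts.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
NEG_INF = -1.0e300
ENTRY_CAP = 0.999


@njit(cache=True, inline="always")
def _phi_std(t):
    return 0.5 * (1.0 + math.erf(t / SQRT2))


@njit(cache=True, fastmath=True)
def _lobs_row(i, l, x, y, sex_i, pars, ndet, U, sites):
    """Observation log-likelihood of individual i alive in period l.

    Sites beyond 5 sigma contribute a per-day non-detection probability
    below g0 * exp(-12.5) ~ 4e-6 g0 and are truncated to zero (sites where
    the individual *was* detected are never truncated).
    """
    g0 = pars[sex_i]
    sig = pars[2 + sex_i]
    inv = 1.0 / (2.0 * sig * sig)
    cut2 = 25.0 * sig * sig
    tot = 0.0
    for j in range(sites.shape[0]):
        u = U[j, l]
        if u <= 0.0:
            continue
        dx = x - sites[j, 0]
        dy = y - sites[j, 1]
        d2 = dx * dx + dy * dy
        nd = ndet[i, j, l]
        if d2 > cut2 and nd <= 0.0:
            continue
        p = g0 * math.exp(-d2 * inv)
        if p > 1.0 - 1e-12:
            p = 1.0 - 1e-12
        if nd > 0.0:
            if p < 1e-300:
                return NEG_INF
            tot += nd * math.log(p) + (u - nd) * math.log1p(-p)
        else:
            tot += u * math.log1p(-p)
    return tot


@njit(cache=True)
def _apply_contrib(sign, e, x, s, N, Nsex, avail, ent, surv, dead):
    """Add/remove one individual's run (e..x, or e=-1 empty) to counts."""
    L = N.shape[0]
    if e >= 0:
        for l in range(e, x + 1):
            N[l] += sign
            Nsex[s, l] += sign
        if e >= 1:
            ent[s, e - 1] += sign
        for l in range(e, x):
            surv[s, l] += sign
        if x <= L - 2:
            dead[s, x] += sign
        m = e if e < L - 1 else L - 1
        for l in range(m):
            avail[s, l] += sign
    else:
        for l in range(L - 1):
            avail[s, l] += sign


@njit(cache=True)
def _proc_pre(pars, pre):
    """Per-iteration constants of the process density (log survival etc.)."""
    pre[0] = math.log(pars[10])
    pre[1] = math.log1p(-pars[10])
    pre[2] = math.log(pars[4])
    pre[3] = math.log(pars[5])
    pre[4] = math.log1p(-pars[4])
    pre[5] = math.log1p(-pars[5])
    pre[6] = pars[6]
    pre[7] = pars[7]


@njit(cache=True)
def _proc_logp(pre, M, N, Nsex, avail, ent, surv, dead):
    """Demographic-process log-density of the full alive-state config.

    ``pre`` holds [log psi1, log(1-psi1), log phi_F, log phi_M,
    log(1-phi_F), log(1-phi_M), gamma_F, gamma_M].
    """
    L = N.shape[0]
    lp = N[0] * pre[0] + (M - N[0]) * pre[1]
    for l in range(L - 1):
        for s in range(2):
            sv = surv[s, l]
            dd = dead[s, l]
            if sv > 0:
                lp += sv * pre[2 + s]
            if dd > 0:
                lp += dd * pre[4 + s]
            av = avail[s, l]
            en = ent[s, l]
            if av > 0:
                a = pre[6 + s] * N[l] / av
                if a > ENTRY_CAP:
                    a = ENTRY_CAP
                if a <= 0.0:
                    if en > 0:
                        return NEG_INF
                else:
                    lp += en * math.log(a) + (av - en) * math.log1p(-a)
            elif en > 0:
                return NEG_INF
    return lp


@njit(cache=True)
def _entry_logp(gam, s, N, avail, ent):
    """Entry terms of the process density for one sex (gamma conditional)."""
    lp = 0.0
    for l in range(N.shape[0] - 1):
        av = avail[s, l]
        en = ent[s, l]
        if av > 0:
            a = gam * N[l] / av
            if a > ENTRY_CAP:
                a = ENTRY_CAP
            if a <= 0.0:
                if en > 0:
                    return NEG_INF
            else:
                lp += en * math.log(a) + (av - en) * math.log1p(-a)
        elif en > 0:
            return NEG_INF
    return lp


@njit(cache=True)
def _trunc_norm_const(x, y, sm, bounds):
    """log normaliser of a bivariate normal centred at (x, y), truncated."""
    zx = math.log(_phi_std((bounds[1] - x) / sm) - _phi_std((bounds[0] - x) / sm))
    zy = math.log(_phi_std((bounds[3] - y) / sm) - _phi_std((bounds[2] - y) / sm))
    return zx + zy


@njit(cache=True)
def _move_logp(sm, ac, bounds, zf, zl, M, L):
    """Movement log-density over observation-constrained path segments.

    Never-alive individuals' whole paths and dead-tail segments are
    integrated out of the movement-scale conditional: they are redrawn
    from the prior at the top of every iteration, so only transitions
    ending at or before each individual's exit period carry information.
    """
    c = -0.5 / (sm * sm)
    tot = 0.0
    for i in range(M):
        if zf[i] < 0:
            continue
        stop = zl[i] if zl[i] < L - 1 else L - 1
        for l in range(stop):
            dx = ac[i, l + 1, 0] - ac[i, l, 0]
            dy = ac[i, l + 1, 1] - ac[i, l, 1]
            tot += c * (dx * dx + dy * dy) - 2.0 * math.log(sm)
            tot -= _trunc_norm_const(ac[i, l, 0], ac[i, l, 1], sm, bounds)
    return tot


@njit(cache=True)
def _obs_total_class(s, pars, zf, zl, sex, ndet, U, sites, ac):
    """Observation log-likelihood summed over alive periods of class s."""
    tot = 0.0
    for i in range(zf.shape[0]):
        if sex[i] != s or zf[i] < 0:
            continue
        for l in range(zf[i], zl[i] + 1):
            tot += _lobs_row(i, l, ac[i, l, 0], ac[i, l, 1], s, pars, ndet, U, sites)
    return tot


N_GAMMA_GRID = 256


@njit(cache=True)
def _gamma_grid_draw(s, lo, hi, N, avail, ent, gw):
    """Exact draw of gamma_s from its 1-D conditional on a uniform grid.

    The conditional under a U(lo, hi) prior is proportional to the entry
    terms of the process density; a 256-cell piecewise-constant
    inverse-CDF draw with within-cell jitter mixes without random-walk
    stickiness.
    """
    ng = N_GAMMA_GRID
    best = -1.0e308
    for k in range(ng):
        gv = lo + (hi - lo) * (k + 0.5) / ng
        gw[k] = _entry_logp(gv, s, N, avail, ent)
        if gw[k] > best:
            best = gw[k]
    tot = 0.0
    for k in range(ng):
        gw[k] = math.exp(gw[k] - best)
        tot += gw[k]
    u = np.random.random() * tot
    run = 0.0
    pick = ng - 1
    for k in range(ng):
        run += gw[k]
        if u <= run:
            pick = k
            break
    return lo + (hi - lo) * (pick + np.random.random()) / ng


@njit(cache=True)
def _refresh_demography(pars, fixed, prior_lo, prior_hi, M, L, sex,
                        N, avail, ent, surv, dead, gw, pre, cache_valid):
    """Gibbs refresh of phi, gamma, psi, psi1 given the current counts.

    Interleaved with the alive-state sweep so entry counts and rates
    equilibrate jointly rather than by a slow alternating random walk.
    """
    if L > 1:
        for s in range(2):
            if fixed[4 + s] == 0:
                sv = 0
                dd = 0
                for l in range(L - 1):
                    sv += surv[s, l]
                    dd += dead[s, l]
                pars[4 + s] = _beta_clamped(1.0 + sv, 1.0 + dd)
            if fixed[6 + s] == 0:
                pars[6 + s] = _gamma_grid_draw(
                    s, prior_lo[6 + s], prior_hi[6 + s], N, avail, ent, gw)
    if fixed[8] == 0:
        nF = 0
        for i in range(M):
            if sex[i] == 0:
                nF += 1
        pars[8] = _beta_clamped(1.0 + nF, 1.0 + (M - nF))
    if fixed[10] == 0:
        pars[10] = _beta_clamped(1.0 + N[0], 1.0 + (M - N[0]))
    _proc_pre(pars, pre)
    cache_valid[0] = 0
    cache_valid[1] = 0


@njit(cache=True)
def _trunc_norm_draw(mx, my, sm, bounds):
    """Rejection draw from a bivariate normal truncated to the rectangle."""
    for _ in range(200):
        x = mx + np.random.normal() * sm
        y = my + np.random.normal() * sm
        if bounds[0] <= x <= bounds[1] and bounds[2] <= y <= bounds[3]:
            return x, y
    # pathological scale: clamp to the rectangle
    x = min(max(mx, bounds[0]), bounds[1])
    y = min(max(my, bounds[2]), bounds[3])
    return x, y


@njit(cache=True)
def _beta_clamped(a, b):
    v = np.random.beta(a, b)
    if v < 1e-12:
        v = 1e-12
    if v > 1.0 - 1e-12:
        v = 1.0 - 1e-12
    return v


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burn,
    thin,
    ndet,        # (M, J, L) float64 detection-day counts
    U,           # (J, L) float64 active days
    sites,       # (J, 2)
    bounds,      # (4,) xmin xmax ymin ymax
    sexobs,      # (M,) int8: -1 unknown, 0 F, 1 M
    first,       # (M,) int64, -1 for augmented
    last,        # (M,) int64
    prior_lo,    # (11,)
    prior_hi,    # (11,)
    fixed,       # (11,) uint8
    pars0,       # (11,)
    zf0,         # (M,) int64 initial entry period (-1 empty)
    zl0,         # (M,) int64 initial exit period
    sex0,        # (M,) int8 initial sexes (all known)
    ac0,         # (M, L, 2)
    markov,      # int64: 1 markov movement, 0 independent
):
    np.random.seed(seed)
    M, J, L = ndet.shape
    pars = pars0.copy()
    zf = zf0.copy()
    zl = zl0.copy()
    sex = sex0.copy()
    ac = ac0.copy()

    # ---- demographic count bookkeeping ----
    N = np.zeros(L, dtype=np.int64)
    Nsex = np.zeros((2, L), dtype=np.int64)
    Lm1 = L - 1 if L > 1 else 1
    avail = np.zeros((2, Lm1), dtype=np.int64)
    ent = np.zeros((2, Lm1), dtype=np.int64)
    surv = np.zeros((2, Lm1), dtype=np.int64)
    dead = np.zeros((2, Lm1), dtype=np.int64)
    for i in range(M):
        _apply_contrib(1, zf[i], zl[i], sex[i], N, Nsex, avail, ent, surv, dead)

    # ---- proposal scales (adapted during burn-in) ----
    # blocks: 0 g0F, 1 g0M, 2 sigF, 3 sigM, 4 gamF, 5 gamM, 6 sigmove, 7 centres
    scales = np.empty(8)
    scales[0] = 0.3
    scales[1] = 0.3
    scales[2] = 0.1
    scales[3] = 0.1
    scales[4] = 0.4
    scales[5] = 0.4
    scales[6] = 0.1
    scales[7] = 0.25 * pars[2]
    acc = np.zeros(8)
    att = np.zeros(8)

    n_keep = (n_iter - burn + thin - 1) // thin
    draws = np.zeros((n_keep, 11 + 2 * L))
    alive_sum = np.zeros((M, L))
    sexF_sum = np.zeros(M)
    kept = 0

    lrow = np.empty(L)
    cand_lp = np.empty(L * L + 1)
    cand_e = np.empty(L * L + 1, dtype=np.int64)
    cand_x = np.empty(L * L + 1, dtype=np.int64)
    pre = np.empty(8)
    gw = np.empty(N_GAMMA_GRID)
    ncmax = L * L + 1
    pc_lp = np.empty((2, ncmax))
    pc_w = np.empty((2, ncmax))
    pc_e = np.empty((2, ncmax), dtype=np.int64)
    pc_x = np.empty((2, ncmax), dtype=np.int64)
    pc_n = np.zeros(2, dtype=np.int64)
    pc_tot = np.zeros(2)
    cache_valid = np.zeros(2, dtype=np.uint8)
    lp2 = np.empty(2)

    for it in range(n_iter):
        # ================= activity centres =================
        sm = pars[9]
        c_move = -0.5 / (sm * sm)
        for i in range(M):
            si = sex[i]
            if markov == 1 and L > 1:
                if zf[i] < 0:
                    # no observation terms anywhere: exact draw from the
                    # movement prior (uniform start, truncated-normal steps)
                    ac[i, 0, 0] = bounds[0] + np.random.random() * (bounds[1] - bounds[0])
                    ac[i, 0, 1] = bounds[2] + np.random.random() * (bounds[3] - bounds[2])
                    for l in range(1, L):
                        ac[i, l, 0], ac[i, l, 1] = _trunc_norm_draw(
                            ac[i, l - 1, 0], ac[i, l - 1, 1], sm, bounds)
                    continue
                if zl[i] < L - 1:
                    # dead tail: joint forward draw from the kernel
                    for l in range(zl[i] + 1, L):
                        ac[i, l, 0], ac[i, l, 1] = _trunc_norm_draw(
                            ac[i, l - 1, 0], ac[i, l - 1, 1], sm, bounds)
            elif zf[i] < 0:
                for l in range(L):
                    ac[i, l, 0] = bounds[0] + np.random.random() * (bounds[1] - bounds[0])
                    ac[i, l, 1] = bounds[2] + np.random.random() * (bounds[3] - bounds[2])
                continue
            l_stop = zl[i] if (markov == 1 and L > 1) else L - 1
            for l in range(l_stop + 1):
                att[7] += 1.0
                xc = ac[i, l, 0]
                yc = ac[i, l, 1]
                xp = xc + np.random.normal() * scales[7]
                yp = yc + np.random.normal() * scales[7]
                if xp < bounds[0] or xp > bounds[1] or yp < bounds[2] or yp > bounds[3]:
                    continue
                dlp = 0.0
                if zf[i] >= 0 and zf[i] <= l <= zl[i]:
                    dlp += _lobs_row(i, l, xp, yp, si, pars, ndet, U, sites)
                    dlp -= _lobs_row(i, l, xc, yc, si, pars, ndet, U, sites)
                if markov == 1 and L > 1:
                    if l > 0:
                        dxp = xp - ac[i, l - 1, 0]
                        dyp = yp - ac[i, l - 1, 1]
                        dxc = xc - ac[i, l - 1, 0]
                        dyc = yc - ac[i, l - 1, 1]
                        dlp += c_move * (dxp * dxp + dyp * dyp - dxc * dxc - dyc * dyc)
                    if l < L - 1:
                        dxp = ac[i, l + 1, 0] - xp
                        dyp = ac[i, l + 1, 1] - yp
                        dxc = ac[i, l + 1, 0] - xc
                        dyc = ac[i, l + 1, 1] - yc
                        dlp += c_move * (dxp * dxp + dyp * dyp - dxc * dxc - dyc * dyc)
                        dlp -= _trunc_norm_const(xp, yp, sm, bounds)
                        dlp += _trunc_norm_const(xc, yc, sm, bounds)
                if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                    ac[i, l, 0] = xp
                    ac[i, l, 1] = yp
                    acc[7] += 1.0

        # ================= alive states =================
        # Detected individuals and alive augmented rows: exact categorical
        # draw over contiguous runs (mandatory detection spans contribute a
        # common observation factor that cancels, so only rows outside the
        # span are evaluated).  Never-alive augmented rows: independence
        # Metropolis with the process-prior categorical as proposal and the
        # non-detection likelihood as acceptance term; the proposal table is
        # shared per sex (identical base counts) and rebuilt only when the
        # demographic counts change.
        _proc_pre(pars, pre)
        cache_valid[0] = 0
        cache_valid[1] = 0
        if True:
          for i in range(M):
            if (i + 1) % 32 == 0:
                _refresh_demography(pars, fixed, prior_lo, prior_hi, M, L, sex,
                                    N, avail, ent, surv, dead, gw, pre,
                                    cache_valid)
            si = sex[i]
            old_e = zf[i]
            old_x = zl[i]
            if first[i] >= 0 or zf[i] >= 0:
                if first[i] == 0 and last[i] == L - 1:
                    continue
                if first[i] >= 0:
                    e_hi = first[i]
                    x_lo = last[i]
                else:
                    e_hi = L - 1
                    x_lo = 0
                for l in range(L):
                    if first[i] >= 0 and first[i] <= l <= last[i]:
                        lrow[l] = 0.0
                    else:
                        lrow[l] = _lobs_row(i, l, ac[i, l, 0], ac[i, l, 1],
                                            si, pars, ndet, U, sites)
                _apply_contrib(-1, old_e, old_x, si, N, Nsex, avail, ent, surv, dead)
                ncand = 0
                if first[i] < 0:
                    # the empty run still contributes to the entry pool
                    cand_e[ncand] = -1
                    cand_x[ncand] = -1
                    _apply_contrib(1, -1, -1, si, N, Nsex, avail, ent, surv, dead)
                    cand_lp[ncand] = _proc_logp(pre, M, N, Nsex, avail, ent, surv, dead)
                    _apply_contrib(-1, -1, -1, si, N, Nsex, avail, ent, surv, dead)
                    ncand += 1
                for e in range(e_hi + 1):
                    x_start = x_lo if x_lo >= e else e
                    for x in range(x_start, L):
                        _apply_contrib(1, e, x, si, N, Nsex, avail, ent, surv, dead)
                        lp = _proc_logp(pre, M, N, Nsex, avail, ent, surv, dead)
                        _apply_contrib(-1, e, x, si, N, Nsex, avail, ent, surv, dead)
                        for l in range(e, x + 1):
                            lp += lrow[l]
                        cand_e[ncand] = e
                        cand_x[ncand] = x
                        cand_lp[ncand] = lp
                        ncand += 1
                mx = cand_lp[0]
                for c in range(1, ncand):
                    if cand_lp[c] > mx:
                        mx = cand_lp[c]
                tot = 0.0
                for c in range(ncand):
                    cand_lp[c] = math.exp(cand_lp[c] - mx)
                    tot += cand_lp[c]
                u = np.random.random() * tot
                pick = ncand - 1
                run = 0.0
                for c in range(ncand):
                    run += cand_lp[c]
                    if u <= run:
                        pick = c
                        break
                zf[i] = cand_e[pick]
                zl[i] = cand_x[pick]
                _apply_contrib(1, zf[i], zl[i], si, N, Nsex, avail, ent, surv, dead)
            else:
                if cache_valid[si] == 0:
                    # empty-run weight with the individual's pool contribution
                    # in place; other candidates on the i-removed base
                    nc = 0
                    pc_e[si, nc] = -1
                    pc_x[si, nc] = -1
                    pc_lp[si, nc] = _proc_logp(pre, M, N, Nsex, avail, ent, surv, dead)
                    nc += 1
                    _apply_contrib(-1, -1, -1, si, N, Nsex, avail, ent, surv, dead)
                    for e in range(L):
                        for x in range(e, L):
                            _apply_contrib(1, e, x, si, N, Nsex, avail, ent, surv, dead)
                            pc_lp[si, nc] = _proc_logp(pre, M, N, Nsex, avail,
                                                       ent, surv, dead)
                            _apply_contrib(-1, e, x, si, N, Nsex, avail, ent, surv, dead)
                            pc_e[si, nc] = e
                            pc_x[si, nc] = x
                            nc += 1
                    _apply_contrib(1, -1, -1, si, N, Nsex, avail, ent, surv, dead)
                    mx = pc_lp[si, 0]
                    for c in range(1, nc):
                        if pc_lp[si, c] > mx:
                            mx = pc_lp[si, c]
                    tot = 0.0
                    for c in range(nc):
                        tot += math.exp(pc_lp[si, c] - mx)
                        pc_w[si, c] = tot
                    pc_tot[si] = tot
                    pc_n[si] = nc
                    cache_valid[si] = 1
                u = np.random.random() * pc_tot[si]
                pick = pc_n[si] - 1
                for c in range(pc_n[si]):
                    if u <= pc_w[si, c]:
                        pick = c
                        break
                e = pc_e[si, pick]
                x = pc_x[si, pick]
                if e >= 0:
                    obs = 0.0
                    for l in range(e, x + 1):
                        obs += _lobs_row(i, l, ac[i, l, 0], ac[i, l, 1],
                                         si, pars, ndet, U, sites)
                    if obs >= 0.0 or math.log(np.random.random()) < obs:
                        _apply_contrib(-1, -1, -1, si, N, Nsex, avail, ent, surv, dead)
                        _apply_contrib(1, e, x, si, N, Nsex, avail, ent, surv, dead)
                        zf[i] = e
                        zl[i] = x
            if zf[i] != old_e or zl[i] != old_x:
                cache_valid[0] = 0
                cache_valid[1] = 0

        # ================= latent sexes =================
        psi = pars[8]
        for i in range(M):
            if sexobs[i] >= 0:
                continue
            s_cur = sex[i]
            _apply_contrib(-1, zf[i], zl[i], s_cur, N, Nsex, avail, ent, surv, dead)
            for s in range(2):
                _apply_contrib(1, zf[i], zl[i], s, N, Nsex, avail, ent, surv, dead)
                lp = _proc_logp(pre, M, N, Nsex, avail, ent, surv, dead)
                _apply_contrib(-1, zf[i], zl[i], s, N, Nsex, avail, ent, surv, dead)
                if zf[i] >= 0:
                    for l in range(zf[i], zl[i] + 1):
                        lp += _lobs_row(i, l, ac[i, l, 0], ac[i, l, 1], s,
                                        pars, ndet, U, sites)
                lp += math.log(psi) if s == 0 else math.log1p(-psi)
                lp2[s] = lp
            mx = lp2[0] if lp2[0] > lp2[1] else lp2[1]
            pF = math.exp(lp2[0] - mx)
            pM = math.exp(lp2[1] - mx)
            s_new = 0 if np.random.random() * (pF + pM) < pF else 1
            sex[i] = np.int8(s_new)
            _apply_contrib(1, zf[i], zl[i], sex[i], N, Nsex, avail, ent, surv, dead)

        # ================= detection scalars =================
        # joint per-sex (g0, sigma) block: the current totals are computed
        # once, each proposal costs a single observation pass
        for s in range(2):
            if fixed[s] == 1 and fixed[2 + s] == 1:
                continue
            t_cur = _obs_total_class(s, pars, zf, zl, sex, ndet, U, sites, ac)
            att[s] += 1.0
            cur_g0 = pars[s]
            cur_sig = pars[2 + s]
            ljac = 0.0
            if fixed[s] == 0:
                t = (math.log(cur_g0 / (1.0 - cur_g0))
                     + np.random.normal() * scales[s])
                prop_g0 = 1.0 / (1.0 + math.exp(-t))
                ljac += (math.log(prop_g0 * (1.0 - prop_g0))
                         - math.log(cur_g0 * (1.0 - cur_g0)))
            else:
                prop_g0 = cur_g0
            if fixed[2 + s] == 0:
                prop_sig = cur_sig * math.exp(np.random.normal() * scales[2 + s])
                ljac += math.log(prop_sig) - math.log(cur_sig)
            else:
                prop_sig = cur_sig
            if (prior_lo[s] < prop_g0 < prior_hi[s]
                    and prior_lo[2 + s] < prop_sig < prior_hi[2 + s]):
                pars[s] = prop_g0
                pars[2 + s] = prop_sig
                t_prop = _obs_total_class(s, pars, zf, zl, sex, ndet, U, sites, ac)
                pars[s] = cur_g0
                pars[2 + s] = cur_sig
                lacc = t_prop - t_cur + ljac
                if lacc >= 0.0 or math.log(np.random.random()) < lacc:
                    pars[s] = prop_g0
                    pars[2 + s] = prop_sig
                    acc[s] += 1.0

        # ================= demographic scalars =================
        _refresh_demography(pars, fixed, prior_lo, prior_hi, M, L, sex,
                            N, avail, ent, surv, dead, gw, pre, cache_valid)

        # ================= movement scale =================
        if fixed[9] == 0 and markov == 1 and L > 1:
            for _rep in range(3):
                att[6] += 1.0
                cur = pars[9]
                prop = cur * math.exp(np.random.normal() * scales[6])
                if prior_lo[9] < prop < prior_hi[9]:
                    l_cur = _move_logp(cur, ac, bounds, zf, zl, M, L)
                    l_prop = _move_logp(prop, ac, bounds, zf, zl, M, L)
                    lacc = l_prop - l_cur + math.log(prop) - math.log(cur)
                    if lacc >= 0.0 or math.log(np.random.random()) < lacc:
                        pars[9] = prop
                        acc[6] += 1.0

        # ================= adaptation (burn-in only) =================
        if it < burn and (it + 1) % 100 == 0:
            for b in range(8):
                if att[b] > 0:
                    rate = acc[b] / att[b]
                    if rate < 0.2:
                        scales[b] *= 0.8
                        if b < 2:          # sigma scale rides the sex block
                            scales[2 + b] *= 0.8
                    elif rate > 0.45:
                        scales[b] *= 1.25
                        if b < 2:
                            scales[2 + b] *= 1.25
                acc[b] = 0.0
                att[b] = 0.0

        # ================= record =================
        if it >= burn and (it - burn) % thin == 0:
            for p in range(11):
                draws[kept, p] = pars[p]
            for l in range(L):
                draws[kept, 11 + l] = N[l]
                draws[kept, 11 + L + l] = Nsex[0, l]
            for i in range(M):
                if zf[i] >= 0:
                    for l in range(zf[i], zl[i] + 1):
                        alive_sum[i, l] += 1.0
                if sex[i] == 0:
                    sexF_sum[i] += 1.0
            kept += 1

    return draws[:kept], alive_sum / max(kept, 1), sexF_sum / max(kept, 1), scales
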