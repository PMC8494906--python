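"""Synthetic camera-trap data generator emulating the study design.

The generator reproduces the survey geometry (a 2.7 x 2.7 km grid with a
camera site in every second cell, two co-located cameras per site, yearly
100-day primary periods with daily secondary occasions) and the
open-population SCR process: sex-specific half-normal detection, yearly
survival and per-capita recruitment, and Markovian activity-centre
relocation.  Default parameter values are the study's reported posterior
modes, so simulated data represent the surveyed lynx population; the seed
makes every output bit-reproducible.

Sex convention: index 0 = female, 1 = male throughout.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from opencamscr.capture_data import (
    Detector,
    DetectorArray,
    RobustDesignHistory,
    SessionSpec,
)
from opencamscr.statespace import StateSpaceMask

HARD_POPULATION_CAP = 10_000


@dataclass
class SimulationParams:
    """Ground-truth parameters of the open-population SCR process.

    Detection (``g0``, per occasion at distance 0; ``sigma``, m), survival
    (``phi``, per year) and recruitment (``gamma``, new individuals of the
    sex per total abundance per year) are (female, male) pairs; ``psi`` is
    the probability that an individual is female; ``sigma_move`` (m) is the
    yearly activity-centre relocation scale, shared across sexes.
    Defaults are the study's reported posterior modes and design
    dimensions (10 yearly periods of 100 days, 38 initial individuals,
    ~18% of detected individuals of unknown sex).
    """

    n_primary: int = 10
    n_secondary: int = 100
    g0: tuple[float, float] = (0.01, 0.01)
    sigma: tuple[float, float] = (3_960.0, 4_070.0)
    phi: tuple[float, float] = (0.82, 0.90)
    gamma: tuple[float, float] = (0.12, 0.09)
    psi: float = 0.53
    sigma_move: float = 4_750.0
    N_initial: int = 38
    p_sex_unknown: float = 0.18
    seed: int = 0

    def __post_init__(self):
        for p in (*self.g0, *self.phi, *self.gamma, self.psi, self.p_sex_unknown):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.sigma) <= 0 or self.sigma_move < 0:
            raise ValueError("sigma must be > 0 and sigma_move >= 0")
        if self.N_initial < 0:
            raise ValueError("N_initial must be >= 0")


@dataclass
class PopulationTrajectory:
    """Simulated ground truth: alive states, sexes and centre paths."""

    alive: np.ndarray             # (n_total, L) uint8
    sex: np.ndarray               # (n_total,) 0=F, 1=M
    activity_centres: np.ndarray  # (n_total, L, 2) metres
    recruits_by_period: np.ndarray  # (L,) entrants per period (period 0 = initials)

    def __post_init__(self):
        runs = np.asarray(self.alive, dtype=np.int8)
        # no zombie revival: each row is a single contiguous run
        for row in runs:
            on = np.flatnonzero(row)
            if on.size and not np.array_equal(on, np.arange(on[0], on[-1] + 1)):
                raise ValueError("alive rows must be contiguous runs")

    @property
    def N_t(self) -> np.ndarray:
        return self.alive.sum(axis=0)

    @property
    def n_total(self) -> int:
        return self.alive.shape[0]


def make_grid_design(
    n_cells_x: int = 10,
    n_cells_y: int = 11,
    cell_size: float = 2_700.0,
    cameras_per_site: int = 2,
) -> DetectorArray:
    """Checkerboard camera design: a site at the centre of every second cell.

    The default 10 x 11 grid of 2.7 km cells yields 55 sites with paired
    co-located cameras, matching the survey layout; nearest neighbouring
    sites are ``cell_size * sqrt(2)`` apart.
    """
    if n_cells_x < 1 or n_cells_y < 1 or cameras_per_site < 1:
        raise ValueError("counts must be >= 1")
    detectors = []
    suffixes = "abcdefgh"
    for ix in range(n_cells_x):
        for iy in range(n_cells_y):
            if (ix + iy) % 2:
                continue
            x = (ix + 0.5) * cell_size
            y = (iy + 0.5) * cell_size
            site = f"S{ix:02d}{iy:02d}"
            for c in range(cameras_per_site):
                detectors.append(Detector(f"{site}{suffixes[c]}", site, x, y))
    return DetectorArray(detectors)


def simulate_population(
    params: SimulationParams,
    mask: StateSpaceMask,
    rng: np.random.Generator | None = None,
) -> PopulationTrajectory:
    """Simulate the demographic and movement process over the mask.

    The initial population has uniform activity centres and
    Bernoulli(psi) sexes.  Each subsequent period, individuals survive
    with phi(sex); Poisson(gamma_s * N_t) recruits of sex s enter with
    uniform centres; surviving individuals' centres relocate by an
    isotropic bivariate normal of scale sigma_move, reflected at the mask
    boundary.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    L = params.n_primary
    xmin, xmax, ymin, ymax = mask.bounds

    def uniform_centres(n):
        return np.column_stack(
            [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
        )

    def reflect(v, lo, hi):
        span = hi - lo
        v = np.mod(v - lo, 2 * span)
        v = np.where(v > span, 2 * span - v, v)
        return v + lo

    n0 = params.N_initial
    sex = list(rng.binomial(1, 1.0 - params.psi, n0))  # 1 = male
    alive_rows = [np.zeros(L, dtype=np.uint8) for _ in range(n0)]
    centres = [np.full((L, 2), np.nan) for _ in range(n0)]
    init_xy = uniform_centres(n0)
    for i in range(n0):
        alive_rows[i][0] = 1
        centres[i][0] = init_xy[i]
    recruits = np.zeros(L, dtype=np.int64)
    recruits[0] = n0

    current = list(range(n0))  # indices of individuals alive at period t
    for t in range(L - 1):
        survivors = []
        for i in current:
            p_surv = params.phi[sex[i]]
            if rng.random() < p_surv:
                survivors.append(i)
                prev = centres[i][t]
                step = rng.normal(0.0, params.sigma_move, 2)
                nxt = prev + step
                centres[i][t + 1, 0] = reflect(nxt[0], xmin, xmax)
                centres[i][t + 1, 1] = reflect(nxt[1], ymin, ymax)
                alive_rows[i][t + 1] = 1
        N_t = len(current)
        for s in (0, 1):
            n_rec = rng.poisson(params.gamma[s] * N_t)
            xy = uniform_centres(n_rec)
            for r in range(n_rec):
                row = np.zeros(L, dtype=np.uint8)
                row[t + 1] = 1
                c = np.full((L, 2), np.nan)
                c[t + 1] = xy[r]
                alive_rows.append(row)
                centres.append(c)
                sex.append(s)
                survivors.append(len(alive_rows) - 1)
                recruits[t + 1] += 1
        current = survivors
        if len(current) > HARD_POPULATION_CAP:
            raise RuntimeError("population exploded beyond the hard cap")

    return PopulationTrajectory(
        alive=np.array(alive_rows, dtype=np.uint8).reshape(len(alive_rows), L),
        sex=np.array(sex, dtype=np.int8),
        activity_centres=np.array(centres).reshape(len(centres), L, 2),
        recruits_by_period=recruits,
    )


def _usage_array(array: DetectorArray, spec: SessionSpec) -> np.ndarray:
    """(J, K, L) binary site-occasion effort from a detector array."""
    site_ids = array.site_ids
    J, K, L = len(site_ids), spec.max_secondary, spec.n_primary
    usage = np.zeros((J, K, L), dtype=np.uint8)
    for l, (start, end) in enumerate(spec.primary_periods):
        for k in range((end - start).days):
            day = start + dt.timedelta(days=k)
            for j, s in enumerate(site_ids):
                if array.site_active(s, day):
                    usage[j, k, l] = 1
    return usage


def simulate_detections(
    traj: PopulationTrajectory,
    array: DetectorArray,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    usage: np.ndarray | None = None,
) -> RobustDesignHistory:
    """Generate daily Bernoulli half-normal detections, masked by effort.

    For each alive individual, site and day, a detection occurs with
    probability ``g0(sex) * exp(-d^2 / (2 sigma(sex)^2))`` where ``d`` is
    the distance from the individual's current activity centre to the
    site.  Individuals never detected in any period are dropped from the
    emitted history (they remain in the trajectory).
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    coords = array.site_coords()
    J = coords.shape[0]
    L = traj.alive.shape[1]
    K = params.n_secondary
    if usage is None:
        usage = np.ones((J, K, L), dtype=np.uint8)
    if usage.shape != (J, K, L):
        raise ValueError("usage shape must be (sites, n_secondary, n_primary)")

    n = traj.n_total
    y = np.zeros((n, J, K, L), dtype=np.uint8)
    g0 = np.asarray(params.g0)
    sig = np.asarray(params.sigma)
    for l in range(L):
        alive = np.flatnonzero(traj.alive[:, l])
        if alive.size == 0:
            continue
        ac = traj.activity_centres[alive, l]
        d2 = ((ac[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        s = traj.sex[alive]
        p = g0[s][:, None] * np.exp(-d2 / (2.0 * sig[s][:, None] ** 2))
        draws = rng.random((alive.size, J, K)) < p[:, :, None]
        y[alive, :, :, l] = draws & (usage[None, :, :, l] > 0)

    detected = y.sum(axis=(1, 2, 3)) > 0
    sexes = traj.sex[detected].astype(np.int8)
    return RobustDesignHistory(
        y=y[detected],
        site_coords=coords,
        usage=usage,
        sexes=sexes,
        individual_ids=[f"ind{i:03d}" for i in np.flatnonzero(detected)],
        site_ids=array.site_ids,
    )


def apply_sex_missingness(
    history: RobustDesignHistory,
    p_unknown: float,
    seed: int = 0,
) -> RobustDesignHistory:
    """Mask each detected individual's sex to unknown with prob p_unknown."""
    if not 0.0 <= p_unknown <= 1.0:
        raise ValueError("p_unknown must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sexes = history.sexes.copy()
    mask = rng.random(sexes.shape[0]) < p_unknown
    sexes[mask] = -1
    return RobustDesignHistory(
        y=history.y.copy(), site_coords=history.site_coords.copy(),
        usage=history.usage.copy(), sexes=sexes,
        individual_ids=list(history.individual_ids), site_ids=list(history.site_ids),
    )


def history_to_captures(
    history: RobustDesignHistory,
    array: DetectorArray,
    spec: SessionSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Timestamped capture records equivalent to a site-level history.

    Each site-occasion detection becomes one record at noon of the
    corresponding calendar day, attributed to a randomly chosen active
    camera of the site (site-level binning recovers the history exactly).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    members = array.site_members()
    rows = []
    for i, j, k, l in zip(*np.nonzero(history.y)):
        start = spec.primary_periods[l][0]
        day = start + dt.timedelta(days=int(k))
        cams = [c for c in members[history.site_ids[j]] if array.detector_active(c, day)]
        cam = cams[rng.integers(len(cams))] if cams else members[history.site_ids[j]][0]
        rows.append(
            {
                "individual_id": history.individual_ids[i],
                "datetime": pd.Timestamp(day) + pd.Timedelta(hours=12),
                "detector_id": cam,
                "sex": {0: "F", 1: "M", -1: "U"}[int(history.sexes[i])],
                "status": "independent",
                "in_period": True,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "datetime", "detector_id", "sex", "status", "in_period"],
    )
    return df.sort_values(["datetime", "individual_id"], kind="stable").reset_index(drop=True)


def simulate_species_photos(
    array: DetectorArray,
    spec: SessionSpec,
    rates: dict[str, float],
    seed: int = 0,
    burst_size: float = 0.5,
) -> pd.DataFrame:
    """Unmarked-species photo streams for relative-abundance indexing.

    Independent passes arrive at each active camera as a Poisson process
    with ``rates[species]`` expected passes per camera-day; each pass
    yields ``1 + Poisson(burst_size)`` photos within a few minutes
    (exercising event de-duplication).  Returns a photo table with
    columns species, datetime, camera_id, site_id.
    """
    rng = np.random.default_rng(seed)
    rows = []
    det_site = {d.detector_id: d.site_id for d in array.detectors}
    for l, (start, end) in enumerate(spec.primary_periods):
        for k in range((end - start).days):
            day = start + dt.timedelta(days=k)
            for cam, site in det_site.items():
                if not array.detector_active(cam, day):
                    continue
                for species, rate in rates.items():
                    for _ in range(rng.poisson(rate)):
                        t0 = pd.Timestamp(day) + pd.Timedelta(seconds=int(rng.integers(86_400)))
                        n_photos = 1 + rng.poisson(burst_size)
                        for p in range(n_photos):
                            rows.append(
                                {
                                    "species": species,
                                    "datetime": t0 + pd.Timedelta(seconds=int(p * 30)),
                                    "camera_id": cam,
                                    "site_id": site,
                                }
                            )
    df = pd.DataFrame(rows, columns=["species", "datetime", "camera_id", "site_id"])
    return df.sort_values(["species", "camera_id", "datetime"], kind="stable").reset_index(
        drop=True
    )
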