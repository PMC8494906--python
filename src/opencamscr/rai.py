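"""Relative abundance index (RAI) for unmarked species.

The RAI expresses de-duplicated photographic events per effective trap
night.  Consecutive photos of a species at one camera belong to the same
event while the rolling gap to the previous photo stays under a 10-minute
threshold (a gap equal to the threshold starts a new event).  Because
sites hold paired cameras whose capture streams overlap, the index is
bootstrapped by drawing one camera per site uniformly at random per
replicate (5,000 by default) and recomputing events and trap nights from
the selected cameras, which reduces camera- and site-level capture bias.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from opencamscr.capture_data import DetectorArray

DEFAULT_THRESHOLD_MIN = 10.0
DEFAULT_N_BOOT = 5_000


@dataclass(frozen=True)
class SpeciesEvent:
    species: str
    datetime: pd.Timestamp
    camera_id: str
    site_id: str


@dataclass
class RAIResult:
    """Bootstrap RAI summary for one species in one session.

    ``mean_rai`` is the mean of per-replicate events-per-trap-night
    ratios and ``sd_rai`` their standard deviation; ``n_events_mean`` and
    ``trap_nights`` are replicate means.  When all cameras at a site
    share identical effort, replicate trap nights are constant and
    ``mean_rai = n_events_mean / trap_nights`` holds exactly.
    """

    species: str
    session: str
    mean_rai: float
    sd_rai: float
    n_events_mean: float
    trap_nights: float


def dedupe_events(photos: pd.DataFrame, threshold_min: float = DEFAULT_THRESHOLD_MIN) -> list[SpeciesEvent]:
    """Collapse photo bursts into events per (species, camera).

    Scanning chronologically within each species-camera stream, a photo
    starts a new event iff its gap to the *previous photo* (rolling gap,
    not gap to the event start) is at least ``threshold_min`` minutes.
    ``threshold_min = 0`` yields one event per photo.
    """
    events: list[SpeciesEvent] = []
    if len(photos) == 0:
        return events
    df = photos.sort_values(["species", "camera_id", "datetime"], kind="stable")
    # an infinite threshold collapses each species-camera stream to one event
    thr = pd.Timedelta(minutes=threshold_min) if np.isfinite(threshold_min) else None
    for (species, camera), grp in df.groupby(["species", "camera_id"], sort=True):
        prev = None
        for row in grp.itertuples(index=False):
            t = pd.Timestamp(row.datetime)
            if prev is None or threshold_min == 0 or (
                thr is not None and t - prev >= thr
            ):
                events.append(SpeciesEvent(species, t, camera, row.site_id))
            prev = t
    events.sort(key=lambda e: (e.species, e.camera_id, e.datetime))
    return events


def compute_rai(n_events: float, trap_nights: float) -> float:
    """Events per effective trap night."""
    if trap_nights <= 0:
        raise ValueError("trap_nights must be > 0")
    return n_events / trap_nights


def _camera_trap_nights(array: DetectorArray, camera: str,
                        start: dt.date, end: dt.date) -> int:
    """Active days of one camera in the half-open session window."""
    if array.effort is None:
        return (end - start).days
    days = [d for d in array.effort.columns if start <= d < end]
    if not days:
        return 0
    return int(array.effort.loc[camera, days].sum())


def bootstrap_rai(
    events: list[SpeciesEvent],
    array: DetectorArray,
    session: tuple[dt.date, dt.date],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    species: str | None = None,
) -> list[RAIResult]:
    """One-camera-per-site bootstrap of the RAI.

    Per replicate, one camera is drawn uniformly per site; that
    replicate's events and trap nights come from the selected cameras
    only.  Sites with no active camera in the session are excluded (with
    a warning).  Returns one :class:`RAIResult` per species (or the
    requested species only).
    """
    import warnings

    start, end = session
    rng = np.random.default_rng(seed)
    members = array.site_members()

    site_cams: dict[str, list[str]] = {}
    for site, cams in members.items():
        active = [c for c in cams if _camera_trap_nights(array, c, start, end) > 0]
        if not active:
            warnings.warn(f"site {site!r} has no active camera in session; excluded",
                          stacklevel=2)
            continue
        site_cams[site] = active
    if not site_cams:
        raise ValueError("no sites with active cameras in the session")

    nights = {
        c: _camera_trap_nights(array, c, start, end)
        for cams in site_cams.values() for c in cams
    }
    in_session = [
        e for e in events
        if start <= e.datetime.date() < end and e.site_id in site_cams
    ]
    all_species = sorted({e.species for e in in_session}) if species is None else [species]

    counts: dict[tuple[str, str], int] = {}
    for e in in_session:
        counts[(e.species, e.camera_id)] = counts.get((e.species, e.camera_id), 0) + 1

    sites = sorted(site_cams)
    results = []
    choices = [site_cams[s] for s in sites]
    picks = np.column_stack(
        [rng.integers(len(c), size=n_boot) for c in choices]
    )  # (n_boot, n_sites)
    for sp in all_species:
        rai_r = np.empty(n_boot)
        ev_r = np.empty(n_boot)
        tn_r = np.empty(n_boot)
        for r in range(n_boot):
            n_ev, tn = 0, 0
            for s_idx, site in enumerate(sites):
                cam = choices[s_idx][picks[r, s_idx]]
                n_ev += counts.get((sp, cam), 0)
                tn += nights[cam]
            ev_r[r], tn_r[r] = n_ev, tn
            rai_r[r] = compute_rai(n_ev, tn)
        results.append(
            RAIResult(
                species=sp, session=f"{start.isoformat()}..{end.isoformat()}",
                mean_rai=float(rai_r.mean()), sd_rai=float(rai_r.std(ddof=1)),
                n_events_mean=float(ev_r.mean()), trap_nights=float(tn_r.mean()),
            )
        )
    return results


def published_session_table() -> pd.DataFrame:
    """The survey's published per-session RAI summary for the Bavarian
    Forest National Park: mean bootstrap event counts for roe deer, red
    deer and red fox, number of camera sites and effective trap nights.
    """
    from importlib.resources import files

    path = files("opencamscr.data").joinpath("bfnp_rai_sessions.csv")
    with path.open() as fh:
        return pd.read_csv(fh, comment="#")
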