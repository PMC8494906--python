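"""Data model and I/O for detectors, effort and individual capture records.

Conventions
-----------
* Coordinates are planar metres.
* A *site* is a camera-trap location holding one or two co-located (or
  opposing) cameras; SCR detections are attributed to sites, so a pair of
  cameras photographing the same animal on the same day yields a single
  site-level detection.
* A secondary occasion is one calendar day; primary periods are half-open
  date intervals ``[start, end)``.
* Effort is binary per detector-day; a site-day is active if at least one
  of its cameras is active.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEX_CODES = {"F": 0, "M": 1, "U": -1}
SEX_LABELS = {0: "F", 1: "M", -1: "U"}


@dataclass(frozen=True)
class Detector:
    """A single camera with a site membership and planar coordinates (m)."""

    detector_id: str
    site_id: str
    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"detector {self.detector_id!r}: non-finite coordinates")


@dataclass
class DetectorArray:
    """Camera array: detectors plus an optional binary per-detector-day effort.

    ``effort`` is a DataFrame indexed by ``detector_id`` with
    ``datetime.date`` columns and 0/1 cells; ``None`` means every camera is
    active on every day (the all-active default).
    """

    detectors: list[Detector]
    effort: pd.DataFrame | None = None

    def __post_init__(self):
        ids = [d.detector_id for d in self.detectors]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate detector_id: {sorted(dupes)}")
        site_of = {}
        for d in self.detectors:
            site_of.setdefault(d.site_id, []).append(d.detector_id)
        for s, members in site_of.items():
            if len(members) > 2:
                raise ValueError(f"site {s!r} has {len(members)} detectors (max 2)")
        if self.effort is not None:
            missing = set(ids) - set(self.effort.index)
            if missing:
                raise ValueError(f"effort missing for detectors: {sorted(missing)}")

    # ------------------------------------------------------------------ #
    @property
    def detector_ids(self) -> list[str]:
        return [d.detector_id for d in self.detectors]

    @property
    def site_ids(self) -> list[str]:
        """Unique site ids in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.detectors:
            seen.setdefault(d.site_id, None)
        return list(seen)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site_coords(self) -> np.ndarray:
        """(n_sites, 2) site coordinates: mean of member-camera coordinates."""
        out = np.empty((self.n_sites, 2))
        for k, s in enumerate(self.site_ids):
            xs = [(d.x, d.y) for d in self.detectors if d.site_id == s]
            out[k] = np.mean(xs, axis=0)
        return out

    def site_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for d in self.detectors:
            out.setdefault(d.site_id, []).append(d.detector_id)
        return out

    def bounding_box(self) -> tuple[float, float, float, float]:
        xs = np.array([d.x for d in self.detectors])
        ys = np.array([d.y for d in self.detectors])
        return float(xs.min()), float(xs.max()), float(ys.min()), float(ys.max())

    def detector_active(self, detector_id: str, day: dt.date) -> bool:
        if self.effort is None:
            return True
        if day not in self.effort.columns:
            return False
        return bool(self.effort.at[detector_id, day])

    def site_active(self, site_id: str, day: dt.date) -> bool:
        return any(self.detector_active(d, day) for d in self.site_members()[site_id])


@dataclass
class SessionSpec:
    """Robust-design session layout.

    ``primary_periods`` are chronologically ordered, non-overlapping
    half-open date intervals, each at most 100 days; a secondary occasion
    is one calendar day.  The biological year runs from ``lynx_year_start``
    (May 1), aligned with the kitten birth pulse.
    """

    primary_periods: list[tuple[dt.date, dt.date]]
    secondary_length: int = 1
    lynx_year_start: tuple[int, int] = (5, 1)

    def __post_init__(self):
        prev_end = None
        for start, end in self.primary_periods:
            if end <= start:
                raise ValueError(f"primary period {start}..{end} is empty")
            if (end - start).days > 100:
                raise ValueError(f"primary period {start}..{end} exceeds 100 days")
            if prev_end is not None and start < prev_end:
                raise ValueError("primary periods overlap or are out of order")
            prev_end = end
        if self.secondary_length != 1:
            raise ValueError("secondary occasions are single calendar days")

    @classmethod
    def yearly_autumn_windows(cls, first_year: int = 2009, n_years: int = 10) -> "SessionSpec":
        """The survey's standard layout: 100-day windows Sep 15 - Dec 24."""
        periods = [
            (dt.date(y, 9, 15), dt.date(y, 12, 24))
            for y in range(first_year, first_year + n_years)
        ]
        return cls(periods)

    @property
    def n_primary(self) -> int:
        return len(self.primary_periods)

    @property
    def max_secondary(self) -> int:
        return max((e - s).days for s, e in self.primary_periods)

    def n_secondary(self, period: int) -> int:
        s, e = self.primary_periods[period]
        return (e - s).days

    def locate(self, day: dt.date) -> tuple[int, int] | None:
        """Return (primary period index, day-within-period index) or None."""
        for l, (s, e) in enumerate(self.primary_periods):
            if s <= day < e:
                return l, (day - s).days
        return None

    def lynx_year(self, day: dt.date) -> int:
        m, d = self.lynx_year_start
        boundary = dt.date(day.year, m, d)
        return day.year if day >= boundary else day.year - 1


@dataclass
class RobustDesignHistory:
    """Binary robust-design detections: individual x site x occasion x period.

    ``y[i, j, k, l]`` is 1 if individual ``i`` was photographed at site
    ``j`` on secondary occasion ``k`` of primary period ``l`` (collapsed to
    at most one detection per site per occasion); ``usage[j, k, l]`` flags
    site-occasion effort.  Sex codes: 0 female, 1 male, -1 unknown.
    """

    y: np.ndarray
    site_coords: np.ndarray
    usage: np.ndarray
    sexes: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        self.usage = np.asarray(self.usage, dtype=np.uint8)
        self.sexes = np.asarray(self.sexes, dtype=np.int8)
        n, J, K, L = self.y.shape
        if self.usage.shape != (J, K, L):
            raise ValueError("usage shape must be (sites, occasions, periods)")
        if self.site_coords.shape != (J, 2):
            raise ValueError("site_coords shape must be (sites, 2)")
        if self.sexes.shape != (n,):
            raise ValueError("one sex code per individual required")
        if not np.all((self.y == 0) | (self.y == 1)):
            raise ValueError("y must be binary")
        if np.any((self.y == 1) & (self.usage[None] == 0)):
            raise ValueError("detections present where usage is zero")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:03d}" for i in range(n)]
        if not self.site_ids:
            self.site_ids = [f"site{j:03d}" for j in range(J)]

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    @property
    def n_primary(self) -> int:
        return self.y.shape[3]

    def detections_per_period(self) -> np.ndarray:
        """(n, L) count of site-occasion detections per individual-period."""
        return self.y.sum(axis=(1, 2))


@dataclass
class ClosedSessionHistory:
    """Single-session history with occasions collapsed to multi-day blocks.

    ``usage[j, k]`` counts the active days inside occasion ``k`` at site
    ``j`` (0..days_per_occasion), retained for effort-compounded detection.
    """

    y: np.ndarray          # (n, J, K) binary
    usage: np.ndarray      # (J, K) int, active days per occasion
    site_coords: np.ndarray
    sexes: np.ndarray
    days_per_occasion: int
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        self.usage = np.asarray(self.usage, dtype=np.int64)
        self.sexes = np.asarray(self.sexes, dtype=np.int8)
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:03d}" for i in range(self.y.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    def detected_mask(self) -> np.ndarray:
        return self.y.sum(axis=(1, 2)) > 0


# ====================================================================== #
# readers / writers
# ====================================================================== #

def read_detectors(path, effort_path=None) -> DetectorArray:
    """Read a detector table (CSV: detector_id, site_id, x_m, y_m).

    An optional wide-format effort file (first column detector_id, ISO-date
    columns, 0/1 cells) attaches per-day activity; without it every camera
    is treated as always active.
    """
    df = pd.read_csv(path, dtype={"detector_id": str, "site_id": str})
    required = {"detector_id", "site_id", "x_m", "y_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"detector file must have columns {sorted(required)}")
    dupes = df["detector_id"][df["detector_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate detector_id: {sorted(set(dupes))}")
    detectors = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            x, y = float(row.x_m), float(row.y_m)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric coordinate at row {row_no}") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(f"non-finite coordinate at row {row_no}")
        detectors.append(Detector(str(row.detector_id), str(row.site_id), x, y))
    effort = read_effort(effort_path) if effort_path is not None else None
    return DetectorArray(detectors, effort)


def write_detectors(array: DetectorArray, path) -> None:
    df = pd.DataFrame(
        {
            "detector_id": [d.detector_id for d in array.detectors],
            "site_id": [d.site_id for d in array.detectors],
            "x_m": [d.x for d in array.detectors],
            "y_m": [d.y for d in array.detectors],
        }
    )
    df.to_csv(path, index=False)


def read_effort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"detector_id": str})
    df = df.set_index("detector_id")
    df.columns = [dt.date.fromisoformat(c) for c in df.columns]
    return df.astype(np.int8)


def write_effort(effort: pd.DataFrame, path) -> None:
    out = effort.copy()
    out.columns = [c.isoformat() for c in out.columns]
    out.to_csv(path, index=True, index_label="detector_id")


def read_captures(path, spec: SessionSpec | None = None) -> pd.DataFrame:
    """Read timestamped identified-individual capture records.

    Columns: individual_id, datetime_iso, detector_id, sex {F,M,U},
    status {juvenile,independent,unknown}.  Records whose timestamp falls
    outside every declared primary period are retained but flagged
    (``in_period`` False) with a warning.
    """
    df = pd.read_csv(
        path,
        dtype={"individual_id": str, "detector_id": str, "sex": str, "status": str},
    )
    if len(df) == 0:
        return pd.DataFrame(
            columns=["individual_id", "datetime", "detector_id", "sex", "status", "in_period"]
        )
    required = {"individual_id", "datetime_iso", "detector_id", "sex", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"capture file must have columns {sorted(required)}")
    df["datetime"] = pd.to_datetime(df["datetime_iso"])
    bad_sex = set(df["sex"]) - set(SEX_CODES)
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    df = df.drop(columns=["datetime_iso"])
    if spec is not None:
        df["in_period"] = [spec.locate(t.date()) is not None for t in df["datetime"]]
        n_out = int((~df["in_period"]).sum())
        if n_out:
            warnings.warn(
                f"{n_out} capture record(s) fall outside every primary period",
                stacklevel=2,
            )
    else:
        df["in_period"] = True
    return df[["individual_id", "datetime", "detector_id", "sex", "status", "in_period"]]


def write_captures(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["datetime_iso"] = out["datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[["individual_id", "datetime_iso", "detector_id", "sex", "status"]].to_csv(
        path, index=False
    )


# ====================================================================== #
# history construction
# ====================================================================== #

def _individual_sex(codes: pd.Series) -> int:
    known = [c for c in codes if c in ("F", "M")]
    if known:
        return SEX_CODES[known[0]]
    return -1


def build_robust_history(
    records: pd.DataFrame,
    array: DetectorArray,
    spec: SessionSpec,
    drop_unknown_status: bool = True,
) -> RobustDesignHistory:
    """Bin capture records into a robust-design site-level history.

    Detections are binned to calendar days, attributed to sites (either
    camera of a pair counts), and collapsed to at most one per site per
    occasion.  Records outside every primary period are excluded (logged);
    unknown-status individuals are dropped before construction.
    """
    site_ids = array.site_ids
    site_index = {s: j for j, s in enumerate(site_ids)}
    det_site = {d.detector_id: d.site_id for d in array.detectors}
    J, K, L = len(site_ids), spec.max_secondary, spec.n_primary

    usage = np.zeros((J, K, L), dtype=np.uint8)
    for l, (start, end) in enumerate(spec.primary_periods):
        for k in range((end - start).days):
            day = start + dt.timedelta(days=k)
            for s, j in site_index.items():
                if array.site_active(s, day):
                    usage[j, k, l] = 1

    recs = records.copy()
    if drop_unknown_status and len(recs):
        n_unknown = int((recs["status"] == "unknown").sum())
        if n_unknown:
            log.info("dropping %d unknown-status records before SCR history", n_unknown)
        recs = recs[recs["status"] != "unknown"]

    ids: list[str] = []
    idx: dict[str, int] = {}
    cells: list[tuple[int, int, int, int]] = []
    sex_codes: dict[str, list[str]] = {}
    n_masked = 0
    for row in recs.itertuples(index=False):
        loc = spec.locate(row.datetime.date())
        if loc is None:
            log.info("record of %s at %s outside primary periods; excluded",
                     row.individual_id, row.datetime)
            continue
        l, k = loc
        det = str(row.detector_id)
        if det not in det_site:
            raise ValueError(f"capture references unknown detector {det!r}")
        j = site_index[det_site[det]]
        if row.individual_id not in idx:
            idx[row.individual_id] = len(ids)
            ids.append(row.individual_id)
            sex_codes[row.individual_id] = []
        sex_codes[row.individual_id].append(row.sex)
        if usage[j, k, l] == 0:
            n_masked += 1
            continue
        cells.append((idx[row.individual_id], j, k, l))
    if n_masked:
        warnings.warn(
            f"{n_masked} record(s) fell on inactive site-days and were masked",
            stacklevel=2,
        )

    y = np.zeros((len(ids), J, K, L), dtype=np.uint8)
    for i, j, k, l in cells:
        y[i, j, k, l] = 1
    sexes = np.array([_individual_sex(pd.Series(sex_codes[i])) for i in ids], dtype=np.int8)
    return RobustDesignHistory(
        y=y, site_coords=array.site_coords(), usage=usage, sexes=sexes,
        individual_ids=ids, site_ids=site_ids,
    )


def collapse_occasions(
    history: RobustDesignHistory,
    days_per_occasion: int,
    period: int = 0,
) -> ClosedSessionHistory:
    """Collapse one primary period's daily occasions into multi-day blocks.

    An occasion detection is 1 if any constituent day is 1; occasion usage
    is the count of active days in the block (kept for effort scaling).
    Trailing days that do not fill a complete block are truncated.
    """
    if days_per_occasion < 1:
        raise ValueError("days_per_occasion must be >= 1")
    yl = history.y[:, :, :, period]
    ul = history.usage[:, :, period]
    n_days = yl.shape[2]
    n_occ = n_days // days_per_occasion
    if n_occ == 0:
        raise ValueError("period shorter than one occasion block")
    yl = yl[:, :, : n_occ * days_per_occasion]
    ul = ul[:, : n_occ * days_per_occasion]
    y = yl.reshape(yl.shape[0], yl.shape[1], n_occ, days_per_occasion).max(axis=3)
    usage = ul.reshape(ul.shape[0], n_occ, days_per_occasion).sum(axis=2)
    return ClosedSessionHistory(
        y=y, usage=usage, site_coords=history.site_coords, sexes=history.sexes,
        days_per_occasion=days_per_occasion, individual_ids=list(history.individual_ids),
    )


# ====================================================================== #
# 4-D history interchange format
# ====================================================================== #

def write_history(history: RobustDesignHistory, path) -> None:
    """Plain-text serialization of the 4-D binary array.

    Header line ``#dims n J K L`` followed by one ``i j k l`` row per
    detection, then ``#usage`` rows and site/sex metadata; round-trips
    exactly through :func:`read_history`.
    """
    n, J, K, L = history.y.shape
    with open(path, "w") as fh:
        fh.write(f"#dims {n} {J} {K} {L}\n")
        fh.write("#individuals " + " ".join(history.individual_ids) + "\n")
        fh.write("#sites " + " ".join(history.site_ids) + "\n")
        fh.write("#sexes " + " ".join(str(int(s)) for s in history.sexes) + "\n")
        for j in range(J):
            fh.write(f"#coord {float(history.site_coords[j, 0])!r} "
                     f"{float(history.site_coords[j, 1])!r}\n")
        for j, k, l in zip(*np.nonzero(history.usage)):
            fh.write(f"u {j} {k} {l}\n")
        for i, j, k, l in zip(*np.nonzero(history.y)):
            fh.write(f"y {i} {j} {k} {l}\n")


def read_history(path) -> RobustDesignHistory:
    dims = None
    ids: list[str] = []
    sites: list[str] = []
    sexes: list[int] = []
    coords: list[tuple[float, float]] = []
    y_cells, u_cells = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#dims":
                dims = tuple(int(p) for p in parts[1:])
            elif parts[0] == "#individuals":
                ids = parts[1:]
            elif parts[0] == "#sites":
                sites = parts[1:]
            elif parts[0] == "#sexes":
                sexes = [int(p) for p in parts[1:]]
            elif parts[0] == "#coord":
                coords.append((float(parts[1]), float(parts[2])))
            elif parts[0] == "u":
                u_cells.append(tuple(int(p) for p in parts[1:]))
            elif parts[0] == "y":
                y_cells.append(tuple(int(p) for p in parts[1:]))
    if dims is None:
        raise ValueError("missing #dims header")
    n, J, K, L = dims
    y = np.zeros((n, J, K, L), dtype=np.uint8)
    usage = np.zeros((J, K, L), dtype=np.uint8)
    for j, k, l in u_cells:
        usage[j, k, l] = 1
    for i, j, k, l in y_cells:
        y[i, j, k, l] = 1
    return RobustDesignHistory(
        y=y, site_coords=np.array(coords), usage=usage,
        sexes=np.array(sexes, dtype=np.int8), individual_ids=ids, site_ids=sites,
    )
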