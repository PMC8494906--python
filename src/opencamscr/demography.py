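"""Status classification and reproductive/age summaries.

Ages follow the biological ("lynx") year starting May 1, aligned with the
kitten birth pulse.  Status per individual-year: *juvenile* (detected
with the mother, under one lynx-year), *independent* (over one year, or
unknown age with proof of independence), or *unknown* (excluded from SCR
histories).  Independents are sub-flagged *floater* when they are a
previous-year juvenile in their second year of life, or an
unknown-origin first-appearance whose age cannot be determined.
Generation time is the mean age of resident reproducing females at their
first documented reproduction; the mean number of recruits is the
overall mean kitten count with the mother at the onset of winter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class StatusRules:
    """Thresholds and flags for individual-year status assignment."""

    juvenile_max_age: float = 1.0       # lynx-years; under this = juvenile
    floater_second_year: bool = True    # previous-year juvenile in year 2
    floater_unknown_first_appearance: bool = True


def classify_status(
    individuals: pd.DataFrame,
    records: pd.DataFrame | None = None,
    rules: StatusRules | None = None,
) -> pd.DataFrame:
    """Per-individual-year status table.

    ``individuals`` needs one row per individual-year with columns
    ``individual_id``, ``year`` (lynx-year of detection), ``birth_year``
    (NaN if unknown), ``with_mother`` (bool: detected accompanying its
    mother), ``proof_of_independence`` (bool) and ``first_appearance``
    (bool: first year the individual was ever seen).  ``records`` may
    supply reproduction rows (``female_id``, ``year``) used to detect the
    contradictory case of an individual classified as a kitten and as a
    reproducing female in the same year.

    Returns a DataFrame with ``status`` in {juvenile, independent,
    unknown}, a ``floater`` flag for independents, and ``exclude_from_scr``
    for unknown-status rows.
    """
    rules = rules or StatusRules()
    req = {"individual_id", "year", "birth_year", "with_mother",
           "proof_of_independence", "first_appearance"}
    if not req.issubset(individuals.columns):
        raise ValueError(f"individuals table needs columns {sorted(req)}")

    reproducing: set[tuple[str, int]] = set()
    if records is not None and len(records):
        reproducing = {
            (str(r.female_id), int(r.year)) for r in records.itertuples(index=False)
        }

    rows = []
    juvenile_years: dict[str, set[int]] = {}
    for row in individuals.sort_values(["individual_id", "year"]).itertuples(index=False):
        ind, year = str(row.individual_id), int(row.year)
        age = year - row.birth_year if pd.notna(row.birth_year) else np.nan
        status, floater = "unknown", False
        if pd.notna(age) and age < rules.juvenile_max_age and row.with_mother:
            status = "juvenile"
            if (ind, year) in reproducing:
                raise ValueError(
                    f"individual {ind!r} is both a kitten and a reproducing "
                    f"female in year {year}"
                )
            juvenile_years.setdefault(ind, set()).add(year)
        elif (pd.notna(age) and age >= rules.juvenile_max_age) or row.proof_of_independence:
            status = "independent"
            if rules.floater_second_year and (year - 1) in juvenile_years.get(ind, set()):
                floater = True
            if (
                rules.floater_unknown_first_appearance
                and pd.isna(row.birth_year)
                and row.first_appearance
            ):
                floater = True
        rows.append(
            {"individual_id": ind, "year": year, "age": age, "status": status,
             "floater": floater, "exclude_from_scr": status == "unknown"}
        )
    return pd.DataFrame(rows)


def generation_time(
    records: pd.DataFrame,
    exclude: tuple[str, ...] = (),
) -> tuple[float, int]:
    """Mean age of known-age reproducing females at first reproduction.

    ``records`` columns: ``female_id``, ``year``, ``n_kittens``,
    ``female_age`` (NaN if unknown).  Only known-age females contribute;
    ``exclude`` lists female ids to drop (e.g. flagged outliers — none
    are dropped by default).  Returns (mean age, number of females).
    """
    df = records[~records["female_id"].isin(exclude)]
    df = df[pd.notna(df["female_age"])]
    if len(df) == 0:
        raise ValueError("no known-age reproducing females")
    firsts = df.sort_values("year", kind="stable").groupby("female_id").first()
    return float(firsts["female_age"].mean()), int(len(firsts))


def mean_recruits(records: pd.DataFrame) -> tuple[float, tuple[int, int], int]:
    """Overall mean kitten count with the mother at the onset of winter.

    All reproduction records contribute (age known or not).  Returns
    (mean, (min, max), number of records).
    """
    if len(records) == 0:
        raise ValueError("no reproduction records")
    counts = records["n_kittens"].astype(int)
    if (counts < 1).any():
        raise ValueError("reproduction records require n_kittens >= 1")
    return float(counts.mean()), (int(counts.min()), int(counts.max())), int(len(counts))


def age_pyramid(individuals: pd.DataFrame) -> pd.DataFrame:
    """Counts by integer age and sex for known-age, known-sex independents.

    ``individuals`` columns: ``individual_id``, ``age`` (years), ``sex``
    ({F, M}).  Returns a table indexed by age with F and M count columns.
    """
    if len(individuals) == 0:
        return pd.DataFrame(columns=["F", "M"]).rename_axis("age")
    df = individuals[pd.notna(individuals["age"]) & individuals["sex"].isin(["F", "M"])]
    if len(df) == 0:
        return pd.DataFrame(columns=["F", "M"]).rename_axis("age")
    tab = (
        df.assign(age=df["age"].astype(int))
        .groupby(["age", "sex"]).size().unstack(fill_value=0)
        .reindex(columns=["F", "M"], fill_value=0)
    )
    tab.columns.name = None
    return tab
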