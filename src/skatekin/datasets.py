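"""Bundled reference tables.

``load_sibling_pairs`` returns the published Celtic Sea blue-skate
sibling-pair table (19 full- and half-sibling pairs with capture year,
position, sex, and total length per member).  Coordinates are stored as
printed ("49.32 N", "6.73 W") and parsed to signed decimal degrees
(west longitude negative).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .growth import GrowthParams, DEFAULT_GROWTH, age_from_length, assign_cohort


def _parse_coord(text: str) -> float:
    value, hemi = text.strip().split()
    sign = -1.0 if hemi.upper() in ("W", "S") else 1.0
    return sign * float(value)


def load_sibling_pairs() -> pd.DataFrame:
    """The 19 published sibling pairs, with signed decimal coordinates."""
    with resources.files("skatekin.data").joinpath(
            "celtic_sea_sibling_pairs.csv").open() as fh:
        df = pd.read_csv(fh)
    for side in ("1", "2"):
        df[f"lat{side}"] = df[f"lat{side}"].map(_parse_coord)
        df[f"lon{side}"] = df[f"lon{side}"].map(_parse_coord)
    return df


def sibling_pair_members(df: pd.DataFrame | None = None,
                         kinship: str | None = None) -> pd.DataFrame:
    """Long-format members of the sibling pairs (one row per capture).

    Individuals caught once but listed in several pairs appear once per
    pair row; callers wanting unique individuals should drop duplicates
    on ``id``.
    """
    if df is None:
        df = load_sibling_pairs()
    if kinship is not None:
        df = df[df["kinship"] == kinship]
    parts = []
    for side in ("1", "2"):
        sub = df[[f"id{side}", f"year{side}", f"lat{side}", f"lon{side}",
                  f"sex{side}", f"length{side}"]].copy()
        sub.columns = ["id", "year", "lat", "lon", "sex", "length"]
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def sibling_pair_cohorts(kinship: str = "HS",
                         params: GrowthParams = DEFAULT_GROWTH) -> pd.DataFrame:
    """Ages and birth cohorts for sibling-pair members via the growth curve."""
    members = sibling_pair_members(kinship=kinship).drop_duplicates("id")
    members = members.copy()
    members["age"] = members["length"].map(lambda L: age_from_length(L, params))
    members["birth_year"] = [assign_cohort(y, a)
                             for y, a in zip(members["year"], members["age"])]
    return members
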