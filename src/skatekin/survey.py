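"""Survey-derived metrics: CPUE and the spatial analysis of kin pairs.

Catch per unit effort standardises trammel-net catches by fishing effort
(net length in km times soak time in hours) and is reported both as
abundance (individuals km^-1 h^-1) and biomass (kg km^-1 h^-1), with
individual weights from the allometric length-weight relationship
W (g) = 0.0038 * L^3.1201.

The kin spatial analysis compares capture-location distances between
sibling pairs and all potential pairs with a two-sample Kolmogorov-
Smirnov statistic; because the all-pairs reference set is non-independent
and the distance distribution has heavy ties at zero (same-haul pairs),
the p-value is also computed by permutation of pair labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088


def weight_from_length(length_cm):
    """Allometric weight (g) from total length (cm): 0.0038 * L^3.1201."""
    L = np.asarray(length_cm, dtype=float)
    if np.any(L < 0):
        raise ValueError("length must be >= 0")
    out = 0.0038 * L ** 3.1201
    return out if out.ndim else float(out)


@dataclass
class EffortRecord:
    """One station-year haul: effort plus the lengths of the catch."""

    station: str
    year: int
    net_length_km: float
    soak_time_h: float
    lengths_cm: tuple

    def __post_init__(self) -> None:
        if self.net_length_km <= 0 or self.soak_time_h <= 0:
            raise ValueError("net length and soak time must be > 0")


def cpue(record: EffortRecord) -> tuple[float, float]:
    """(abundance, biomass) CPUE for one haul.

    Unit effort is net km x soak hours; abundance is count per unit
    effort, biomass is summed allometric weight (converted to kg) per
    unit effort.
    """
    effort = record.net_length_km * record.soak_time_h
    lengths = np.asarray(record.lengths_cm, dtype=float)
    abundance = lengths.size / effort
    biomass = float(weight_from_length(lengths).sum()) / 1000.0 / effort if lengths.size else 0.0
    return abundance, biomass


def annual_summary(records: list[EffortRecord],
                   prime_stations: set[str] | None = None) -> pd.DataFrame:
    """Yearly mean +/- SD CPUE over (a) all stations and (b) prime stations.

    Repeat visits to a station within a year are averaged within the
    station before averaging across stations.
    """
    rows = []
    for rec in records:
        a, b = cpue(rec)
        rows.append({"station": rec.station, "year": rec.year,
                     "abundance": a, "biomass": b})
    df = pd.DataFrame(rows)
    per_station = df.groupby(["year", "station"], as_index=False).mean()

    def _summ(sub: pd.DataFrame, scope: str) -> pd.DataFrame:
        g = sub.groupby("year").agg(
            abundance_mean=("abundance", "mean"),
            abundance_sd=("abundance", "std"),
            biomass_mean=("biomass", "mean"),
            biomass_sd=("biomass", "std"),
            n_stations=("station", "nunique"),
        ).reset_index()
        g.insert(0, "scope", scope)
        return g

    out = [_summ(per_station, "all")]
    if prime_stations:
        sub = per_station[per_station["station"].isin(prime_stations)]
        out.append(_summ(sub, "prime"))
    return pd.concat(out, ignore_index=True)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance (km) between decimal-degree coordinates."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    h = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    return out if out.ndim else float(out)


def kin_proximity_test(kin_distances, all_distances, n_perm: int = 9999,
                       rng=None) -> dict:
    """Are sibling pairs captured closer together than chance predicts?

    Two-sample KS of kin-pair distances against all potential-pair
    distances.  Returns the KS D, the asymptotic p, and a permutation p
    obtained by reshuffling which pairs carry the kin label.
    """
    rng = np.random.default_rng(rng)
    kin = np.asarray(kin_distances, dtype=float)
    ref = np.asarray(all_distances, dtype=float)
    if kin.size == 0 or ref.size == 0:
        raise ValueError("both distance sets must be non-empty")
    d_obs, p_asym = stats.ks_2samp(kin, ref)
    pool = ref  # reference = all potential pairs (kin pairs included)
    exceed = 0
    for _ in range(n_perm):
        lab = rng.choice(pool.size, size=kin.size, replace=False)
        d_perm = stats.ks_2samp(pool[lab], ref).statistic
        if d_perm >= d_obs:
            exceed += 1
    return {"D": float(d_obs), "p_asymptotic": float(p_asym),
            "p_permutation": (exceed + 1) / (n_perm + 1)}
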