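"""Independent validation of unplanned-share estimates against salvage logging.

Forest management typically responds to wind, bark-beetle and fire damage
with salvage logging, so national statistics on the fraction of fellings
that are salvage provide an independent (if volume- rather than area-based)
check on map-derived unplanned shares.  Area-based shares are compared to
volume-based salvage fractions without conversion; a perfect correlation is
not expected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


def unplanned_share(series: pd.DataFrame, unit_to_country: pd.Series) -> pd.DataFrame:
    """Per country and year: unplanned disturbed area / total disturbed area.

    ``unit_to_country`` maps unit_id -> country_id and must cover every unit
    in the series.  Country-years with zero total disturbance are excluded
    (flagged by their absence).
    """
    df = series.copy()
    missing = set(df["unit_id"]) - set(unit_to_country.index)
    if missing:
        raise ValueError(f"units without a country: {sorted(missing)}")
    df["country_id"] = df["unit_id"].map(unit_to_country)
    wide = (
        df.groupby(["country_id", "year", "cause"])["area_km2"]
        .sum()
        .unstack("cause", fill_value=0.0)
    )
    total = wide.sum(axis=1)
    out = (
        (wide.get("unplanned", 0.0) / total[total > 0])
        .dropna()
        .rename("unplanned_share")
        .reset_index()
    )
    return out


@dataclass
class ValidationResult:
    r_overall: float
    p_overall: float
    r_per_year_mean: float
    per_year: pd.DataFrame  # year, r, n_countries
    n_pairs: int
    pairs: pd.DataFrame


def correlate(shares: pd.DataFrame, salvage: pd.DataFrame) -> ValidationResult:
    """Pearson correlation between map shares and salvage fractions.

    The overall r pools all matched country-years; the per-year value is
    computed across countries within each year (years with >= 3 countries)
    and summarized by its unweighted mean.
    """
    pairs = shares.merge(salvage, on=["country_id", "year"])
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched country-year pairs (need >= 3)")
    r, p = pearsonr(pairs["unplanned_share"], pairs["salvage_fraction"])
    rows = []
    for year, grp in pairs.groupby("year"):
        if len(grp) >= 3 and grp["unplanned_share"].nunique() > 1 and grp[
            "salvage_fraction"
        ].nunique() > 1:
            ry, _ = pearsonr(grp["unplanned_share"], grp["salvage_fraction"])
            rows.append((year, float(ry), len(grp)))
    per_year = pd.DataFrame(rows, columns=["year", "r", "n_countries"])
    r_year = float(per_year["r"].mean()) if len(per_year) else np.nan
    return ValidationResult(float(r), float(p), r_year, per_year, len(pairs), pairs)
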