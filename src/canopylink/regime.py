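"""Disturbance-regime change analysis.

Attributed patch areas are aggregated to analysis units and years, the late
20th century (default 1986-2000, keeping 2000 with the earlier period so a
December-1999 storm recorded in 2000 stays with its period) is contrasted
with the early 21st century (2001-2020) by period means, and differences are
tested with the two-sample Van der Waerden normal-scores test.  Each unit is
then classified by the joint signs of its planned and unplanned changes into
the linked-change quadrants.  A period comparison is used instead of linear
trends because annual disturbance series are dominated by single large
events.  Per-unit p-values are mapped without multiple-testing correction,
mirroring how such unit-level significance maps are usually reported.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm, rankdata

from .gridio import unit_id_grid
from .patches import DisturbanceMap, Patch

log = logging.getLogger(__name__)

CAUSES = ("planned", "unplanned")
QUADRANTS = (
    "both_up",
    "both_down",
    "planned_up_unplanned_down",
    "planned_down_unplanned_up",
)


@dataclass
class PeriodSpec:
    period1: tuple[int, int] = (1986, 2000)
    period2: tuple[int, int] = (2001, 2020)
    alpha: float = 0.05

    def __post_init__(self):
        for per in (self.period1, self.period2):
            if per[1] - per[0] + 1 < 2:
                raise ValueError("each period needs at least 2 years")
        if not (self.period1[1] < self.period2[0] or self.period2[1] < self.period1[0]):
            raise ValueError("periods must be disjoint")

    def years1(self):
        return range(self.period1[0], self.period1[1] + 1)

    def years2(self):
        return range(self.period2[0], self.period2[1] + 1)


# ------------------------------------------------------------ aggregation


def aggregate_annual(
    patches: list[Patch],
    classes: pd.Series,
    units: pd.DataFrame,
    dmap: DisturbanceMap,
) -> pd.DataFrame:
    """Per unit, year and cause: disturbed canopy area in km^2.

    Each patch's pixels are allocated to the unit containing their centers,
    so a patch straddling a boundary splits in proportion to the pixel areas
    on each side.  Pixels outside every unit are logged and reported under
    unit_id -1.  The result is a complete (unit, year, cause) grid with
    explicit zeros.
    """
    ugrid = unit_id_grid(units, dmap.shape, dmap.pixel_size)
    px_km2 = dmap.pixel_size**2 / 1e6
    recs = []
    for p in patches:
        cause = classes.loc[p.patch_id]
        uids, counts = np.unique(ugrid[p.pixels[:, 0], p.pixels[:, 1]], return_counts=True)
        for uid, cnt in zip(uids, counts):
            recs.append((int(uid), p.year, cause, cnt * px_km2))
    df = pd.DataFrame(recs, columns=["unit_id", "year", "cause", "area_km2"])
    outside = df.loc[df["unit_id"] == -1, "area_km2"].sum()
    if outside > 0:
        log.info("%.4f km2 of patch area falls outside all units", outside)
    df = df[df["unit_id"] != -1]
    df = df.groupby(["unit_id", "year", "cause"], as_index=False)["area_km2"].sum()
    years = range(dmap.year_range[0], dmap.year_range[1] + 1)
    full = pd.MultiIndex.from_product(
        [sorted(units["unit_id"]), years, CAUSES], names=["unit_id", "year", "cause"]
    )
    out = (
        df.set_index(["unit_id", "year", "cause"])["area_km2"]
        .reindex(full, fill_value=0.0)
        .reset_index()
    )
    return out


# ------------------------------------------------------------ VdW test


@dataclass
class VdwResult:
    statistic: float  # Z in asymptotic mode, T (score sum of sample 2) in permutation
    p_value: float
    mode: str


def _normal_scores(pooled: np.ndarray) -> np.ndarray:
    n = len(pooled)
    ranks = rankdata(pooled)  # midranks for ties
    return norm.ppf(ranks / (n + 1.0))


def vdw_test(
    sample1,
    sample2,
    mode: str = "asymptotic",
    seed: int | None = None,
    n_perm: int = 10000,
) -> VdwResult:
    """Two-sample Van der Waerden normal-scores test (two-sided).

    Pooled values are ranked (midranks for ties) and transformed to normal
    scores a_i = Phi^-1(R_i/(N+1)); the statistic is the score sum of the
    second sample.  Asymptotic mode standardizes it by the exact permutation
    moments, Z = (T - n2*abar) / sqrt(n1*n2/(N*(N-1)) * sum((a-abar)^2)),
    and refers to the standard normal.  Permutation mode counts group
    reassignments with |T - E[T]| at least as large as observed, enumerating
    all C(N, n2) splits when that count is at most 1e5.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([x1, x2])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; p = 1 by convention", stacklevel=2)
        return VdwResult(0.0, 1.0, mode)
    a = _normal_scores(pooled)
    N = n1 + n2
    abar = a.mean()
    T = a[n1:].sum()
    if mode == "asymptotic":
        var = n1 * n2 / (N * (N - 1.0)) * np.sum((a - abar) ** 2)
        z = (T - n2 * abar) / np.sqrt(var)
        p = 2.0 * (1.0 - norm.cdf(abs(z)))
        return VdwResult(float(z), float(min(p, 1.0)), mode)
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")
    obs = abs(T - n2 * abar)
    tol = 1e-12
    if comb(N, n2, exact=True) <= 100_000:
        count = total = 0
        for idx in itertools.combinations(range(N), n2):
            t = a[list(idx)].sum()
            total += 1
            if abs(t - n2 * abar) >= obs - tol:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            t = a[rng.choice(N, size=n2, replace=False)].sum()
            if abs(t - n2 * abar) >= obs - tol:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return VdwResult(float(T), float(p), mode)


# ------------------------------------------------------------ period change


def _annual_values(series: pd.DataFrame, unit, cause, years) -> np.ndarray:
    sel = series[(series["unit_id"] == unit) & (series["cause"] == cause)]
    by_year = sel.set_index("year")["area_km2"]
    return by_year.reindex(list(years), fill_value=0.0).to_numpy()


def _quadrant(pct_planned: float, pct_unplanned: float) -> str:
    if pct_planned == 0 or pct_unplanned == 0:
        return "no_change"
    if pct_planned > 0:
        return "both_up" if pct_unplanned > 0 else "planned_up_unplanned_down"
    return "planned_down_unplanned_up" if pct_unplanned > 0 else "both_down"


def period_change(
    series: pd.DataFrame,
    units: pd.DataFrame,
    spec: PeriodSpec | None = None,
    mode: str = "asymptotic",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-unit change records plus the domain-level summary.

    For every unit and cause the two period means of annual disturbed area,
    the percent change and the Van der Waerden p-value are computed; units
    are then binned into the linked-change quadrants (exactly-zero change in
    a cause gives a fifth no_change bucket, and a cause with zero area in
    the first period flags the unit as excluded from percent-change maps
    while its areas still count in the totals).
    """
    spec = spec or PeriodSpec()
    records = []
    for unit in sorted(units["unit_id"]):
        rec = {"unit_id": unit}
        excluded = False
        for cause in CAUSES:
            v1 = _annual_values(series, unit, cause, spec.years1())
            v2 = _annual_values(series, unit, cause, spec.years2())
            m1, m2 = v1.mean(), v2.mean()
            rec[f"{cause}_mean1"] = m1
            rec[f"{cause}_mean2"] = m2
            if m1 == 0:
                rec[f"{cause}_pct_change"] = np.nan
                excluded = True
            else:
                rec[f"{cause}_pct_change"] = 100.0 * (m2 - m1) / m1
            res = vdw_test(v1, v2, mode=mode, seed=seed)
            rec[f"{cause}_p"] = res.p_value
            rec[f"{cause}_significant"] = res.p_value < spec.alpha
        rec["excluded"] = excluded
        rec["quadrant"] = (
            "excluded"
            if excluded
            else _quadrant(rec["planned_pct_change"], rec["unplanned_pct_change"])
        )
        records.append(rec)
    records = pd.DataFrame(records)

    # domain-wide summary from unit-summed annual totals
    tot = series.groupby(["year", "cause"])["area_km2"].sum().unstack("cause")
    summary = {}
    for cause in CAUSES:
        t1 = tot[cause].reindex(list(spec.years1()), fill_value=0.0).to_numpy()
        t2 = tot[cause].reindex(list(spec.years2()), fill_value=0.0).to_numpy()
        m1, m2 = t1.mean(), t2.mean()
        summary[f"{cause}_mean1_km2"] = float(m1)
        summary[f"{cause}_mean2_km2"] = float(m2)
        summary[f"{cause}_pct_change"] = float(100.0 * (m2 - m1) / m1) if m1 else np.nan
        summary[f"{cause}_p"] = vdw_test(t1, t2, mode=mode, seed=seed).p_value
    for per, years in (("period1", spec.years1()), ("period2", spec.years2())):
        sub = tot.reindex(list(years), fill_value=0.0)
        total = sub.to_numpy().sum()
        summary[f"unplanned_share_{per}"] = (
            float(sub["unplanned"].sum() / total) if total else np.nan
        )
    summary["quadrant_shares"] = quadrant_summary(records, units)
    summary["quadrant_shares_significant"] = quadrant_summary(
        records, units, significant_only=True, alpha=spec.alpha
    )
    return records, summary


def quadrant_summary(
    records: pd.DataFrame,
    units: pd.DataFrame,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Share of units and of forest area in each linked-change quadrant.

    Forest-area shares are weighted by unit forest_area_km2.  Percentages
    are relative to all units with an assigned quadrant, so with
    ``significant_only`` the quadrant rows count only units where both
    causes changed significantly while the denominator stays the full
    included set (the remainder appears as not_significant); units without
    an assignable percent change are reported as excluded and do not enter
    the denominator.
    """
    df = records.merge(units[["unit_id", "forest_area_km2"]], on="unit_id")
    quad = df["quadrant"].copy()
    if significant_only:
        insig = ~(df["planned_significant"] & df["unplanned_significant"])
        quad = quad.mask(insig & (quad != "excluded"), "not_significant")
    included = quad != "excluded"
    n_inc = included.sum()
    area_inc = df.loc[included, "forest_area_km2"].sum()
    rows = []
    for q in QUADRANTS + ("no_change", "not_significant", "excluded"):
        sel = quad == q
        if q == "excluded":
            if sel.any():
                rows.append((q, np.nan, np.nan))
            continue
        if q == "not_significant" and not significant_only:
            continue
        rows.append(
            (
                q,
                100.0 * sel.sum() / n_inc if n_inc else np.nan,
                100.0 * df.loc[sel, "forest_area_km2"].sum() / area_inc
                if area_inc
                else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["quadrant", "share_units_pct", "share_forest_area_pct"])
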