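"""Synthetic disturbance landscapes with a known generating regime.

The generator emulates the statistical structure the attribution and
regime-change analyses assume, on a planar pixel grid with no geographic
projection (meters, origin at the upper-left corner, y down):

* planned openings: many small compact patches (1-60 pixels) placed
  uniformly, at a steady rate with a gradual linear trend whose period-mean
  ratio equals ``planned_trend`` (+24% by default);
* wind: large irregular patches concentrated in storm pulse years and
  spatially clustered around storm centers;
* bark beetle: mid-size patches preferentially seeded near previous-year
  wind patches (seeding probability proportional to exp(-d/delta)),
  producing the wind-beetle amplification without asserting a mechanism;
* fire: large patches confined to a designated subregion;
* spectral layers: pre-disturbance index and disturbance magnitude drawn
  from class-conditional normals separated by ``spectral_separation``.

Events never overlap (the source maps record one disturbance year per
pixel), and annual pixel budgets are apportioned with largest-remainder
rounding so the realized period ratios and the long-run unplanned share
match the configuration by construction.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_dilation, distance_transform_edt
from shapely.geometry import box

from .patches import DisturbanceMap, Patch

log = logging.getLogger(__name__)

CAUSE_CODES = {"planned": 1, "wind": 2, "bark_beetle": 3, "fire": 4}
UNPLANNED_AGENTS = ("wind", "bark_beetle", "fire")
#: agent mix of the reference point database the generator emulates
REFERENCE_POINT_COUNTS = {"wind": 6986, "bark_beetle": 727, "fire": 1543}
#: points per labeled patch in that database (12571 points / 9256 patches)
POINTS_PER_PATCH = 1.36

# Between-patch sd of the spectral effect: harvests remove the canopy near
# completely and so have a narrow magnitude distribution, while the severity
# of wind, beetle and fire events varies from patch to patch.
_PATCH_SD_PLANNED = 0.25
_PATCH_SD_UNPLANNED = 0.5
_PIXEL_SD = 0.5  # sd of pixel noise around the patch effect


class PlacementError(RuntimeError):
    """Raised when an event cannot be placed on the remaining free pixels."""


@dataclass
class SimConfig:
    grid_shape: tuple[int, int] = (500, 500)
    pixel_size: float = 30.0
    year_start: int = 1986
    year_end: int = 2020
    split_year: int = 2000  # last year of the early period
    n_units: int = 16
    units_per_country: int = 4
    planned_rate: float = 0.0042  # fraction of forest pixels harvested / yr
    planned_trend: float = 1.24  # period-2 / period-1 rate ratio
    unplanned_trend: float = 1.30
    unplanned_share: float = 0.178  # long-run share of disturbed area
    storm_years: dict = field(
        default_factory=lambda: {1990: 1.0, 2000: 3.0, 2005: 1.0, 2007: 1.5, 2018: 2.0}
    )
    storm_boost: float = 8.0  # pulse weight multiplier per unit intensity
    storm_sigma_m: float = 1500.0  # scatter of wind patches around storm centers
    beetle_delta_m: float = 1500.0  # e-folding distance of beetle-follows-wind
    fire_region: tuple[float, float, float, float] = (0.55, 0.55, 1.0, 1.0)
    spectral_separation: float = 2.0  # standardized class mean difference
    planned_size: tuple[int, int] = (1, 60)
    planned_size_median_px: float = 9.0  # right-skewed harvest sizes
    planned_size_sigma: float = 0.8  # lognormal log-sd, clipped to planned_size
    wind_size: tuple[int, int] = (100, 600)  # storms shed many patches, not one blob
    beetle_size: tuple[int, int] = (10, 150)
    fire_size: tuple[int, int] = (50, 800)
    points_total: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.planned_rate < 0:
            raise ValueError("planned_rate must be >= 0")
        if self.planned_trend <= 0 or self.unplanned_trend <= 0:
            raise ValueError("trend ratios must be > 0")
        if not 0 < self.unplanned_share < 1:
            raise ValueError("unplanned_share must be in (0, 1)")
        yrs = set(self.years)
        if not set(self.storm_years) <= yrs:
            raise ValueError("storm_years must lie within the simulated years")
        if not self.year_start <= self.split_year < self.year_end:
            raise ValueError("split_year must fall inside the year range")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "planned_size", "wind_size", "beetle_size",
                    "fire_size", "fire_region"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "storm_years" in raw:
            raw["storm_years"] = {int(k): float(v) for k, v in raw["storm_years"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of the generated landscape.

    events: one row per placed event (event_id, agent, year, n_pixels);
    cause_grid / event_grid: per-pixel cause code and event id (-1 = none).
    """

    events: pd.DataFrame
    cause_grid: np.ndarray
    event_grid: np.ndarray
    config: SimConfig

    @property
    def unplanned_grid(self) -> np.ndarray:
        return np.isin(self.cause_grid, [CAUSE_CODES[a] for a in UNPLANNED_AGENTS])

    def patch_class(self, patches: list[Patch]) -> pd.Series:
        """Majority-vote true binary class (planned/unplanned) per patch."""
        unp = self.unplanned_grid
        out = {}
        for p in patches:
            frac = unp[p.pixels[:, 0], p.pixels[:, 1]].mean()
            out[p.patch_id] = "unplanned" if frac > 0.5 else "planned"
        return pd.Series(out, name="true_class")


@dataclass
class SimulatedLandscape:
    dmap: DisturbanceMap
    points: pd.DataFrame
    units: pd.DataFrame
    truth: SyntheticTruth
    salvage: pd.DataFrame | None = None


# ------------------------------------------------------------- budgeting


def _apportion(total: int, weights) -> np.ndarray:
    """Integer split of *total* proportional to *weights* (largest remainder)."""
    w = np.asarray(weights, dtype=float)
    if total <= 0 or w.sum() <= 0:
        return np.zeros(len(w), dtype=int)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = int(total - base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _planned_budgets(cfg: SimConfig) -> dict[int, int]:
    """Linearly ramped planned pixel budget whose period-mean ratio is the trend."""
    years = np.array(cfg.years)
    p1 = years[years <= cfg.split_year]
    p2 = years[years > cfg.split_year]
    g = (cfg.planned_trend - 1.0) / (p2.mean() - p1.mean())
    w = 1.0 + g * (years - p1.mean())
    n_px = cfg.grid_shape[0] * cfg.grid_shape[1]
    return {int(y): int(round(cfg.planned_rate * n_px * wy)) for y, wy in zip(years, w)}


def _unplanned_budgets(cfg: SimConfig, total_planned: int) -> dict[int, int]:
    """Pulsed unplanned pixel budget hitting the share and trend by construction."""
    total_unplanned = int(round(total_planned * cfg.unplanned_share / (1 - cfg.unplanned_share)))
    years = np.array(cfg.years)
    p1 = years[years <= cfg.split_year]
    p2 = years[years > cfg.split_year]
    r = cfg.unplanned_trend * len(p2) / len(p1)
    u1 = int(round(total_unplanned / (1.0 + r)))
    u2 = total_unplanned - u1
    out = {}
    for per_total, per_years in ((u1, p1), (u2, p2)):
        wts = [1.0 + cfg.storm_boost * cfg.storm_years.get(int(y), 0.0) for y in per_years]
        for y, b in zip(per_years, _apportion(per_total, wts)):
            out[int(y)] = int(b)
    return out


def _agent_fractions(year: int, cfg: SimConfig) -> dict[str, float]:
    if year in cfg.storm_years:
        return {"wind": 0.75, "bark_beetle": 0.10, "fire": 0.15}
    if (year - 1) in cfg.storm_years:
        return {"wind": 0.30, "bark_beetle": 0.50, "fire": 0.20}
    return {"wind": 0.45, "bark_beetle": 0.30, "fire": 0.25}


# ------------------------------------------------------------- placement


def _grow(rng, free, seed_rc, target, jitter):
    """Randomized priority-flood region growth over free pixels.

    Small jitter yields compact near-disk patches, large jitter irregular
    amoeba-like ones.  Growth never crosses already-disturbed pixels and
    may return fewer than *target* pixels when locally trapped.
    """
    nrows, ncols = free.shape
    r0, c0 = seed_rc
    if not free[r0, c0]:
        return []
    heap = [(0.0, r0, c0)]
    visited = {(r0, c0)}
    out = []
    while heap and len(out) < target:
        _, r, c = heapq.heappop(heap)
        out.append((r, c))
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and free[rr, cc] and (rr, cc) not in visited:
                visited.add((rr, cc))
                d = float(np.hypot(rr - r0, cc - c0))
                heapq.heappush(heap, (d + rng.uniform(0.0, jitter), rr, cc))
    return out


def _uniform_free_seed(rng, free, region=None, max_tries=2000):
    nrows, ncols = free.shape
    if region is None:
        region = (0, 0, nrows, ncols)
    r0, c0, r1, c1 = region
    for _ in range(max_tries):
        r = int(rng.integers(r0, r1))
        c = int(rng.integers(c0, c1))
        if free[r, c]:
            return r, c
    sub = free[r0:r1, c0:c1]
    idx = np.argwhere(sub)
    if len(idx) == 0:
        return None
    r, c = idx[rng.integers(len(idx))]
    return int(r + r0), int(c + c0)


def _log_uniform_size(rng, lo, hi):
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _dilate8(mask: np.ndarray) -> np.ndarray:
    return binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


class _Placer:
    def __init__(self, cfg: SimConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.year_grid = np.zeros(cfg.grid_shape, dtype=np.uint16)
        self.cause_grid = np.zeros(cfg.grid_shape, dtype=np.uint8)
        self.event_grid = np.full(cfg.grid_shape, -1, dtype=np.int32)
        self.free = np.ones(cfg.grid_shape, dtype=bool)
        # green-up adjacency constraint for harvests: no new planned pixel
        # may touch (queen) a planned pixel of the same or previous year
        self.harvest_blocked = np.zeros(cfg.grid_shape, dtype=bool)
        self.events = []

    def start_year(self, year):
        recent = (self.cause_grid == CAUSE_CODES["planned"]) & (
            self.year_grid == year - 1
        )
        self.harvest_blocked = _dilate8(recent)

    def commit(self, pixels, agent, year):
        pix = np.asarray(pixels)
        eid = len(self.events)
        self.year_grid[pix[:, 0], pix[:, 1]] = year
        self.cause_grid[pix[:, 0], pix[:, 1]] = CAUSE_CODES[agent]
        self.event_grid[pix[:, 0], pix[:, 1]] = eid
        self.free[pix[:, 0], pix[:, 1]] = False
        if agent == "planned":
            nrows, ncols = self.free.shape
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r = np.clip(pix[:, 0] + dr, 0, nrows - 1)
                    c = np.clip(pix[:, 1] + dc, 0, ncols - 1)
                    self.harvest_blocked[r, c] = True
        self.events.append(
            {"event_id": eid, "agent": agent, "year": year, "n_pixels": len(pix)}
        )

    def place_budget(self, agent, year, budget, size_range, jitter, seed_fn):
        remaining = budget
        failures = 0
        while remaining > 0:
            if agent == "planned":
                # harvest sizes are right-skewed: lognormal, clipped
                cfg = self.cfg
                size = int(
                    np.clip(
                        round(
                            np.exp(
                                self.rng.normal(
                                    np.log(cfg.planned_size_median_px),
                                    cfg.planned_size_sigma,
                                )
                            )
                        ),
                        size_range[0],
                        size_range[1],
                    )
                )
            else:
                size = _log_uniform_size(self.rng, *size_range)
            size = min(size, remaining)
            mask = (
                self.free & ~self.harvest_blocked
                if agent == "planned"
                else self.free
            )
            seed = seed_fn(mask)
            if seed is None:
                raise PlacementError(
                    f"cannot place {agent} event of {size} px in year {year}: "
                    "no free pixels left"
                )
            grown = _grow(self.rng, mask, seed, size, jitter)
            if not grown:
                failures += 1
                if failures > 200:
                    raise PlacementError(
                        f"cannot place {agent} event of {size} px in year {year}"
                    )
                continue
            failures = 0
            self.commit(grown, agent, year)
            remaining -= len(grown)


def _fire_region_px(cfg: SimConfig):
    nrows, ncols = cfg.grid_shape
    r0, c0, r1, c1 = cfg.fire_region
    return (int(r0 * nrows), int(c0 * ncols), max(int(r1 * nrows), int(r0 * nrows) + 1),
            max(int(c1 * ncols), int(c0 * ncols) + 1))


def _simulate_events(cfg: SimConfig, rng) -> _Placer:
    placer = _Placer(cfg, rng)
    planned_b = _planned_budgets(cfg)
    unplanned_b = _unplanned_budgets(cfg, sum(planned_b.values()))
    sigma_px = cfg.storm_sigma_m / cfg.pixel_size
    fire_rect = _fire_region_px(cfg)
    nrows, ncols = cfg.grid_shape

    for year in cfg.years:
        placer.start_year(year)
        fracs = _agent_fractions(year, cfg)
        agent_budget = dict(
            zip(
                UNPLANNED_AGENTS,
                _apportion(unplanned_b[year], [fracs[a] for a in UNPLANNED_AGENTS]),
            )
        )

        # --- wind: clustered around storm centers
        if agent_budget["wind"] > 0:
            intensity = cfg.storm_years.get(year, 0.0)
            n_centers = max(1, min(3, int(np.ceil(intensity)))) if intensity else 1
            centers = [
                (int(rng.integers(0, nrows)), int(rng.integers(0, ncols)))
                for _ in range(n_centers)
            ]

            def wind_seed(mask):
                for _ in range(200):
                    cr, cc = centers[int(rng.integers(len(centers)))]
                    r = int(round(cr + rng.normal(0, sigma_px)))
                    c = int(round(cc + rng.normal(0, sigma_px)))
                    if 0 <= r < nrows and 0 <= c < ncols and mask[r, c]:
                        return r, c
                return _uniform_free_seed(rng, mask)

            placer.place_budget("wind", year, agent_budget["wind"],
                                cfg.wind_size, jitter=4.0, seed_fn=wind_seed)

        # --- bark beetle: follows previous-year wind
        if agent_budget["bark_beetle"] > 0:
            prev_wind = (placer.cause_grid == CAUSE_CODES["wind"]) & (
                placer.year_grid == year - 1
            )
            if prev_wind.any():
                dist = distance_transform_edt(~prev_wind) * cfg.pixel_size
                weight = np.exp(-dist / cfg.beetle_delta_m)

                def beetle_seed(mask):
                    w = np.where(mask, weight, 0.0).ravel()
                    s = w.sum()
                    if s <= 0:
                        return _uniform_free_seed(rng, mask)
                    flat = int(rng.choice(len(w), p=w / s))
                    return flat // ncols, flat % ncols

            else:
                def beetle_seed(mask):
                    return _uniform_free_seed(rng, mask)

            placer.place_budget("bark_beetle", year, agent_budget["bark_beetle"],
                                cfg.beetle_size, jitter=2.0, seed_fn=beetle_seed)

        # --- fire: confined to the fire-prone subregion
        if agent_budget["fire"] > 0:
            placer.place_budget(
                "fire", year, agent_budget["fire"], cfg.fire_size, jitter=3.0,
                seed_fn=lambda mask: _uniform_free_seed(rng, mask, fire_rect),
            )

        # --- planned: small compact patches, uniform over the grid
        if planned_b[year] > 0:
            placer.place_budget(
                "planned", year, planned_b[year], cfg.planned_size, jitter=0.3,
                seed_fn=lambda mask: _uniform_free_seed(rng, mask),
            )
    return placer


def _spectral_layers(cfg: SimConfig, placer: _Placer, rng):
    """Class-conditional spectral bands.

    Pixel values are patch effect + pixel noise: the patch effect is
    N(mu_class, patch_sd) with a class-specific between-patch sd (narrow for
    harvests, wider for ecological agents) and pixels add N(0, _PIXEL_SD).
    The unplanned-minus-planned mean difference equals spectral_separation
    times the average marginal class sd for the disturbance magnitude (a
    Cohen's d between the class pixel distributions) and half of it for the
    pre-disturbance index.  Magnitude is undefined (NaN) on undisturbed
    pixels.
    """
    shape = cfg.grid_shape
    pre = rng.normal(0.0, _PIXEL_SD, shape)
    mag = np.full(shape, np.nan)
    marginal_sd = 0.5 * (
        float(np.hypot(_PATCH_SD_PLANNED, _PIXEL_SD))
        + float(np.hypot(_PATCH_SD_UNPLANNED, _PIXEL_SD))
    )
    unplanned_codes = {CAUSE_CODES[a] for a in UNPLANNED_AGENTS}
    for ev in placer.events:
        pix = np.argwhere(placer.event_grid == ev["event_id"])
        unplanned = CAUSE_CODES[ev["agent"]] in unplanned_codes
        patch_sd = _PATCH_SD_UNPLANNED if unplanned else _PATCH_SD_PLANNED
        mu_mag = cfg.spectral_separation * marginal_sd if unplanned else 0.0
        mu_pre = 0.5 * cfg.spectral_separation * marginal_sd if unplanned else 0.0
        eff_mag = rng.normal(mu_mag, patch_sd)
        eff_pre = rng.normal(mu_pre, patch_sd)
        n = len(pix)
        mag[pix[:, 0], pix[:, 1]] = eff_mag + rng.normal(0, _PIXEL_SD, n)
        pre[pix[:, 0], pix[:, 1]] = eff_pre + rng.normal(0, _PIXEL_SD, n)
    return pre, mag


# ------------------------------------------------------------- units


def _factor_pair(n: int) -> tuple[int, int]:
    best = (1, n)
    for a in range(1, int(np.sqrt(n)) + 1):
        if n % a == 0:
            best = (a, n // a)
    return best


def make_units(cfg: SimConfig) -> pd.DataFrame:
    """Square pseudo-administrative units tiling the grid.

    Units are numbered row-major; countries are contiguous runs of
    ``units_per_country`` consecutive units.
    """
    a, b = _factor_pair(cfg.n_units)
    nrows, ncols = cfg.grid_shape
    rb = np.round(np.linspace(0, nrows, a + 1)).astype(int)
    cb = np.round(np.linspace(0, ncols, b + 1)).astype(int)
    px = cfg.pixel_size
    rows = []
    for i in range(a):
        for j in range(b):
            uid = i * b + j
            geom = box(cb[j] * px, rb[i] * px, cb[j + 1] * px, rb[i + 1] * px)
            area = (rb[i + 1] - rb[i]) * (cb[j + 1] - cb[j]) * px**2 / 1e6
            rows.append(
                {
                    "unit_id": uid,
                    "country_id": uid // cfg.units_per_country,
                    "forest_area_km2": area,
                    "geometry": geom,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- points


def make_reference_points(cfg: SimConfig, truth: SyntheticTruth, rng) -> pd.DataFrame:
    """Agent-labeled point occurrences over a sample of unplanned events.

    The total point count defaults to 1.36 per unplanned event and is split
    across agents proportional to the wind/beetle/fire mix of the reference
    database being emulated; each sampled event receives at least one
    interior point, surplus points land in random events so that several
    points can share a patch.
    """
    ev = truth.events
    if ev.empty:
        return pd.DataFrame(columns=["x", "y", "year", "agent"])
    unp = ev[ev["agent"].isin(UNPLANNED_AGENTS)]
    if unp.empty:
        return pd.DataFrame(columns=["x", "y", "year", "agent"])
    n_total = cfg.points_total or int(round(POINTS_PER_PATCH * len(unp)))
    agents = [a for a in UNPLANNED_AGENTS if (unp["agent"] == a).any()]
    alloc = _apportion(n_total, [REFERENCE_POINT_COUNTS[a] for a in agents])
    px = cfg.pixel_size
    rows = []
    for agent, n_pts in zip(agents, alloc):
        ids = unp.loc[unp["agent"] == agent, "event_id"].to_numpy()
        if n_pts == 0 or len(ids) == 0:
            continue
        if n_pts <= len(ids):
            chosen = rng.choice(ids, size=n_pts, replace=False)
        else:
            extra = rng.choice(ids, size=n_pts - len(ids), replace=True)
            chosen = np.concatenate([ids, extra])
        for eid in chosen:
            pix = np.argwhere(truth.event_grid == eid)
            r, c = pix[int(rng.integers(len(pix)))]
            year = int(ev.loc[ev["event_id"] == eid, "year"].iloc[0])
            rows.append(
                {"x": (c + 0.5) * px, "y": (r + 0.5) * px, "year": year, "agent": agent}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- top level


def simulate_landscape(cfg: SimConfig) -> SimulatedLandscape:
    """Generate a full synthetic study system (raster, points, units, truth)."""
    rng = np.random.default_rng(cfg.seed)
    placer = _simulate_events(cfg, rng)
    pre, mag = _spectral_layers(cfg, placer, rng)
    dmap = DisturbanceMap(
        year_grid=placer.year_grid,
        pixel_size=cfg.pixel_size,
        pre_grid=pre,
        mag_grid=mag,
        year_range=(cfg.year_start, cfg.year_end),
    )
    truth = SyntheticTruth(
        events=pd.DataFrame(
            placer.events, columns=["event_id", "agent", "year", "n_pixels"]
        ),
        cause_grid=placer.cause_grid,
        event_grid=placer.event_grid,
        config=cfg,
    )
    units = make_units(cfg)
    points = make_reference_points(cfg, truth, rng)
    return SimulatedLandscape(dmap=dmap, points=points, units=units, truth=truth)


def truth_annual_series(truth: SyntheticTruth, units: pd.DataFrame) -> pd.DataFrame:
    """Attribution-free annual series from the true per-pixel causes."""
    from .gridio import unit_id_grid

    cfg = truth.config
    ugrid = unit_id_grid(units, cfg.grid_shape, cfg.pixel_size)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    disturbed = truth.cause_grid > 0
    u = ugrid[disturbed]
    codes = truth.cause_grid[disturbed]
    ev_year = truth.events.set_index("event_id")["year"]
    yr = ev_year.reindex(truth.event_grid[disturbed]).to_numpy()
    unplanned = np.isin(codes, [CAUSE_CODES[a] for a in UNPLANNED_AGENTS])
    px_km2 = cfg.pixel_size**2 / 1e6
    df = pd.DataFrame({"unit_id": u, "year": yr})
    df["cause"] = np.where(unplanned, "unplanned", "planned")
    df = df[df["unit_id"] >= 0]
    agg = df.groupby(["unit_id", "year", "cause"]).size().mul(px_km2)
    full = pd.MultiIndex.from_product(
        [sorted(units["unit_id"]), years, ("planned", "unplanned")],
        names=["unit_id", "year", "cause"],
    )
    return agg.reindex(full, fill_value=0.0).rename("area_km2").reset_index()


def simulate_salvage_table(
    truth_series: pd.DataFrame,
    units: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Country-year salvage-logging fractions from the true unplanned shares.

    salvage fraction = true unplanned area share + zero-mean Gaussian noise,
    truncated to [0, 1].  Country-years with zero total disturbance are
    omitted.  noise_sd = 0 reproduces the true shares exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from .validation import unplanned_share

    mapping = units.set_index("unit_id")["country_id"]
    shares = unplanned_share(truth_series, mapping)
    if year_range is not None:
        shares = shares[(shares["year"] >= year_range[0]) & (shares["year"] <= year_range[1])]
    rng = np.random.default_rng(seed)
    frac = shares["unplanned_share"].to_numpy()
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, len(frac))
    out = shares[["country_id", "year"]].copy()
    out["salvage_fraction"] = np.clip(frac, 0.0, 1.0)
    return out.reset_index(drop=True)
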