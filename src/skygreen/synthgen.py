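"""Synthetic scenes, towns and cohorts with known ground truth.

The study's raw inputs (street-view imagery, road GIS layers, questionnaire
cohort) are not redistributable, so every stage of the pipeline is exercised
on generated inputs whose truth is known by construction:

* ``render_scene`` draws rectangular vegetation patches (azimuth x elevation
  boxes, a crude stand-in for segmented tree crowns) into an equirectangular
  label mask and returns the analytic per-band visibility truth alongside.
* ``generate_town`` lays out a rectangular road grid with seeded park points
  and a 250-m population grid.
* ``simulate_cohort`` draws participants whose latent weekly walking minutes
  follow a linear model with district random intercepts and a known
  greenery effect, then snaps the latent value onto the achievable
  questionnaire grid so the outcome scorer round-trips exactly.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box

from .cohort import OutcomeCodebook
from .geoexposure import RoadNetwork
from .skyproj import BandSpec, EquirectangularMask, analytic_visibility_oracle

__all__ = [
    "TreeScene",
    "SimCohortSpec",
    "render_scene",
    "generate_town",
    "simulate_cohort",
    "random_scene",
    "synthetic_exposures",
]

#: Plausible marginal distribution of the five greenery indices, matching the
#: exposure summary scale of a mid-size Japanese city (% means and SDs for
#: overall visibility and the four elevation bands, horizon to zenith).
INDEX_MEANS = {"overall_pct": 6.98, "band1_pct": 37.82, "band2_pct": 22.05,
               "band3_pct": 10.94, "band4_pct": 5.54}
INDEX_SDS = {"overall_pct": 3.5, "band1_pct": 12.8, "band2_pct": 8.5,
             "band3_pct": 4.7, "band4_pct": 3.0}


@dataclass(frozen=True)
class TreeScene:
    """Rectangular vegetation patches on the panorama sphere.

    Patches are ``((az_lo, az_hi), (el_lo, el_hi))`` boxes in degrees;
    elevations may extend below the horizon, but only the sky half
    contributes to visibility truth.
    """

    patches: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    width_px: int = 1664
    vegetation_id: int = 8
    background_id: int = 2

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.width_px % 2:
            raise ValueError("width_px must be positive and even")
        for (_az, (el_lo, el_hi)) in self.patches:
            if not (-90.0 <= el_lo <= 90.0 and -90.0 <= el_hi <= 90.0):
                raise ValueError("patch elevations must lie in [-90, 90]")


def render_scene(
    scene: TreeScene, band_spec: BandSpec | None = None
) -> tuple[EquirectangularMask, tuple[float, tuple[float, ...]]]:
    """Rasterise a scene into a label mask and return its analytic truth.

    Pixels whose centre falls inside any patch get the vegetation id; the
    truth (overall and per-band percentages) comes from the closed-form
    oracle applied to the sky-half portions of the patches.
    """
    band_spec = band_spec or BandSpec()
    w = scene.width_px
    h = w // 2
    labels = np.full((h, w), scene.background_id, dtype=np.uint8)

    col_az = (np.arange(w) + 0.5) * 360.0 / w  # pixel-centre azimuths
    row_el = 90.0 - (np.arange(h) + 0.5) * 180.0 / h  # pixel-centre elevations
    for (az_lo, az_hi), (el_lo, el_hi) in scene.patches:
        if az_hi - az_lo >= 360.0:
            cmask = np.ones(w, dtype=bool)
        else:
            a0, a1 = az_lo % 360.0, az_hi % 360.0
            if a0 < a1:
                cmask = (col_az >= a0) & (col_az < a1)
            else:
                cmask = (col_az >= a0) | (col_az < a1)
        rmask = (row_el >= el_lo) & (row_el < el_hi)
        labels[np.ix_(rmask, cmask)] = scene.vegetation_id

    sky_patches = []
    for (az, (el_lo, el_hi)) in scene.patches:
        lo, hi = max(el_lo, 0.0), min(el_hi, 90.0)
        if hi > lo:
            sky_patches.append((az, (lo, hi)))
    truth = analytic_visibility_oracle(sky_patches, band_spec)
    mask = EquirectangularMask(
        labels=labels, vegetation_ids=frozenset({scene.vegetation_id})
    )
    return mask, truth


def random_scene(
    rng: np.random.Generator,
    n_patches: tuple[int, int] = (1, 6),
    width_px: int = 1664,
) -> TreeScene:
    """A random scene of sky-half vegetation boxes, for oracle-convergence
    tests and demo imagery."""
    k = int(rng.integers(n_patches[0], n_patches[1] + 1))
    patches = []
    for _ in range(k):
        az_lo = float(rng.uniform(0.0, 360.0))
        az_w = float(rng.uniform(10.0, 120.0))
        el_lo = float(rng.uniform(0.0, 80.0))
        el_hi = float(min(90.0, el_lo + rng.uniform(5.0, 50.0)))
        patches.append(((az_lo, az_lo + az_w), (el_lo, el_hi)))
    return TreeScene(patches=tuple(patches), width_px=width_px)


def generate_town(
    grid_size: int = 5,
    edge_length_m: float = 250.0,
    seed: int = 0,
    n_parks: int = 12,
    pop_cell_m: float = 250.0,
    mean_density_per_km2: float = 6000.0,
) -> tuple[RoadNetwork, list[tuple[float, float]], list[tuple[Polygon, float]]]:
    """A rectangular road grid with seeded parks and a population grid.

    Returns ``(roads, park_points, grid_cells)`` where ``grid_cells`` is a
    list of (cell polygon, population count) pairs on ``pop_cell_m`` cells.
    Deterministic under a fixed seed.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    rng = np.random.default_rng(seed)
    L = edge_length_m
    edges: dict[str, tuple[LineString, str]] = {}
    eid = 0
    for i in range(grid_size):
        for j in range(grid_size):
            x, y = i * L, j * L
            if i + 1 < grid_size:
                edges[f"e{eid:04d}"] = (
                    LineString([(x, y), (x + L, y)]), "street")
                eid += 1
            if j + 1 < grid_size:
                edges[f"e{eid:04d}"] = (
                    LineString([(x, y), (x, y + L)]), "street")
                eid += 1
    roads = RoadNetwork(edges=edges)

    extent = (grid_size - 1) * L
    parks = [
        (float(rng.uniform(0, extent)), float(rng.uniform(0, extent)))
        for _ in range(n_parks)
    ]

    cells: list[tuple[Polygon, float]] = []
    n_cells = int(np.ceil(extent / pop_cell_m)) if extent > 0 else 1
    for ci in range(n_cells):
        for cj in range(n_cells):
            poly = box(ci * pop_cell_m, cj * pop_cell_m,
                       (ci + 1) * pop_cell_m, (cj + 1) * pop_cell_m)
            density = float(rng.lognormal(np.log(mean_density_per_km2), 0.4))
            cells.append((poly, density * poly.area / 1e6))
    return roads, parks, cells


# questionnaire category frequencies, roughly matching a middle-aged to older
# community cohort
_AGE_LEVELS = ["20s", "30s", "40s", "50s", "60s", "70+"]
_AGE_P = [0.035, 0.092, 0.153, 0.177, 0.345, 0.198]
_MARITAL = ["married", "divorced/widowed", "single"]
_MARITAL_P = [0.77, 0.10, 0.13]
_EDU = ["junior high", "high school", "junior college", "college+", "other"]
_EDU_P = [0.034, 0.433, 0.271, 0.257, 0.005]
_ALCOHOL = ["never", "unable", "current", "former"]
_ALCOHOL_P = [0.593, 0.021, 0.329, 0.057]


@dataclass(frozen=True)
class SimCohortSpec:
    """Generative model of the simulated cohort.

    Latent minutes/week = intercept + sum_k beta_k * index_k + covariate
    effects + district intercept N(0, district_sd^2) + N(0, residual_sd^2),
    floored at 0 and snapped to the achievable questionnaire grid.
    """

    n_participants: int = 2000
    n_districts: int = 20
    true_beta: dict[str, float] = field(
        default_factory=lambda: {"overall_pct": 3.0})
    intercept: float = 105.0
    district_sd: float = 10.0
    residual_sd: float = 20.0
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "gender_female": -12.0, "age_per_level": 6.0, "working": -8.0})
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.district_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for v, r in self.missingness.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missingness rate for {v} must be in [0, 1)")


def synthetic_exposures(n: int, seed: int = 0) -> pd.DataFrame:
    """Draw per-participant greenery indices from the plausible marginals.

    Bands are positively correlated through a shared neighbourhood-greenness
    factor, as they are when derived from real street scenes.
    """
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=n)
    out = {}
    for col in INDEX_MEANS:
        z = 0.6 * shared + 0.8 * rng.normal(size=n)
        out[col] = np.clip(INDEX_MEANS[col] + INDEX_SDS[col] * z, 0.0, 100.0)
    return pd.DataFrame(out)


def _snap_to_grid(latent: np.ndarray, codebook: OutcomeCodebook
                  ) -> tuple[list[str], list[str], np.ndarray]:
    grid = codebook.grid().sort_values("minutes_per_week", kind="stable")
    # deduplicate grid values, keeping the first category pair per value
    grid = grid.drop_duplicates("minutes_per_week")
    values = grid["minutes_per_week"].to_numpy()
    idx = np.searchsorted(values, latent)
    idx = np.clip(idx, 1, len(values) - 1)
    lower_closer = (latent - values[idx - 1]) <= (values[idx] - latent)
    idx = np.where(lower_closer, idx - 1, idx)
    dur = grid["duration_cat"].to_numpy()[idx]
    freq = grid["frequency_cat"].to_numpy()[idx]
    return list(dur), list(freq), values[idx]


def simulate_cohort(
    spec: SimCohortSpec,
    exposures: pd.DataFrame,
    codebook: OutcomeCodebook | None = None,
    district_ids: "np.ndarray | list[str] | None" = None,
) -> pd.DataFrame:
    """Simulate a questionnaire cohort whose outcome scorer round-trips.

    ``exposures`` holds one row per participant with the greenery index
    columns (and optionally ``population_density_per_km2`` / ``n_parks``).
    The returned table carries the questionnaire categories, the scored
    outcome ``walking_min_per_week`` and the pre-snap latent value
    ``latent_min_per_week`` for diagnostics.
    """
    codebook = codebook or OutcomeCodebook()
    n = spec.n_participants
    if len(exposures) < n:
        raise ValueError("need one exposure row per participant")
    exposures = exposures.iloc[:n].reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)

    if district_ids is None:
        district = rng.integers(0, spec.n_districts, size=n)
        district_labels = np.array([f"d{d:02d}" for d in district])
        n_districts = spec.n_districts
    else:
        district_labels = np.asarray(district_ids)[:n]
        levels, district = np.unique(district_labels, return_inverse=True)
        n_districts = len(levels)
    district_effect = rng.normal(0.0, spec.district_sd, size=n_districts)

    age = rng.choice(_AGE_LEVELS, size=n, p=_AGE_P)
    gender = rng.choice(["male", "female"], size=n, p=[0.29, 0.71])
    marital = rng.choice(_MARITAL, size=n, p=_MARITAL_P)
    education = rng.choice(_EDU, size=n, p=_EDU_P)
    family_size = rng.choice([1, 2, 3, 4, 5, 6],
                             size=n, p=[0.113, 0.400, 0.230, 0.161, 0.058, 0.038])
    working = rng.random(size=n) < 0.508
    alcohol = rng.choice(_ALCOHOL, size=n, p=_ALCOHOL_P)

    eff = spec.covariate_effects
    latent = np.full(n, spec.intercept)
    for col, beta in spec.true_beta.items():
        latent = latent + beta * exposures[col].to_numpy()
    latent = latent + eff.get("gender_female", 0.0) * (gender == "female")
    age_idx = np.array([_AGE_LEVELS.index(a) for a in age])
    latent = latent + eff.get("age_per_level", 0.0) * age_idx
    latent = latent + eff.get("working", 0.0) * working
    latent = latent + district_effect[district]
    latent = latent + rng.normal(0.0, spec.residual_sd, size=n)
    latent = np.maximum(latent, 0.0)

    dur, freq, snapped = _snap_to_grid(latent, codebook)

    table = pd.DataFrame({
        "participant_id": [f"p{i:05d}" for i in range(n)],
        "district_id": district_labels,
        "age_group": age,
        "gender": gender,
        "marital": marital,
        "education": education,
        "family_size": family_size,
        "working": working,
        "alcohol": alcohol,
        "duration_cat": dur,
        "frequency_cat": freq,
        "walking_min_per_week": snapped,
        "latent_min_per_week": latent,
        "district_effect_min": district_effect[district],
    })
    for col in exposures.columns:
        table[col] = exposures[col].to_numpy()
    if "population_density_per_km2" not in table:
        table["population_density_per_km2"] = np.maximum(
            rng.normal(6500.0, 2000.0, size=n), 100.0)
    if "n_parks" not in table:
        table["n_parks"] = 12

    for var, rate in spec.missingness.items():
        hit = rng.random(size=n) < rate
        table.loc[hit, var] = np.nan
    return table
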