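"""End-to-end demonstration pipeline on a synthetic town.

Chains every stage — scene rendering, sky-map projection, road sampling,
panorama assignment, network-buffer exposure, cohort simulation and the
mixed-model fits — on generated inputs with known ground truth.  The run is
deterministic under a fixed seed and returns, besides the fitted tables, the
manifest of truths needed to assert correctness:

* per-site analytic visibility of each rendered scene;
* the generative cohort parameters; and
* for each of the five separately-fitted indices, the implied marginal slope
  (the least-squares projection of the true fixed-effect predictor onto that
  model's design), which is what an unbiased single-index fit estimates when
  the outcome was generated from the overall index alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import INDEX_COLUMNS, complete_case_filter, fit_table
from .geoexposure import (
    NeighbourhoodExposure,
    PipelineConfig,
    count_parks,
    neighbourhood_exposure,
    network_buffer,
    population_density,
    sample_points_along_network,
)
from .imagery import ImageMetadata, select_panorama
from .skyproj import BandSpec, SkyMapGeometry, build_skymap, green_visibility
from .synthgen import SimCohortSpec, TreeScene, generate_town, render_scene, simulate_cohort

__all__ = ["DemoResult", "run_demo", "site_visibility_table", "marginal_truths"]


@dataclass
class DemoResult:
    """Everything the demo computes, plus its ground truth manifest."""

    sites: pd.DataFrame  # per-site visibility (+ analytic truth columns)
    exposures: pd.DataFrame  # per-participant neighbourhood exposure
    cohort: pd.DataFrame  # simulated questionnaire cohort (included only)
    fits_a: pd.DataFrame  # Model A results, one row per index
    fits_b: pd.DataFrame  # Model B results
    truths: dict  # generative parameters and implied marginal slopes
    masks: dict = field(default_factory=dict)  # site_id -> label raster


def _greenness_field(x: np.ndarray, y: np.ndarray, extent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth spatial greenness in [0, 1]: a gradient plus a low-frequency
    ripple with seeded phases, so buffer means still vary across town."""
    ph = rng.uniform(0.0, 2.0 * np.pi, size=4)
    u, v = x / extent, y / extent
    f = (
        0.45 * u
        + 0.25 * np.sin(2.0 * np.pi * u + ph[0])
        + 0.25 * np.sin(2.0 * np.pi * v + ph[1])
        + 0.15 * np.sin(2.0 * np.pi * (u + v) + ph[2])
        + 0.15 * np.cos(2.0 * np.pi * (u - v) + ph[3])
    )
    lo, hi = f.min(), f.max()
    return (f - lo) / max(hi - lo, 1e-12)


def _scene_for_site(g: float, rng: np.random.Generator, width_px: int) -> TreeScene:
    """Street trees as azimuth/elevation boxes; greener sites get wider and
    taller crowns.  Two tree rows flank the street (near azimuths 90 and 270),
    elevation extents growing with local greenness."""
    patches = []
    n_trees = 1 + int(round(3 * g))
    for _ in range(n_trees):
        side = 90.0 if rng.random() < 0.5 else 270.0
        az_c = side + rng.normal(0.0, 40.0)
        az_w = 10.0 + 35.0 * g * rng.uniform(0.5, 1.5)
        el_lo = rng.uniform(-5.0, 8.0)
        el_hi = min(88.0, el_lo + 8.0 + 45.0 * g * rng.uniform(0.6, 1.4))
        if rng.random() < 0.25 * g:  # occasional overhead canopy
            el_hi = min(88.0, el_hi + 30.0)
        patches.append(((az_c - az_w / 2.0, az_c + az_w / 2.0),
                        (max(-90.0, el_lo), el_hi)))
    return TreeScene(patches=tuple(patches), width_px=width_px)


def site_visibility_table(
    sites, scenes: dict[str, TreeScene], assignments: dict[str, bool],
    cfg: PipelineConfig, width_px: int = 832,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Render and project each resolved site's scene; unresolved sites get
    missing visibility.  Returns the table and the rendered label rasters."""
    band_spec = BandSpec(cfg.band_edges_deg)
    rows, masks = [], {}
    for site in sites:
        rec = {"site_id": site.site_id, "x": site.x, "y": site.y,
               "edge_id": site.edge_id, "offset_m": site.offset_m}
        if assignments.get(site.site_id, False):
            mask, (true_overall, true_bands) = render_scene(
                scenes[site.site_id], band_spec)
            geom = SkyMapGeometry.for_mask(mask, cfg.map_resolution_px)
            vis = green_visibility(build_skymap(mask, geom, band_spec),
                                   site_id=site.site_id)
            rec["overall_pct"] = vis.overall_pct
            for i, p in enumerate(vis.band_pct):
                rec[f"band{i + 1}_pct"] = p
            rec["true_overall_pct"] = true_overall
            for i, p in enumerate(true_bands):
                rec[f"true_band{i + 1}_pct"] = p
            masks[site.site_id] = mask.labels
        else:
            for i in range(band_spec.n_bands):
                rec[f"band{i + 1}_pct"] = np.nan
                rec[f"true_band{i + 1}_pct"] = np.nan
            rec["overall_pct"] = np.nan
            rec["true_overall_pct"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows), masks


def marginal_truths(cohort: pd.DataFrame, spec: SimCohortSpec,
                    n_mc: int = 400, mc_seed: int = 123456789) -> dict[str, float]:
    """Implied per-index slope of each single-index Model A fit.

    A single-index fit estimates the projection of the measured outcome's
    conditional mean onto that model's design.  Marginally over the random
    district effects — the expectation under which the mixed-model slope is
    unbiased — that mean is E[snap(fixed predictor + district effect +
    noise) | X], which folds in both the linear generative model and the
    questionnaire measurement layer (zero-floor and snap to the achievable
    category grid); it is evaluated by Monte Carlo over the noise terms from
    the known generative parameters.  When only the overall index generates
    the outcome, the band truths are its spatially-induced projections.
    """
    from .cohort import OutcomeCodebook
    from .synthgen import _AGE_LEVELS, _snap_to_grid

    eff = spec.covariate_effects
    age_idx = cohort["age_group"].map(_AGE_LEVELS.index).to_numpy()
    m = np.full(len(cohort), spec.intercept, dtype=float)
    for col, beta in spec.true_beta.items():
        m = m + beta * cohort[col].to_numpy()
    m = m + eff.get("gender_female", 0.0) * (cohort["gender"] == "female").to_numpy()
    m = m + eff.get("age_per_level", 0.0) * age_idx
    m = m + eff.get("working", 0.0) * cohort["working"].to_numpy().astype(float)
    noise_sd = float(np.hypot(spec.district_sd, spec.residual_sd))

    rng = np.random.default_rng(mc_seed)
    codebook = OutcomeCodebook()
    mean_meas = np.zeros(len(cohort))
    for _ in range(n_mc):
        latent = np.maximum(m + rng.normal(0.0, noise_sd, size=len(cohort)), 0.0)
        _, _, snapped = _snap_to_grid(latent, codebook)
        mean_meas += snapped
    mean_meas /= n_mc

    covs = pd.get_dummies(cohort[["age_group", "gender"]], drop_first=True)
    truths = {}
    for name in INDEX_COLUMNS:
        X = np.column_stack([
            np.ones(len(cohort)),
            cohort[name].to_numpy(dtype=float),
            covs.to_numpy(dtype=float),
        ])
        coef, *_ = np.linalg.lstsq(X, mean_meas, rcond=None)
        truths[name] = float(coef[1])
    return truths


def run_demo(
    seed: int = 7,
    grid_size: int = 6,
    edge_length_m: float = 250.0,
    n_participants: int = 600,
    n_districts_side: int = 3,
    true_beta_overall: float = 3.0,
    missing_image_rate: float = 0.05,
    cfg: PipelineConfig | None = None,
    panorama_width_px: int = 832,
    fit_model_b: bool = True,
) -> DemoResult:
    """Run the full synthetic pipeline deterministically under one seed."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    extent = (grid_size - 1) * edge_length_m

    roads, parks, grid_cells = generate_town(
        grid_size, edge_length_m, seed=int(rng.integers(2**31)))
    sites = sample_points_along_network(roads, cfg.sample_interval_m)

    # panorama metadata: most sites get a nearby greener-month image, a few
    # only a distant candidate that falls outside the search radius
    alphabet = np.array(list("ABCDEFGHJKLMNPQRSTUVWXYZabcdefghjkmnpqrstuvwxyz0123456789-_"))
    assignments: dict[str, bool] = {}
    seasons: dict[str, str] = {}
    for site in sites:
        pano_id = "".join(rng.choice(alphabet, size=22))
        month = int(rng.choice([4, 5, 6, 7, 8, 9, 3, 10],
                               p=[0.1, 0.1, 0.25, 0.25, 0.15, 0.1, 0.02, 0.03]))
        offset = (rng.uniform(-6, 6), rng.uniform(-6, 6))
        if rng.random() < missing_image_rate:
            offset = (30.0, 30.0)  # beyond the 10 m search radius
        cand = ImageMetadata(
            pano_id=pano_id, lat=0.0, lon=0.0,
            x=site.x + offset[0], y=site.y + offset[1],
            year=int(rng.integers(2013, 2016)), month=month,
        )
        a = select_panorama(site.site_id, (site.x, site.y), [cand],
                            search_radius_m=cfg.image_search_radius_m)
        assignments[site.site_id] = not a.missing
        if not a.missing:
            seasons[site.site_id] = a.season

    # scenes driven by a smooth greenness field
    xs = np.array([s.x for s in sites])
    ys = np.array([s.y for s in sites])
    gfield = _greenness_field(xs, ys, extent, rng)
    scenes = {
        s.site_id: _scene_for_site(g, rng, panorama_width_px)
        for s, g in zip(sites, gfield)
    }
    site_table, masks = site_visibility_table(
        sites, scenes, assignments, cfg, panorama_width_px)

    # participants: residences scattered over the town, districts = blocks
    px = rng.uniform(0.0, extent, size=n_participants)
    py = rng.uniform(0.0, extent, size=n_participants)
    block = extent / n_districts_side + 1e-9
    exposures = []
    for i in range(n_participants):
        buf = network_buffer(roads, (px[i], py[i]), cfg.buffer_network_m,
                             cfg.snap_tolerance_m)
        corridor = buf.corridor_polygon(cfg.corridor_halfwidth_m)
        exp = neighbourhood_exposure(
            f"p{i:05d}", site_table, buf, cfg,
            population_density_per_km2=population_density(grid_cells, corridor),
            n_parks=count_parks(parks, corridor),
        )
        exposures.append(exp)
    exp_table = pd.DataFrame([{
        "participant_id": e.participant_id,
        "n_sites": e.n_sites,
        "overall_pct": e.mean_overall_pct,
        **{f"band{i + 1}_pct": p for i, p in enumerate(e.mean_band_pct)},
        "population_density_per_km2": e.population_density_per_km2,
        "n_parks": e.n_parks,
        "included": e.included,
        "x": px[i], "y": py[i],
        "district_id": f"d{int(px[i] // block)}{int(py[i] // block)}",
    } for i, e in enumerate(exposures)])

    included = exp_table[exp_table["included"]].reset_index(drop=True)
    spec = SimCohortSpec(
        n_participants=len(included),
        n_districts=n_districts_side**2,
        true_beta={"overall_pct": true_beta_overall},
        seed=int(rng.integers(2**31)),
    )
    cohort = simulate_cohort(
        spec,
        included[INDEX_COLUMNS + ["population_density_per_km2", "n_parks"]],
        district_ids=included["district_id"].to_numpy(),
    )
    cohort["participant_id"] = included["participant_id"].to_numpy()

    cohort_cc, _removed = complete_case_filter(cohort)
    fits_a = fit_table(cohort_cc, "A")
    fits_b = fit_table(cohort_cc, "B") if fit_model_b else pd.DataFrame()

    truths = {
        "true_beta": dict(spec.true_beta),
        "intercept": spec.intercept,
        "district_sd": spec.district_sd,
        "residual_sd": spec.residual_sd,
        "marginal_beta": marginal_truths(cohort_cc, spec),
        "n_sites": len(sites),
        "n_sites_resolved": int(sum(assignments.values())),
        "n_participants_included": len(included),
        "seasons": seasons,
    }
    return DemoResult(
        sites=site_table, exposures=exp_table, cohort=cohort_cc,
        fits_a=fits_a, fits_b=fits_b, truths=truths, masks=masks,
    )
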