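"""Hemispheric sky-map projection of equirectangular label masks.

A street-view panorama in equirectangular projection covers 360° of azimuth
(columns) by 180° of elevation (rows, zenith at the top row).  The upper
hemisphere of such a panorama can be re-rendered as a *sky map*: a disc whose
centre is the zenith (elevation 90°) and whose rim is the horizon (elevation
0°), analogous to a hemispherical fisheye photograph.  Green visibility is
then the share of disc pixels carrying a vegetation class label, overall and
stratified into elevation ("latitude") bands of the virtual hemisphere.

Two projection dialects are provided:

``orthographic_elevation`` (default)
    The disc is orthographic in elevation: a sky direction at elevation φ
    lands at polar radius r = R·cosφ.  Panorama rows map linearly to
    elevation, the equirectangular convention.

``literal_formula``
    Reproduces verbatim the published mapping Y = (R/r)·√(R²−r²) with
    R = W/2π, clipping Y to the sky half of the panorama.  Under
    r = R·cosφ this Y equals R·tanφ, which is unbounded at the zenith;
    the dialect exists for reproduction studies only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "EquirectangularMask",
    "SkyMapGeometry",
    "SkyMap",
    "BandSpec",
    "GreenVisibilityRecord",
    "ProjectionDialect",
    "build_skymap",
    "band_area_fraction",
    "green_visibility",
    "analytic_visibility_oracle",
]

OUTSIDE_DISC = -1
NON_VEGETATION = 0
VEGETATION = 1


class ProjectionDialect(str, enum.Enum):
    ORTHOGRAPHIC_ELEVATION = "orthographic_elevation"
    LITERAL_FORMULA = "literal_formula"


class ShapeError(ValueError):
    """Raised for a panorama whose height is not half its width."""


class GeometryError(ValueError):
    """Raised for a degenerate sky-map geometry."""


class ResolutionError(ValueError):
    """Raised when the raster is too coarse to populate every band."""


@dataclass(frozen=True)
class EquirectangularMask:
    """A full-panorama per-pixel class-label raster.

    Columns map linearly to azimuth [0°, 360°); rows map linearly to
    elevation with the top row at +90° (zenith) and the bottom row at −90°.

    Parameters
    ----------
    labels
        ``(H, W)`` integer array of class ids, one label per pixel.
    vegetation_ids
        Class ids counted as green (default ``{8}``, the Cityscapes
        vegetation train id).
    """

    labels: np.ndarray
    vegetation_ids: frozenset[int] = frozenset({8})

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ShapeError(f"labels must be 2-D, got shape {labels.shape}")
        h, w = labels.shape
        if w != 2 * h:
            raise ShapeError(
                f"equirectangular panorama requires H = W/2, got W={w}, H={h}"
            )
        if not self.vegetation_ids:
            raise ValueError("vegetation_ids must be non-empty")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "vegetation_ids", frozenset(self.vegetation_ids))

    @property
    def width_px(self) -> int:
        return self.labels.shape[1]

    @property
    def height_px(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class SkyMapGeometry:
    """Geometry of the square sky-map raster.

    ``radius_R`` is the sky-chart radius in source-pixel units, R = W/2π by
    convention; it only enters the ``literal_formula`` dialect, where the
    published relation is applied in source-pixel units.
    """

    radius_R: float
    map_resolution_px: int = 1024
    projection_dialect: ProjectionDialect = ProjectionDialect.ORTHOGRAPHIC_ELEVATION

    def __post_init__(self) -> None:
        if self.radius_R <= 0:
            raise GeometryError("radius_R must be positive")
        if self.map_resolution_px < 64 or self.map_resolution_px % 2:
            raise GeometryError("map_resolution_px must be even and >= 64")
        object.__setattr__(
            self, "projection_dialect", ProjectionDialect(self.projection_dialect)
        )

    @classmethod
    def for_mask(
        cls,
        mask: EquirectangularMask,
        map_resolution_px: int = 1024,
        projection_dialect: ProjectionDialect = ProjectionDialect.ORTHOGRAPHIC_ELEVATION,
    ) -> "SkyMapGeometry":
        return cls(
            radius_R=mask.width_px / (2.0 * np.pi),
            map_resolution_px=map_resolution_px,
            projection_dialect=projection_dialect,
        )


@dataclass(frozen=True)
class BandSpec:
    """Elevation-band boundaries in degrees, horizon to zenith.

    Band *b* covers ``[edges[b], edges[b+1])`` with the top band closed at
    90°, so every sky direction belongs to exactly one band.
    """

    edges_deg: tuple[float, ...] = (0.0, 22.5, 45.0, 67.5, 90.0)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges_deg)
        if len(edges) < 2:
            raise ValueError("need at least two band edges")
        if edges[0] != 0.0 or edges[-1] != 90.0:
            raise ValueError("band edges must start at 0 and end at 90 degrees")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        object.__setattr__(self, "edges_deg", edges)

    @property
    def n_bands(self) -> int:
        return len(self.edges_deg) - 1

    def band_of(self, elevation_deg: np.ndarray) -> np.ndarray:
        """Band index of each elevation; the top band is closed at 90°."""
        idx = np.searchsorted(self.edges_deg, elevation_deg, side="right") - 1
        return np.clip(idx, 0, self.n_bands - 1)


@dataclass(frozen=True)
class SkyMap:
    """A projected hemispheric disc raster plus its per-pixel band index."""

    geometry: SkyMapGeometry
    pixels: np.ndarray  # (S, S) in {OUTSIDE_DISC, NON_VEGETATION, VEGETATION}
    band_of_pixel: np.ndarray  # (S, S), OUTSIDE_DISC outside the disc
    band_spec: BandSpec

    @property
    def in_disc(self) -> np.ndarray:
        return self.pixels != OUTSIDE_DISC


@dataclass(frozen=True)
class GreenVisibilityRecord:
    """Overall and per-band green visibility of one site's sky map."""

    site_id: str
    overall_pct: float
    band_pct: tuple[float, ...]
    n_disc_pixels: int
    n_band_pixels: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.n_band_pixels) != self.n_disc_pixels:
            raise ValueError("band pixel counts must sum to disc pixel count")


def _disc_coordinates(resolution: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised polar coordinates of pixel centres; r_norm in R units."""
    s = resolution
    # pixel centres, disc radius = s/2 in raster units
    c = (np.arange(s) + 0.5) - s / 2.0
    xx, yy = np.meshgrid(c, -c)  # north (azimuth 0) up, azimuth clockwise
    r_norm = np.hypot(xx, yy) / (s / 2.0)
    theta = np.arctan2(xx, yy)  # 0 at up, increasing clockwise (east of north)
    theta = np.mod(theta, 2.0 * np.pi)
    inside = r_norm <= 1.0
    return r_norm, theta, inside


@lru_cache(maxsize=8)
def _inverse_mapping(
    w: int, h: int, geometry: SkyMapGeometry, band_spec: BandSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cached (rows, cols, inside, band) lookup for one panorama geometry.

    The inverse map depends only on the panorama shape, the sky-map geometry
    and the band spec, so projecting a batch of same-shaped masks reduces to
    one fancy-indexing pass per mask.
    """
    r_norm, theta, inside = _disc_coordinates(geometry.map_resolution_px)

    if geometry.projection_dialect is ProjectionDialect.ORTHOGRAPHIC_ELEVATION:
        # r = R cos(phi)  =>  phi = arccos(r/R); zenith pixel gets phi = 90.
        phi = np.degrees(np.arccos(np.clip(r_norm, 0.0, 1.0)))
        # equirectangular rows: row 0 centre at +90 - 90/h degrees... map
        # elevation linearly: row = (90 - phi)/180 * h, nearest pixel.
        rows = np.clip(((90.0 - phi) / 180.0 * h).astype(np.intp), 0, h - 1)
    else:
        # literal published relation, in source-pixel units: R = W/2pi,
        # Y = (R/r)*sqrt(R^2 - r^2) measured upward from the horizon row.
        R = geometry.radius_R
        r_px = r_norm * R
        with np.errstate(divide="ignore", invalid="ignore"):
            y_src = (R / r_px) * np.sqrt(np.maximum(R * R - r_px * r_px, 0.0))
        y_src = np.where(r_px == 0.0, np.inf, y_src)
        # horizon = row h/2; clip into the sky half [0, h/2 - 1]
        rows = np.clip((h / 2.0 - 1.0 - y_src), 0, h / 2.0 - 1.0)
        rows = np.nan_to_num(rows, nan=0.0, posinf=0.0).astype(np.intp)
        phi = np.degrees(np.arccos(np.clip(r_norm, 0.0, 1.0)))  # banding only

    cols = np.mod((theta / (2.0 * np.pi) * w).astype(np.intp), w)

    band = np.full(r_norm.shape, OUTSIDE_DISC, dtype=np.int16)
    band[inside] = band_spec.band_of(phi[inside])
    for arr in (rows, cols, inside, band):
        arr.setflags(write=False)
    return rows, cols, inside, band


def build_skymap(mask: EquirectangularMask, geometry: SkyMapGeometry,
                 band_spec: BandSpec | None = None) -> SkyMap:
    """Project the sky half of an equirectangular mask onto a hemispheric disc.

    Every in-disc output pixel is assigned by inverse mapping: from its polar
    coordinates (r, θ) the sky direction (azimuth, elevation) is recovered and
    the source mask is sampled at the nearest pixel.  Labels are categorical,
    so nearest-neighbour sampling is the only admissible interpolation.
    """
    band_spec = band_spec or BandSpec()
    w, h = mask.width_px, mask.height_px
    rows, cols, inside, band = _inverse_mapping(w, h, geometry, band_spec)

    sampled = mask.labels[rows, cols]
    veg_ids = np.fromiter(mask.vegetation_ids, dtype=np.int64)
    is_veg = np.isin(sampled, veg_ids)

    pixels = np.full(sampled.shape, OUTSIDE_DISC, dtype=np.int8)
    pixels[inside] = np.where(is_veg[inside], VEGETATION, NON_VEGETATION)
    return SkyMap(geometry=geometry, pixels=pixels, band_of_pixel=band,
                  band_spec=band_spec)


def band_area_fraction(band_index: int, spec: BandSpec | None = None) -> float:
    """Exact share of disc area occupied by one elevation band.

    Under the orthographic mapping r = R·cosφ, the annulus for elevations
    [lo, hi) has area fraction cos²(lo) − cos²(hi); the fractions over all
    bands sum to 1.
    """
    spec = spec or BandSpec()
    if not 0 <= band_index < spec.n_bands:
        raise IndexError(f"band index {band_index} out of range 0..{spec.n_bands - 1}")
    lo, hi = spec.edges_deg[band_index], spec.edges_deg[band_index + 1]
    return float(np.cos(np.radians(lo)) ** 2 - np.cos(np.radians(hi)) ** 2)


def green_visibility(skymap: SkyMap, spec: BandSpec | None = None,
                     site_id: str = "") -> GreenVisibilityRecord:
    """Overall and per-band percentage of vegetation pixels in the disc.

    The overall denominator is *all* in-disc pixels — the whole hemisphere
    above the horizon including sky, buildings and other objects.
    """
    spec = spec or skymap.band_spec
    if spec.edges_deg != skymap.band_spec.edges_deg:
        raise ValueError("band spec differs from the one the sky map was built with")
    inside = skymap.in_disc
    n_disc = int(inside.sum())
    if n_disc == 0:
        raise GeometryError("sky map contains no in-disc pixels")
    veg = skymap.pixels == VEGETATION

    band_counts: list[int] = []
    band_pcts: list[float] = []
    for b in range(spec.n_bands):
        in_band = skymap.band_of_pixel == b
        n_b = int(in_band.sum())
        if n_b == 0:
            raise ResolutionError(
                f"band {b} contains zero pixels at resolution "
                f"{skymap.geometry.map_resolution_px}; increase map_resolution_px"
            )
        band_counts.append(n_b)
        band_pcts.append(100.0 * int((veg & in_band).sum()) / n_b)

    overall = 100.0 * int(veg.sum()) / n_disc
    return GreenVisibilityRecord(
        site_id=site_id,
        overall_pct=overall,
        band_pct=tuple(band_pcts),
        n_disc_pixels=n_disc,
        n_band_pixels=tuple(band_counts),
    )


def _normalise_patches(
    patches: Sequence[tuple[tuple[float, float], tuple[float, float]]],
) -> list[tuple[float, float, float, float]]:
    """Split azimuth-wrapping patches and validate elevation ranges."""
    out: list[tuple[float, float, float, float]] = []
    for (az_lo, az_hi), (el_lo, el_hi) in patches:
        if not (0.0 <= el_lo <= 90.0 and 0.0 <= el_hi <= 90.0):
            raise ValueError(
                f"patch elevation [{el_lo}, {el_hi}] outside [0, 90] degrees"
            )
        if el_hi <= el_lo or az_hi <= az_lo:
            continue  # empty patch
        if az_hi - az_lo >= 360.0:
            out.append((0.0, 360.0, el_lo, el_hi))
            continue
        a0, a1 = az_lo % 360.0, az_hi % 360.0
        if a1 > a0:
            out.append((a0, a1, el_lo, el_hi))
        else:  # wraps past 360
            out.append((a0, 360.0, el_lo, el_hi))
            out.append((0.0, a1, el_lo, el_hi))
    return out


def _union_length(intervals: list[tuple[float, float]]) -> float:
    total, end = 0.0, -np.inf
    for lo, hi in sorted(intervals):
        if lo > end:
            total += hi - lo
            end = hi
        elif hi > end:
            total += hi - end
            end = hi
    return total


def analytic_visibility_oracle(
    patches: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    spec: BandSpec | None = None,
) -> tuple[float, tuple[float, ...]]:
    """Closed-form visibility of a scene of rectangular vegetation patches.

    Each patch is ``((az_lo, az_hi), (el_lo, el_hi))`` in degrees.  Overlaps
    are merged exactly by a sweep over elevation slabs: within a slab the
    azimuth union length is constant, and the orthographic disc measure of a
    slab [a, b] is cos²(a) − cos²(b).

    Returns ``(overall_pct, band_pct)``.
    """
    spec = spec or BandSpec()
    norm = _normalise_patches(patches)
    band_veg = np.zeros(spec.n_bands)  # vegetated area, disc-fraction units

    cuts = sorted({e for p in norm for e in (p[2], p[3])} | set(spec.edges_deg))
    for a, b in zip(cuts, cuts[1:]):
        az_ints = [(p[0], p[1]) for p in norm if p[2] <= a and p[3] >= b]
        if not az_ints:
            continue
        frac_az = _union_length(az_ints) / 360.0
        slab_area = np.cos(np.radians(a)) ** 2 - np.cos(np.radians(b)) ** 2
        mid = 0.5 * (a + b)
        band_veg[spec.band_of(np.array(mid))] += frac_az * slab_area

    band_areas = np.array([band_area_fraction(b, spec) for b in range(spec.n_bands)])
    band_pct = 100.0 * band_veg / band_areas
    overall = 100.0 * band_veg.sum()  # band areas sum to 1
    return float(overall), tuple(float(p) for p in band_pct)
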