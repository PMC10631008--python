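"""Panorama selection and seasonality bookkeeping.

Street-view panoramas come with a metadata record (22-character PanoID,
coordinates, acquisition year/month, heading).  For every road sample site
the panorama is chosen among candidates within a 10 m search radius, with a
seasonal preference: images from the greener months (April–September) are
preferred over winter-half images regardless of distance, and within the
preferred stratum the nearest image wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageMetadata",
    "SiteImageAssignment",
    "select_panorama",
    "season_summary",
    "season_summary_from_counts",
    "vegetation_mask",
    "season_of_month",
]

SEASONS = ("spring", "summer", "autumn", "winter")

_SEASON_BY_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of_month(month: int) -> str:
    """Meteorological season: Mar–May spring, Jun–Aug summer, Sep–Nov autumn,
    Dec–Feb winter."""
    try:
        return _SEASON_BY_MONTH[int(month)]
    except KeyError:
        raise ValueError(f"month must be 1..12, got {month}") from None


@dataclass(frozen=True)
class ImageMetadata:
    """One panorama's metadata record."""

    pano_id: str
    lat: float
    lon: float
    x: float
    y: float
    year: int
    month: int
    heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if len(self.pano_id) != 22:
            raise ValueError(f"pano_id must be 22 characters, got {self.pano_id!r}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")


@dataclass(frozen=True)
class SiteImageAssignment:
    """The panorama chosen for one site, or a missing marker."""

    site_id: str
    chosen: ImageMetadata | None
    distance_m: float = float("nan")
    season: str | None = None

    @property
    def missing(self) -> bool:
        return self.chosen is None


def select_panorama(
    site_id: str,
    site_xy: tuple[float, float],
    candidates: Sequence[ImageMetadata],
    search_radius_m: float = 10.0,
    year_range: tuple[int, int] = (2013, 2015),
    green_months: frozenset[int] = frozenset(range(4, 10)),
) -> SiteImageAssignment:
    """Choose the panorama for a site under the proximity and seasonal rules.

    Among candidates within ``search_radius_m`` (projected metres) and
    ``year_range``, any greener-month image (April–September by default) is
    preferred over any other, however close; within the preferred stratum the
    nearest wins, then the latest year, then the lexicographically smallest
    PanoID.  With no candidate in radius the assignment is missing.
    """
    if search_radius_m < 0:
        raise ValueError("search_radius_m must be non-negative")
    sx, sy = site_xy
    eligible: list[tuple[float, ImageMetadata]] = []
    for c in candidates:
        if not year_range[0] <= c.year <= year_range[1]:
            continue
        d = float(np.hypot(c.x - sx, c.y - sy))
        if d <= search_radius_m:
            eligible.append((d, c))
    if not eligible:
        return SiteImageAssignment(site_id=site_id, chosen=None)

    green = [(d, c) for d, c in eligible if c.month in green_months]
    pool = green if green else eligible
    d, chosen = min(pool, key=lambda dc: (dc[0], -dc[1].year, dc[1].pano_id))
    return SiteImageAssignment(
        site_id=site_id,
        chosen=chosen,
        distance_m=d,
        season=season_of_month(chosen.month),
    )


def season_summary(assignments: Iterable[SiteImageAssignment]) -> pd.DataFrame:
    """Counts and two-decimal percentages per season over resolved sites.

    Percentages are computed over non-missing assignments only.
    """
    counts = dict.fromkeys(SEASONS, 0)
    for a in assignments:
        if not a.missing:
            counts[a.season] += 1
    return season_summary_from_counts(counts)


def season_summary_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Season table from raw per-season counts (two-decimal percentages)."""
    total = sum(counts.get(s, 0) for s in SEASONS)
    if total == 0:
        raise ValueError("no resolved assignments to summarise")
    return pd.DataFrame(
        {
            "season": list(SEASONS),
            "n": [counts.get(s, 0) for s in SEASONS],
            "pct": [round(100.0 * counts.get(s, 0) / total, 2) for s in SEASONS],
        }
    )


def vegetation_mask(labels: np.ndarray, vegetation_ids: Iterable[int]) -> np.ndarray:
    """Boolean raster: true where the class id is a vegetation class."""
    ids = list(vegetation_ids)
    if not ids:
        raise ValueError("vegetation_ids must be non-empty")
    labels = np.asarray(labels)
    return np.isin(labels, np.asarray(ids, dtype=labels.dtype))
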