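"""Per-species covariates: geography statistics, IUCN regrouping, model design.

A species profile row carries the two interest responses (paper counts,
Wikipedia pageview counts), morphology/ecology traits, cultural flags, and
geography.  This module computes the derived covariates:

* :func:`dispersion_range` — mean pairwise great-circle distance between
  occurrence points, a sampling-robust range-size proxy;
* :func:`range_centroid` — spherical (3-D unit vector) centroid of the
  occurrence points, safe across the antimeridian;
* :func:`assign_region` / :class:`RegionLookup` — biogeographic realm of the
  centroid from a user-supplied point->realm grid;
* :func:`regroup_iucn` — the 9 Red List codes collapsed to
  Threatened / NonThreatened / Unknown;
* :func:`prepare_design` — the model-ready design matrix: log transforms,
  z-scoring, and treatment-coded factors with Domain=multiple and
  IUCN=Unknown baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "REALMS",
    "IUCN_GROUPS",
    "dispersion_range",
    "range_centroid",
    "RegionLookup",
    "assign_region",
    "regroup_iucn",
    "DesignTransform",
    "prepare_design",
]

EARTH_RADIUS_KM = 6371.0

#: the eight biogeographic realms used for the crossed random intercept
REALMS = (
    "Afrotropical", "Antarctic", "Australasian", "Nearctic",
    "Neotropical", "Oriental", "Pacific", "Palaearctic",
)

#: Red List code -> 3-level conservation-status group
IUCN_GROUPS = {
    "EX": "Threatened", "EW": "Threatened", "CR": "Threatened",
    "EN": "Threatened", "VU": "Threatened",
    "NT": "NonThreatened", "LC": "NonThreatened",
    "DD": "Unknown", "NE": "Unknown",
}

#: pairwise-distance computations switch to pair subsampling above this
EXACT_PAIRWISE_LIMIT = 5000
SUBSAMPLED_PAIRS = 1_000_000


def _check_coords(lon: np.ndarray, lat: np.ndarray) -> None:
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
        raise ValueError("coordinates out of range (|lat|<=90, |lon|<=360)")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon1,lat1) and (lon2,lat2) degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def dispersion_range(
    points,
    *,
    metric: str = "haversine",
    dedupe: bool = False,
    seed: int = 0,
) -> float:
    """Mean pairwise distance (km) between occurrence points.

    ``points`` is a sequence of ``(lon, lat)`` pairs in degrees.  A single
    point has dispersion 0.  Exact duplicates are kept by default (set
    ``dedupe=True`` to drop them).  Above ``EXACT_PAIRWISE_LIMIT`` points the
    mean is estimated from a seeded random draw of ``SUBSAMPLED_PAIRS``
    ordered pairs (i != j); below it, all unordered pairs are used exactly.

    ``metric="euclidean_deg"`` gives plain Euclidean distance in degrees,
    for cross-checks only.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array of lon/lat")
    lon, lat = pts[:, 0], pts[:, 1]
    _check_coords(lon, lat)
    if dedupe:
        pts = np.unique(pts, axis=0)
        lon, lat = pts[:, 0], pts[:, 1]
    n = len(pts)
    if n == 1:
        return 0.0

    def dist(i, j):
        if metric == "haversine":
            return haversine_km(lon[i], lat[i], lon[j], lat[j])
        if metric == "euclidean_deg":
            return np.hypot(lon[i] - lon[j], lat[i] - lat[j])
        raise ValueError(f"unknown metric {metric!r}")

    if n <= EXACT_PAIRWISE_LIMIT:
        iu, ju = np.triu_indices(n, k=1)
        return float(np.mean(dist(iu, ju)))
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, SUBSAMPLED_PAIRS)
    j = rng.integers(0, n - 1, SUBSAMPLED_PAIRS)
    j = np.where(j >= i, j + 1, j)  # exclude i == j
    return float(np.mean(dist(i, j)))


def range_centroid(points) -> tuple[float, float]:
    """Spherical centroid (lon, lat) of occurrence points.

    Points are mapped to 3-D unit vectors, averaged, and the mean vector is
    normalised back to the sphere — correct across the antimeridian, where a
    naive lon/lat average fails.

    Raises
    ------
    ValueError
        If the mean vector norm is ~0 (e.g. an exactly antipodal pair), for
        which no centroid is defined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array of lon/lat")
    lon = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    _check_coords(pts[:, 0], pts[:, 1])
    v = np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=1
    ).mean(axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate centroid: mean vector has zero norm")
    v = v / norm
    return float(np.degrees(np.arctan2(v[1], v[0]))), float(np.degrees(np.arcsin(np.clip(v[2], -1, 1))))


class RegionLookup:
    """Point -> biogeographic-realm lookup on a regular lon/lat grid.

    Built from a table of grid-cell centres ``(lon, lat, region)``.  A query
    point is assigned the realm of the nearest cell centre, provided the
    point falls within that cell; otherwise ``"Unknown"`` with a warning.
    """

    def __init__(self, table: pd.DataFrame):
        for col in ("lon", "lat", "region"):
            if col not in table.columns:
                raise ValueError(f"region lookup table needs column {col!r}")
        self.table = table.reset_index(drop=True)
        self._lon = self.table["lon"].to_numpy(float)
        self._lat = self.table["lat"].to_numpy(float)
        lon_u = np.unique(self._lon)
        lat_u = np.unique(self._lat)
        self.dlon = float(np.median(np.diff(lon_u))) if len(lon_u) > 1 else 360.0
        self.dlat = float(np.median(np.diff(lat_u))) if len(lat_u) > 1 else 180.0

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionLookup":
        return cls(pd.read_csv(path))

    def __call__(self, lon: float, lat: float) -> str:
        dl = np.abs(self._lon - lon)
        dl = np.minimum(dl, 360.0 - dl)  # wrap the antimeridian
        db = np.abs(self._lat - lat)
        inside = (dl <= self.dlon / 2 + 1e-9) & (db <= self.dlat / 2 + 1e-9)
        if not inside.any():
            warnings.warn(
                f"centroid ({lon:.3f}, {lat:.3f}) outside region lookup coverage",
                stacklevel=2,
            )
            return "Unknown"
        cand = np.flatnonzero(inside)
        best = cand[np.argmin(dl[cand] ** 2 + db[cand] ** 2)]
        return str(self.table.loc[best, "region"])


def assign_region(centroid: tuple[float, float], lookup: RegionLookup) -> str:
    """Realm of a range centroid under a point->realm lookup (deterministic)."""
    return lookup(centroid[0], centroid[1])


def regroup_iucn(iucn_raw: str) -> str:
    """Collapse a 9-category Red List code to Threatened/NonThreatened/Unknown."""
    try:
        return IUCN_GROUPS[iucn_raw]
    except KeyError:
        raise ValueError(f"unknown IUCN code {iucn_raw!r}") from None


# ---------------------------------------------------------------------------
# model design
# ---------------------------------------------------------------------------

#: factor levels with the baseline (all-dummies-zero) level first
DOMAIN_LEVELS = ("multiple", "freshwater", "marine", "terrestrial")
IUCN_LEVELS = ("Unknown", "Threatened", "NonThreatened")

_BINARY = ("colorful", "common_name", "human_use", "harmful")


@dataclass
class DesignTransform:
    """Frozen transform parameters so a design can be reproduced exactly."""

    variant: str
    continuous: tuple[str, ...]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def apply(self, profiles: pd.DataFrame) -> pd.DataFrame:
        return _build_design(profiles, self.variant, self)[0]


def _raw_continuous(profiles: pd.DataFrame, variant: str) -> pd.DataFrame:
    """Log-transformed (not yet scaled) continuous covariates.

    Size, uniqueness and divergence time are strictly positive by
    construction so use log(x); range size is 0 for single-occurrence
    species so uses log(1+x).
    """
    out = pd.DataFrame(index=profiles.index)
    out["size"] = np.log(profiles["size_mm"].to_numpy(float))
    out["range"] = np.log1p(profiles["range_km"].to_numpy(float))
    if variant == "eq1":
        out["uniqueness"] = np.log(profiles["family_uniqueness"].to_numpy(float))
        out["phylo_dist"] = np.log(profiles["phylo_dist_myr"].to_numpy(float))
    else:
        out["uniqueness"] = np.log(profiles["genus_uniqueness"].to_numpy(float))
    return out


def _build_design(profiles, variant, transform=None):
    cont = _raw_continuous(profiles, variant)
    if cont.isna().any().any():
        raise ValueError("missing values in continuous covariates")
    if transform is None:
        transform = DesignTransform(variant=variant, continuous=tuple(cont.columns))
        for col in cont.columns:
            sd = float(cont[col].std(ddof=0))
            if sd < 1e-12:
                raise ValueError(f"zero-variance continuous column: {col}")
            transform.means[col] = float(cont[col].mean())
            transform.sds[col] = sd
    for col in cont.columns:
        cont[col] = (cont[col] - transform.means[col]) / transform.sds[col]

    design = pd.DataFrame(index=profiles.index)
    design["const"] = 1.0
    design["size"] = cont["size"]
    design["colorful"] = profiles["colorful"].astype(float)
    design["range"] = cont["range"]
    dom = profiles["habitat_domain"].astype(str)
    bad = set(dom) - set(DOMAIN_LEVELS)
    if bad:
        raise ValueError(f"unknown habitat_domain level(s): {sorted(bad)}")
    for lev in DOMAIN_LEVELS[1:]:
        design[f"domain_{lev}"] = (dom == lev).astype(float)
    design["uniqueness"] = cont["uniqueness"]
    design["common_name"] = profiles["common_name"].astype(float)
    grp = profiles["iucn_group"].astype(str)
    bad = set(grp) - set(IUCN_LEVELS)
    if bad:
        raise ValueError(f"unknown iucn_group level(s): {sorted(bad)}")
    for lev in IUCN_LEVELS[1:]:
        design[f"iucn_{lev}"] = (grp == lev).astype(float)
    design["human_use"] = profiles["human_use"].astype(float)
    design["harmful"] = profiles["harmful"].astype(float)
    if variant == "eq1":
        design["phylo_dist"] = cont["phylo_dist"]
    if design.isna().any().any():
        raise ValueError("missing values in design")
    return design, transform


def prepare_design(
    profiles: pd.DataFrame,
    formula_variant: str = "eq1",
    transform: DesignTransform | None = None,
) -> tuple[pd.DataFrame, DesignTransform]:
    """Model-ready fixed-effects design for the interest models.

    ``eq1`` (all-phyla model): standardized log size, colorful flag,
    standardized log1p range, habitat-domain dummies (baseline ``multiple``),
    standardized log family uniqueness, common-name flag, IUCN-group dummies
    (baseline ``Unknown``), human-use flag, harmful flag, standardized log
    divergence time from humans.  ``eq2`` (within-phylum model) swaps family
    for genus uniqueness and drops divergence time.

    Continuous columns are z-scored; pass a stored :class:`DesignTransform`
    to reuse training means/sds on new data.  Returns ``(design, transform)``;
    the design carries a ``const`` intercept column.
    """
    if formula_variant not in ("eq1", "eq2"):
        raise ValueError(f"formula_variant must be 'eq1' or 'eq2', got {formula_variant!r}")
    return _build_design(profiles, formula_variant, transform)


#: default covariate grouping for variance partitioning
SPECIES_TRAIT_TERMS = (
    "size", "colorful", "range",
    "domain_freshwater", "domain_marine", "domain_terrestrial", "uniqueness",
)
CULTURE_TERMS = (
    "common_name", "iucn_Threatened", "iucn_NonThreatened",
    "human_use", "harmful", "phylo_dist",
)
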