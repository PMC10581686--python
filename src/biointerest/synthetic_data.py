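"""Synthetic taxonomies, traits, occurrences and interest counts.

Every pipeline stage is testable offline against data with known ground
truth.  The generator emulates the statistical structure the interest
models assume:

* a nested Phylum/Class/Order taxonomy with heavy-tailed (discrete
  lognormal) order sizes, plus synonym/subspecies/fossil decoy rows to
  exercise backbone cleaning;
* trait distributions — lognormal body sizes, Bernoulli cultural flags, a
  9-code IUCN status collapsed to 3 groups, a 4-level habitat domain with
  "multiple" the majority level, lognormal range sizes and divergence
  times;
* interest counts from a log-linear predictor eta = X beta + b_taxo +
  b_region with independent Gaussian random intercepts at each taxonomic
  level and for the biogeographic realm: papers ~ NB2(exp(eta_sci),
  theta_sci), pageviews ~ ZINB2(exp(eta_pop), theta_pop, pi_pop).

Coefficients are expressed on the transformed-covariate scale (the
standardized design that :func:`biointerest.traits_geo.prepare_design`
builds), so refitting the models on generated data recovers them directly.
The default scenario mirrors the scale of the real harvest: ~3000 species,
29 phyla, 8 realms, a zero-heavy papers distribution (~50% zeros) and
long-tailed pageviews.

Every draw flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits_geo import prepare_design, regroup_iucn

__all__ = [
    "GeneratorConfig",
    "gen_backbone",
    "gen_species_frame",
    "gen_profiles",
    "gen_occurrences",
    "synthetic_realm_grid",
]

TETRAPOD_CLASSES = ("Amphibia", "Reptilia", "Aves", "Mammalia")

_DEFAULT_BETA_SCI = {
    # intercept set so that ~half the species have zero papers under the
    # default taxonomy and dispersion (the zero-heavy regime of real
    # literature harvests)
    "const": -0.6, "size": 0.3, "colorful": 0.4, "range": 0.5,
    "domain_freshwater": -0.1, "domain_marine": 0.1, "domain_terrestrial": 0.2,
    "uniqueness": -0.2, "common_name": 0.8,
    "iucn_Threatened": 0.3, "iucn_NonThreatened": 0.4,
    "human_use": 0.6, "harmful": 0.4, "phylo_dist": -0.3,
}
_DEFAULT_BETA_POP = {
    # pageviews: few zeros beyond the inflation component, heavy right tail
    "const": 6.0, "size": 0.4, "colorful": 0.5, "range": 0.4,
    "domain_freshwater": -0.2, "domain_marine": 0.1, "domain_terrestrial": 0.3,
    "uniqueness": -0.1, "common_name": 1.0,
    "iucn_Threatened": 0.3, "iucn_NonThreatened": 0.5,
    "human_use": 0.7, "harmful": 0.5, "phylo_dist": -0.4,
}

_IUCN_PROBS = {
    "EX": 0.005, "EW": 0.005, "CR": 0.03, "EN": 0.05, "VU": 0.06,
    "NT": 0.05, "LC": 0.40, "DD": 0.15, "NE": 0.25,
}
_DOMAIN_PROBS = {"multiple": 0.40, "terrestrial": 0.35, "marine": 0.15,
                 "freshwater": 0.10}


@dataclass
class GeneratorConfig:
    """Known-truth parameters of the synthetic study system."""

    seed: int = 0
    # taxonomy shape
    n_phyla: int = 29
    classes_per_phylum: int = 2
    orders_per_class: int = 2
    order_size_law: tuple = ("lognormal", 5.0, 1.5)  # heavy-tailed order sizes
    decoy_frac: float = 0.15       # synonym/subspecies/fossil rows in backbone
    mean_genus_size: float = 4.0   # species per genus (geometric)
    genera_per_family: float = 3.0
    # traits
    trait_prevalences: dict = field(default_factory=lambda: {
        "colorful": 0.25, "blue": 0.08, "red": 0.10, "common_name": 0.40,
        "model_organism": 0.005, "harmful": 0.10, "human_use": 0.30,
    })
    size_lognormal: tuple = (3.9, 1.5)    # log mm: median ~50 mm
    phylo_lognormal: tuple = (6.5, 0.8)   # log Myr: median ~665 Myr
    range_lognormal: tuple = (6.0, 2.0)   # log km: median ~400 km
    iucn_probs: dict = field(default_factory=lambda: dict(_IUCN_PROBS))
    domain_probs: dict = field(default_factory=lambda: dict(_DOMAIN_PROBS))
    # interest-count model (coefficients on the standardized design scale)
    beta_sci: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_SCI))
    beta_pop: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_POP))
    theta_sci: float = 0.7
    theta_pop: float = 0.3
    pi_pop: float = 0.05
    sigma_taxo: float = 0.5    # SD of each nested taxonomic intercept level
    sigma_region: float = 0.3
    n_regions: int = 8

    def __post_init__(self):
        for p in list(self.trait_prevalences.values()) + [self.pi_pop, self.decoy_frac]:
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.theta_sci <= 0 or self.theta_pop <= 0:
            raise ValueError("theta must be > 0")
        if self.sigma_taxo < 0 or self.sigma_region < 0:
            raise ValueError("random-intercept SDs must be >= 0")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _phylum_names(n):
    base = ["Chordata", "Arthropoda", "Tracheophyta"]
    return (base + [f"Phylum{i:02d}" for i in range(4, n + 1)])[:n]


def _class_names(phylum, k):
    if phylum == "Chordata":
        pool = list(TETRAPOD_CLASSES) + ["Actinopterygii", "Chondrichthyes"]
        return pool[:k] if k <= len(pool) else pool + [
            f"{phylum}_cl{i}" for i in range(len(pool) + 1, k + 1)]
    return [f"{phylum}_cl{i}" for i in range(1, k + 1)]


def _taxonomy_shape(cfg: GeneratorConfig):
    """(phylum, class, order) label triples for every order."""
    out = []
    for ph in _phylum_names(cfg.n_phyla):
        for cl in _class_names(ph, cfg.classes_per_phylum):
            for k in range(1, cfg.orders_per_class + 1):
                out.append((ph, cl, f"{cl}_ord{k}"))
    return out


def _order_sizes(cfg: GeneratorConfig, rng, n_orders):
    law, *pars = cfg.order_size_law
    if law == "lognormal":
        mu, sd = pars
        return np.maximum(1, np.round(rng.lognormal(mu, sd, n_orders))).astype(int)
    if law == "fixed":
        return np.full(n_orders, int(pars[0]))
    raise ValueError(f"unknown order_size_law {law!r}")


def _kingdom(phylum):
    return "Plantae" if phylum == "Tracheophyta" else "Animalia"


def gen_backbone(cfg: GeneratorConfig) -> pd.DataFrame:
    """A GBIF-style backbone with heavy-tailed order sizes and decoy rows.

    Decoys (fraction ``cfg.decoy_frac`` of extra rows) are synonyms,
    subspecies/varieties, doubtful names and fossil specimens that backbone
    cleaning must drop; with ``decoy_frac=0`` cleaning is the identity.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = _taxonomy_shape(cfg)
    sizes = _order_sizes(cfg, rng, len(shape))
    rows = []
    tid = 0
    for (ph, cl, od), n in zip(shape, sizes):
        genera = _assign_groups(rng, n, cfg.mean_genus_size)
        fams = _assign_groups(rng, genera.max() + 1, cfg.genera_per_family)
        for i in range(n):
            tid += 1
            g = genera[i]
            rows.append({
                "taxon_id": f"t{tid:07d}",
                "name": f"{od}_g{g} sp{i}",
                "rank": "species", "status": "accepted", "fossil": False,
                "kingdom": _kingdom(ph), "phylum": ph, "class_": cl,
                "order": od, "family": f"{od}_f{fams[g]}",
                "genus": f"{od}_g{g}",
            })
    df = pd.DataFrame(rows)
    n_decoy = int(round(cfg.decoy_frac * len(df)))
    if n_decoy:
        src = df.sample(n=n_decoy, replace=True, random_state=rng.integers(2**31))
        kinds = rng.choice(["synonym", "subspecies", "variety", "fossil", "doubtful"],
                           size=n_decoy)
        decoys = src.copy().reset_index(drop=True)
        decoys["taxon_id"] = [f"d{j:07d}" for j in range(n_decoy)]
        decoys["status"] = np.where(kinds == "synonym", "synonym",
                                    np.where(kinds == "doubtful", "doubtful",
                                             "accepted"))
        decoys["rank"] = np.where(np.isin(kinds, ["subspecies", "variety"]),
                                  kinds, "species")
        decoys["fossil"] = kinds == "fossil"
        df = pd.concat([df, decoys], ignore_index=True)
        df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    return df


def _assign_groups(rng, n, mean_size):
    """Assign n items to groups with ~geometric sizes; returns group index per item."""
    if n <= 0:
        return np.zeros(0, int)
    p = 1.0 / max(mean_size, 1.0)
    out = np.empty(n, int)
    g = 0
    i = 0
    while i < n:
        size = int(rng.geometric(p))
        out[i:i + size] = g
        i += size
        g += 1
    return out


def gen_species_frame(cfg: GeneratorConfig, n_species: int = 3000) -> pd.DataFrame:
    """A species table of exactly ``n_species`` rows over the cfg taxonomy.

    Species are spread over orders with heavy-tailed weights, then genera and
    families are nested inside orders — a direct stand-in for the output of
    backbone cleaning + stratified sampling when a fixed dataset size is
    wanted (e.g. parameter-recovery studies).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = _taxonomy_shape(cfg)
    w = _order_sizes(cfg, rng, len(shape)).astype(float)
    counts = rng.multinomial(n_species, w / w.sum())
    rows = []
    tid = 0
    for (ph, cl, od), n in zip(shape, counts):
        if n == 0:
            continue
        genera = _assign_groups(rng, n, cfg.mean_genus_size)
        fams = _assign_groups(rng, genera.max() + 1, cfg.genera_per_family)
        for i in range(n):
            tid += 1
            g = genera[i]
            rows.append({
                "species_id": f"s{tid:06d}",
                "name": f"{od}_g{g} sp{i}",
                "kingdom": _kingdom(ph), "phylum": ph, "class_": cl, "order": od,
                "family": f"{od}_f{fams[g]}", "genus": f"{od}_g{g}",
            })
    return pd.DataFrame(rows)


def _draw_categorical(rng, probs: dict, n):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], float)
    return np.array(keys)[rng.choice(len(keys), size=n, p=p / p.sum())]


def gen_profiles(species: pd.DataFrame, cfg: GeneratorConfig,
                 rng: np.random.Generator | None = None,
                 geo: pd.DataFrame | None = None):
    """Traits + interest counts for a species table; returns (profiles, truth).

    Traits are drawn per the config; uniqueness counts are tallied from the
    generated taxonomy itself (so they are self-consistent with the
    family/genus labels).  Counts come from the log-linear predictor with
    nested taxonomic and crossed realm random intercepts; ``truth`` carries
    the design, coefficient vectors, random intercepts and linear predictors
    used.

    ``geo``, if given, supplies precomputed geography per species
    (columns ``species_id, range_km, centroid_lon, centroid_lat, region``,
    e.g. derived from generated occurrence points) instead of drawing it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = len(species)
    prof = species.reset_index(drop=True).copy()

    for flag, p in cfg.trait_prevalences.items():
        prof[flag] = rng.random(n) < p
    mu, sd = cfg.size_lognormal
    prof["size_mm"] = rng.lognormal(mu, sd, n)
    mu, sd = cfg.phylo_lognormal
    prof["phylo_dist_myr"] = rng.lognormal(mu, sd, n)
    mu, sd = cfg.range_lognormal
    prof["range_km"] = rng.lognormal(mu, sd, n)
    prof["habitat_domain"] = _draw_categorical(rng, cfg.domain_probs, n)
    prof["iucn_raw"] = _draw_categorical(rng, cfg.iucn_probs, n)
    prof["iucn_group"] = [regroup_iucn(c) for c in prof["iucn_raw"]]
    prof["family_uniqueness"] = prof.groupby("family")["species_id"].transform("size")
    prof["genus_uniqueness"] = prof.groupby("genus")["species_id"].transform("size")
    lat = rng.uniform(-55.0, 70.0, n)
    lon = rng.uniform(-180.0, 180.0, n)
    prof["centroid_lon"] = lon
    prof["centroid_lat"] = lat
    realm_of = _realm_function()
    prof["region"] = [realm_of(lo, la) for lo, la in zip(lon, lat)]
    if geo is not None:
        geo = geo.set_index("species_id")
        for col in ("range_km", "centroid_lon", "centroid_lat", "region"):
            if col in geo.columns:
                prof[col] = prof["species_id"].map(geo[col]).fillna(prof[col])

    design, transform = prepare_design(prof, "eq1")
    beta_s = pd.Series(cfg.beta_sci).reindex(design.columns).fillna(0.0)
    beta_p = pd.Series(cfg.beta_pop).reindex(design.columns).fillna(0.0)

    b = {}
    eta_re = np.zeros((2, n))
    level_defs = [
        ("phylum", prof["phylum"].astype(str), cfg.sigma_taxo),
        ("phylum:class", prof["phylum"].astype(str) + "/" + prof["class_"].astype(str),
         cfg.sigma_taxo),
        ("phylum:class:order",
         prof["phylum"].astype(str) + "/" + prof["class_"].astype(str) + "/"
         + prof["order"].astype(str), cfg.sigma_taxo),
        ("region", prof["region"].astype(str), cfg.sigma_region),
    ]
    for which in (0, 1):  # independent intercepts for the two responses
        b[which] = {}
        for name, labels, sdv in level_defs:
            codes, levels = pd.factorize(labels, sort=True)
            draws = rng.normal(0.0, sdv, len(levels))
            b[which][name] = pd.Series(draws, index=levels)
            eta_re[which] += draws[codes]

    Xmat = design.to_numpy(float)
    eta_sci = Xmat @ beta_s.to_numpy() + eta_re[0]
    eta_pop = Xmat @ beta_p.to_numpy() + eta_re[1]

    mu_sci = np.exp(eta_sci)
    prof["n_papers"] = rng.negative_binomial(
        cfg.theta_sci, cfg.theta_sci / (cfg.theta_sci + mu_sci))
    mu_pop = np.exp(eta_pop)
    views = rng.negative_binomial(
        cfg.theta_pop, cfg.theta_pop / (cfg.theta_pop + mu_pop))
    inflated = rng.random(n) < cfg.pi_pop
    prof["n_views"] = np.where(inflated, 0, views)

    truth = {
        "beta_sci": beta_s, "beta_pop": beta_p,
        "theta_sci": cfg.theta_sci, "theta_pop": cfg.theta_pop,
        "pi_pop": cfg.pi_pop,
        "eta_sci": eta_sci, "eta_pop": eta_pop,
        "b_sci": b[0], "b_pop": b[1],
        "design": design, "transform": transform,
    }
    return prof, truth


def gen_occurrences(centroid: tuple[float, float], spread_km: float,
                    n_points: int, rng: np.random.Generator) -> np.ndarray:
    """Occurrence points scattered isotropically around a centroid.

    Small-angle approximation: lat/lon offsets are Gaussian with SD
    ``spread_km`` (converted to degrees, the lon offset widened by
    1/cos(lat)).  ``spread_km=0`` duplicates the centroid; the expected mean
    pairwise distance grows monotonically with ``spread_km``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    lon0, lat0 = centroid
    km_per_deg = 111.19492664455873  # pi * 6371 / 180
    dlat = rng.normal(0.0, spread_km, n_points) / km_per_deg
    coslat = max(np.cos(np.radians(np.clip(lat0, -85.0, 85.0))), 0.05)
    dlon = rng.normal(0.0, spread_km, n_points) / (km_per_deg * coslat)
    lat = np.clip(lat0 + dlat, -89.9, 89.9)
    lon = (lon0 + dlon + 180.0) % 360.0 - 180.0
    return np.column_stack([lon, lat])


def _realm_function():
    """Crude synthetic partition of the globe into the 8 realms.

    A longitude/latitude box rule — a stand-in for real biogeographic
    polygons, adequate for generating self-consistent region labels.
    """
    def realm(lon, lat):
        if lat < -60:
            return "Antarctic"
        if -180 <= lon < -30:
            return "Nearctic" if lat > 25 else "Neotropical"
        if -30 <= lon < 60:
            return "Palaearctic" if lat > 30 else "Afrotropical"
        if 60 <= lon < 130:
            return "Palaearctic" if lat > 40 else "Oriental"
        return "Pacific" if lat > 25 else "Australasian"
    return realm


def synthetic_realm_grid(step: float = 5.0) -> pd.DataFrame:
    """A point->realm lookup grid using the synthetic realm boxes."""
    realm_of = _realm_function()
    lons = np.arange(-180 + step / 2, 180, step)
    lats = np.arange(-90 + step / 2, 90, step)
    rows = [
        {"lon": lo, "lat": la, "region": realm_of(lo, la)}
        for la in lats for lo in lons
    ]
    return pd.DataFrame(rows)
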