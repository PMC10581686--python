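"""Cleaning and stratified sampling of a GBIF-style backbone taxonomy.

The sampling frame for a Tree-of-Life interest survey is a backbone taxonomy
table (one row per name, GBIF Darwin Core column conventions).  Two steps live
here:

1. :func:`clean_backbone` — keep only accepted, extant, species-rank names.
2. :func:`stratified_sample` — draw a random sample stratified by order, with
   per-order quotas that damp the enormous size imbalance between orders
   (beetle orders have >300,000 species, many orders have a handful) while
   deliberately over-representing tetrapods.

Quota rules, applied per order of size ``n``:

* tetrapod orders (class in ``cfg.tetrapod_classes``): ``small_tetrapod_quota``
  (default 1) if ``n < small_tetrapod_threshold`` (default 10), else
  ``tetrapod_quota`` (default 20);
* otherwise, if ``n`` falls in a bracket of ``cfg.bracket_caps`` the bracket's
  cap applies (defaults: 10,001–50,000 → 20; 50,001–100,000 → 40;
  >100,000 → 60);
* otherwise ``ceil(base_fraction * n)`` with ``base_fraction`` defaulting to
  0.002 (ceiling ensures every non-empty order contributes at least one
  species; a ``floor`` mode is available).

Quotas are always clamped to the order's size.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingConfig",
    "StratifiedSample",
    "read_backbone",
    "clean_backbone",
    "order_quota",
    "stratified_sample",
]

#: statuses a backbone row may carry
VALID_STATUSES = frozenset({"accepted", "synonym", "doubtful"})

#: ranks a backbone row may carry
VALID_RANKS = frozenset(
    {"species", "subspecies", "variety", "form", "genus", "family",
     "order", "class", "phylum", "kingdom", "unranked"}
)

#: four-limbed vertebrate classes, over-sampled by design
DEFAULT_TETRAPOD_CLASSES = frozenset({"Amphibia", "Reptilia", "Aves", "Mammalia"})

#: Darwin Core / GBIF backbone column names -> internal names
GBIF_COLUMN_MAP = {
    "taxonID": "taxon_id",
    "scientificName": "name",
    "taxonRank": "rank",
    "taxonomicStatus": "status",
    "kingdom": "kingdom",
    "phylum": "phylum",
    "class": "class_",
    "order": "order",
    "family": "family",
    "genus": "genus",
}

_REQUIRED = ["taxon_id", "name", "rank", "status", "fossil",
             "kingdom", "phylum", "class_", "order", "family", "genus"]


@dataclass(frozen=True)
class SamplingConfig:
    """Quota rules for the order-stratified species sample.

    Parameters
    ----------
    base_fraction
        Fraction of an order's species sampled when no cap applies.
    bracket_caps
        ``(lower, upper, quota)`` triples, inclusive bounds, ordered and
        non-overlapping; caps override the fraction.
    tetrapod_quota, small_tetrapod_threshold, small_tetrapod_quota
        Flat quotas for tetrapod orders; the tetrapod rule overrides brackets.
    tetrapod_classes
        Class names treated as tetrapods.
    rounding
        ``"ceil"`` (default; every non-empty order contributes) or ``"floor"``
        for the fractional quota.
    seed
        Seed for the single sampling RNG.
    """

    base_fraction: float = 0.002
    bracket_caps: tuple[tuple[float, float, int], ...] = (
        (10_001, 50_000, 20),
        (50_001, 100_000, 40),
        (100_001, math.inf, 60),
    )
    tetrapod_quota: int = 20
    small_tetrapod_threshold: int = 10
    small_tetrapod_quota: int = 1
    tetrapod_classes: frozenset[str] = DEFAULT_TETRAPOD_CLASSES
    rounding: str = "ceil"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.base_fraction <= 1:
            raise ValueError(f"base_fraction must be in (0, 1], got {self.base_fraction}")
        for q in (self.tetrapod_quota, self.small_tetrapod_quota):
            if q < 1:
                raise ValueError(f"quotas must be positive integers, got {q}")
        if self.rounding not in ("ceil", "floor"):
            raise ValueError(f"rounding must be 'ceil' or 'floor', got {self.rounding!r}")
        prev_hi = -math.inf
        for lo, hi, quota in self.bracket_caps:
            if quota < 1:
                raise ValueError(f"bracket quota must be positive, got {quota}")
            if lo > hi or lo <= prev_hi:
                raise ValueError("bracket_caps must be ordered and non-overlapping")
            prev_hi = hi


def read_backbone(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a backbone table (TSV/CSV with GBIF column names).

    A boolean ``fossil`` column is accepted directly; alternatively a
    ``basisOfRecord`` column is mapped to ``fossil = (basisOfRecord ==
    "Fossil_Specimen")``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.rename(columns=GBIF_COLUMN_MAP)
    if "fossil" in df.columns:
        df["fossil"] = df["fossil"].astype(str).str.lower().isin(("true", "1", "yes"))
    elif "basisOfRecord" in df.columns:
        df["fossil"] = df["basisOfRecord"] == "Fossil_Specimen"
    else:
        raise ValueError("backbone needs a 'fossil' or 'basisOfRecord' column")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"backbone is missing columns: {missing}")
    return df


def clean_backbone(records: pd.DataFrame) -> pd.DataFrame:
    """Keep accepted, extant names at species rank.

    Removes synonyms and doubtful names, subspecies/varieties (and any other
    non-species rank), and fossil records.  Input row order is preserved;
    the operation is idempotent.

    Raises
    ------
    ValueError
        If ``records`` is empty, or a status/rank value is outside the
        closed vocabulary (the offending value is named).
    """
    if len(records) == 0:
        raise ValueError("no records")
    bad_status = set(records["status"]) - VALID_STATUSES
    if bad_status:
        raise ValueError(f"unknown taxonomicStatus value(s): {sorted(bad_status)}")
    bad_rank = set(records["rank"]) - VALID_RANKS
    if bad_rank:
        raise ValueError(f"unknown taxonRank value(s): {sorted(bad_rank)}")
    keep = (
        (records["status"] == "accepted")
        & (records["rank"] == "species")
        & (~records["fossil"].astype(bool))
    )
    return records.loc[keep].copy()


def order_quota(n_in_order: int, is_tetrapod: bool, cfg: SamplingConfig) -> int:
    """Number of species to draw from an order of ``n_in_order`` species.

    Tetrapod rule overrides bracket caps; bracket caps override the base
    fraction; the result is clamped to the order size.
    """
    if n_in_order < 1:
        raise ValueError(f"order size must be >= 1, got {n_in_order}")
    if is_tetrapod:
        quota = (
            cfg.small_tetrapod_quota
            if n_in_order < cfg.small_tetrapod_threshold
            else cfg.tetrapod_quota
        )
    else:
        quota = None
        for lo, hi, cap in cfg.bracket_caps:
            if lo <= n_in_order <= hi:
                quota = cap
                break
        if quota is None:
            frac = cfg.base_fraction * n_in_order
            quota = math.ceil(frac) if cfg.rounding == "ceil" else math.floor(frac)
            quota = max(quota, 1) if cfg.rounding == "ceil" else quota
    return min(quota, n_in_order)


@dataclass
class StratifiedSample:
    """An order-stratified species sample plus its per-order report."""

    species: pd.DataFrame
    report: dict = field(default_factory=dict)

    def to_files(self, out_tsv: str | Path, out_json: str | Path | None = None) -> None:
        self.species.to_csv(out_tsv, sep="\t", index=False)
        if out_json is not None:
            Path(out_json).write_text(json.dumps(self.report, indent=2))


def stratified_sample(cleaned: pd.DataFrame, cfg: SamplingConfig) -> StratifiedSample:
    """Draw the order-stratified random sample from a cleaned backbone.

    Within every order, ``order_quota`` species are drawn uniformly without
    replacement.  One seeded generator is consumed order-by-order in sorted
    order-name sequence, so identical input and seed give identical output on
    any platform.  Orders with an empty order label are skipped with a
    warning.  The output carries a ``sampled_from_order`` annotation column.
    """
    rng = np.random.default_rng(cfg.seed)
    pieces: list[pd.DataFrame] = []
    report: dict[str, dict] = {"seed": cfg.seed, "orders": {}}
    grouped = {name: idx for name, idx in cleaned.groupby("order", sort=True).groups.items()}
    for order_name in sorted(grouped):
        idx = grouped[order_name]
        if order_name == "" or pd.isna(order_name):
            logger.warning("skipping %d species with empty order label", len(idx))
            continue
        sub = cleaned.loc[idx]
        is_tetrapod = bool(set(sub["class_"]) & cfg.tetrapod_classes)
        quota = order_quota(len(sub), is_tetrapod, cfg)
        take = rng.choice(len(sub), size=quota, replace=False)
        drawn = sub.iloc[np.sort(take)].copy()
        drawn["sampled_from_order"] = order_name
        pieces.append(drawn)
        report["orders"][str(order_name)] = {
            "n_species": int(len(sub)),
            "quota": int(quota),
            "drawn": int(len(drawn)),
            "tetrapod": is_tetrapod,
        }
    if not pieces:
        raise ValueError("no orders to sample from")
    out = pd.concat(pieces, ignore_index=True)
    report["n_sampled"] = int(len(out))
    return StratifiedSample(species=out, report=report)
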