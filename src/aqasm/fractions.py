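"""Merge 0.1 and 0.2 um filter-fraction communities with qPCR weights.

Sequential filtration splits one water sample into a 0.2 um retentate
(F02, larger cells) and a 0.1 um retentate of its filtrate (F01,
ultra-small cells). Each fraction is sequenced separately; 16S qPCR totals
say how much biomass each fraction contributed, so the whole-community
profile is the qPCR-weighted convex combination of the two fraction
profiles. Taxon partitioning between the fractions (how much of a taxon's
population passes the 0.2 um filter) falls out of the same weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class UnusablePairError(ValueError):
    """A (site, time_point) lacks one of the two fraction qPCR entries."""


@dataclass(frozen=True)
class FractionWeights:
    """qPCR-derived contribution of each filter fraction; w01 + w02 = 1."""

    site: str
    time_point: str
    w01: float
    w02: float

    def __post_init__(self) -> None:
        if self.w01 < 0 or self.w02 < 0:
            raise ValueError("weights must be non-negative")
        if not math.isclose(self.w01 + self.w02, 1.0, abs_tol=1e-12):
            raise ValueError("weights must sum to 1")


def compute_fraction_weights(qpcr: pd.DataFrame, site: str,
                             time_point: str) -> FractionWeights:
    """w_f = copies_f / (copies_F01 + copies_F02) for one water sample."""
    sel = qpcr[(qpcr["site"] == site) & (qpcr["time_point"] == time_point)]
    copies = {}
    for frac in ("F01", "F02"):
        rows = sel[sel["fraction"] == frac]
        if len(rows) != 1:
            raise UnusablePairError(
                f"({site}, {time_point}): need exactly one {frac} qPCR entry, "
                f"found {len(rows)}")
        copies[frac] = float(rows["gene_copies_per_L"].iloc[0])
    total = copies["F01"] + copies["F02"]
    if total <= 0:
        raise UnusablePairError(f"({site}, {time_point}): non-positive total")
    return FractionWeights(site, time_point,
                           w01=copies["F01"] / total,
                           w02=copies["F02"] / total)


def merge_fractions(rel_f01: pd.Series, rel_f02: pd.Series,
                    weights: FractionWeights) -> pd.Series:
    """Convex combination of the two fraction profiles.

    merged(o) = w01 * relF01(o) + w02 * relF02(o). OTU sets are aligned by
    union with zero fill (logged when they differ); the output sums to 1.
    """
    if not math.isclose(rel_f01.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("F01 profile does not sum to 1")
    if not math.isclose(rel_f02.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("F02 profile does not sum to 1")
    if set(rel_f01.index) != set(rel_f02.index):
        logger.info("merge_fractions: OTU sets differ, aligning by union")
    a, b = rel_f01.align(rel_f02, fill_value=0.0)
    return weights.w01 * a + weights.w02 * b


def merge_sample_pairs(table, metadata: pd.DataFrame,
                       qpcr: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Merge every fractionated (site, time_point) water sample in a table.

    Returns a DataFrame of merged relative abundances indexed by
    "site:time_point" plus a dict of the weights used. Samples with only
    one fraction present are passed through as-is with a logged caveat.
    """
    from .io import OTUTable, relative_abundance

    if isinstance(table, OTUTable):
        rel = relative_abundance(table)
    else:
        rel = table
    meta = metadata.loc[rel.index]
    water = meta[meta["fraction"].isin(["F01", "F02"])]
    merged_rows, weights_used = {}, {}
    for (site, tp), grp in water.groupby(["site", "time_point"]):
        fracs = dict(zip(grp["fraction"], grp["sample_id"]))
        key = f"{site}:{tp}"
        if set(fracs) == {"F01", "F02"}:
            w = compute_fraction_weights(qpcr, site, tp)
            merged_rows[key] = merge_fractions(
                rel.loc[fracs["F01"]], rel.loc[fracs["F02"]], w)
            weights_used[key] = {"F01": w.w01, "F02": w.w02}
        else:
            only = next(iter(fracs.values()))
            logger.warning("(%s, %s): single fraction %s used as bulk",
                           site, tp, only)
            merged_rows[key] = rel.loc[only]
            weights_used[key] = {f: 1.0 for f in fracs}
    bulk = meta[(meta["fraction"] == "bulk")]
    for sid in bulk["sample_id"]:
        merged_rows[sid] = rel.loc[sid]
    out = pd.DataFrame(merged_rows).T
    out.index.name = "sample"
    return out, weights_used


def ultrasmall_population_share(rel_f01_t: float, rel_f02_t: float,
                                weights: FractionWeights) -> float:
    """Fraction of a taxon's total population that passed the 0.2 um filter.

    share = w01*relF01(t) / (w01*relF01(t) + w02*relF02(t)); NaN when the
    taxon is absent from both fractions.
    """
    num = weights.w01 * rel_f01_t
    den = num + weights.w02 * rel_f02_t
    if den == 0:
        return float("nan")
    return num / den


def fraction_enrichment_factor(rel_f01_t: float, rel_f02_t: float) -> float:
    """Relative-abundance ratio F01/F02 for one taxon.

    >1 means the taxon is enriched among ultra-small cells. Returns +inf
    (flagged by the caller as "absent in reference fraction") when the
    taxon is undetected in F02.
    """
    if rel_f02_t == 0:
        return float("inf")
    return rel_f01_t / rel_f02_t
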