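"""Trace taxa along the soil -> seepage -> groundwater flow path.

Mobilization and persistence are quantified by (i) compartment enrichment
factors (ratio of a taxon's mean relative abundance in a target vs source
compartment), (ii) shared-OTU fractions between compartments relative to a
named reference side, and (iii) the abundance contribution of the shared
OTU set to the downstream community, optionally within a focal taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EnrichmentResult:
    taxon: str
    source_mean: float
    target_mean: float
    factor: float          # target_mean / source_mean; NaN when flagged
    flag: str = "ok"       # ok | absent_in_source | absent_in_both
    lower_bound: float = float("nan")  # censored bound when absent_in_source


@dataclass
class SharedOTUReport:
    reference: str                 # which side the denominator counts
    shared: list[str]
    fraction_shared: float
    n_reference: int
    taxon_breakdown: dict = field(default_factory=dict)


def compartment_enrichment(rel: pd.DataFrame, source_samples, target_samples,
                           taxon: str = "", columns=None,
                           detection_floor: float = 1e-5) -> EnrichmentResult:
    """Mean relative abundance in target divided by mean in source.

    ``rel`` holds per-sample relative abundances (samples x OTUs or
    samples x taxa); ``columns`` restricts to the OTUs/taxa making up the
    focal taxon (summed per sample before averaging). Means are unweighted
    arithmetic means across samples. A zero source mean with a non-zero
    target yields flag ``absent_in_source`` and a censored lower bound
    ``target_mean / detection_floor`` instead of an infinite factor.
    """
    cols = list(columns) if columns is not None else list(rel.columns)
    src = rel.loc[list(source_samples), cols].sum(axis=1).mean()
    tgt = rel.loc[list(target_samples), cols].sum(axis=1).mean()
    if src == 0 and tgt == 0:
        return EnrichmentResult(taxon, src, tgt, float("nan"),
                                flag="absent_in_both")
    if src == 0:
        return EnrichmentResult(taxon, src, tgt, float("nan"),
                                flag="absent_in_source",
                                lower_bound=tgt / detection_floor)
    return EnrichmentResult(taxon, src, tgt, tgt / src)


def detected_otus(counts: pd.DataFrame, samples) -> set[str]:
    """OTUs with >=1 read in >=1 of the given samples."""
    sub = counts.loc[list(samples)]
    return set(sub.columns[(sub > 0).any(axis=0)])


def shared_otus(counts: pd.DataFrame, samples_a, samples_b,
                reference: str = "A",
                taxonomy: pd.DataFrame | None = None,
                rank: str = "phylum") -> SharedOTUReport:
    """Shared-OTU fraction between two compartments.

    fraction_shared = |detected(A) ∩ detected(B)| / |detected(reference)|.
    The reference side is part of the report because the fraction is
    asymmetric.
    """
    det_a = detected_otus(counts, samples_a)
    det_b = detected_otus(counts, samples_b)
    if not det_a or not det_b:
        raise ValueError("a compartment has no detected OTUs")
    shared = sorted(det_a & det_b)
    ref_set = det_a if reference == "A" else det_b
    report = SharedOTUReport(reference=reference, shared=shared,
                             fraction_shared=len(shared) / len(ref_set),
                             n_reference=len(ref_set))
    if taxonomy is not None and shared:
        report.taxon_breakdown = taxon_breakdown_of_shared(
            shared, taxonomy, rank)
    return report


def taxon_breakdown_of_shared(shared, taxonomy: pd.DataFrame,
                              rank: str = "phylum") -> dict[str, float]:
    """Per-taxon fractions of the shared OTU set; values sum to 1."""
    shared = list(shared)
    labels = taxonomy.reindex(shared)[rank].fillna("unclassified")
    frac = labels.value_counts(normalize=True)
    return frac.to_dict()


def shared_abundance_contribution(shared, target_rel: pd.Series,
                                  focal_otus=None) -> float:
    """Summed relative abundance of the shared OTUs in a target community.

    With ``focal_otus`` given, the contribution is renormalized within that
    focal taxon's OTUs: sum(shared ∩ focal) / sum(focal). With no focal
    set, it is the plain sum over the whole community (denominator 1).
    """
    shared = set(shared)
    if focal_otus is None:
        cols = [o for o in target_rel.index if o in shared]
        return float(target_rel.loc[cols].sum())
    focal = [o for o in focal_otus if o in target_rel.index]
    denom = float(target_rel.loc[focal].sum())
    if denom == 0:
        return float("nan")
    cols = [o for o in focal if o in shared]
    return float(target_rel.loc[cols].sum()) / denom


def aggregate_by_rank(rel: pd.DataFrame, taxonomy: pd.DataFrame,
                      rank: str) -> pd.DataFrame:
    """Sum per-OTU relative abundances up to a taxonomic rank."""
    labels = taxonomy.reindex(rel.columns)[rank].fillna("unclassified")
    return rel.T.groupby(labels.values).sum().T
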