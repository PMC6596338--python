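"""Community-assembly inference from phylogenetic and taxonomic turnover.

For every pair of communities the model computes:

* abundance-weighted beta mean-nearest-taxon distance (betaMNTD),
* its standardized effect size betaNTI against a tip-shuffling null
  (999 randomizations by default; |betaNTI| > 2 signals selection), and
* the rescaled Raup-Crick index on Bray-Curtis distance (RC_bray in
  [-1, 1]; |RC| > 0.95 signals dispersal-driven turnover when selection
  is absent),

and classifies the dominant assembly process:

    betaNTI >  2                     -> variable selection
    betaNTI < -2                     -> homogeneous selection
    |betaNTI| <= 2, RC >  0.95       -> dispersal limitation
    |betaNTI| <= 2, RC < -0.95       -> homogenizing dispersal
    otherwise                        -> undominated

The tip-shuffling null permutes the OTU <-> tip assignment over the full
OTU pool of the analyzed table; the Raup-Crick null reassembles both
communities preserving each one's richness and read total, drawing
membership with probability proportional to occurrence frequency across
the metacommunity and reads proportional to metacommunity relative
abundance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

PROCESSES = ("variable_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal",
             "undominated", "undefined")


# ---------------------------------------------------------------------------
# distances


def patristic_distances(tree: dendropy.Tree,
                        otu_ids=None) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix (sum of branch lengths).

    ``otu_ids`` selects and orders the tips; default is the tree's taxon
    order. Raises on missing branch lengths.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a missing branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if otu_ids is None:
        otu_ids = [t.label for t in tree.taxon_namespace]
    missing = [o for o in otu_ids if o not in taxa]
    if missing:
        raise ValueError(f"OTUs not on tree: {missing[:5]}")
    p = len(otu_ids)
    D = np.zeros((p, p))
    for i, j in itertools.combinations(range(p), 2):
        d = pdm.patristic_distance(taxa[otu_ids[i]], taxa[otu_ids[j]])
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=otu_ids, columns=otu_ids)


def beta_mntd(rel_k: np.ndarray, rel_m: np.ndarray, D: np.ndarray) -> float:
    """Abundance-weighted beta mean-nearest-taxon distance.

    betaMNTD = 1/2 [ sum_i rel_k(i) min_{j in m} d(i,j)
                   + sum_j rel_m(j) min_{i in k} d(j,i) ]

    where i runs over OTUs present in community k and j over those in m.
    An OTU present in both communities has nearest-taxon distance 0.
    """
    k = np.flatnonzero(rel_k > 0)
    m = np.flatnonzero(rel_m > 0)
    if k.size == 0 or m.size == 0:
        raise ValueError("empty community")
    sub = D[np.ix_(k, m)]
    return 0.5 * (rel_k[k] @ sub.min(axis=1) + rel_m[m] @ sub.min(axis=0))


def beta_nti(rel_k: np.ndarray, rel_m: np.ndarray, D: np.ndarray,
             n_reps: int = 999, seed=None) -> tuple[float, float, float]:
    """Standardized effect size of betaMNTD under a tip-shuffling null.

    Each replicate permutes the OTU <-> tip assignment over the full pool
    (all rows of ``D``) and recomputes betaMNTD. Returns
    (beta_nti, null_mean, null_sd); beta_nti is NaN when the null is
    degenerate (sd = 0).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    obs = beta_mntd(rel_k, rel_m, D)
    p = D.shape[0]
    k = np.flatnonzero(rel_k > 0)
    m = np.flatnonzero(rel_m > 0)
    wk, wm = rel_k[k], rel_m[m]
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(p)
        sub = D[np.ix_(perm[k], perm[m])]
        null[r] = 0.5 * (wk @ sub.min(axis=1) + wm @ sub.min(axis=0))
    mu = null.mean()
    sd = null.std(ddof=1)
    if sd == 0:
        return float("nan"), mu, sd
    return (obs - mu) / sd, mu, sd


def bray_curtis(rel_k: np.ndarray, rel_m: np.ndarray) -> float:
    """Bray-Curtis dissimilarity of two relative-abundance profiles:
    BC = 1 - sum_o min(rel_k(o), rel_m(o))."""
    return 1.0 - np.minimum(rel_k, rel_m).sum()


def rc_bray(counts_k: np.ndarray, counts_m: np.ndarray,
            meta_counts: np.ndarray, n_reps: int = 999,
            seed=None) -> float:
    """Rescaled Raup-Crick index on Bray-Curtis distance, in [-1, 1].

    Null communities preserve each observed sample's richness and read
    total: membership is drawn without replacement with probability
    proportional to each OTU's occurrence frequency across the
    metacommunity; every member gets one read and the remaining reads are
    assigned multinomially with probability proportional to metacommunity
    relative abundance. P = (#null < obs + 0.5 #ties) / n_reps;
    RC = 2 (P - 1/2).
    """
    rng = np.random.default_rng(seed)
    meta_counts = np.asarray(meta_counts)
    occ = (meta_counts > 0).sum(axis=0).astype(float)
    if occ.sum() == 0:
        raise ValueError("empty metacommunity")
    p_occ = occ / occ.sum()
    meta_rel = meta_counts.sum(axis=0).astype(float)
    meta_rel /= meta_rel.sum()
    pool = np.arange(meta_counts.shape[1])

    def profile(c):
        c = np.asarray(c, dtype=np.int64)
        rich = int((c > 0).sum())
        reads = int(c.sum())
        if rich == 0:
            raise ValueError("empty community")
        if rich > (occ > 0).sum():
            raise ValueError("sample richness exceeds metacommunity richness")
        return c / reads, rich, reads

    rel_k, rich_k, reads_k = profile(counts_k)
    rel_m, rich_m, reads_m = profile(counts_m)
    obs = bray_curtis(rel_k, rel_m)

    def null_community(rich, reads):
        members = rng.choice(pool, size=rich, replace=False, p=p_occ)
        w = meta_rel[members]
        if w.sum() == 0:
            w = np.ones(rich)
        counts = np.ones(rich) + rng.multinomial(reads - rich, w / w.sum())
        vec = np.zeros(meta_counts.shape[1])
        vec[members] = counts / reads
        return vec

    less = ties = 0
    for _ in range(n_reps):
        bc = bray_curtis(null_community(rich_k, reads_k),
                         null_community(rich_m, reads_m))
        if abs(bc - obs) < 1e-12:
            ties += 1
        elif bc < obs:
            less += 1
    p_val = (less + 0.5 * ties) / n_reps
    return 2.0 * (p_val - 0.5)


def classify_assembly(beta_nti_value: float, rc_bray_value: float) -> str:
    """Five-way assembly-process classification from the two indices."""
    if np.isnan(beta_nti_value) or np.isnan(rc_bray_value):
        return "undefined"
    if beta_nti_value > 2:
        return "variable_selection"
    if beta_nti_value < -2:
        return "homogeneous_selection"
    if rc_bray_value > 0.95:
        return "dispersal_limitation"
    if rc_bray_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


# ---------------------------------------------------------------------------
# model / results


class CommunityAssembly:
    """Pairwise assembly-process model for a set of communities.

    Parameters
    ----------
    table : OTUTable
        Counts for the samples to analyze (fraction samples allowed when
        ``metadata`` and ``qpcr`` are given; they are merged per site and
        time point before analysis).
    tree : dendropy.Tree or DataFrame
        OTU phylogeny, or a precomputed patristic distance matrix.
    metadata, qpcr : optional
        Enable qPCR-weighted merging of F01/F02 fraction samples.
    """

    def __init__(self, table, tree, metadata=None, qpcr=None):
        self.table = table
        self.metadata = metadata
        self.qpcr = qpcr
        if isinstance(tree, pd.DataFrame):
            self._dist = tree
            self.tree = None
        else:
            self.tree = tree
            self._dist = None

    def _distance_matrix(self, otu_ids) -> pd.DataFrame:
        if self._dist is not None:
            return self._dist.loc[otu_ids, otu_ids]
        return patristic_distances(self.tree, otu_ids)

    def fit(self, samples=None, depth: int = 7876, n_reps: int = 999,
            seed=None) -> "AssemblyResults":
        """Rarefy, merge fractions where indicated, and compute all
        pairwise betaMNTD / betaNTI / RC_bray results.

        ``samples`` restricts which pairs are compared (post-merge
        identifiers, i.e. "site:time_point" for fractionated water
        samples); the full table always serves as the metacommunity of
        the Raup-Crick null and as the tip-shuffling pool.
        """
        from .io import rarefy, relative_abundance
        from .fractions import merge_sample_pairs

        rng = np.random.default_rng(seed)
        rared = rarefy(self.table, depth, seed=rng.integers(2**31))
        if self.metadata is not None and self.qpcr is not None:
            merged_rel, _ = merge_sample_pairs(rared, self.metadata, self.qpcr)
            # the Raup-Crick null needs integer counts: re-discretize the
            # merged profile with a seeded multinomial draw at depth
            counts = pd.DataFrame(
                [rng.multinomial(depth, row / row.sum())
                 for _, row in merged_rel.iterrows()],
                index=merged_rel.index, columns=merged_rel.columns)
            rel = merged_rel
        else:
            counts = rared.counts
            rel = relative_abundance(rared)
        keep = counts.columns[(counts.sum(axis=0) > 0)
                              | (rel.sum(axis=0) > 0)]
        counts, rel = counts[keep], rel[keep]
        D = self._distance_matrix(list(keep)).to_numpy()

        if samples is None:
            names = sorted(counts.index)
        else:
            missing = set(samples) - set(counts.index)
            if missing:
                raise ValueError(f"unknown samples: {sorted(missing)}")
            names = sorted(samples)
        rows = []
        for a, b in itertools.combinations(names, 2):
            sub_seed = rng.integers(2**31)
            sub = np.random.default_rng(sub_seed)
            bm = beta_mntd(rel.loc[a].to_numpy(), rel.loc[b].to_numpy(), D)
            bnti, mu, sd = beta_nti(rel.loc[a].to_numpy(),
                                    rel.loc[b].to_numpy(), D,
                                    n_reps=n_reps,
                                    seed=sub.integers(2**31))
            rc = rc_bray(counts.loc[a].to_numpy(), counts.loc[b].to_numpy(),
                         counts.to_numpy(), n_reps=n_reps,
                         seed=sub.integers(2**31))
            rows.append({"sample_a": a, "sample_b": b, "beta_mntd": bm,
                         "null_mean": mu, "null_sd": sd, "beta_nti": bnti,
                         "rc_bray": rc,
                         "process": classify_assembly(bnti, rc),
                         "n_reps": n_reps, "seed": sub_seed})
        return AssemblyResults(pd.DataFrame(rows), depth=depth,
                               n_reps=n_reps, seed=seed)


@dataclass
class AssemblyResults:
    """Per-pair assembly indices and process classifications."""

    pairs: pd.DataFrame
    depth: int
    n_reps: int
    seed: object = None

    def process_counts(self) -> pd.Series:
        return self.pairs["process"].value_counts()

    @property
    def modal_process(self) -> str:
        return self.process_counts().idxmax()

    def summary(self) -> str:
        lines = [
            "Community assembly null-model results",
            f"  pairs: {len(self.pairs)}   rarefaction depth: {self.depth}"
            f"   randomizations: {self.n_reps}",
            "",
            self.pairs[["sample_a", "sample_b", "beta_mntd", "beta_nti",
                        "rc_bray", "process"]].to_string(index=False,
                                                         float_format="%.3f"),
            "",
            "process counts: " + ", ".join(
                f"{k}={v}" for k, v in self.process_counts().items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)
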