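"""Compositionally aware co-occurrence network with stability selection.

Pipeline: filter rare OTUs (>= 100 total reads and present in >= 30% of
samples), centered log-ratio transform the counts, estimate a sparse
conditional-dependence graph by Meinshausen-Buhlmann neighborhood
selection (per-node L1-penalized regressions along a log-spaced lambda
path), pick the sparsity level and score edge confidence by StARS
(selection frequency across random subsamples), keep positive edges with
confidence > 0.5, and cluster the result by greedy modularity
maximization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path


@dataclass(frozen=True)
class NetworkConfig:
    """Tuning parameters of the network pipeline (defaults follow the
    study settings: nlambda=20, lambda.min.ratio=1e-2, 50 StARS
    resamples, confidence cutoff 0.5, >=100 reads / >=30% prevalence)."""

    min_total_reads: int = 100
    min_prevalence: float = 0.30
    nlambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_reps: int = 50
    stars_instability_threshold: float = 0.05
    confidence_cutoff: float = 0.5
    pseudocount: float = 1.0
    seed: object = None

    def __post_init__(self):
        if not (0 < self.min_prevalence <= 1):
            raise ValueError("min_prevalence must be in (0, 1]")
        for name in ("min_total_reads", "nlambda", "stars_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def prevalence_abundance_filter(table, cfg: NetworkConfig):
    """Keep OTUs with >= min_total_reads total AND present (>= 1 read)
    in >= ceil(min_prevalence * n_samples) samples."""
    from .io import OTUTable

    counts = table.counts if isinstance(table, OTUTable) else table
    n = counts.shape[0]
    need = math.ceil(cfg.min_prevalence * n)
    total_ok = counts.sum(axis=0) >= cfg.min_total_reads
    prev_ok = (counts > 0).sum(axis=0) >= need
    keep = counts.columns[total_ok & prev_ok]
    if len(keep) == 0:
        raise ValueError("no OTU passes the prevalence/abundance filter")
    out = counts[keep].copy()
    return OTUTable(out) if isinstance(table, OTUTable) else out


def clr_transform(counts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of counts: per sample,
    x = log(count + pseudocount), clr = x - mean(x). Row means are 0."""
    from .io import OTUTable

    if isinstance(counts, OTUTable):
        counts = counts.counts
    arr = np.asarray(counts, dtype=float)
    logged = np.log(arr + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(clr, index=counts.index, columns=counts.columns)
    return clr


# ---------------------------------------------------------------------------
# neighborhood selection


def _lambda_path(X: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Shared log-spaced path from lambda_max (smallest lambda selecting
    nothing anywhere) down to lambda_max * lambda_min_ratio."""
    n, p = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    gram = np.abs(Xc.T @ Xc) / n
    np.fill_diagonal(gram, 0.0)
    lam_max = gram.max()
    if lam_max <= 0:
        raise ValueError("degenerate data: all columns uncorrelated/constant")
    return np.logspace(np.log10(lam_max),
                       np.log10(lam_max * cfg.lambda_min_ratio),
                       cfg.nlambda)


def mb_neighborhood_path(clr: np.ndarray, cfg: NetworkConfig,
                         lambdas: np.ndarray | None = None):
    """Per-lambda undirected edge sets from per-node lasso regressions.

    For each node j, its CLR profile is regressed on all other columns
    along the lambda path. An undirected edge (i, j) exists at a lambda
    if either direction selects it (union rule); the stored coefficient
    is the mean of the directed coefficients that selected it.

    Returns (lambdas, adjacency boolean array (nlambda, p, p),
    coefficient array (nlambda, p, p), directed-selection array).
    """
    X = np.asarray(clr, dtype=float)
    n, p = X.shape
    if n < 4 or p < 2:
        raise ValueError("need >= 4 samples and >= 2 OTUs")
    if lambdas is None:
        lambdas = _lambda_path(X, cfg)
    Xc = X - X.mean(axis=0, keepdims=True)
    nlam = len(lambdas)
    beta = np.zeros((nlam, p, p))  # beta[l, j, i] = coef of i predicting j
    others = np.arange(p)
    for j in range(p):
        idx = others[others != j]
        # lasso_path evaluates alphas in decreasing order, matching our path
        alphas_out, coefs, _ = lasso_path(Xc[:, idx], Xc[:, j],
                                          alphas=lambdas)
        assert np.allclose(alphas_out, lambdas)
        beta[:, j, idx] = coefs.T
    directed = beta != 0
    adj = directed | directed.transpose(0, 2, 1)
    with np.errstate(invalid="ignore"):
        nsel = directed.astype(float) + directed.transpose(0, 2, 1)
        coef = np.where(nsel > 0,
                        (beta + beta.transpose(0, 2, 1)) / np.maximum(nsel, 1),
                        0.0)
    for l in range(nlam):
        np.fill_diagonal(adj[l], False)
        np.fill_diagonal(coef[l], 0.0)
    return lambdas, adj, coef, directed


def stars_confidence(clr: np.ndarray, cfg: NetworkConfig, seed=None):
    """StARS: subsample, refit the path, and score edge stability.

    Subsample size is min(floor(10 sqrt(n)), floor(0.8 n)) without
    replacement. Per-edge confidence at a lambda is the fraction of
    subsamples selecting the edge; the selected lambda is the densest one
    whose monotonized average edge instability 2 theta (1 - theta) stays
    <= the threshold. Returns (selected index, lambdas, confidence at the
    selected lambda (p, p), full confidence array, subsample index list).
    """
    X = np.asarray(clr, dtype=float)
    n, p = X.shape
    b = min(int(10 * math.sqrt(n)), int(0.8 * n))
    if b < 4:
        raise ValueError("subsample size below 4; need more samples")
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    lambdas = _lambda_path(X, cfg)
    freq = np.zeros((cfg.nlambda, p, p))
    subsamples = []
    for _ in range(cfg.stars_reps):
        idx = rng.choice(n, size=b, replace=False)
        subsamples.append(np.sort(idx).tolist())
        _, adj, _, _ = mb_neighborhood_path(X[idx], cfg, lambdas=lambdas)
        freq += adj
    theta = freq / cfg.stars_reps
    iu = np.triu_indices(p, 1)
    instability = (2 * theta * (1 - theta))[:, iu[0], iu[1]].mean(axis=1)
    # monotonize from the sparse (large-lambda) end, then take the densest
    # lambda still under the threshold; fall back to the sparsest
    mono = np.maximum.accumulate(instability)
    ok = np.flatnonzero(mono <= cfg.stars_instability_threshold)
    sel = int(ok.max()) if ok.size else 0
    return sel, lambdas, theta[sel], theta, subsamples


# ---------------------------------------------------------------------------
# model / results


class CooccurrenceNetwork:
    """Stability-selected co-occurrence network model for an OTU table."""

    def __init__(self, table, config: NetworkConfig | None = None,
                 taxonomy: pd.DataFrame | None = None):
        self.config = config or NetworkConfig()
        self.table = table
        self.taxonomy = taxonomy

    def fit(self, seed=None) -> "NetworkResults":
        cfg = self.config
        filtered = prevalence_abundance_filter(self.table, cfg)
        from .io import OTUTable
        counts = (filtered.counts if isinstance(filtered, OTUTable)
                  else filtered)
        otu_ids = list(counts.columns)
        clr = clr_transform(counts, cfg.pseudocount).to_numpy()
        sel, lambdas, conf, theta, subsamples = stars_confidence(
            clr, cfg, seed=seed if seed is not None else cfg.seed)
        _, adj, coef, _ = mb_neighborhood_path(clr, cfg, lambdas=lambdas)
        iu = np.triu_indices(len(otu_ids), 1)
        rows = []
        for i, j in zip(*iu):
            if adj[sel, i, j] or conf[i, j] > 0:
                rows.append({"otu_a": otu_ids[i], "otu_b": otu_ids[j],
                             "coefficient": coef[sel, i, j],
                             "confidence": conf[i, j],
                             "selected": bool(adj[sel, i, j])})
        edges = pd.DataFrame(
            rows, columns=["otu_a", "otu_b", "coefficient", "confidence",
                           "selected"])
        return NetworkResults(edges=edges, otu_ids=otu_ids, config=cfg,
                              selected_lambda_index=sel,
                              lambdas=lambdas, taxonomy=self.taxonomy,
                              subsample_indices=subsamples)


def filter_network(edges: pd.DataFrame, otu_ids, cfg: NetworkConfig,
                   taxonomy: pd.DataFrame | None = None) -> nx.Graph:
    """Build the high-confidence positive graph: keep edges that were
    selected on the full data with coefficient > 0 and confidence
    strictly > the cutoff. All filtered-table OTUs remain as nodes."""
    g = nx.Graph()
    g.add_nodes_from(otu_ids)
    if taxonomy is not None:
        for o in otu_ids:
            if o in taxonomy.index:
                g.nodes[o].update(taxonomy.loc[o].to_dict())
    for _, e in edges.iterrows():
        if (e["selected"] and e["coefficient"] > 0
                and e["confidence"] > cfg.confidence_cutoff):
            g.add_edge(e["otu_a"], e["otu_b"],
                       coefficient=float(e["coefficient"]),
                       confidence=float(e["confidence"]))
    return g


def greedy_modularity_clusters(graph: nx.Graph) -> tuple[pd.Series, float]:
    """Greedy modularity maximization; isolated nodes become singleton
    clusters. Returns (cluster labels 1..k by decreasing size, modularity
    of the partition on the non-trivial subgraph)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    core = graph.subgraph([n for n in graph if graph.degree[n] > 0])
    labels = {}
    if core.number_of_edges() > 0:
        comms = nx.community.greedy_modularity_communities(core)
        mod = nx.community.modularity(core, comms)
        for cid, comm in enumerate(comms, start=1):
            for node in comm:
                labels[node] = cid
    else:
        mod = float("nan")
    next_id = max(labels.values(), default=0)
    for node in graph:
        if node not in labels:
            next_id += 1
            labels[node] = next_id
    return pd.Series(labels, name="cluster"), mod


def degree_distribution(graph: nx.Graph):
    """Per-node degrees and a degree histogram (sum of degrees = 2|E|)."""
    degrees = pd.Series(dict(graph.degree()), name="degree")
    hist = degrees.value_counts().sort_index()
    return degrees, hist


def neighbor_composition_test(graph: nx.Graph, taxonomy: pd.DataFrame,
                              group_a, group_b, label_rank: str = "phylum",
                              label_value: str = "Patescibacteria"):
    """Mann-Whitney U on the per-node fraction of first-degree neighbors
    carrying a taxonomic label, compared between two node groups.

    Exact p for combined n <= 20 without ties; normal approximation with
    tie correction otherwise. Returns (U, p, per-node fractions).
    """
    def frac(node):
        nbrs = list(graph.neighbors(node))
        if not nbrs:
            return float("nan")
        hits = sum(1 for v in nbrs
                   if taxonomy.at[v, label_rank] == label_value)
        return hits / len(nbrs)

    fa = np.array([frac(v) for v in group_a if v in graph])
    fb = np.array([frac(v) for v in group_b if v in graph])
    fa, fb = fa[~np.isnan(fa)], fb[~np.isnan(fb)]
    if fa.size == 0 or fb.size == 0:
        raise ValueError("a group has no nodes with neighbors")
    has_ties = len(np.unique(np.concatenate([fa, fb]))) < fa.size + fb.size
    method = "exact" if (fa.size + fb.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(fa, fb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), (fa, fb)


@dataclass
class NetworkResults:
    """Fitted co-occurrence network: scored edges plus derived views."""

    edges: pd.DataFrame
    otu_ids: list
    config: NetworkConfig
    selected_lambda_index: int
    lambdas: np.ndarray
    taxonomy: pd.DataFrame | None = None
    subsample_indices: list = field(default_factory=list)

    def graph(self) -> nx.Graph:
        return filter_network(self.edges, self.otu_ids, self.config,
                              self.taxonomy)

    def clusters(self):
        return greedy_modularity_clusters(self.graph())

    def degree_distribution(self):
        return degree_distribution(self.graph())

    def summary(self) -> str:
        g = self.graph()
        labels, mod = self.clusters()
        n_clusters = labels[labels.map(labels.value_counts()) > 1].nunique()
        kept = g.number_of_edges()
        lines = [
            "Co-occurrence network (neighborhood selection + StARS)",
            f"  OTUs after filter: {len(self.otu_ids)}   candidate edges "
            f"scored: {len(self.edges)}",
            f"  selected lambda: {self.lambdas[self.selected_lambda_index]:.4g}"
            f" (index {self.selected_lambda_index + 1}/{len(self.lambdas)})",
            f"  positive edges with confidence > "
            f"{self.config.confidence_cutoff}: {kept}",
            f"  non-singleton clusters: {n_clusters}   modularity: {mod:.3f}"
            if kept else "  (no edges retained)",
        ]
        return "\n".join(lines)

    def to_edge_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)
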