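"""Synthetic hillslope datasets with known ground truth.

The generator emulates the study design the pipeline targets: forest-soil
communities feed seepage (with per-clade mobilization odds), seepage seeds
a series of groundwater wells whose communities form under a configurable
assembly regime, and every water sample is split into 0.1 um / 0.2 um
filter-fraction counts by per-clade binomial partitioning, with qPCR
totals consistent with the split. Hydrochemistry follows the environmental
gradient that drives niche-based regimes; a sparse positive-association
graph can be planted in the groundwater log-abundances.

Scenario presets (``assembly_regime``): ``selection``,
``homogeneous_selection``, ``dispersal_limitation``,
``homogenizing_dispersal``, ``neutral``, ``disjoint``.
"""

from __future__ import annotations

import itertools
import json
import math
import random
from dataclasses import dataclass, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import OTUTable

REGIMES = ("selection", "homogeneous_selection", "dispersal_limitation",
           "homogenizing_dispersal", "neutral", "disjoint")

_PHYLA = ("Proteobacteria", "Nitrospirota", "Acidobacteriota",
          "Planctomycetota", "Bacteroidota")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic dataset."""

    seed: int = 0
    n_otus: int = 150
    n_clades: int = 6
    metacommunity_sigma: float = 1.5   # log-normal abundance spread
    n_soil: int = 10
    n_seepage: int = 10
    wells: tuple = ("H13", "H31", "H41", "H51")
    well_distances: tuple = (0.0, 1.3, 2.7, 5.4)   # km along the hillslope
    n_time_points: int = 1
    assembly_regime: str = "neutral"
    # source tracking: one clade is preferentially mobilized into seepage
    mobilized_clade: int = 0
    mobilization_multiplier: float = 100.0
    soil_suppression: float = 0.05     # mobilized clade is rare in soil
    # fraction partitioning: probability an individual passes the 0.2 um
    # filter, per clade
    ultrasmall_clades: tuple = (0,)
    ultrasmall_share: float = 0.25
    baseline_share: float = 0.02
    # environment / niches
    env_params: tuple = ("DO", "nitrate", "sulfate", "ammonium", "sodium",
                         "potassium", "magnesium", "calcium", "TIC", "TOC")
    niche_param: str = "DO"
    niche_breadth: float = 0.5
    env_contrast: float = 2.0          # +/- value of the two regimes
    establishment_prob: float = 0.7    # recruitment stochasticity
    sample_noise_sd: float = 0.5       # per-sample lognormal noise (log sd)
    private_fraction: float = 0.3      # dispersal limitation membership
    # planted positive-association modules: tuples of OTU index tuples;
    # every within-module pair is a planted edge (module members share a
    # log-normal latent factor, giving an exact clique-structured
    # conditional-dependence graph)
    planted_modules: tuple = ()
    association_effect: float = 2.0
    read_depth: int = 20000
    qpcr_total_range: tuple = (1.2e7, 8.6e8)  # gene copies per liter

    def __post_init__(self):
        if self.assembly_regime not in REGIMES:
            raise ValueError(f"unknown regime {self.assembly_regime!r}")
        if not (0 <= self.ultrasmall_share <= 1
                and 0 <= self.baseline_share <= 1):
            raise ValueError("partition shares must be probabilities")
        seen = set()
        for mod in self.planted_modules:
            if len(set(mod)) != len(mod):
                raise ValueError("planted module repeats an OTU")
            if seen & set(mod):
                raise ValueError("planted modules overlap")
            seen |= set(mod)
        if len(self.wells) != len(self.well_distances):
            raise ValueError("wells and well_distances length mismatch")


@dataclass
class GroundTruth:
    """What each pipeline stage should recover from the bundle."""

    clade_of_otu: dict
    mobilized_clade: int
    mobilization_multiplier: float
    ultrasmall_share_by_clade: dict
    expected_process_by_pair: dict     # "a|b" -> process label
    env_by_well: dict
    niche_sign_by_clade: dict
    planted_edges: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class ScenarioBundle:
    """A complete internally consistent dataset."""

    config: ScenarioConfig
    tree: dendropy.Tree
    table: OTUTable                 # soil bulk + water F01/F02 counts
    bulk_counts: pd.DataFrame       # pre-split water counts, "site:tp" index
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    qpcr: pd.DataFrame
    hydrochem: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# tree and clades


def generate_tree(n_otus: int, seed=None,
                  ultrametric: bool = True) -> dendropy.Tree:
    """Birth-death tree with ``n_otus`` extant tips labeled Otu000001..."""
    if n_otus < 3:
        raise ValueError("need at least 3 OTUs")
    py_rng = random.Random(int(np.random.default_rng(seed).integers(2**31)))
    from dendropy.simulate import treesim
    tree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.2,
                                    num_extant_tips=n_otus, rng=py_rng)
    if not ultrametric:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= py_rng.uniform(0.5, 1.5)
    for i, taxon in enumerate(tree.taxon_namespace):
        taxon.label = f"Otu{i + 1:06d}"
    return tree


def _patristic_array(tree: dendropy.Tree, otu_ids) -> np.ndarray:
    from .assembly import patristic_distances
    return patristic_distances(tree, otu_ids).to_numpy()


def assign_clades(tree: dendropy.Tree, otu_ids, n_clades: int) -> np.ndarray:
    """Partition tips into phylogenetically coherent clades by average-
    linkage clustering of patristic distances."""
    D = _patristic_array(tree, otu_ids)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return hierarchy.fcluster(Z, t=n_clades, criterion="maxclust") - 1


def brownian_optima(tree: dendropy.Tree, otu_ids, rng,
                    burst_rate: float = 4.0) -> np.ndarray:
    """Niche optima evolved by early-burst Brownian motion along the tree.

    The Brownian rate decays exponentially toward the present
    (``exp(-burst_rate * depth / height)``), so most trait variance arises
    on deep branches: clades are strongly niche-conserved, which is the
    premise the phylogenetic null-model approach rests on. Values are
    standardized to mean 0, sd 1 across tips.
    """
    height = max(leaf.distance_from_root()
                 for leaf in tree.leaf_node_iter()) or 1.0
    vals, depths = {}, {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            vals[node], depths[node] = 0.0, 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0)
            rate = math.exp(-burst_rate * depths[node.parent_node] / height)
            step = rng.normal(0.0, rate * math.sqrt(
                max(node.edge.length or 0.0, 1e-9)))
            vals[node] = vals[node.parent_node] + step
    by_label = {leaf.taxon.label: vals[leaf] for leaf in tree.leaf_node_iter()}
    x = np.array([by_label[o] for o in otu_ids])
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# scenario generation


def _lognormal_noise(rng, size, sd):
    return np.exp(rng.normal(0.0, sd, size=size))


def generate_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Generate the full dataset bundle plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = generate_tree(cfg.n_otus, seed=rng.integers(2**31))
    otu_ids = [t.label for t in tree.taxon_namespace]
    clades = assign_clades(tree, otu_ids, cfg.n_clades)
    optima = brownian_optima(tree, otu_ids, rng)

    # log-normal metacommunity species-abundance distribution
    meta_abund = np.exp(rng.normal(0.0, cfg.metacommunity_sigma,
                                   size=cfg.n_otus))

    # per-clade multipliers
    mob = np.ones(cfg.n_otus)
    mob[clades == cfg.mobilized_clade] = cfg.mobilization_multiplier
    soil_scale = np.ones(cfg.n_otus)
    soil_scale[clades == cfg.mobilized_clade] = cfg.soil_suppression
    q_pass = np.full(cfg.n_otus, cfg.baseline_share)
    for c in cfg.ultrasmall_clades:
        q_pass[clades == c] = cfg.ultrasmall_share

    soil_pool = meta_abund * soil_scale
    seepage_pool = soil_pool * mob

    counts, meta_rows = {}, []

    def add_sample(sid, compartment, site, tp, fraction, assemblage, vec):
        counts[sid] = vec
        meta_rows.append({"sample_id": sid, "compartment": compartment,
                          "site": site, "time_point": tp,
                          "fraction": fraction, "assemblage": assemblage})

    # ---- soil (bulk) ----
    for i in range(cfg.n_soil):
        w = soil_pool * _lognormal_noise(rng, cfg.n_otus, 0.3)
        vec = rng.multinomial(cfg.read_depth, w / w.sum())
        add_sample(f"SOIL{i + 1}", "soil", f"H1TS{i + 1}", "T1", "bulk",
                   "none", vec)

    bulk_rows, qpcr_rows, hydro_rows = {}, [], []

    def split_fractions(site, tp, compartment, assemblage, weights):
        # biomass splits by the per-clade filter-passage probability, but
        # each fraction is sequenced to full depth (sequencing depth is
        # unrelated to biomass); qPCR totals carry the biomass shares
        w01 = weights * q_pass
        w02 = weights * (1.0 - q_pass)
        share01 = w01.sum() / weights.sum()
        f01 = rng.multinomial(cfg.read_depth, w01 / w01.sum())
        f02 = rng.multinomial(cfg.read_depth, w02 / w02.sum())
        bulk_rows[f"{site}:{tp}"] = f01 + f02
        for frac, vec in (("F01", f01), ("F02", f02)):
            add_sample(f"{site}_{tp}_{frac}", compartment, site, tp, frac,
                       assemblage, vec)
        total = rng.uniform(*cfg.qpcr_total_range)
        qpcr_rows.append({"site": site, "time_point": tp, "fraction": "F01",
                          "gene_copies_per_L": total * share01})
        qpcr_rows.append({"site": site, "time_point": tp, "fraction": "F02",
                          "gene_copies_per_L": total * (1.0 - share01)})

    # ---- seepage (fractionated water) ----
    for i in range(cfg.n_seepage):
        w = seepage_pool * _lognormal_noise(rng, cfg.n_otus, 0.3)
        split_fractions(f"H1L{i + 1}", "T1", "seepage", "none", w)

    # ---- groundwater wells under the assembly regime ----
    regime = cfg.assembly_regime
    n_wells = len(cfg.wells)
    # niche regimes: environments sit on real clade optima, so selection
    # acts on phylogenetically coherent species pools
    sizes = np.bincount(clades, minlength=cfg.n_clades)
    eligible = [c for c in range(cfg.n_clades)
                if sizes[c] >= max(10, cfg.n_otus // 20)]
    clade_opt = {c: float(optima[clades == c].mean()) for c in eligible}
    env_by_well = {}
    if regime == "selection":
        lo = min(clade_opt, key=clade_opt.get)
        hi = max(clade_opt, key=clade_opt.get)
        for i, well in enumerate(cfg.wells):
            env_by_well[well] = clade_opt[hi if i % 2 else lo]
    elif regime == "homogeneous_selection":
        # the environment matches the clade whose niche optimum is most
        # isolated from all others, so filtering is clade-specific
        focal = max(eligible, key=lambda c: min(
            abs(clade_opt[c] - clade_opt[o])
            for o in eligible if o != c))
        env_by_well = {w: clade_opt[focal] for w in cfg.wells}
    else:
        env_by_well = {w: 0.0 for w in cfg.wells}

    # dispersal limitation: each OTU establishes in one primary well, with
    # a small immigration probability decaying with hillslope distance
    assignment = rng.integers(0, n_wells, size=cfg.n_otus)
    private_masks = {}
    for i, w in enumerate(cfg.wells):
        p_im = 0.08 * math.exp(-cfg.well_distances[i] / 2.0)
        private_masks[w] = ((assignment == i)
                            | (rng.random(cfg.n_otus) < p_im))
    disjoint_masks = {w: assignment == i for i, w in enumerate(cfg.wells)}

    modules = [np.asarray(m, dtype=int) for m in cfg.planted_modules]

    for t in range(cfg.n_time_points):
        tp = f"T{t + 1}"
        # homogenizing dispersal: high exchange homogenizes which taxa
        # establish, so all wells share one realized colonization field
        shared_mask = rng.random(cfg.n_otus) < 0.5
        shared_field = _lognormal_noise(rng, cfg.n_otus, 1.0) * shared_mask
        for i, well in enumerate(cfg.wells):
            if regime == "neutral":
                w = seepage_pool * _lognormal_noise(rng, cfg.n_otus,
                                                    cfg.sample_noise_sd)
            elif regime == "homogenizing_dispersal":
                w = (seepage_pool * shared_field
                     * _lognormal_noise(rng, cfg.n_otus, 0.1))
            elif regime == "dispersal_limitation":
                w = (seepage_pool * private_masks[well]
                     * _lognormal_noise(rng, cfg.n_otus, 1.0))
            elif regime == "disjoint":
                w = seepage_pool * disjoint_masks[well]
            else:  # niche-based regimes: truncated Gaussian filter plus
                # recruitment stochasticity (drift decides which members of
                # the suitable species pool establish in each sample)
                env = env_by_well[well]
                filt = np.exp(-(optima - env) ** 2
                              / (2 * cfg.niche_breadth ** 2))
                filt[filt < 1e-2] = 0.0
                establish = rng.random(cfg.n_otus) < cfg.establishment_prob
                w = (meta_abund * filt * establish
                     * _lognormal_noise(rng, cfg.n_otus, 0.5))
            logw = np.log(np.where(w > 0, w, 1e-300))
            for members in modules:
                logw[members] += cfg.association_effect * rng.normal()
            w = np.where(w > 0, np.exp(logw - logw[w > 0].max()), 0.0)
            split_fractions(well, tp, "groundwater", "HTL", w)
            # hydrochemistry for this (well, time point)
            row = {"site": well, "time_point": tp}
            for k, param in enumerate(cfg.env_params):
                if param == cfg.niche_param:
                    row[param] = env_by_well[well] + rng.normal(0, 0.2)
                else:
                    base = (3 * k) % 7 + i  # well-graded baseline
                    row[param] = base + rng.normal(0, 0.5)
            hydro_rows.append(row)

    table = OTUTable(pd.DataFrame.from_dict(counts, orient="index",
                                            columns=otu_ids, dtype=np.int64))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    bulk = pd.DataFrame.from_dict(bulk_rows, orient="index",
                                  columns=otu_ids, dtype=np.int64)
    taxonomy = _make_taxonomy(otu_ids, clades, cfg)
    qpcr = pd.DataFrame(qpcr_rows)
    hydrochem = pd.DataFrame(hydro_rows).set_index(["site", "time_point"])

    truth = GroundTruth(
        clade_of_otu={o: int(c) for o, c in zip(otu_ids, clades)},
        mobilized_clade=cfg.mobilized_clade,
        mobilization_multiplier=cfg.mobilization_multiplier,
        ultrasmall_share_by_clade={
            int(c): (cfg.ultrasmall_share if c in cfg.ultrasmall_clades
                     else cfg.baseline_share)
            for c in range(cfg.n_clades)},
        expected_process_by_pair=_expected_processes(cfg, env_by_well),
        env_by_well=env_by_well,
        niche_sign_by_clade=_niche_signs(clades, optima, cfg),
        planted_edges=[[otu_ids[i], otu_ids[j]]
                       for m in modules
                       for i, j in itertools.combinations(sorted(m), 2)],
    )
    return ScenarioBundle(cfg, tree, table, bulk, metadata, taxonomy, qpcr,
                          hydrochem, truth)


def _make_taxonomy(otu_ids, clades, cfg: ScenarioConfig) -> pd.DataFrame:
    patesci = {cfg.mobilized_clade, *cfg.ultrasmall_clades}
    rows = []
    for o, c in zip(otu_ids, clades):
        if c in patesci:
            phylum, klass = "Patescibacteria", "Paceibacteria"
        else:
            phylum = _PHYLA[c % len(_PHYLA)]
            klass = f"Class{c}"
        rows.append({"otu_id": o, "domain": "Bacteria", "phylum": phylum,
                     "class": klass, "order": f"Order{c}",
                     "family": f"Family{c}", "genus": "unclassified"})
    return pd.DataFrame(rows).set_index("otu_id")


def _expected_processes(cfg: ScenarioConfig, env_by_well) -> dict:
    expected = {}
    label_map = {
        "neutral": "undominated",
        "dispersal_limitation": "dispersal_limitation",
        "disjoint": "dispersal_limitation",
        "homogenizing_dispersal": "homogenizing_dispersal",
        "homogeneous_selection": "homogeneous_selection",
    }
    wells = sorted(cfg.wells)
    for i, a in enumerate(wells):
        for b in wells[i + 1:]:
            if cfg.assembly_regime == "selection":
                lab = ("variable_selection"
                       if env_by_well[a] != env_by_well[b]
                       else "homogeneous_selection")
            else:
                lab = label_map[cfg.assembly_regime]
            expected[f"{a}|{b}"] = lab
    return expected


def _niche_signs(clades, optima, cfg: ScenarioConfig) -> dict:
    if cfg.assembly_regime not in ("selection", "homogeneous_selection"):
        return {}
    return {int(c): int(np.sign(optima[clades == c].mean()))
            for c in np.unique(clades)}


# ---------------------------------------------------------------------------
# presets and disk I/O


# niche-based regimes need a larger, more even species pool and a filter
# narrow relative to the between-clade niche spread to express selection
_PRESET_OVERRIDES = {
    "selection": dict(n_otus=300, metacommunity_sigma=0.8,
                      establishment_prob=0.6, niche_breadth=0.25),
    "homogeneous_selection": dict(n_otus=300, metacommunity_sigma=0.8,
                                  establishment_prob=0.6, niche_breadth=0.2),
}


def scenario_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named preset: one config per assembly regime."""
    if name not in REGIMES:
        raise ValueError(f"unknown scenario {name!r}; one of {REGIMES}")
    kwargs = dict(_PRESET_OVERRIDES.get(name, {}))
    kwargs.update(overrides)
    return ScenarioConfig(seed=seed, assembly_regime=name, **kwargs)


def write_bundle(bundle: ScenarioBundle, directory) -> dict:
    """Write all core formats plus ground-truth JSON; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": d / "otu_table.tsv",
        "bulk_counts": d / "bulk_counts.tsv",
        "metadata": d / "metadata.csv",
        "taxonomy": d / "taxonomy.tsv",
        "qpcr": d / "qpcr.csv",
        "hydrochem": d / "hydrochem.csv",
        "tree": d / "tree.nwk",
        "ground_truth": d / "ground_truth.json",
    }
    bundle.table.to_tsv(paths["otu_table"])
    bundle.bulk_counts.to_csv(paths["bulk_counts"], sep="\t",
                              index_label="sample")
    bundle.metadata.to_csv(paths["metadata"], index=False)
    bundle.taxonomy.to_csv(paths["taxonomy"], sep="\t",
                           index_label="otu_id")
    bundle.qpcr.to_csv(paths["qpcr"], index=False)
    bundle.hydrochem.reset_index().to_csv(paths["hydrochem"], index=False)
    bundle.tree.write(path=str(paths["tree"]), schema="newick")
    paths["ground_truth"].write_text(bundle.ground_truth.to_json())
    return {k: str(v) for k, v in paths.items()}
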