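"""Phylogenetic/taxonomic turnover null models against brute-force oracles."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from aqasm import (CommunityAssembly, beta_mntd, beta_nti, bray_curtis,
                   classify_assembly, generate_scenario, generate_tree,
                   patristic_distances, rc_bray, scenario_config)


# --- oracles ---------------------------------------------------------------


def patristic_oracle(tree):
    """Independent path-walk: sum branch lengths up to the two leaves'
    common ancestor via root paths."""
    leaves = list(tree.leaf_node_iter())
    paths = {}
    for leaf in leaves:
        path, node = [], leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        pa = paths[a.taxon.label]
        pb = paths[b.taxon.label]
        shared = {id(n) for n in pa} & {id(n) for n in pb}
        d = sum(n.edge.length for n in pa if id(n) not in shared)
        d += sum(n.edge.length for n in pb if id(n) not in shared)
        out[frozenset((a.taxon.label, b.taxon.label))] = d
    return out


def beta_mntd_oracle(rel_k, rel_m, D):
    """Naive double loop over detected OTUs."""
    k = [i for i in range(len(rel_k)) if rel_k[i] > 0]
    m = [j for j in range(len(rel_m)) if rel_m[j] > 0]
    s1 = sum(rel_k[i] * min(D[i][j] for j in m) for i in k)
    s2 = sum(rel_m[j] * min(D[j][i] for i in k) for j in m)
    return 0.5 * (s1 + s2)


# --- patristic distances ---------------------------------------------------


def test_two_tip_tree_distance():
    tree = dendropy.Tree.get(data="(A:0.1,B:0.2);", schema="newick")
    D = patristic_distances(tree, ["A", "B"])
    assert np.isclose(D.loc["A", "B"], 0.3)
    assert (np.diag(D) == 0).all()


def test_patristic_matches_path_walk_oracle():
    tree = generate_tree(10, seed=3)
    D = patristic_distances(tree)
    oracle = patristic_oracle(tree)
    for (a, b), d in ((tuple(k), v) for k, v in oracle.items()):
        assert np.isclose(D.loc[a, b], d, atol=1e-12)


def test_missing_branch_length_errors():
    tree = dendropy.Tree.get(data="(A:0.1,(B,C:0.2):0.1);", schema="newick")
    with pytest.raises(ValueError, match="branch length"):
        patristic_distances(tree, ["A", "B", "C"])


# --- betaMNTD --------------------------------------------------------------


def test_beta_mntd_identical_communities_zero(rng):
    D = np.abs(rng.normal(size=(5, 5)))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    rel = rng.dirichlet(np.ones(5))
    assert beta_mntd(rel, rel.copy(), D) == 0.0


def test_beta_mntd_hand_example():
    # k = {A: .5, B: .5}, m = {C: 1}; d(A,C)=.2, d(B,C)=.4
    D = np.array([[0.0, 0.1, 0.2],
                  [0.1, 0.0, 0.4],
                  [0.2, 0.4, 0.0]])
    rel_k = np.array([0.5, 0.5, 0.0])
    rel_m = np.array([0.0, 0.0, 1.0])
    assert np.isclose(beta_mntd(rel_k, rel_m, D), 0.25)


def test_beta_mntd_matches_oracle_on_random_instances(rng):
    for _ in range(100):
        p = rng.integers(3, 16)
        D = np.abs(rng.normal(size=(p, p)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        rel_k = rng.dirichlet(np.ones(p)) * (rng.random(p) < 0.7)
        rel_m = rng.dirichlet(np.ones(p)) * (rng.random(p) < 0.7)
        if rel_k.sum() == 0 or rel_m.sum() == 0:
            continue
        rel_k /= rel_k.sum()
        rel_m /= rel_m.sum()
        assert np.isclose(beta_mntd(rel_k, rel_m, D),
                          beta_mntd_oracle(rel_k, rel_m, D), atol=1e-12)


# --- betaNTI ---------------------------------------------------------------


def test_beta_nti_star_tree_degenerate():
    """Equal pairwise distances are permutation-invariant: sd_null = 0."""
    p = 6
    D = np.ones((p, p)) - np.eye(p)
    rel_k = np.full(p, 1 / p) * np.array([1, 1, 1, 0, 0, 0]) * 3 / p
    rel_k = rel_k / rel_k.sum()
    rel_m = np.array([0, 0, 0, 1, 1, 1]) / 3
    v, mu, sd = beta_nti(rel_k, rel_m, D, n_reps=49, seed=0)
    assert sd == 0 and np.isnan(v)
    assert classify_assembly(v, 0.0) == "undefined"


def test_beta_nti_deterministic_given_seed(rng):
    D = np.abs(rng.normal(size=(12, 12)))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    a = rng.dirichlet(np.ones(12)) * (np.arange(12) < 7)
    b = rng.dirichlet(np.ones(12)) * (np.arange(12) >= 5)
    a, b = a / a.sum(), b / b.sum()
    r1 = beta_nti(a, b, D, n_reps=99, seed=5)
    r2 = beta_nti(a, b, D, n_reps=99, seed=5)
    assert r1 == r2 and not np.isnan(r1[0])


# --- Bray-Curtis and Raup-Crick -------------------------------------------


def test_bray_curtis_cases():
    a = np.array([0.7, 0.3, 0.0])
    b = np.array([0.3, 0.7, 0.0])
    assert np.isclose(bray_curtis(a, a), 0.0)
    assert np.isclose(bray_curtis(a, b), 0.4)
    disjoint = np.array([0.0, 0.0, 1.0])
    assert np.isclose(bray_curtis(a, disjoint), 1.0)


def test_bray_curtis_matches_scipy():
    from scipy.spatial.distance import braycurtis
    r = np.random.default_rng(4)
    for _ in range(20):
        a = r.dirichlet(np.ones(8))
        b = r.dirichlet(np.ones(8))
        assert np.isclose(bray_curtis(a, b), braycurtis(a, b), atol=1e-12)


def test_rc_bray_extremes_and_bounds():
    r = np.random.default_rng(9)
    pool = 120
    meta = r.multinomial(30000, r.dirichlet(np.ones(pool) * 0.5), size=6)
    k = np.zeros(pool, int)
    m = np.zeros(pool, int)
    k[:40] = r.multinomial(2000, r.dirichlet(np.ones(40)))
    m[60:110] = r.multinomial(2000, r.dirichlet(np.ones(50)))
    disjoint = rc_bray(k, m, meta, n_reps=499, seed=1)
    assert disjoint == 1.0
    same = np.zeros(pool, int)
    same[:50] = r.multinomial(2000, r.dirichlet(np.ones(50)))
    identical = rc_bray(same, same.copy(), meta, n_reps=499, seed=1)
    assert identical <= -0.95
    assert -1 <= disjoint <= 1 and -1 <= identical <= 1


def test_rc_bray_richness_exceeding_pool_errors():
    meta = np.array([[5, 0], [0, 5]])
    with pytest.raises(ValueError):
        rc_bray(np.array([1, 1]), np.array([1, 1]),
                np.array([[5, 0]]) * 0, n_reps=9, seed=0)


# --- classification --------------------------------------------------------


@pytest.mark.parametrize("bnti,rc,label", [
    (2.5, 0.1, "variable_selection"),
    (-2.5, 0.1, "homogeneous_selection"),
    (1.63, 1.0, "dispersal_limitation"),
    (-0.61, -0.99, "homogenizing_dispersal"),
    (0.0, 0.0, "undominated"),
    (float("nan"), 0.0, "undefined"),
])
def test_classification_thresholds(bnti, rc, label):
    assert classify_assembly(bnti, rc) == label


# --- end-to-end model ------------------------------------------------------


def test_assembly_model_pair_count_and_determinism(neutral_bundle):
    b = neutral_bundle
    model = CommunityAssembly(b.table, b.tree, metadata=b.metadata,
                              qpcr=b.qpcr)
    gw = sorted({f"{r.site}:{r.time_point}"
                 for _, r in b.metadata.iterrows()
                 if r.compartment == "groundwater"})
    res1 = model.fit(samples=gw, depth=2000, n_reps=49, seed=3)
    res2 = model.fit(samples=gw, depth=2000, n_reps=49, seed=3)
    assert len(res1.pairs) == 6  # 4 wells -> 6 pairs
    pd.testing.assert_frame_equal(res1.pairs, res2.pairs)
    assert "pairs" in res1.summary() or "pair" in res1.summary()


def test_dispersal_limitation_scenario_recovered():
    b = generate_scenario(scenario_config("dispersal_limitation", seed=4))
    model = CommunityAssembly(b.table, b.tree, metadata=b.metadata,
                              qpcr=b.qpcr)
    gw = sorted({f"{r.site}:{r.time_point}"
                 for _, r in b.metadata.iterrows()
                 if r.compartment == "groundwater"})
    res = model.fit(samples=gw, depth=5000, n_reps=199, seed=8)
    assert res.modal_process == "dispersal_limitation"
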