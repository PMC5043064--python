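import itertools

import numpy as np
import pytest

from msatpop.io_genotypes import GenotypeDataset, allele_frequencies
from msatpop.structure_distance import (
    PairwiseStatMatrix, weir_fst_global, weir_fst_pairwise, r_st,
    allele_size_permutation_test, nei_distance, distance_matrix,
    neighbor_joining, bootstrap_tree,
)
from msatpop.synthetic_data import SimulationConfig, simulate
from conftest import make_ds, toy_two_pop, fixed_diff_pops


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_oracle(ds, pops):
    """Independent direct transcription of the variance-component
    formulas, per allele, ratio of sums."""
    A = B = C = 0.0
    for j, locus in enumerate(ds.loci):
        alleles = sorted({int(a) for i in range(ds.n_individuals)
                          for a in ds.calls[i, j] if a != 0})
        if len(alleles) < 2:
            continue
        n = []
        p = []
        h = []
        for pop in pops:
            idx = [i for i, q in enumerate(ds.populations) if q == pop]
            g = ds.calls[idx, j, :]
            g = g[g[:, 0] != 0]
            n.append(len(g))
            p.append([np.mean([int(a1 == al) + int(a2 == al) for a1, a2 in g]) / 2
                      for al in alleles])
            h.append([np.mean([(a1 != a2) and (al in (a1, a2)) for a1, a2 in g])
                      for al in alleles])
        n = np.array(n, float)
        r = len(pops)
        nbar = n.mean()
        nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
        for k in range(len(alleles)):
            pk = np.array([row[k] for row in p])
            hk = np.array([row[k] for row in h])
            pbar = (n * pk).sum() / n.sum()
            s2 = (n * (pk - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * hk).sum() / n.sum()
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


def test_theta_matches_direct_formula(toy_two_pop):
    pops = ["A", "B"]
    assert weir_fst_global(toy_two_pop, pops)["theta"] == pytest.approx(
        wc_theta_oracle(toy_two_pop, pops), abs=1e-12)


def test_theta_extremes(fixed_diff_pops):
    assert weir_fst_global(fixed_diff_pops)["theta"] == pytest.approx(1.0)
    same = [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)],
            [(100, 100)], [(100, 102)], [(102, 102)], [(100, 102)]] * 3
    dup = make_ds({"A": same, "B": same})
    theta, p = weir_fst_pairwise(dup, "A", "B", n_perm=200, seed=0)
    assert abs(theta) < 0.05
    assert p > 0.3


def test_theta_invariant_to_allele_relabeling(toy_two_pop):
    ds = toy_two_pop
    relabeled = ds.calls.copy()
    relabeled[relabeled > 0] = relabeled[relabeled > 0] * 3 + 7
    ds2 = GenotypeDataset(ds.individuals, ds.populations, ds.species,
                          ds.loci, relabeled)
    assert weir_fst_global(ds)["theta"] == pytest.approx(
        weir_fst_global(ds2)["theta"], abs=1e-12)


def test_pairwise_significance_detects_differentiation(fixed_diff_pops):
    theta, p = weir_fst_pairwise(fixed_diff_pops, "A", "B", n_perm=200, seed=1)
    assert theta == pytest.approx(1.0)
    assert p == pytest.approx(1 / 201, abs=1e-12)


# ---------------------------------------------------------------------------
# R_ST and the allele-size permutation test
# ---------------------------------------------------------------------------

def test_rst_fixed_sizes():
    ds = make_ds({"A": [[(100, 100)]] * 4, "B": [[(120, 120)]] * 4})
    assert r_st(ds) == pytest.approx(1.0)


def test_rst_identical_distributions():
    same = [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)]]
    ds = make_ds({"A": same, "B": same})
    assert abs(r_st(ds)) < 0.3


def test_rst_matches_anova_oracle():
    """One-way ANOVA on gene-copy sizes, computed directly."""
    ds = make_ds({
        "A": [[(100, 104)], [(104, 104)], [(100, 100)]],
        "B": [[(112, 116)], [(116, 116)], [(112, 112)]],
    })
    groups = [np.array([100, 104, 104, 104, 100, 100], float),
              np.array([112, 116, 116, 116, 112, 112], float)]
    sizes = np.array([6.0, 6.0])
    N, r = 12, 2
    grand = np.concatenate(groups).mean()
    ms_a = sum(s * (g.mean() - grand) ** 2 for s, g in zip(sizes, groups)) / (r - 1)
    ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - r)
    n0 = (N - (sizes ** 2).sum() / N) / (r - 1)
    sig_a = (ms_a - ms_w) / n0
    oracle = sig_a / (sig_a + ms_w)
    assert r_st(ds) == pytest.approx(oracle, abs=1e-12)


def test_rst_shift_invariance():
    ds = make_ds({"A": [[(100, 104)], [(104, 104)]],
                  "B": [[(112, 116)], [(116, 116)]]})
    shifted = GenotypeDataset(ds.individuals, ds.populations, ds.species,
                              ds.loci, ds.calls + 50)
    assert r_st(ds) == pytest.approx(r_st(shifted), abs=1e-12)


def test_size_permutation_requires_positive_n():
    ds = make_ds({"A": [[(100, 104)]], "B": [[(112, 116)]]})
    with pytest.raises(ValueError):
        allele_size_permutation_test(ds, n_perm=0)


def test_size_permutation_detects_size_structure():
    """Two populations whose alleles occupy distant size ranges (a
    mutational, phylogeographic signal) give a significant test; the
    same genotype structure with interleaved sizes does not."""
    rng = np.random.default_rng(2)
    sizes_a = [100, 102, 104, 106]
    sizes_b = [140, 142, 144, 146]

    def pop_rows(size_sets):
        rows = []
        for _ in range(8):
            rows.append([tuple(sorted(rng.choice(s, 2))) for s in size_sets])
        return rows

    far = make_ds({
        "A": pop_rows([sizes_a] * 3),
        "B": pop_rows([sizes_b] * 3),
    })
    res = allele_size_permutation_test(far, n_perm=199, seed=5)
    assert res.p_value < 0.05
    # same genotype identity structure, interleaved sizes: no mutational signal
    inter_a = [100, 140, 104, 144]
    inter_b = [102, 142, 106, 146]
    near = make_ds({
        "A": pop_rows([inter_a] * 3),
        "B": pop_rows([inter_b] * 3),
    })
    res2 = allele_size_permutation_test(near, n_perm=199, seed=6)
    assert res2.p_value > 0.05
    # add-one rule bounds
    assert 1 / 200 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# Nei distances
# ---------------------------------------------------------------------------

def test_nei_distance_values(toy_two_pop):
    ds = make_ds({
        "A": [[(100, 100), (200, 202)], [(100, 100), (200, 202)]],
        "B": [[(100, 102), (200, 200)], [(100, 102), (200, 200)]],
    })
    t = allele_frequencies(ds)
    # locus 1: x={100:1}, y={100:.5,102:.5}; locus 2: x={200:.5,202:.5}, y={200:1}
    expected = 1 - (np.sqrt(0.5) + np.sqrt(0.5)) / 2
    assert nei_distance(t, "A", "B", "DA") == pytest.approx(expected, abs=1e-12)
    same = allele_frequencies(make_ds({
        "A": [[(1, 2)], [(1, 1)]], "B": [[(1, 2)], [(1, 1)]]}))
    assert nei_distance(same, "A", "B", "DA") == pytest.approx(0.0, abs=1e-12)
    assert nei_distance(same, "A", "B", "standard") == pytest.approx(0.0, abs=1e-12)
    disjoint = allele_frequencies(make_ds({
        "A": [[(1, 1)]], "B": [[(9, 9)]]}))
    assert nei_distance(disjoint, "A", "B", "DA") == pytest.approx(1.0)


def test_nei_distance_bounds_on_simulation():
    cfg = SimulationConfig(K=4, N=30, m=0.005, s=0, mu=2e-3,
                           generations=150, sample_n=12, seed=21)
    ds, _ = simulate(cfg)
    t = allele_frequencies(ds)
    for a, b in itertools.combinations(ds.population_order(), 2):
        da = nei_distance(t, a, b, "DA")
        assert 0 <= da <= 1
        assert nei_distance(t, a, b, "standard") >= -1e-12


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> path metric."""
    nodes = [(i, None) for i in range(n)]
    # build tree as parent pointers with lengths
    import collections
    adj = collections.defaultdict(list)
    nxt = n
    pool = list(range(n))
    while len(pool) > 1:
        i = pool.pop(rng.integers(len(pool)))
        j = pool.pop(rng.integers(len(pool)))
        li, lj = rng.uniform(0.1, 2.0, 2)
        adj[nxt] += [(i, li), (j, lj)]
        adj[i].append((nxt, li))
        adj[j].append((nxt, lj))
        pool.append(nxt)
        nxt += 1
    D = np.zeros((n, n))
    for s in range(n):
        # BFS path lengths
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        for t in range(n):
            D[s, t] = dist[t]
    return D


def test_nj_three_taxa_closed_form():
    names = ["a", "b", "c"]
    D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
    tree = neighbor_joining(PairwiseStatMatrix(names, D, "d"))
    cm = tree.cophenetic_matrix()
    idx = {p: i for i, p in enumerate(cm.populations)}
    for x, y in itertools.combinations(names, 2):
        assert cm.values[idx[x], idx[y]] == pytest.approx(
            D[names.index(x), names.index(y)], abs=1e-12)


@pytest.mark.parametrize("n", [4, 5, 6, 8])
def test_nj_recovers_additive_matrices(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        D = random_additive_matrix(rng, n)
        names = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(PairwiseStatMatrix(names, D, "d"))
        cm = tree.cophenetic_matrix()
        idx = [cm.populations.index(nm) for nm in names]
        assert np.allclose(cm.values[np.ix_(idx, idx)], D, atol=1e-9)


def test_nj_topology_robust_to_small_perturbation():
    names = ["a", "b", "c", "d"]
    # ((a,b),(c,d)) with internal edge 2
    D = np.array([[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float)
    base = neighbor_joining(PairwiseStatMatrix(names, D, "d")).bipartitions()
    rng = np.random.default_rng(0)
    for _ in range(5):
        E = D + rng.uniform(-0.05, 0.05, D.shape)
        E = (E + E.T) / 2
        np.fill_diagonal(E, 0)
        tree = neighbor_joining(PairwiseStatMatrix(names, E, "d"))
        assert tree.bipartitions() == base


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        neighbor_joining(PairwiseStatMatrix(
            ["a", "b"], np.zeros((2, 2)), "d"))
    bad = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError):
        neighbor_joining(PairwiseStatMatrix(["a", "b", "c"], bad, "d"))


def test_nj_agrees_with_skbio():
    """Cross-check topology against an independent implementation."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(3)
    D = random_additive_matrix(rng, 6)
    D = D + rng.uniform(0, 0.01, D.shape)
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    names = [f"t{i}" for i in range(6)]
    mine = neighbor_joining(PairwiseStatMatrix(names, D, "d"))
    ref = skbio_nj(DistanceMatrix(D, names))
    ref_bps = set()
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        other = frozenset(names) - side
        if 1 < len(side) < len(names) - 1:
            key = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
            ref_bps.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    mine_bps = {min(bp, frozenset(names) - bp, key=lambda s: (len(s), sorted(s)))
                for bp in mine.bipartitions()}
    assert mine_bps == ref_bps


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _two_cluster_dataset(seed=0):
    cfg = SimulationConfig(K=2, N=60, m=0.0, s=0, mu=2e-3,
                           generations=300, sample_n=40, seed=seed)
    ds, _ = simulate(cfg)
    # split each deme's sample into two pseudo-populations
    pops = []
    counters = {}
    for p in ds.populations:
        counters[p] = counters.get(p, 0) + 1
        pops.append(f"{p}{'x' if counters[p] % 2 else 'y'}")
    return GenotypeDataset(ds.individuals, pops, ds.species, ds.loci,
                           ds.calls.copy())


def test_bootstrap_supports_separating_edge():
    ds = _two_cluster_dataset(1)
    tree = bootstrap_tree(ds, B=100, seed=2)
    sep = frozenset({"D01x", "D01y"})
    target = {bp: s for bp, s in tree.supports.items()}
    key = [bp for bp in target if bp in (sep, frozenset(ds.population_order()) - sep)]
    assert key, "separating edge missing from the NJ tree"
    assert target[key[0]] >= 95.0


def test_bootstrap_b1_and_order_invariance():
    ds = _two_cluster_dataset(3)
    tree = bootstrap_tree(ds, B=1, seed=4)
    assert set(tree.supports.values()) <= {0.0, 100.0}
    perm_pops = list(reversed(ds.population_order()))
    tree2 = bootstrap_tree(ds, B=30, seed=5, populations=perm_pops)
    tree1 = bootstrap_tree(ds, B=30, seed=5)
    assert set(tree1.bipartitions()) == set(tree2.bipartitions())


def test_bootstrap_needs_two_loci():
    ds = make_ds({"A": [[(1, 2)]], "B": [[(1, 1)]], "C": [[(2, 2)]]})
    with pytest.raises(ValueError):
        bootstrap_tree(ds, B=10)
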