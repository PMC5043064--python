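"""Population differentiation and genetic-distance trees.

Weir-Cockerham variance-components F-statistics (theta) with genotype
permutation significance, the allele-size analogue R_ST with the
allele-size permutation test (observed R_ST vs pR_ST from permuting
size labels among allelic states), Nei genetic distances (DA and
standard D), neighbor-joining tree construction, and bipartition
bootstrap support over loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_genotypes import MISSING, GenotypeDataset, AlleleFrequencyTable, allele_frequencies


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _locus_arrays(ds: GenotypeDataset, pops: list[str], locus_j: int):
    """Per-population typed counts, allele frequencies and heterozygote
    frequencies for one locus. Returns (alleles, n, p, h) with p and h of
    shape (n_pops, n_alleles); populations with no typed data get n=0."""
    alleles: list[int] = sorted(
        {int(a) for i in range(ds.n_individuals)
         for a in ds.calls[i, locus_j] if a != MISSING}
    )
    aindex = {a: k for k, a in enumerate(alleles)}
    n = np.zeros(len(pops))
    p = np.zeros((len(pops), len(alleles)))
    h = np.zeros((len(pops), len(alleles)))
    for pi, pop in enumerate(pops):
        idx = ds.indices_of(pop)
        g = ds.calls[idx, locus_j, :]
        typed = g[g[:, 0] != MISSING]
        n[pi] = typed.shape[0]
        if typed.shape[0] == 0:
            continue
        for a1, a2 in typed.tolist():
            p[pi, aindex[a1]] += 1
            p[pi, aindex[a2]] += 1
            if a1 != a2:
                h[pi, aindex[a1]] += 1
                h[pi, aindex[a2]] += 1
        p[pi] /= 2 * n[pi]
        h[pi] /= n[pi]
    return alleles, n, p, h


def _wc_components_locus(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham (1984) variance components for one locus.

    ``n``: typed sample sizes per population; ``p``/``h``: per-population
    allele and heterozygote-carrier frequencies, shape (r, alleles).
    Returns per-allele arrays (a, b, c): among-population, among-
    individual-within-population and within-individual components.
    Populations with n=0 are dropped; requires >=2 populations with data.
    """
    keep = n > 0
    n, p, h = n[keep], p[keep], h[keep]
    r = n.size
    if r < 2:
        raise ValueError("Weir-Cockerham components need >=2 populations with data")
    nbar = n.mean()
    if nbar <= 1:
        raise ValueError("need more than one typed individual on average")
    nsum = n.sum()
    nc = (nsum - (n ** 2).sum() / nsum) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / nsum
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / nsum
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _wc_f_within(n: int, p: np.ndarray, h: np.ndarray):
    """Single-population Weir-Cockerham components (b, c) per allele,
    for the within-population inbreeding coefficient f = 1 - sum c / sum (b+c)."""
    if n < 2:
        raise ValueError("need >=2 typed individuals")
    b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
    c = h / 2
    return b, c


def weir_fst_global(ds: GenotypeDataset, populations: list[str] | None = None
                    ) -> dict[str, float]:
    """Multilocus Weir-Cockerham theta, f (F_IS) and F (F_IT).

    Variance components are summed over alleles and loci ("ratio of
    sums"); loci monomorphic across the chosen populations, or typed in
    fewer than two of them, contribute nothing.
    """
    pops = populations if populations is not None else ds.population_order()
    if len(pops) < 2:
        raise ValueError("theta needs >=2 populations")
    A = B = C = 0.0
    for j in range(ds.n_loci):
        alleles, n, p, h = _locus_arrays(ds, pops, j)
        if len(alleles) < 2 or (n > 0).sum() < 2 or n[n > 0].mean() <= 1:
            continue
        a, b, c = _wc_components_locus(n, p, h)
        A += a.sum()
        B += b.sum()
        C += c.sum()
    denom = A + B + C
    theta = A / denom if denom != 0 else float("nan")
    fis = 1 - C / (B + C) if (B + C) != 0 else float("nan")
    fit = 1 - C / denom if denom != 0 else float("nan")
    return {"theta": theta, "fis": fis, "fit": fit}


# ---------------------------------------------------------------------------
# Pairwise theta with permutation significance
# ---------------------------------------------------------------------------

@dataclass
class PairwiseStatMatrix:
    """Symmetric matrix of a pairwise statistic over populations."""

    populations: list[str]
    values: np.ndarray
    statistic: str
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.populations)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape must match population count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.values[i, j])


def weir_fst_pairwise(ds: GenotypeDataset, pop_a: str, pop_b: str,
                      n_perm: int = 10_000, seed: int | None = None
                      ) -> tuple[float, float | None]:
    """Multilocus theta between two populations, with significance by
    permuting multilocus genotypes (individuals) between the two
    populations. Returns (theta, p) with the add-one permutation rule;
    p is None when n_perm == 0."""
    sub = ds.subset(populations=[pop_a, pop_b])
    res = weir_fst_global(sub, [pop_a, pop_b])
    theta = res["theta"]
    if np.isnan(theta):
        return theta, None
    if n_perm == 0:
        return theta, None
    rng = np.random.default_rng(seed)
    labels = list(sub.populations)
    hits = 0
    for _ in range(n_perm):
        perm = list(labels)
        rng.shuffle(perm)
        permuted = GenotypeDataset(sub.individuals, perm, sub.species,
                                   sub.loci, sub.calls.copy())
        t = weir_fst_global(permuted, [pop_a, pop_b])["theta"]
        if not np.isnan(t) and t >= theta:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return theta, p


def pairwise_fst_matrix(ds: GenotypeDataset, populations: list[str] | None = None,
                        n_perm: int = 0, seed: int | None = None) -> PairwiseStatMatrix:
    """All pairwise thetas (diagonal NaN), optionally with permutation p."""
    pops = populations if populations is not None else ds.population_order()
    k = len(pops)
    vals = np.full((k, k), np.nan)
    ps = np.full((k, k), np.nan) if n_perm else None
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(k), 2):
        sub_seed = int(rng.integers(2 ** 31)) if n_perm else None
        t, p = weir_fst_pairwise(ds, pops[i], pops[j], n_perm=n_perm, seed=sub_seed)
        vals[i, j] = vals[j, i] = t
        if ps is not None and p is not None:
            ps[i, j] = ps[j, i] = p
    return PairwiseStatMatrix(pops, vals, "weir_theta", ps)


# ---------------------------------------------------------------------------
# R_ST and the allele-size permutation test
# ---------------------------------------------------------------------------

def _rst_components(ds: GenotypeDataset, pops: list[str]):
    """Per-locus among-population and within-population variance
    components of allele size (one-way ANOVA on gene copies)."""
    sig_a = []
    sig_w = []
    for j in range(ds.n_loci):
        groups = []
        for pop in pops:
            idx = ds.indices_of(pop)
            g = ds.calls[idx, j, :]
            typed = g[g[:, 0] != MISSING]
            if typed.shape[0]:
                groups.append(typed.ravel().astype(float))
        if len(groups) < 2:
            continue
        sizes = np.array([len(g) for g in groups], dtype=float)
        N, r = sizes.sum(), len(groups)
        if N <= r:
            continue
        means = np.array([g.mean() for g in groups])
        grand = np.concatenate(groups).mean()
        ss_among = float((sizes * (means - grand) ** 2).sum())
        ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
        ms_a = ss_among / (r - 1)
        ms_w = ss_within / (N - r)
        n0 = (N - (sizes ** 2).sum() / N) / (r - 1)
        sig_a.append((ms_a - ms_w) / n0)
        sig_w.append(ms_w)
    return np.array(sig_a), np.array(sig_w)


def r_st(ds: GenotypeDataset, populations: list[str] | None = None) -> float:
    """Multilocus R_ST: the allele-size analogue of theta, from summed
    among/within variance components of allele size across loci."""
    pops = populations if populations is not None else ds.population_order()
    if len(pops) < 2:
        raise ValueError("R_ST needs >=2 populations")
    sa, sw = _rst_components(ds, pops)
    if sa.size == 0:
        raise ValueError("no locus with size variation across >=2 populations")
    denom = sa.sum() + sw.sum()
    if denom == 0:
        return float("nan")
    return float(sa.sum() / denom)


@dataclass
class PermutationTestResult:
    observed: float
    p_value: float
    n_permutations: int
    null_mean: float
    null_sd: float
    statistic: str = "R_ST"


def allele_size_permutation_test(ds: GenotypeDataset, n_perm: int = 10_000,
                                 seed: int | None = None,
                                 populations: list[str] | None = None
                                 ) -> PermutationTestResult:
    """Test whether stepwise-mutation (size) information contributes to
    differentiation: permutes the size labels among the distinct allelic
    states at each locus (keeping genotype identity structure) and
    recomputes pR_ST. p = (1 + #{pR_ST >= R_ST}) / (1 + n_perm).

    A significant result means R_ST exceeds its size-randomized null, so
    mutation is non-negligible relative to drift/migration; under recent
    drift-only divergence the observed R_ST behaves like an F_ST and the
    test is non-significant.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    pops = populations if populations is not None else ds.population_order()
    observed = r_st(ds, pops)
    if np.isnan(observed):
        raise ValueError("R_ST undefined on monomorphic dataset")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    per_locus_alleles = []
    for j in range(ds.n_loci):
        vals = np.unique(ds.calls[:, j, :])
        per_locus_alleles.append(vals[vals != MISSING])
    for b in range(n_perm):
        calls = ds.calls.copy()
        for j, alleles in enumerate(per_locus_alleles):
            if alleles.size < 2:
                continue
            newsizes = rng.permutation(alleles)
            mapping = np.zeros(int(alleles.max()) + 1, dtype=np.int32)
            mapping[alleles] = newsizes
            col = calls[:, j, :]
            typed = col != MISSING
            col[typed] = mapping[col[typed]]
        permuted = GenotypeDataset(ds.individuals, ds.populations, ds.species,
                                   ds.loci, calls)
        null[b] = r_st(permuted, pops)
    hits = int((null >= observed).sum())
    p = (1 + hits) / (1 + n_perm)
    return PermutationTestResult(observed, p, n_perm,
                                 float(null.mean()), float(null.std(ddof=1)))


# ---------------------------------------------------------------------------
# Nei genetic distances
# ---------------------------------------------------------------------------

def nei_distance(freq_table: AlleleFrequencyTable, pop_a: str, pop_b: str,
                 variant: str = "DA") -> float:
    """Nei genetic distance between two populations from allele
    frequencies.

    DA (Nei, Tajima & Tateno): 1 - (1/L) sum_l sum_a sqrt(x_a y_a),
    bounded in [0, 1]. Standard D: -ln(Jxy / sqrt(Jx Jy)) with J the
    per-locus mean frequency products. Loci untyped in either population
    are dropped; no shared typed locus is an error.
    """
    if variant not in ("DA", "standard"):
        raise ValueError("variant must be 'DA' or 'standard'")
    shared = [l for l in freq_table.loci
              if freq_table.gene_count(pop_a, l) > 0
              and freq_table.gene_count(pop_b, l) > 0]
    if not shared:
        raise ValueError(f"no shared typed loci between {pop_a} and {pop_b}")
    if variant == "DA":
        total = 0.0
        for locus in shared:
            x = freq_table.freqs(pop_a, locus)
            y = freq_table.freqs(pop_b, locus)
            total += sum(np.sqrt(x[a] * y[a]) for a in set(x) & set(y))
        return 1.0 - total / len(shared)
    jxy = jx = jy = 0.0
    for locus in shared:
        x = freq_table.freqs(pop_a, locus)
        y = freq_table.freqs(pop_b, locus)
        jxy += sum(x[a] * y[a] for a in set(x) & set(y))
        jx += sum(v * v for v in x.values())
        jy += sum(v * v for v in y.values())
    jxy /= len(shared)
    jx /= len(shared)
    jy /= len(shared)
    if jxy <= 0:
        raise ValueError("standard D undefined: no shared alleles")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def distance_matrix(freq_table: AlleleFrequencyTable,
                    populations: list[str] | None = None,
                    variant: str = "DA") -> PairwiseStatMatrix:
    pops = populations if populations is not None else list(freq_table.populations)
    k = len(pops)
    vals = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        d = nei_distance(freq_table, pops[i], pops[j], variant)
        vals[i, j] = vals[j, i] = d
    return PairwiseStatMatrix(pops, vals, f"nei_{variant}")


def write_phylip_matrix(matrix: PairwiseStatMatrix, path) -> None:
    """PHYLIP-style square distance matrix file."""
    lines = [f"{len(matrix.populations)}"]
    for i, pop in enumerate(matrix.populations):
        row = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(len(matrix.populations)))
        lines.append(f"{pop:<12s} {row}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str | None = None
    children: list = field(default_factory=list)  # (child _Node, length, raw_length)
    leaves: frozenset = frozenset()


@dataclass
class PopTree:
    """Unrooted population tree (stored with an arbitrary root) with
    branch lengths and optional bootstrap supports per internal
    bipartition (percent of replicates)."""

    root: _Node
    leaf_names: list[str]
    supports: dict[frozenset, float] | None = None

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the frozenset of leaf names
        on the smaller/lexicographic side of an internal edge."""
        full = frozenset(self.leaf_names)
        out: set[frozenset] = set()
        def visit(node: _Node):
            for child, _, _ in node.children:
                side = child.leaves
                if 1 < len(side) < len(full) - 1:
                    out.add(self._canonical(side))
                visit(child)
        visit(self.root)
        return out

    def _canonical(self, side: frozenset) -> frozenset:
        other = frozenset(self.leaf_names) - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return min(side, other, key=lambda s: sorted(s))

    def cophenetic_matrix(self) -> PairwiseStatMatrix:
        """Pairwise leaf path-length distances along the tree."""
        dists: dict[str, dict[str, float]] = {}
        def collect(node: _Node) -> dict[str, float]:
            if node.name is not None and not node.children:
                return {node.name: 0.0}
            sides = []
            for child, ln, _ in node.children:
                sub = collect(child)
                sides.append({k: v + ln for k, v in sub.items()})
            for s1, s2 in itertools.combinations(sides, 2):
                for u, du in s1.items():
                    for v, dv in s2.items():
                        dists.setdefault(u, {})[v] = du + dv
                        dists.setdefault(v, {})[u] = du + dv
            merged: dict[str, float] = {}
            for s in sides:
                merged.update(s)
            return merged
        collect(self.root)
        names = sorted(self.leaf_names)
        k = len(names)
        m = np.zeros((k, k))
        for i, j in itertools.combinations(range(k), 2):
            m[i, j] = m[j, i] = dists[names[i]][names[j]]
        return PairwiseStatMatrix(names, m, "cophenetic")

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: _Node) -> str:
            if not node.children:
                return node.name or ""
            inner = ",".join(f"{fmt(c)}:{ln:.6f}" for c, ln, _ in node.children)
            label = ""
            if with_support and self.supports is not None:
                key = self._canonical(node.leaves)
                if key in self.supports:
                    label = f"{self.supports[key]:.0f}"
            return f"({inner}){label}"
        return fmt(self.root) + ";"


def _annotate_leafsets(node: _Node) -> frozenset:
    if not node.children:
        node.leaves = frozenset([node.name])
        return node.leaves
    node.leaves = frozenset().union(*(_annotate_leafsets(c) for c, _, _ in node.children))
    return node.leaves


def neighbor_joining(matrix: PairwiseStatMatrix) -> PopTree:
    """Saitou-Nei neighbor joining with the Q criterion.

    Ties in Q are broken deterministically by the lexicographically
    smallest (cluster, cluster) pair of representative population names.
    Negative branch lengths are clamped to zero with the deficit moved
    to the sister edge (sum preserved); the raw values are kept on the
    tree's edges. Exact on additive matrices.
    """
    if len(matrix.populations) < 3:
        raise ValueError("need >=3 populations")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("distances must be finite")
    nodes = [_Node(name=p) for p in matrix.populations]
    reps = [p for p in matrix.populations]  # lexicographic tie-break key
    D = matrix.values.astype(float).copy()
    while len(nodes) > 2:
        n = len(nodes)
        R = D.sum(axis=1)
        best = None
        for i, j in itertools.combinations(range(n), 2):
            q = (n - 2) * D[i, j] - R[i] - R[j]
            key = (q, *sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        ci, cj = li, lj
        if ci < 0:
            cj += ci
            ci = 0.0
        if cj < 0:
            ci += cj
            cj = 0.0
        ci, cj = max(ci, 0.0), max(cj, 0.0)
        new = _Node(children=[(nodes[i], ci, li), (nodes[j], cj, lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        D = newD
    # join final two clusters
    d = D[0, 1]
    root = _Node(children=[(nodes[0], d / 2, d / 2), (nodes[1], d / 2, d / 2)])
    _annotate_leafsets(root)
    return PopTree(root, list(matrix.populations))


def bootstrap_tree(ds: GenotypeDataset, B: int = 10_000, variant: str = "DA",
                   seed: int | None = None,
                   populations: list[str] | None = None) -> PopTree:
    """NJ tree on the full data with bootstrap-over-loci supports.

    Loci are resampled with replacement B times; each replicate's
    distance matrix and NJ tree are recomputed, and each internal
    bipartition of the full-data tree gets the percentage of replicates
    containing it.
    """
    if ds.n_loci < 2:
        raise ValueError("bootstrap over loci needs >=2 loci")
    if B < 1:
        raise ValueError("B must be >=1")
    pops = populations if populations is not None else ds.population_order()
    freq = allele_frequencies(ds)
    full = neighbor_joining(distance_matrix(freq, pops, variant))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = ds.n_loci
    for _ in range(B):
        pick = rng.integers(0, L, size=L)
        calls = ds.calls[:, pick, :]
        loci = [f"L{k}_{ds.loci[p]}" for k, p in enumerate(pick)]
        bs = GenotypeDataset(ds.individuals, ds.populations, ds.species, loci, calls)
        try:
            tree = neighbor_joining(distance_matrix(allele_frequencies(bs), pops, variant))
        except ValueError:
            continue
        bps = tree.bipartitions()
        for bp in target:
            if bp in bps:
                counts[bp] += 1
    full.supports = {bp: 100.0 * c / B for bp, c in counts.items()}
    return full
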