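"""Exact Hardy-Weinberg tests and multiple-testing correction.

The tests are conditional on the observed allele counts (Levene's
distribution): a genotype table T with heterozygote total h has
conditional probability

    P(T) = n! * prod_j m_j! / (2n)! * 2^h / prod_{i<=j} c_ij!

Small tables are tested by complete enumeration; larger ones by a
Markov chain over genotype tables (random re-pairing of two
individuals' gene copies, Metropolis-weighted by 2^h so the stationary
law is Levene's), run with dememorization / batches / iterations-per-
batch parameters and a batch-mean Monte Carlo standard error. The
two-sided "probability test" orders tables by conditional probability;
the heterozygote-deficiency test orders them by total heterozygote
count. A multilocus deficiency test couples independent per-locus
chains and compares the summed heterozygote counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_genotypes import MISSING, GenotypeDataset

LN2 = math.log(2.0)
#: complete enumeration is used when the conditional table space is
#: no larger than this; otherwise the Markov chain.
ENUMERATION_CAP = 100_000


@dataclass
class McChainParams:
    """Markov-chain schedule (defaults: 10,000 dememorization steps,
    1,000 batches of 10,000 iterations)."""

    dememorization: int = 10_000
    batches: int = 1_000
    iterations_per_batch: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.dememorization, self.batches, self.iterations_per_batch) <= 0:
            raise ValueError("chain parameters must be positive")


@dataclass
class HweResult:
    p_value: float
    se_p: float
    method: str  # "exact_enumeration" | "markov_chain"
    direction: str  # "two_sided" | "deficiency"
    population: str | None = None
    locus: str | None = None


def genotype_counts(ds: GenotypeDataset, population: str, locus: str
                    ) -> dict[tuple[int, int], int]:
    """Typed genotype counts at one locus in one population, keyed by
    sorted allele pair."""
    j = ds.loci.index(locus)
    idx = ds.indices_of(population)
    g = ds.calls[idx, j, :]
    typed = g[g[:, 0] != MISSING]
    out: dict[tuple[int, int], int] = {}
    for a1, a2 in typed.tolist():
        key = (a1, a2)
        out[key] = out.get(key, 0) + 1
    return out


def _margins(counts: dict[tuple[int, int], int]) -> tuple[list[int], list[int]]:
    """(sorted allele list, gene-copy counts per allele)."""
    m: dict[int, int] = {}
    for (a, b), c in counts.items():
        m[a] = m.get(a, 0) + c
        m[b] = m.get(b, 0) + c
    alleles = sorted(m)
    return alleles, [m[a] for a in alleles]


def _table_stat(counts: dict[tuple[int, int], int]) -> tuple[float, int]:
    """(table-dependent log-probability part S = h ln2 - sum ln c!,
    heterozygote total h)."""
    h = sum(c for (a, b), c in counts.items() if a != b)
    s = h * LN2 - sum(math.lgamma(c + 1) for c in counts.values())
    return s, h


def _enumerate_tables(margins: list[int], cap: int):
    """All genotype tables with the given allele-count margins, as
    (S, h) pairs; returns None if more than ``cap`` tables exist."""
    k = len(margins)
    out: list[tuple[float, int]] = []
    rem = list(margins)
    cell = {}

    def fill_row(i: int) -> bool:
        if i == k:
            counts = {key: c for key, c in cell.items() if c > 0}
            if len(out) >= cap:
                return False
            h = sum(c for (a, b), c in counts.items() if a != b)
            s = h * LN2 - sum(math.lgamma(c + 1) for c in counts.values())
            out.append((s, h))
            return True

        def rec(j: int, left: int) -> bool:
            if j == k:
                if left % 2 == 0:
                    cell[(i, i)] = left // 2
                    ok = fill_row(i + 1)
                    del cell[(i, i)]
                    return ok
                return True
            for c in range(min(left, rem[j]) + 1):
                cell[(i, j)] = c
                rem[j] -= c
                ok = rec(j + 1, left - c)
                rem[j] += c
                del cell[(i, j)]
                if not ok:
                    return False
            return True

        return rec(i + 1, rem[i])

    completed = fill_row(0)
    return out if completed else None


def _exact_p(counts: dict[tuple[int, int], int],
             tables: list[tuple[float, int]], direction: str) -> float:
    s_obs, h_obs = _table_stat(counts)
    S = np.array([t[0] for t in tables])
    H = np.array([t[1] for t in tables])
    w = np.exp(S - S.max())
    w /= w.sum()
    if direction == "two_sided":
        mask = S <= s_obs + 1e-9
    else:
        mask = H <= h_obs
    return float(min(w[mask].sum(), 1.0))


class _GenotypeChain:
    """Markov chain over genotype tables conditional on allele counts.

    The state is the explicit list of n genotypes. A move picks two
    distinct individuals and one of the three re-pairings of their four
    labeled gene copies uniformly, and always accepts. The chain is
    symmetric on labeled pairings, whose uniform law pushes forward to
    Levene's distribution over genotype tables (pairing 2n labeled gene
    copies uniformly at random is exactly Levene's model); listing the
    two cross re-pairings separately supplies the 2^h heterozygote
    weight, so no Metropolis correction is applied.
    """

    def __init__(self, counts: dict[tuple[int, int], int], rng: np.random.Generator):
        self.rng = rng
        self.genotypes: list[tuple[int, int]] = []
        for pair, c in counts.items():
            self.genotypes.extend([tuple(sorted(pair))] * c)
        self.n = len(self.genotypes)
        self.counts: dict[tuple[int, int], int] = {}
        for g in self.genotypes:
            self.counts[g] = self.counts.get(g, 0) + 1
        self.s, self.h = _table_stat(self.counts)

    def _remove(self, pair):
        c = self.counts[pair]
        self.s += math.log(c)
        if c == 1:
            del self.counts[pair]
        else:
            self.counts[pair] = c - 1
        if pair[0] != pair[1]:
            self.h -= 1
            self.s -= LN2

    def _add(self, pair):
        c = self.counts.get(pair, 0)
        self.s -= math.log(c + 1)
        self.counts[pair] = c + 1
        if pair[0] != pair[1]:
            self.h += 1
            self.s += LN2

    def run(self, iters: int, s_obs: float, h_obs: int, direction: str,
            record: np.ndarray | None = None) -> float:
        """Run ``iters`` moves; return the fraction of visited states at
        least as extreme as the observed table. If ``record`` is given,
        the per-iteration heterozygote count is written into it."""
        rng = self.rng
        n = self.n
        us = rng.integers(0, n, size=iters)
        vs = rng.integers(0, n - 1, size=iters)
        picks = rng.integers(0, 3, size=iters)
        hits = 0
        g = self.genotypes
        for t in range(iters):
            u = us[t]
            v = vs[t]
            if v >= u:
                v += 1
            a, b = g[u]
            c, d = g[v]
            pick = picks[t]
            if pick == 0:
                new_u, new_v = (a, b), (c, d)
            elif pick == 1:
                new_u = (a, c) if a <= c else (c, a)
                new_v = (b, d) if b <= d else (d, b)
            else:
                new_u = (a, d) if a <= d else (d, a)
                new_v = (b, c) if b <= c else (c, b)
            if (new_u, new_v) != ((a, b), (c, d)):
                self._remove((a, b))
                self._remove((c, d))
                self._add(new_u)
                self._add(new_v)
                g[u] = new_u
                g[v] = new_v
            if record is not None:
                record[t] = self.h
            if direction == "two_sided":
                if self.s <= s_obs + 1e-9:
                    hits += 1
            else:
                if self.h <= h_obs:
                    hits += 1
        return hits / iters


def hwe_exact(counts: dict[tuple[int, int], int],
              params: McChainParams | None = None,
              direction: str = "two_sided",
              population: str | None = None,
              locus: str | None = None,
              enumeration_cap: int = ENUMERATION_CAP) -> HweResult | None:
    """Exact HWE test for one locus-population genotype table.

    Returns None (no test) for monomorphic or empty tables. Complete
    enumeration when the conditional table space is within
    ``enumeration_cap``; otherwise the Markov chain with ``params``.
    """
    if direction not in ("two_sided", "deficiency"):
        raise ValueError("direction must be 'two_sided' or 'deficiency'")
    n = sum(counts.values())
    if n < 1:
        return None
    alleles, margins = _margins(counts)
    if len(alleles) < 2:
        return None
    aindex = {a: i for i, a in enumerate(alleles)}
    norm = {}
    for (a, b), c in counts.items():
        i, j = sorted((aindex[a], aindex[b]))
        norm[(i, j)] = norm.get((i, j), 0) + c
    tables = _enumerate_tables(margins, enumeration_cap)
    if tables is not None:
        p = _exact_p(norm, tables, direction)
        return HweResult(p, 0.0, "exact_enumeration", direction, population, locus)
    if params is None:
        params = McChainParams()
    rng = np.random.default_rng(params.seed)
    chain = _GenotypeChain(norm, rng)
    s_obs, h_obs = _table_stat(norm)
    chain.run(params.dememorization, s_obs, h_obs, direction)
    batch_means = np.empty(params.batches)
    for b in range(params.batches):
        # re-anchor the running log-statistic to cancel float drift
        chain.s, chain.h = _table_stat(chain.counts)
        batch_means[b] = chain.run(params.iterations_per_batch, s_obs, h_obs, direction)
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(params.batches))
    return HweResult(p, se, "markov_chain", direction, population, locus)


def global_heterozygote_deficiency(ds: GenotypeDataset, population: str,
                                   params: McChainParams | None = None
                                   ) -> HweResult | None:
    """Multilocus one-sided heterozygote-deficiency test for one
    population: independent per-locus chains are run in parallel and the
    summed heterozygote counts across loci are compared with the
    observed sum. Reduces to the per-locus deficiency test when only one
    locus is polymorphic; None when none is.
    """
    if params is None:
        params = McChainParams()
    tables = []
    for locus in ds.loci:
        counts = genotype_counts(ds, population, locus)
        alleles, _ = _margins(counts)
        if len(alleles) >= 2:
            tables.append((locus, counts))
    if not tables:
        return None
    if len(tables) == 1:
        res = hwe_exact(tables[0][1], params, "deficiency",
                        population, tables[0][0])
        return HweResult(res.p_value, res.se_p, res.method, "deficiency",
                         population, None)
    rng = np.random.default_rng(params.seed)
    chains = []
    h_obs_total = 0
    for locus, counts in tables:
        alleles, _ = _margins(counts)
        aindex = {a: i for i, a in enumerate(alleles)}
        norm = {}
        for (a, b), c in counts.items():
            i, j = sorted((aindex[a], aindex[b]))
            norm[(i, j)] = norm.get((i, j), 0) + c
        ch = _GenotypeChain(norm, rng)
        h_obs_total += ch.h
        chains.append(ch)
    # dememorize each chain on its own marginal deficiency statistic
    for ch in chains:
        ch.run(params.dememorization, float("inf"), ch.n, "deficiency")
    batch_means = np.empty(params.batches)
    iters = params.iterations_per_batch
    for b in range(params.batches):
        total = np.zeros(iters, dtype=np.int64)
        for ch in chains:
            ch.s, ch.h = _table_stat(ch.counts)
            trace = np.empty(iters, dtype=np.int64)
            ch.run(iters, float("inf"), -1, "deficiency", record=trace)
            total += trace
        batch_means[b] = float((total <= h_obs_total).mean())
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(params.batches))
    return HweResult(p, se, "markov_chain", "deficiency", population, None)


def holm_correction(p_values, alpha: float = 0.05):
    """Holm step-down (sequential Bonferroni) adjustment.

    Returns (adjusted p-values, rejection flags at ``alpha``); empty
    input gives empty arrays.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adj, reject
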