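"""Within-population and species-level diversity statistics.

Per population: observed (A), rarefied (A_R) and effective (A_E)
alleles per locus, observed/expected heterozygosity, the inbreeding
coefficient F_IS (Weir-Cockerham f or the Nei-style ratio of multilocus
means), and the equilibrium multilocus outcrossing rate
t = (1 - F_IS) / (1 + F_IS). Per species: pooled allelic diversity and
the Nei decomposition of gene diversity into H_S / H_T with F_ST, next
to the multilocus Weir-Cockerham theta.

Rarefaction follows the hypergeometric form: the expected number of
distinct alleles among 2g gene copies drawn without replacement from
the sampled copies, at a standardized size of g = 10 diploids by
default; populations typed below g at any locus report NA, matching
the convention of standard allelic-richness software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io_genotypes import (
    MISSING,
    GenotypeDataset,
    AlleleFrequencyTable,
    allele_frequencies,
)
from .structure_distance import _locus_arrays, _wc_f_within, weir_fst_global


@dataclass
class RarefactionConfig:
    """Standardized rarefaction size in diploid individuals (2g gene copies)."""

    g: int = 10

    def __post_init__(self) -> None:
        if self.g < 2:
            raise ValueError("rarefaction size g must be >= 2")


@dataclass
class PopDiversityRecord:
    """One per-population summary row.

    ``a_rarefied`` is None when any locus is typed below the rarefaction
    size; ``f_is`` is None when every locus is monomorphic. SEs are
    standard errors over loci. The identity t(1+F_IS) = 1-F_IS holds by
    construction.
    """

    population: str
    n: int
    a_obs: float
    a_rarefied: float | None
    a_effective: float
    h_o: float
    h_o_se: float
    h_e: float
    h_e_se: float
    f_is: float | None
    f_is_se: float | None
    t: float | None


@dataclass
class SpeciesSummary:
    species: str
    n_ind: int
    n_pop: int
    a: float
    a_se: float
    a_e: float
    a_e_se: float
    h_o: float
    h_o_se: float
    h_s: float
    h_s_se: float
    h_t: float
    h_t_se: float
    f_is: float
    f_st_nei: float
    f_st_theta: float


# ---------------------------------------------------------------------------
# Per-locus building blocks
# ---------------------------------------------------------------------------

def observed_alleles(freq_table: AlleleFrequencyTable, population: str
                     ) -> tuple[dict[str, int], float | None]:
    """Distinct alleles per typed locus and their mean (A).

    Loci with no typed individuals are skipped; all loci untyped gives
    a None mean.
    """
    per_locus: dict[str, int] = {}
    for locus in freq_table.loci:
        if freq_table.gene_count(population, locus) > 0:
            per_locus[locus] = len(freq_table.allele_counts(population, locus))
    mean = float(np.mean(list(per_locus.values()))) if per_locus else None
    return per_locus, mean


def rarefied_allelic_richness(counts: dict[int, int],
                              cfg: RarefactionConfig = RarefactionConfig()
                              ) -> float | None:
    """Expected number of distinct alleles in a random draw of 2g gene
    copies without replacement:
    A_R = sum_i [1 - C(N - n_i, 2g) / C(N, 2g)], N = total gene copies.

    Returns None (undefined) when N < 2g. Negative counts are an error.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("allele counts must be non-negative")
    n_genes = sum(counts.values())
    k = 2 * cfg.g
    if n_genes < k:
        return None
    denom = math.comb(n_genes, k)
    return float(sum(1 - math.comb(n_genes - c, k) / denom for c in counts.values() if c > 0))


def effective_alleles(freqs: dict[int, float]) -> float | None:
    """A_E = 1 / sum p_i^2; None on an empty frequency map."""
    if not freqs:
        return None
    return 1.0 / sum(p * p for p in freqs.values())


def heterozygosities(ds: GenotypeDataset, population: str) -> dict:
    """Per-locus H_O and H_E with across-locus means and SEs.

    H_O is the fraction of typed individuals heterozygous at the locus.
    H_E comes in two variants: the plain gene diversity 1 - sum p^2 and
    Nei's small-sample unbiased (2n/(2n-1)) (1 - sum p^2). Loci with no
    typed individuals are skipped from all means; monomorphic typed loci
    contribute zeros.
    """
    idx = ds.indices_of(population)
    ho, he, he_unb, loci = [], [], [], []
    for j, locus in enumerate(ds.loci):
        g = ds.calls[idx, j, :]
        typed = g[g[:, 0] != MISSING]
        n = typed.shape[0]
        if n == 0:
            continue
        het = float((typed[:, 0] != typed[:, 1]).mean())
        vals, cnt = np.unique(typed.ravel(), return_counts=True)
        p = cnt / (2 * n)
        gd = 1.0 - float((p ** 2).sum())
        ho.append(het)
        he.append(gd)
        he_unb.append(2 * n / (2 * n - 1) * gd if n > 0 else gd)
        loci.append(locus)

    def se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return {
        "loci": loci,
        "h_o": np.array(ho),
        "h_e_biased": np.array(he),
        "h_e_unbiased": np.array(he_unb),
        "h_o_mean": float(np.mean(ho)) if ho else None,
        "h_o_se": se(ho),
        "h_e_biased_mean": float(np.mean(he)) if he else None,
        "h_e_unbiased_mean": float(np.mean(he_unb)) if he_unb else None,
        "h_e_se": se(he_unb),
    }


def f_is(ds: GenotypeDataset, population: str,
         estimator: str = "weir_cockerham") -> float | None:
    """Multilocus within-population inbreeding coefficient.

    ``"nei"``: 1 - mean(H_O) / mean(unbiased H_E), a ratio of multilocus
    means. ``"weir_cockerham"``: the small-sample variance-components f,
    summing components over alleles and loci. None when every typed
    locus is monomorphic.
    """
    if estimator == "nei":
        h = heterozygosities(ds, population)
        if h["h_o_mean"] is None or h["h_e_unbiased_mean"] in (None, 0.0):
            return None
        if h["h_e_unbiased_mean"] == 0:
            return None
        return 1.0 - h["h_o_mean"] / h["h_e_unbiased_mean"]
    if estimator != "weir_cockerham":
        raise ValueError("estimator must be 'weir_cockerham' or 'nei'")
    B = C = 0.0
    any_poly = False
    for j in range(ds.n_loci):
        alleles, n, p, hh = _locus_arrays(ds, [population], j)
        if len(alleles) < 2 or n[0] < 2:
            continue
        any_poly = True
        b, c = _wc_f_within(int(n[0]), p[0], hh[0])
        B += b.sum()
        C += c.sum()
    if not any_poly or (B + C) == 0:
        return None
    return 1.0 - C / (B + C)


def _f_is_se(ds: GenotypeDataset, population: str, estimator: str) -> float | None:
    """Jackknife-free SE: standard error of single-locus F_IS values
    across polymorphic loci (the convention of per-locus "(SE)" columns)."""
    vals = [v for v in per_locus_f_is(ds, population, estimator).values() if v is not None]
    if len(vals) < 2:
        return None
    return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))


def per_locus_f_is(ds: GenotypeDataset, population: str,
                   estimator: str = "nei") -> dict[str, float | None]:
    """Single-locus F_IS per locus (None at monomorphic/untyped loci)."""
    idx = ds.indices_of(population)
    out: dict[str, float | None] = {}
    for j, locus in enumerate(ds.loci):
        alleles, n, p, hh = _locus_arrays(ds, [population], j)
        if len(alleles) < 2 or n[0] < 2:
            out[locus] = None
            continue
        if estimator == "nei":
            g = ds.calls[idx, j, :]
            typed = g[g[:, 0] != MISSING]
            nn = typed.shape[0]
            het = float((typed[:, 0] != typed[:, 1]).mean())
            gd = (1.0 - float((p[0] ** 2).sum())) * 2 * nn / (2 * nn - 1)
            out[locus] = 1.0 - het / gd if gd > 0 else None
        else:
            b, c = _wc_f_within(int(n[0]), p[0], hh[0])
            denom = b.sum() + c.sum()
            out[locus] = 1.0 - c.sum() / denom if denom != 0 else None
    return out


def outcrossing_rate(f_is_value: float) -> float:
    """Equilibrium multilocus outcrossing rate t = (1 - F_IS)/(1 + F_IS).

    Exceeds 1 when F_IS is negative (heterozygote excess relative to
    random mating). Undefined at F_IS <= -1.
    """
    if f_is_value <= -1:
        raise ValueError("outcrossing rate undefined for F_IS <= -1")
    return (1.0 - f_is_value) / (1.0 + f_is_value)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def population_diversity(ds: GenotypeDataset,
                         cfg: RarefactionConfig = RarefactionConfig(),
                         estimator: str = "weir_cockerham",
                         he_variant: str = "unbiased") -> list[PopDiversityRecord]:
    """Per-population summary rows (one per population, in dataset order)."""
    if he_variant not in ("unbiased", "biased"):
        raise ValueError("he_variant must be 'unbiased' or 'biased'")
    freq = allele_frequencies(ds)
    records = []
    for pop in ds.population_order():
        _, a_mean = observed_alleles(freq, pop)
        ar_vals = []
        ar_defined = True
        ae_vals = []
        for locus in ds.loci:
            counts = freq.allele_counts(pop, locus)
            if not counts:
                continue
            ar = rarefied_allelic_richness(counts, cfg)
            if ar is None:
                ar_defined = False
            else:
                ar_vals.append(ar)
            ae = effective_alleles(freq.freqs(pop, locus))
            if ae is not None:
                ae_vals.append(ae)
        h = heterozygosities(ds, pop)
        fis = f_is(ds, pop, estimator)
        fis_se = _f_is_se(ds, pop, "nei" if estimator == "nei" else "weir_cockerham")
        t = outcrossing_rate(fis) if fis is not None and fis > -1 else None
        he_mean = h["h_e_unbiased_mean"] if he_variant == "unbiased" else h["h_e_biased_mean"]
        records.append(PopDiversityRecord(
            population=pop,
            n=len(ds.indices_of(pop)),
            a_obs=a_mean,
            a_rarefied=float(np.mean(ar_vals)) if (ar_defined and ar_vals) else None,
            a_effective=float(np.mean(ae_vals)) if ae_vals else None,
            h_o=h["h_o_mean"],
            h_o_se=h["h_o_se"],
            h_e=he_mean,
            h_e_se=h["h_e_se"],
            f_is=fis,
            f_is_se=fis_se,
            t=t,
        ))
    return records


def diversity_table(records: list[PopDiversityRecord]) -> pd.DataFrame:
    """Records as a DataFrame with NA for undefined cells."""
    rows = []
    for r in records:
        rows.append({
            "population": r.population, "n": r.n, "a_obs": r.a_obs,
            "a_rarefied": r.a_rarefied, "a_effective": r.a_effective,
            "ho": r.h_o, "ho_se": r.h_o_se, "he": r.h_e, "he_se": r.h_e_se,
            "fis": r.f_is, "fis_se": r.f_is_se, "t": r.t,
        })
    return pd.DataFrame(rows)


def species_summary(ds: GenotypeDataset, species: str) -> SpeciesSummary:
    """Species-level summary over the member populations.

    A and A_E are computed on the pooled species sample per locus.
    The Nei decomposition uses plain gene diversities: H_S = mean over
    populations of per-population 1 - sum p^2, H_T = 1 - sum pbar^2 of
    the unweighted mean allele frequencies, so identical populations
    give F_ST(nei) = (H_T - H_S)/H_T = 0 exactly and H_T >= H_S always
    (Jensen). Weir-Cockerham multilocus theta and f are reported
    alongside.
    """
    sub = ds.subset(species=species)
    pops = sub.population_order()
    if len(pops) < 2:
        raise ValueError("species summary needs >=2 populations")
    freq = allele_frequencies(sub)
    # pooled species-level frequencies
    pooled = GenotypeDataset(sub.individuals, [species] * sub.n_individuals,
                             sub.species, sub.loci, sub.calls.copy())
    pooled_freq = allele_frequencies(pooled)
    a_vals, ae_vals = [], []
    for locus in sub.loci:
        counts = pooled_freq.allele_counts(species, locus)
        if counts:
            a_vals.append(len(counts))
            ae_vals.append(effective_alleles(pooled_freq.freqs(species, locus)))
    hs_l, ht_l = [], []
    for locus in sub.loci:
        per_pop_gd = []
        per_pop_p: list[dict[int, float]] = []
        for pop in pops:
            f = freq.freqs(pop, locus)
            if not f:
                continue
            per_pop_gd.append(1.0 - sum(v * v for v in f.values()))
            per_pop_p.append(f)
        if len(per_pop_p) < 2:
            continue
        alleles = set().union(*per_pop_p)
        pbar = {a: np.mean([f.get(a, 0.0) for f in per_pop_p]) for a in alleles}
        hs_l.append(float(np.mean(per_pop_gd)))
        ht_l.append(1.0 - sum(v * v for v in pbar.values()))
    # H_O at species level: mean over populations of population means
    ho_means = [heterozygosities(sub, pop)["h_o_mean"] for pop in pops]
    ho_means = [v for v in ho_means if v is not None]
    wc = weir_fst_global(sub, pops)
    hs = float(np.mean(hs_l)) if hs_l else 0.0
    ht = float(np.mean(ht_l)) if ht_l else 0.0

    def se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return SpeciesSummary(
        species=species,
        n_ind=sub.n_individuals,
        n_pop=len(pops),
        a=float(np.mean(a_vals)),
        a_se=se(a_vals),
        a_e=float(np.mean(ae_vals)),
        a_e_se=se(ae_vals),
        h_o=float(np.mean(ho_means)),
        h_o_se=se(ho_means),
        h_s=hs,
        h_s_se=se(hs_l),
        h_t=ht,
        h_t_se=se(ht_l),
        f_is=wc["fis"],
        f_st_nei=(ht - hs) / ht if ht > 0 else float("nan"),
        f_st_theta=wc["theta"],
    )


def private_alleles(freq_table: AlleleFrequencyTable,
                    populations: list[str] | None = None
                    ) -> dict[str, list[tuple[str, int, float]]]:
    """Alleles private to one population among the given set.

    An allele at a locus is private to a population when present there
    and absent from every other population in the set. Returns, per
    population, a list of (locus, allele, local frequency).
    """
    pops = populations if populations is not None else list(freq_table.populations)
    if len(pops) < 2:
        raise ValueError("private alleles need >=2 populations")
    out: dict[str, list[tuple[str, int, float]]] = {p: [] for p in pops}
    for locus in freq_table.loci:
        presence: dict[int, list[str]] = {}
        for pop in pops:
            for a in freq_table.allele_counts(pop, locus):
                presence.setdefault(a, []).append(pop)
        for a, where in presence.items():
            if len(where) == 1:
                pop = where[0]
                out[pop].append((locus, a, freq_table.freqs(pop, locus)[a]))
    return out


# ---------------------------------------------------------------------------
# Published per-population summary (transcribed printed values)
# ---------------------------------------------------------------------------

def load_published_population_summary() -> pd.DataFrame:
    """Published per-population summary statistics for the three
    Indo-West Pacific Rhizophora species (54 populations genotyped at 13
    microsatellite loci): sample size N, allelic diversity (A, A_R,
    A_E), heterozygosities with SEs, F_IS with SE, and the outcrossing
    rate t. A_R is NA for populations sampled below the rarefaction
    standard of 10 individuals.
    """
    with resources.files("msatpop.data").joinpath(
            "rhizophora_populations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
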