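"""Null-allele frequency estimation and its diagnostics.

A null allele fails to amplify in PCR: null/visible individuals score
as visible homozygotes and null/null individuals score as blanks, so
nulls inflate apparent homozygosity and F_IS locus by locus. The
Dempster expectation-maximization estimator fits, per locus and
population, visible allele frequencies p_i plus a null frequency r
under random mating:

    P(apparent i/j het) = 2 p_i p_j
    P(apparent i/i hom) = p_i^2 + 2 p_i r
    P(blank)            = r^2

Downstream diagnostics: F_ST recomputed with null-corrected visible
frequencies (the "excluding null alleles" scheme), the regression of
single-locus F_IS on estimated null frequency (nulls produce a positive
slope; genuine inbreeding does not, because mating system affects all
loci equally), and a per-population screen that classifies a positive
multilocus F_IS as inbreeding-like or null-artifact-like from the
heterogeneity of F_IS across null-free vs null-affected loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_genotypes import MISSING, GenotypeDataset
from .hwe import genotype_counts
from .structure_distance import _wc_components_locus


@dataclass
class NullAlleleEstimate:
    r_hat: float
    iterations: int
    converged: bool
    visible_freqs: dict[int, float] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    population: str | None = None
    locus: str | None = None


@dataclass
class RegressionDiagnostic:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_points: int


def _loglik(het: dict[tuple[int, int], int], hom: dict[int, int], blanks: int,
            p: dict[int, float], r: float) -> float:
    ll = 0.0
    for (a, b), c in het.items():
        ll += c * np.log(max(2 * p[a] * p[b], 1e-300))
    for a, c in hom.items():
        ll += c * np.log(max(p[a] ** 2 + 2 * p[a] * r, 1e-300))
    if blanks:
        ll += blanks * np.log(max(r * r, 1e-300))
    return float(ll)


def em_null_frequency(counts: dict[tuple[int, int], int],
                      n_blank: int = 0,
                      tol: float = 1e-9,
                      max_iter: int = 10_000,
                      population: str | None = None,
                      locus: str | None = None) -> NullAlleleEstimate:
    """Dempster EM for the null-allele frequency at one locus.

    ``counts`` are apparent genotype counts among typed individuals;
    ``n_blank`` is the number of all-missing individuals at the locus,
    treated as candidate null homozygotes (all blanks attributed to
    nulls; a technical-failure mixture is not modelled here but blanks
    can be pre-thinned by the caller).

    The E-step allocates each apparent homozygote between true
    homozygote and visible/null heterozygote, and blanks to null/null;
    the M-step re-estimates gene-copy frequencies including r. The
    observed-data likelihood is non-decreasing across iterations;
    convergence is declared when the largest parameter change drops
    below ``tol``.
    """
    het = {tuple(sorted(k)): v for k, v in counts.items() if k[0] != k[1]}
    hom = {k[0]: v for k, v in counts.items() if k[0] == k[1]}
    n = sum(counts.values()) + n_blank
    if n < 1:
        raise ValueError("need at least one typed or blank individual")
    alleles = sorted({a for k in counts for a in k})
    if not alleles:
        # every individual blank: r is 1 by definition
        return NullAlleleEstimate(1.0, 0, True, {}, 0.0, population, locus)
    # init: equal shares, r from blanks (plus a nudge so EM can move)
    r = max(np.sqrt(n_blank / n), 0.05)
    p = {a: (1 - r) / len(alleles) for a in alleles}
    ll = _loglik(het, hom, n_blank, p, r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected gene-copy counts
        copies = {a: 0.0 for a in alleles}
        null_copies = 2.0 * n_blank
        for (a, b), c in het.items():
            copies[a] += c
            copies[b] += c
        for a, c in hom.items():
            denom = p[a] ** 2 + 2 * p[a] * r
            w_null = (2 * p[a] * r / denom) if denom > 0 else 0.0
            # a true homozygote carries two a-copies; a null het one of each
            copies[a] += c * (2 * (1 - w_null) + w_null)
            null_copies += c * w_null
        # M-step
        total = 2.0 * n
        new_p = {a: copies[a] / total for a in alleles}
        new_r = null_copies / total
        delta = max(abs(new_r - r), max(abs(new_p[a] - p[a]) for a in alleles))
        p, r = new_p, new_r
        new_ll = _loglik(het, hom, n_blank, p, r)
        # near the r = 0 boundary the iterates decay geometrically, so
        # convergence is declared on either parameter or likelihood change
        if delta < tol or abs(new_ll - ll) < tol * (1 + abs(new_ll)):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return NullAlleleEstimate(float(r), it, converged, p, ll, population, locus)


def estimate_null_frequencies(ds: GenotypeDataset,
                              tol: float = 1e-9,
                              max_iter: int = 10_000
                              ) -> list[NullAlleleEstimate]:
    """EM estimates for every (population, locus) with any data."""
    out = []
    for pop in ds.population_order():
        idx = ds.indices_of(pop)
        for j, locus in enumerate(ds.loci):
            g = ds.calls[idx, j, :]
            blanks = int((g[:, 0] == MISSING).sum())
            counts = genotype_counts(ds, pop, locus)
            if not counts and blanks == 0:
                continue
            out.append(em_null_frequency(counts, blanks, tol, max_iter,
                                         population=pop, locus=locus))
    return out


# ---------------------------------------------------------------------------
# ENA-corrected F_ST
# ---------------------------------------------------------------------------

def ena_corrected_fst(ds: GenotypeDataset,
                      null_estimates: list[NullAlleleEstimate],
                      populations: list[str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta with the null-allele correction.

    The null is carried as an explicit extra allele state: per
    (population, locus), the EM visible allele frequencies (summing to
    1 - r_hat) replace the raw apparent frequencies, each visible
    allele's heterozygote-carrier frequency combines the observed
    visible/visible heterozygotes with the EM-expected visible/null
    heterozygotes hidden among apparent homozygotes, and the null
    state's own components are excluded from the variance sums over
    alleles. Denominators are all sampled individuals at the locus
    (blanks included), matching the EM. This removes the artifactual
    among-population variance that population-specific null frequencies
    add to apparent frequencies; with every r_hat zero and no blanks it
    reduces to the uncorrected theta exactly. A locus with r_hat = 1 in
    any population is dropped with a warning.
    """
    pops = populations if populations is not None else ds.population_order()
    if len(pops) < 2:
        raise ValueError("theta needs >=2 populations")
    est = {(e.population, e.locus): e for e in null_estimates}
    A = B = C = 0.0
    for j, locus in enumerate(ds.loci):
        if any((p, locus) in est and est[(p, locus)].r_hat >= 1.0 for p in pops):
            warnings.warn(f"locus {locus}: r_hat = 1, dropped from corrected theta")
            continue
        alleles: set[int] = set()
        for p in pops:
            e = est.get((p, locus))
            if e is not None:
                alleles.update(e.visible_freqs)
        alleles_sorted = sorted(alleles)
        if len(alleles_sorted) < 2:
            continue
        aindex = {a: k for k, a in enumerate(alleles_sorted)}
        rows_n, rows_p, rows_h = [], [], []
        for p in pops:
            e = est.get((p, locus))
            idx = ds.indices_of(p)
            g = ds.calls[idx, j, :]
            typed = g[g[:, 0] != MISSING]
            nn = g.shape[0]  # typed + blank: the EM denominator
            if e is None or typed.shape[0] == 0:
                rows_n.append(0.0)
                rows_p.append(np.zeros(len(alleles_sorted)))
                rows_h.append(np.zeros(len(alleles_sorted)))
                continue
            pv = np.zeros(len(alleles_sorted))
            for a, f in e.visible_freqs.items():
                pv[aindex[a]] = f
            hv = np.zeros(len(alleles_sorted))
            hom = np.zeros(len(alleles_sorted))
            for a1, a2 in typed.tolist():
                if a1 != a2:
                    hv[aindex[a1]] += 1
                    hv[aindex[a2]] += 1
                else:
                    hom[aindex[a1]] += 1
            # expected visible/null heterozygotes among apparent homozygotes
            if e.r_hat > 0:
                denom = pv ** 2 + 2 * pv * e.r_hat
                with np.errstate(invalid="ignore", divide="ignore"):
                    w = np.where(denom > 0, 2 * pv * e.r_hat / denom, 0.0)
                hv += hom * w
            hv /= nn
            rows_n.append(float(nn))
            rows_p.append(pv)
            rows_h.append(hv)
        n = np.array(rows_n)
        if (n > 0).sum() < 2 or n[n > 0].mean() <= 1:
            continue
        a, b, c = _wc_components_locus(n, np.vstack(rows_p), np.vstack(rows_h))
        A += a.sum()
        B += b.sum()
        C += c.sum()
    denom = A + B + C
    return A / denom if denom != 0 else float("nan")


# ---------------------------------------------------------------------------
# F_IS vs null-frequency diagnostics
# ---------------------------------------------------------------------------

def fis_null_regression(points: list[tuple[float, float]]
                        ) -> RegressionDiagnostic | None:
    """OLS of single-locus F_IS on estimated null frequency.

    ``points`` are (r_hat, F_IS) pairs over (population, locus) cells;
    non-finite pairs must be excluded by the caller. Returns slope,
    intercept, Pearson r and the two-sided p; None (undefined) when
    r_hat has zero variance. Fewer than 3 points is an error.
    """
    if len(points) < 3:
        raise ValueError("regression needs >=3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("points must be finite")
    if np.allclose(x, x[0]):
        return None
    res = stats.linregress(x, y)
    return RegressionDiagnostic(float(res.slope), float(res.intercept),
                                float(res.rvalue), float(res.pvalue), len(points))


def collect_fis_null_points(ds: GenotypeDataset,
                            null_estimates: list[NullAlleleEstimate]
                            ) -> list[tuple[float, float]]:
    """(r_hat, single-locus F_IS) pairs over all (population, locus)
    cells where both are defined. The per-locus F_IS is the Nei-style
    1 - H_O/H_E at that locus (locus-level variance-components f is
    unstable at small n)."""
    from .diversity import per_locus_f_is

    points = []
    for pop in ds.population_order():
        fis = per_locus_f_is(ds, pop, "nei")
        for e in null_estimates:
            if e.population != pop:
                continue
            f = fis.get(e.locus)
            if f is not None and np.isfinite(f) and np.isfinite(e.r_hat):
                points.append((e.r_hat, f))
    return points


def fis_heterogeneity_screen(per_locus_fis: dict[str, float | None],
                             null_estimates: dict[str, float],
                             r_threshold: float = 0.05,
                             fis_band: float = 0.05) -> str:
    """Classify a population's F_IS pattern across loci.

    Mating system affects every locus equally, while nulls act only
    where they segregate, so: F_IS near zero or negative at null-free
    loci with elevated F_IS confined to null-affected loci is
    "null-artifact-like"; uniformly positive F_IS across null-free loci
    is "inbreeding-like". When nearly all loci carry an elevated r_hat
    (as genuine inbreeding itself induces, since homozygote excess
    mimics nulls at every locus), uniformity of positive F_IS across all
    loci decides. Fewer than 3 usable loci: "inconclusive".
    """
    usable = {l: f for l, f in per_locus_fis.items()
              if f is not None and np.isfinite(f)}
    if len(usable) < 3:
        return "inconclusive"
    null_free = [f for l, f in usable.items()
                 if null_estimates.get(l, 0.0) < r_threshold]
    affected = [f for l, f in usable.items()
                if null_estimates.get(l, 0.0) >= r_threshold]
    if len(null_free) >= 3 and len(null_free) >= 0.5 * len(usable):
        mean_nf = float(np.mean(null_free))
        if mean_nf > fis_band and np.mean([f > 0 for f in null_free]) >= 0.5:
            return "inbreeding-like"
        if mean_nf <= fis_band and any(f > fis_band for f in affected):
            return "null-artifact-like"
        return "inconclusive"
    # Null-free loci are a minority (or absent). Genuine inbreeding makes
    # r_hat track each locus's chance homozygote excess, so conditioning
    # on low r_hat would cherry-pick low-F_IS loci and mimic the artifact
    # signature; a genome-wide cause is instead indicated by uniformly
    # positive F_IS across all loci.
    vals = list(usable.values())
    if float(np.median(vals)) > fis_band and np.mean([f > 0 for f in vals]) >= 0.7:
        return "inbreeding-like"
    return "inconclusive"
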