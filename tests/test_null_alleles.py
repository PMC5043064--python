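import itertools

import numpy as np
import pytest

from msatpop.io_genotypes import allele_frequencies
from msatpop.null_alleles import (
    NullAlleleEstimate, em_null_frequency, estimate_null_frequencies,
    ena_corrected_fst, fis_null_regression, fis_heterogeneity_screen,
    collect_fis_null_points,
)
from msatpop.structure_distance import weir_fst_global
from msatpop.synthetic_data import SimulationConfig, simulate, inject_nulls
from msatpop.diversity import per_locus_f_is


def grid_mle_r(het, hom, blanks, step=1e-3):
    """Independent oracle: profile the two-visible-allele null model
    likelihood over a (r, p1) grid and return the maximizing r."""
    alleles = sorted({a for k in list(het) + [(a, a) for a in hom] for a in k})
    assert len(alleles) == 2
    a1, a2 = alleles
    best, best_r = -np.inf, 0.0
    for r in np.arange(0.0, 0.6 + step, step):
        for p1 in np.arange(step, 1 - r - step + 1e-12, 5 * step):
            p = {a1: p1, a2: 1 - r - p1}
            if p[a2] <= 0:
                continue
            ll = 0.0
            for (x, y), c in het.items():
                ll += c * np.log(2 * p[x] * p[y])
            for a, c in hom.items():
                ll += c * np.log(p[a] ** 2 + 2 * p[a] * r)
            if blanks:
                ll += blanks * np.log(max(r * r, 1e-300))
            if ll > best:
                best, best_r = ll, r
    return best_r


def test_em_zero_when_no_excess_no_blanks():
    counts = {(1, 1): 25, (1, 2): 50, (2, 2): 25}
    est = em_null_frequency(counts)
    assert est.converged
    assert est.r_hat == pytest.approx(0.0, abs=1e-3)


def test_em_matches_grid_search_mle():
    cases = [
        ({(1, 2): 10}, {1: 20, 2: 10}, 2),
        ({(1, 2): 30}, {1: 20, 2: 15}, 0),
        ({(1, 2): 5}, {1: 30, 2: 25}, 6),
    ]
    for het, hom, blanks in cases:
        counts = dict(het)
        counts.update({(a, a): c for a, c in hom.items()})
        est = em_null_frequency(counts, n_blank=blanks)
        oracle = grid_mle_r(het, hom, blanks)
        assert est.r_hat == pytest.approx(oracle, abs=2e-3)


def test_em_likelihood_nondecreasing():
    counts = {(1, 1): 30, (1, 2): 10, (2, 2): 12}
    lls = []
    for k in range(1, 12):
        est = em_null_frequency(counts, n_blank=4, max_iter=k, tol=0)
        lls.append(est.log_likelihood)
    assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))


def test_em_scale_free_relabeling():
    counts = {(100, 100): 30, (100, 140): 10, (140, 140): 12}
    shifted = {(300, 300): 30, (300, 302): 10, (302, 302): 12}
    e1 = em_null_frequency(counts, n_blank=3)
    e2 = em_null_frequency(shifted, n_blank=3)
    assert e1.r_hat == pytest.approx(e2.r_hat, abs=1e-9)


def test_em_recovers_injected_null_frequency():
    """Mean EM estimate over replicates matches the injected frequency
    within 3 standard errors (i.i.d. null-mass injection, r = 0.2)."""
    vals = []
    for rep in range(25):
        cfg = SimulationConfig(K=1, N=150, m=0, s=0, mu=5e-3, L=1,
                               generations=60, sample_n=120, seed=700 + rep)
        ds, _ = simulate(cfg)
        obs = inject_nulls(ds, {0: 0.2}, seed=rep, mode="mass")
        est = estimate_null_frequencies(obs)
        vals.append(est[0].r_hat)
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 0.2) <= 3 * se


def test_ena_identity_when_no_nulls():
    cfg = SimulationConfig(K=3, N=40, m=0.01, s=0, mu=2e-3,
                           generations=100, sample_n=20, seed=3)
    ds, _ = simulate(cfg)
    theta = weir_fst_global(ds)["theta"]
    ft = allele_frequencies(ds)
    est = [NullAlleleEstimate(0.0, 0, True, ft.freqs(p, l), 0.0, p, l)
           for p in ds.population_order() for l in ds.loci]
    assert ena_corrected_fst(ds, est) == pytest.approx(theta, abs=1e-14)


def test_ena_leaves_clean_loci_untouched():
    """Restricting to the loci without nulls, the corrected theta equals
    the uncorrected one."""
    cfg = SimulationConfig(K=3, N=40, m=0.01, s=0, mu=2e-3,
                           generations=100, sample_n=20, seed=4)
    ds, _ = simulate(cfg)
    from msatpop.io_genotypes import GenotypeDataset
    sub = GenotypeDataset(ds.individuals, ds.populations, ds.species,
                          ds.loci[5:], ds.calls[:, 5:, :].copy())
    ft = allele_frequencies(sub)
    est = [NullAlleleEstimate(0.0, 0, True, ft.freqs(p, l), 0.0, p, l)
           for p in sub.population_order() for l in sub.loci]
    assert ena_corrected_fst(sub, est) == pytest.approx(
        weir_fst_global(sub)["theta"], abs=1e-14)


def test_ena_corrects_lineage_null_bias():
    """With a null lineage segregating at population-specific
    frequencies, the corrected theta is closer to the null-free truth
    than the uncorrected theta in >=80% of replicates."""
    from msatpop.structure_distance import _locus_arrays, _wc_components_locus
    from msatpop.io_genotypes import MISSING

    def visible_theta(ds, null_loci, r):
        pops = ds.population_order()
        A = B = C = 0.0
        for j in range(ds.n_loci):
            al, n, p, h = _locus_arrays(ds, pops, j)
            if len(al) < 2 or (n > 0).sum() < 2:
                continue
            a, b, c = _wc_components_locus(n, p, h)
            keep = list(range(len(al)))
            if j in null_loci:
                col = ds.calls[:, j, :]
                typed = col[:, 0] != MISSING
                vals, cnt = np.unique(col[typed], return_counts=True)
                na = vals[np.argmin(np.abs(cnt / cnt.sum() - r))]
                keep = [i for i, x in enumerate(al) if x != na]
            A += a[keep].sum()
            B += b[keep].sum()
            C += c[keep].sum()
        return A / (A + B + C)

    wins, reps = 0, 10
    r = 0.3
    for rep in range(reps):
        cfg = SimulationConfig(K=4, N=60, m=0.008, s=0, mu=1e-3,
                               generations=250, sample_n=50,
                               seed=900 + rep, n_founder_alleles=8)
        clean, _ = simulate(cfg)
        null_loci = set(range(13))
        truth = visible_theta(clean, null_loci, r)
        obs = inject_nulls(clean, {l: r for l in null_loci},
                           seed=1900 + rep, mode="lineage")
        raw = weir_fst_global(obs)["theta"]
        ena = ena_corrected_fst(obs, estimate_null_frequencies(obs))
        wins += abs(ena - truth) < abs(raw - truth)
    assert wins >= 0.8 * reps


def test_regression_trivials():
    pts = [(0.0, 0.1), (0.1, 0.3), (0.2, 0.5)]
    reg = fis_null_regression(pts)
    assert reg.slope == pytest.approx(2.0)
    assert reg.r == pytest.approx(1.0)
    assert fis_null_regression([(0.0, 0.1), (0.0, 0.2), (0.0, 0.3)]) is None
    with pytest.raises(ValueError):
        fis_null_regression([(0.0, 0.1), (0.1, 0.2)])


def test_screen_trivials():
    fis_uniform = {f"L{i}": 0.3 for i in range(13)}
    nulls_zero = {f"L{i}": 0.0 for i in range(13)}
    assert fis_heterogeneity_screen(fis_uniform, nulls_zero) == "inbreeding-like"
    fis_mixed = {f"L{i}": (0.4 if i < 4 else -0.02) for i in range(13)}
    nulls_mixed = {f"L{i}": (0.25 if i < 4 else 0.0) for i in range(13)}
    assert fis_heterogeneity_screen(fis_mixed, nulls_mixed) == "null-artifact-like"
    assert fis_heterogeneity_screen({"L1": 0.2, "L2": 0.1}, {}) == "inconclusive"


@pytest.mark.parametrize("scenario,expected", [
    ("selfing", "inbreeding-like"),
    ("nulls", "null-artifact-like"),
])
def test_screen_on_truth_labeled_simulations(scenario, expected):
    hits, reps = 0, 10
    for rep in range(reps):
        if scenario == "selfing":
            cfg = SimulationConfig(K=1, N=100, m=0, s=0.5, mu=5e-3,
                                   generations=120, sample_n=30, seed=300 + rep)
        else:
            cfg = SimulationConfig(K=1, N=100, m=0, s=0.0, mu=5e-3,
                                   generations=120, sample_n=30, seed=600 + rep,
                                   null_spec={0: 0.25, 3: 0.25, 6: 0.25, 9: 0.25})
        ds, _ = simulate(cfg)
        est = {e.locus: e.r_hat for e in estimate_null_frequencies(ds)}
        label = fis_heterogeneity_screen(per_locus_f_is(ds, "D01", "nei"), est)
        hits += label == expected
    assert hits >= 9


def test_collect_points_skips_undefined():
    cfg = SimulationConfig(K=2, N=50, m=0.01, s=0, mu=2e-3,
                           generations=80, sample_n=20, seed=8,
                           null_spec={0: 0.2})
    ds, _ = simulate(cfg)
    est = estimate_null_frequencies(ds)
    pts = collect_fis_null_points(ds, est)
    assert all(np.isfinite(x) and np.isfinite(y) for x, y in pts)
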