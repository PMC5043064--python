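"""End-to-end analysis pipeline and command-line interface.

``run_analysis`` executes the full chain on a genotype file — null
alleles, HWE with Holm correction, per-population and species tables,
allele-size permutation test, pairwise theta, Nei distance / NJ trees
with locus bootstrap, and the F_IS diagnostics — writing TSV/Newick/
JSON outputs plus a MANIFEST that marks which stages completed.
``run_validation`` runs simulate-analyze loops over the scenario
presets and tabulates parameter recovery. The ``msatpop`` CLI exposes
``analyze``, ``simulate``, ``validate`` and ``convert``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import click
import yaml

from . import diversity, hwe, null_alleles, structure_distance, synthetic_data
from .io_genotypes import (
    GenotypeDataset, read_genepop, read_long_csv, write_genepop, write_long_csv,
    allele_frequencies,
)

log = logging.getLogger("msatpop")


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    input_format: str = "auto"          # auto | genepop | csv
    species_map: dict[str, str] = field(default_factory=dict)
    rarefaction_g: int = 10
    mc_dememorization: int = 10_000
    mc_batches: int = 1_000
    mc_iterations: int = 10_000
    n_permutations: int = 10_000
    bootstrap_b: int = 10_000
    fis_estimator: str = "weir_cockerham"
    he_variant: str = "unbiased"
    distance_variant: str = "DA"
    alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis settings (filesystem paths excluded, so
        the same analysis in a different directory hashes identically)."""
        d = asdict(self)
        d.pop("input_path")
        d.pop("output_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _load_dataset(cfg: RunConfig) -> GenotypeDataset:
    path = Path(cfg.input_path)
    fmt = cfg.input_format
    if fmt == "auto":
        fmt = "csv" if path.suffix.lower() == ".csv" else "genepop"
    ds = read_long_csv(path) if fmt == "csv" else read_genepop(path)
    if cfg.species_map:
        species = [cfg.species_map.get(p, s)
                   for p, s in zip(ds.populations, ds.species)]
        ds = GenotypeDataset(ds.individuals, ds.populations, species,
                             ds.loci, ds.calls.copy())
    return ds


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the analysis chain; returns the machine-readable summary.

    Stages (in order): load -> null-allele EM -> HWE + global deficiency
    with Holm flags -> diversity tables -> allele-size permutation test
    -> pairwise theta -> distances/NJ/bootstrap -> F_IS diagnostics.
    Stage failures raise with a stage-named message; outputs written so
    far stay on disk and MANIFEST.json records completeness.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    rng = np.random.default_rng(cfg.seed)

    def write_manifest():
        (out / "MANIFEST.json").write_text(json.dumps(
            {"config_hash": cfg.config_hash(), "stages": manifest}, indent=2))

    def stage(name):
        def deco(fn):
            log.info("stage %s: start (seed=%d)", name, cfg.seed)
            try:
                fn()
            except Exception as exc:
                manifest[name] = f"failed: {exc}"
                write_manifest()
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest[name] = "ok"
            write_manifest()
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        state["ds"] = _load_dataset(cfg)
        if state["ds"].n_individuals == 0:
            raise ValueError("empty input")
        summary["n_individuals"] = state["ds"].n_individuals
        summary["n_populations"] = len(state["ds"].population_order())
        summary["n_loci"] = state["ds"].n_loci

    ds: GenotypeDataset = state["ds"]

    @stage("null_alleles")
    def _nulls():
        est = null_alleles.estimate_null_frequencies(ds)
        state["null_est"] = est
        with (out / "null_alleles.tsv").open("w") as fh:
            fh.write("population\tlocus\tr_hat\titerations\tconverged\n")
            for e in est:
                fh.write(f"{e.population}\t{e.locus}\t{e.r_hat:.6f}"
                         f"\t{e.iterations}\t{e.converged}\n")

    @stage("hwe")
    def _hwe():
        params = hwe.McChainParams(cfg.mc_dememorization, cfg.mc_batches,
                                   cfg.mc_iterations,
                                   seed=int(rng.integers(2 ** 31)))
        rows = []
        for pop in ds.population_order():
            for locus in ds.loci:
                counts = hwe.genotype_counts(ds, pop, locus)
                res = hwe.hwe_exact(counts, params, "two_sided", pop, locus)
                if res is not None:
                    rows.append(res)
        adj, reject = (hwe.holm_correction([r.p_value for r in rows], cfg.alpha)
                       if rows else (np.array([]), np.array([])))
        with (out / "hwe.tsv").open("w") as fh:
            fh.write("population\tlocus\tp\tse_p\tmethod\tp_holm\treject\n")
            for r, a, rej in zip(rows, adj, reject):
                fh.write(f"{r.population}\t{r.locus}\t{r.p_value:.6g}\t{r.se_p:.3g}"
                         f"\t{r.method}\t{a:.6g}\t{bool(rej)}\n")
        globals_ = []
        for pop in ds.population_order():
            g = hwe.global_heterozygote_deficiency(ds, pop, params)
            if g is not None:
                globals_.append((pop, g))
        gadj, grej = (hwe.holm_correction([g.p_value for _, g in globals_], cfg.alpha)
                      if globals_ else (np.array([]), np.array([])))
        with (out / "hwe_global_deficiency.tsv").open("w") as fh:
            fh.write("population\tp\tse_p\tp_holm\treject\n")
            for (pop, g), a, rej in zip(globals_, gadj, grej):
                fh.write(f"{pop}\t{g.p_value:.6g}\t{g.se_p:.3g}\t{a:.6g}\t{bool(rej)}\n")
        summary["hwe_tests"] = len(rows)
        summary["hwe_significant_holm"] = int(np.sum(reject)) if len(rows) else 0

    @stage("diversity")
    def _div():
        records = diversity.population_diversity(
            ds, diversity.RarefactionConfig(cfg.rarefaction_g),
            cfg.fis_estimator, cfg.he_variant)
        diversity.diversity_table(records).to_csv(
            out / "population_diversity.tsv", sep="\t", index=False,
            na_rep="NA", float_format="%.4f")
        species_rows = []
        for sp in ds.species_order():
            sub = ds.subset(species=sp)
            if len(sub.population_order()) >= 2:
                species_rows.append(diversity.species_summary(ds, sp))
        with (out / "species_summary.tsv").open("w") as fh:
            fh.write("species\tn_ind\tn_pop\ta\ta_e\th_o\th_s\th_t"
                     "\tf_is\tf_st_nei\tf_st_theta\n")
            for r in species_rows:
                fh.write(f"{r.species}\t{r.n_ind}\t{r.n_pop}\t{r.a:.4f}"
                         f"\t{r.a_e:.4f}\t{r.h_o:.4f}\t{r.h_s:.4f}\t{r.h_t:.4f}"
                         f"\t{r.f_is:.4f}\t{r.f_st_nei:.4f}\t{r.f_st_theta:.4f}\n")
        state["records"] = records

    @stage("size_permutation")
    def _sizeperm():
        if len(ds.population_order()) < 2:
            manifest["size_permutation"] = "skipped: <2 populations"
            return
        res = structure_distance.allele_size_permutation_test(
            ds, n_perm=cfg.n_permutations, seed=int(rng.integers(2 ** 31)))
        summary["r_st"] = res.observed
        summary["r_st_p"] = res.p_value
        summary["p_r_st_mean"] = res.null_mean

    @stage("differentiation")
    def _fst():
        for sp in ds.species_order():
            sub = ds.subset(species=sp)
            pops = sub.population_order()
            if len(pops) < 2:
                continue
            mat = structure_distance.pairwise_fst_matrix(
                sub, pops, n_perm=cfg.n_permutations,
                seed=int(rng.integers(2 ** 31)))
            tag = sp.replace(" ", "_").replace(".", "")
            np.savetxt(out / f"pairwise_theta_{tag}.tsv", mat.values,
                       delimiter="\t", header="\t".join(pops), comments="")
            if mat.p_values is not None:
                np.savetxt(out / f"pairwise_theta_p_{tag}.tsv", mat.p_values,
                           delimiter="\t", header="\t".join(pops), comments="")
            summary[f"theta_{tag}"] = structure_distance.weir_fst_global(sub, pops)["theta"]

    @stage("trees")
    def _trees():
        freq = allele_frequencies(ds)
        pops = ds.population_order()
        if len(pops) < 3:
            manifest["trees"] = "skipped: <3 populations"
            return
        mat = structure_distance.distance_matrix(freq, pops, cfg.distance_variant)
        structure_distance.write_phylip_matrix(mat, out / "nei_distances.phy")
        tree = structure_distance.bootstrap_tree(
            ds, B=cfg.bootstrap_b, variant=cfg.distance_variant,
            seed=int(rng.integers(2 ** 31)), populations=pops)
        (out / "nj_tree.nwk").write_text(tree.newick(with_support=True) + "\n")

    @stage("diagnostics")
    def _diag():
        est = state["null_est"]
        points = null_alleles.collect_fis_null_points(ds, est)
        diag: dict = {"n_points": len(points)}
        if len(points) >= 3:
            reg = null_alleles.fis_null_regression(points)
            if reg is not None:
                diag.update(slope=reg.slope, intercept=reg.intercept,
                            r=reg.r, p_value=reg.p_value)
        screens = {}
        by_pop: dict[str, dict[str, float]] = {}
        for e in est:
            by_pop.setdefault(e.population, {})[e.locus] = e.r_hat
        for pop in ds.population_order():
            fis = diversity.per_locus_f_is(ds, pop, "nei")
            screens[pop] = null_alleles.fis_heterogeneity_screen(
                fis, by_pop.get(pop, {}))
        diag["screen"] = screens
        (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        summary["diagnostics"] = diag

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    write_manifest()
    return summary


def run_validation(presets: list[str] | None = None, replicates: int = 10,
                   seed: int = 0) -> dict:
    """Simulate-analyze loops checking parameter recovery.

    Per preset and replicate: the pipeline's F_IS estimate vs the
    selfing expectation s/(2-s), mean EM r_hat at null-injected loci vs
    the injected r, multilocus theta vs the regime, and the exact HWE
    test's rejection rate at alpha = 0.05 under panmixia.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    all_presets = synthetic_data.scenario_presets()
    names = presets if presets is not None else list(all_presets)
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed, "replicates": replicates, "presets": {}}
    for name in names:
        cfg = all_presets[name]
        fis_vals, theta_vals, rhat_vals, hwe_rej = [], [], [], []
        for _ in range(replicates):
            ds, truth = synthetic_data.simulate(
                synthetic_data.with_seed(cfg, int(rng.integers(2 ** 31))))
            pops = ds.population_order()
            fis = [diversity.f_is(ds, p, "weir_cockerham") for p in pops]
            fis_vals.extend(v for v in fis if v is not None)
            if len(pops) >= 2:
                theta_vals.append(
                    structure_distance.weir_fst_global(ds, pops)["theta"])
            if cfg.null_spec:
                est = null_alleles.estimate_null_frequencies(ds)
                affected = {ds.loci[l] for l in cfg.null_spec}
                rhat_vals.extend(e.r_hat for e in est if e.locus in affected)
            if name == "core_panmictic":
                for pop in pops[:1]:
                    for locus in ds.loci[:3]:
                        counts = hwe.genotype_counts(ds, pop, locus)
                        res = hwe.hwe_exact(counts, direction="two_sided")
                        if res is not None:
                            hwe_rej.append(res.p_value < 0.05)
        entry: dict = {"expected_fis": cfg.s / (2 - cfg.s)}
        if fis_vals:
            entry["fis_mean"] = float(np.mean(fis_vals))
            entry["fis_se"] = float(np.std(fis_vals, ddof=1) / np.sqrt(len(fis_vals)))
        if theta_vals:
            entry["theta_mean"] = float(np.mean(theta_vals))
        if rhat_vals:
            entry["rhat_mean"] = float(np.mean(rhat_vals))
            entry["rhat_injected"] = list(cfg.null_spec.values())[0]
        if hwe_rej:
            entry["hwe_rejection_rate"] = float(np.mean(hwe_rej))
        report["presets"][name] = entry
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """Microsatellite population-genetics analysis pipeline."""
    logging.basicConfig(level=log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@main.command()
@click.argument("input_path", type=click.Path(exists=True))
@click.option("--out", "output_dir", required=True, type=click.Path())
@click.option("--config", "config_yaml", type=click.Path(exists=True),
              help="YAML file overriding any RunConfig field.")
@click.option("--seed", default=0, show_default=True)
@click.option("--permutations", default=10_000, show_default=True)
@click.option("--bootstrap", default=10_000, show_default=True)
@click.option("--mc-batches", default=1_000, show_default=True)
@click.option("--mc-iterations", default=10_000, show_default=True)
@click.option("--rarefaction-g", default=10, show_default=True)
def analyze(input_path, output_dir, config_yaml, seed, permutations, bootstrap,
            mc_batches, mc_iterations, rarefaction_g):
    """Run the full analysis chain on a GENEPOP or long CSV file."""
    cfg = RunConfig(input_path=input_path, output_dir=output_dir, seed=seed,
                    n_permutations=permutations, bootstrap_b=bootstrap,
                    mc_batches=mc_batches, mc_iterations=mc_iterations,
                    rarefaction_g=rarefaction_g)
    if config_yaml:
        overrides = yaml.safe_load(Path(config_yaml).read_text()) or {}
        for k, v in overrides.items():
            setattr(cfg, k, v)
    run_analysis(cfg)
    click.echo(f"analysis complete; outputs in {output_dir}")


@main.command()
@click.option("--preset", default="fragmented_drift", show_default=True,
              type=click.Choice(list(synthetic_data.scenario_presets())))
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "output_path", required=True, type=click.Path())
@click.option("--format", "fmt", default="genepop",
              type=click.Choice(["genepop", "csv"]), show_default=True)
def simulate(preset, seed, output_path, fmt):
    """Simulate a dataset from a named preset and write it to a file."""
    cfg = synthetic_data.with_seed(synthetic_data.scenario_presets()[preset], seed)
    ds, truth = synthetic_data.simulate(cfg)
    if fmt == "genepop":
        write_genepop(ds, output_path)
    else:
        write_long_csv(ds, output_path)
    sidecar = Path(output_path).with_suffix(".truth.json")
    sidecar.write_text(json.dumps({
        "expected_fis": truth.expected_fis,
        "realized_null": truth.realized_null,
        "preset": preset, "seed": seed,
    }, indent=2))
    click.echo(f"wrote {output_path} (+ {sidecar.name})")


@main.command()
@click.option("--preset", "presets", multiple=True)
@click.option("--replicates", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "output_path", type=click.Path())
def validate(presets, replicates, seed, output_path):
    """Run the simulation-validation suite and print/write the report."""
    report = run_validation(list(presets) or None, replicates, seed)
    text = json.dumps(report, indent=2)
    if output_path:
        Path(output_path).write_text(text)
    click.echo(text)


@main.command()
@click.argument("input_path", type=click.Path(exists=True))
@click.argument("output_path", type=click.Path())
def convert(input_path, output_path):
    """Convert between GENEPOP and long CSV (direction from suffixes)."""
    src = Path(input_path)
    dst = Path(output_path)
    ds = read_long_csv(src) if src.suffix.lower() == ".csv" else read_genepop(src)
    if dst.suffix.lower() == ".csv":
        write_long_csv(ds, dst)
    else:
        write_genepop(ds, dst)
    click.echo(f"wrote {dst}")


if __name__ == "__main__":
    main()
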