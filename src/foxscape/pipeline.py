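"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: diversity -> differentiation ->
Ne/bottleneck -> tree/PCoA -> clustering/profiles/migrants -> landscape.
Every stage writes CSV/raster/Newick artifacts into the output directory and
the run ends with a manifest (versions, seeds, parameters, warnings, stage
status). A stage failure halts the run with the stage name; outputs written
so far are kept.
"""

from __future__ import annotations

import configparser
import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genodata import (DataError, GenotypeTable, HaplotypeCounts, SiteMap,
                       read_genotype_table, read_haplotype_counts,
                       read_raster_grid, write_distance_matrix,
                       write_raster_grid)
from . import clustering, landscape, ne_bottleneck, popgen, trees

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genotypes: str | None = None
    genotype_dialect: str = "two-column"
    haplotypes: str | None = None
    sites: str | None = None            # CSV: site,x,y (planar km)
    raster: str | None = None           # ESRI ASCII resistance grid
    output_dir: str = "foxscape_out"
    include_sites: list[str] | None = None
    rarefaction_g: int | None = None
    maf_cutoff: float = 0.05
    bottleneck_model: str = "TPM"
    p_smm: float = 0.7
    bottleneck_nsim: int = 200
    k_min: int = 1
    k_max: int = 4
    replicates: int = 2
    cycles: int = 2000
    burn_in: int = 1000
    q_threshold: float = 0.75
    grid_cells: int = 100
    idw_power: float = 2.0
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        for name in ("genotypes", "haplotypes", "sites", "raster"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise DataError(f"input path for {name!r} does not exist: {p}")
        if self.genotypes is None and self.haplotypes is None:
            raise DataError("need at least one of genotypes/haplotypes")


def load_config(path) -> PipelineConfig:
    """Read an INI-style config; keys may live in any section."""
    cp = configparser.ConfigParser()
    cp.read(path)
    flat: dict[str, str] = {}
    for sec in cp.sections():
        flat.update(cp[sec])
    kwargs = {}
    for f in PipelineConfig.__dataclass_fields__.values():
        if f.name not in flat:
            continue
        raw = flat[f.name]
        if f.name == "include_sites":
            kwargs[f.name] = [s.strip() for s in raw.split(",") if s.strip()]
        elif f.type in ("int", "int | None"):
            kwargs[f.name] = int(raw)
        elif f.type == "float":
            kwargs[f.name] = float(raw)
        else:
            kwargs[f.name] = raw
    return PipelineConfig(**kwargs)


def _read_sites_csv(path) -> SiteMap:
    df = pd.read_csv(path)
    return SiteMap({str(r.site): (float(r.x), float(r.y))
                    for r in df.itertuples()})


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all applicable stages; return the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "stages": {},
        "warnings": [],
    }

    def record_warnings(wlist):
        manifest["warnings"].extend(str(w.message) for w in wlist)

    def stage(name):
        def deco(fn):
            def run():
                try:
                    with warnings.catch_warnings(record=True) as wl:
                        warnings.simplefilter("always")
                        fn()
                    record_warnings(wl)
                    manifest["stages"][name] = "complete"
                except Exception as err:
                    manifest["stages"][name] = f"failed: {err}"
                    _write_manifest(manifest, out)
                    raise PipelineError(name, err) from err
            return run
        return deco

    gt: GenotypeTable | None = None
    hc: HaplotypeCounts | None = None
    sites: SiteMap | None = None
    raster = None
    if cfg.genotypes:
        gt = read_genotype_table(cfg.genotypes, cfg.genotype_dialect)
    if cfg.haplotypes:
        hc = read_haplotype_counts(cfg.haplotypes)
        if cfg.include_sites:
            hc.included_sites = list(cfg.include_sites)
    if cfg.sites:
        sites = _read_sites_csv(cfg.sites)
    if cfg.raster:
        raster = read_raster_grid(cfg.raster)

    results: dict = {}

    @stage("diversity")
    def s_div():
        rows = []
        if hc is not None:
            part = popgen.global_fst_from_diversity(hc)
            results["partition"] = part
            pd.DataFrame({
                "site": list(part.per_site_h),
                "gene_diversity": list(part.per_site_h.values()),
            }).to_csv(out / "haplotype_diversity.csv", index=False)
            json.dump({"h_total": part.h_total,
                       "h_within_mean": part.h_within_mean,
                       "h_within_sd": part.h_within_sd,
                       "fst_mt": part.fst},
                      open(out / "diversity_partition.json", "w"), indent=1)
        if gt is not None:
            summ = popgen.site_summary_stats(gt, cfg.rarefaction_g)
            for s, v in summ.items():
                rows.append({"site": s, "n": v.n, "Ho": v.ho_mean,
                             "He": v.he_mean, "AR": v.ar_mean, "Fis": v.f_is})
            pd.DataFrame(rows).to_csv(out / "site_summaries.csv", index=False)
            results["summaries"] = summ

    @stage("differentiation")
    def s_diff():
        if hc is not None:
            res = popgen.pairwise_haplotype_fst(hc)
            write_distance_matrix(res.linearized, out / "mtdna_fst_linearized.csv")
            res.pairwise.to_dataframe().to_csv(out / "mtdna_fst_pairwise.csv")
            results["fst_mt_pairwise"] = res
        if gt is not None:
            theta = popgen.weir_cockerham_theta(
                gt, seed=int(rng.integers(1 << 31)))
            results["theta"] = theta
            json.dump({"theta": theta.global_estimate, "ci95": theta.ci95},
                      open(out / "theta.json", "w"), indent=1)
            da = popgen.nei_da_distance(gt)
            results["da"] = da
            write_distance_matrix(da.pairwise, out / "nei_da.csv")
        if hc is not None and gt is not None and results.get("partition"):
            sb = popgen.sex_biased_gene_flow_ratio(
                results["theta"].global_estimate, results["partition"].fst)
            json.dump(asdict(sb), open(out / "sex_bias.json", "w"), indent=1)

    @stage("ne_bottleneck")
    def s_ne():
        if gt is None:
            return
        rows = []
        for s in gt.sites:
            try:
                ne = ne_bottleneck.ld_ne(gt, s, cfg.maf_cutoff,
                                         seed=int(rng.integers(1 << 31)))
                bt = ne_bottleneck.bottleneck_heterozygosity_test(
                    gt, s, cfg.bottleneck_model, cfg.p_smm,
                    cfg.bottleneck_nsim, seed=int(rng.integers(1 << 31)))
                rows.append({"site": s, "Ne": ne.ne, "Ne_lo": ne.ci95[0],
                             "Ne_hi": ne.ci95[1],
                             "bottleneck_p": bt.wilcoxon_p})
            except DataError as err:
                rows.append({"site": s, "Ne": np.nan, "Ne_lo": np.nan,
                             "Ne_hi": np.nan, "bottleneck_p": np.nan,
                             "note": str(err)})
        pd.DataFrame(rows).to_csv(out / "ne_bottleneck.csv", index=False)

    @stage("tree_pcoa")
    def s_tree():
        if gt is None:
            return
        tree = trees.bootstrap_support(gt, n_boot=min(cfg.n_perm, 999),
                                       seed=int(rng.integers(1 << 31)))
        (out / "nj_tree.nwk").write_text(tree.newick() + "\n")
        ord_ = trees.pcoa_individuals(gt)
        k = ord_.coordinates.shape[1]
        df = pd.DataFrame(ord_.coordinates,
                          columns=[f"axis{i+1}" for i in range(k)])
        df.insert(0, "individual", ord_.individuals)
        df.to_csv(out / "pcoa_coordinates.csv", index=False)
        pd.DataFrame({"eigenvalue": ord_.eigenvalues}).to_csv(
            out / "pcoa_eigenvalues.csv", index=False)

    @stage("clustering")
    def s_cluster():
        if gt is None:
            return
        runs = []
        for K in range(cfg.k_min, cfg.k_max + 1):
            for _ in range(cfg.replicates):
                runs.append(clustering.admixture_mcmc(
                    gt, K, cfg.cycles, cfg.burn_in,
                    seed=int(rng.integers(1 << 31))))
        prof = clustering.align_runs_build_profiles(runs)
        results["profiles"] = prof
        qdf = pd.DataFrame(prof.consensus_q[prof.chosen_K],
                           columns=[f"q{k+1}" for k in range(prof.chosen_K)])
        qdf.insert(0, "individual", prof.individuals)
        qdf.to_csv(out / "ancestry_q.csv", index=False)
        pd.DataFrame({"profile": [str(p) for p in prof.profile_counts.index],
                      "count": prof.profile_counts.values}).to_csv(
            out / "cluster_profiles.csv", index=False)
        chosen_run = clustering.ClusterRun(
            prof.chosen_K, prof.consensus_q[prof.chosen_K], np.nan,
            np.array([]), cfg.cycles, cfg.burn_in, cfg.seed,
            individuals=prof.individuals)
        calls = clustering.classify_migrants(chosen_run, gt.site_of,
                                             cfg.q_threshold)
        pd.DataFrame([asdict(c) for c in calls]).to_csv(
            out / "migrant_calls.csv", index=False)
        json.dump({"chosen_K": prof.chosen_K,
                   "nested": {str(k): v for k, v in prof.nested.items()},
                   "valid": {str(k): v for k, v in prof.valid.items()}},
                  open(out / "chosen_k.json", "w"), indent=1)

    @stage("landscape")
    def s_land():
        if sites is None:
            return
        gdist = None
        if results.get("da") is not None:
            gdist = results["da"].pairwise
        elif results.get("fst_mt_pairwise") is not None:
            gdist = results["fst_mt_pairwise"].linearized
        if gdist is None:
            return
        sub = SiteMap({s: sites[s] for s in gdist.labels})
        rs = landscape.distance_decay_residuals(gdist, sub)
        grid = landscape.grid_over_sites(sub, cfg.grid_cells)
        surf = landscape.idw_residual_surface(rs, grid, cfg.idw_power)
        write_raster_grid(surf, out / "residual_surface.asc")
        mantel_rows = []
        if raster is not None:
            rd = landscape.resistance_distance(raster, sub)
            write_distance_matrix(rd, out / "resistance_distance.csv")
            ed = sub.euclidean_distances()
            for name, x, y, z in (
                    ("gen_vs_resistance", gdist, rd, None),
                    ("gen_vs_euclidean", gdist, ed, None),
                    ("gen_vs_resistance_given_euclid", gdist, rd, ed),
                    ("gen_vs_euclid_given_resistance", gdist, ed, rd)):
                if z is None:
                    mr = landscape.mantel_test(
                        x, y, cfg.n_perm, seed=int(rng.integers(1 << 31)),
                        log_y=True)
                else:
                    mr = landscape.partial_mantel_test(
                        x, y, z, cfg.n_perm, seed=int(rng.integers(1 << 31)))
                mantel_rows.append({"test": name, "r": mr.r, "p": mr.p})
            pd.DataFrame(mantel_rows).to_csv(out / "mantel_tests.csv",
                                             index=False)

    for runner in (s_div, s_diff, s_ne, s_tree, s_cluster, s_land):
        runner()
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
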