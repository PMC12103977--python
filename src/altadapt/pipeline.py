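"""End-to-end orchestration: simulate -> phenospace -> normalize -> coexpr
-> sweep -> enrich, with a run manifest for reproducibility.

Each stage consumes the previous stage's outputs, writes TSV/JSON results
under the output directory, and records wall time in the manifest.  Seeded
stages are bitwise reproducible given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import RunConfig, classify_windows, write_results
from .coexpr import (
    detect_modules,
    hub_genes,
    module_trait_assoc,
    pick_soft_threshold,
    adjacency,
    tom_dissimilarity,
)
from .phenospace import phenospace_analysis
from .selection_enrichment import gene_clr_test, hub_region_diversity, region_enrichment
from .sweepscan import scan_windows, top_outliers, windows_from_sites
from .synthetic_data import (
    SWEEP_TAXA,
    TAXON_SPECIES,
    simulate_bundle,
    write_bundle,
)
from .xnorm import apply_scaling, conserved_genes, rbh_orthologs, scaling_factors

log = logging.getLogger("altadapt")

DEFAULT_CONFIG = {
    "simulate": {
        "n_genes": 2000,
        "n_placed_genes": 200,
        "sweep_fraction": 0.01,
        "hub_weight": 3.0,
        "n_chrom": 22,
        "theta": 0.003,
        "f_s": 0.2,
        "w": 0.8,
    },
    "phenospace": {"reference": "L_tree_sparrow", "n_draws": 5000},
    "normalize": {"reference_species": "treesparrow"},
    "coexpr": {"expression_axes": 29},
    "sweep": {},
    "enrich": {"n_candidate_genes": 8},
}


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULT_CONFIG))


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: list[str]) -> None:
        self.stages[stage] = {"wall_time_s": round(seconds, 3), "outputs": outputs}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_all(
    seed: int,
    outdir: str | Path,
    config: dict | None = None,
    run_config: RunConfig | None = None,
    write_files: bool = True,
) -> dict:
    """Run the whole synthetic-data pipeline; returns in-memory results.

    Stages run in dependency order; a failure aborts with a stage-named
    error while earlier outputs remain on disk.
    """
    cfg = default_config()
    for k, v in (config or {}).items():
        cfg.setdefault(k, {}).update(v)
    rc = run_config or RunConfig(random_seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config_hash=_hash_config(cfg))
    results: dict = {"config": cfg}
    rng_root = np.random.SeedSequence(seed)
    stage_keys = {
        name: key
        for name, key in zip(
            ("simulate", "phenospace", "coexpr", "enrich"), rng_root.spawn(4)
        )
    }

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                outputs = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest.record(name, time.perf_counter() - t0, outputs)

        return wrap

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def _():
        bundle = simulate_bundle(seed, **cfg["simulate"])
        results["bundle"] = bundle
        if write_files:
            write_bundle(bundle, outdir / "synthetic", seed=seed)
            return [str(outdir / "synthetic")]
        return []

    bundle = results["bundle"]

    # -- phenospace (morphospace of the 5 traits) --------------------------
    @_stage("phenospace")
    def _():
        ph = phenospace_analysis(
            bundle.traits,
            bundle.tree,
            reference=cfg["phenospace"]["reference"],
            n_draws=cfg["phenospace"]["n_draws"],
            rng=np.random.default_rng(stage_keys["phenospace"]),
        )
        results["phenospace"] = ph
        files = []
        if write_files:
            p = outdir / "phenospace"
            p.mkdir(exist_ok=True)
            ph["pca"].individual_scores.to_csv(p / "scores.tsv", sep="\t")
            tsv_tab = pd.DataFrame(
                [
                    (r.taxon, r.reference, r.mean, r.sd)
                    for r in ph["tsv"].values()
                ],
                columns=["taxon", "reference", "tsv_mean", "tsv_sd"],
            )
            write_results(tsv_tab, p / "tsv.tsv")
            if ph["hsd"] is not None:
                write_results(ph["hsd"], p / "hsd.tsv")
            files = [str(p)]
        return files

    # -- normalize ---------------------------------------------------------
    @_stage("normalize")
    def _():
        ex = bundle.expression
        ortho = rbh_orthologs(
            ex["hits"],
            pivot=cfg["normalize"]["reference_species"],
            evalue_max=rc.rbh_evalue,
            identity_min=rc.rbh_identity_pct,
        )
        # merged ortholog-space matrix keyed by pivot-species gene ids
        pivot = cfg["normalize"]["reference_species"]
        parts = []
        for sp, mat in ex["expr"].items():
            ids = ortho[sp]
            sub = mat.loc[ids]
            sub.index = ortho[pivot]
            parts.append(sub)
        merged = pd.concat(parts, axis=1)[ex["samples"]]
        cons = conserved_genes(merged, rc.cv_threshold)
        factors = scaling_factors(
            merged, ex["sample_species"], cons, reference=pivot
        )
        normalized = apply_scaling(merged, factors, ex["sample_species"])
        results["normalize"] = {
            "orthologs": ortho,
            "conserved": cons,
            "factors": factors,
            "normalized": normalized,
        }
        files = []
        if write_files:
            p = outdir / "normalize"
            p.mkdir(exist_ok=True)
            normalized.to_csv(p / "normalized.tsv", sep="\t")
            write_results(
                {"factors": factors, "n_orthologs": len(ortho),
                 "n_conserved": len(cons)},
                p / "factors.json", config=rc, seed=seed,
            )
            files = [str(p)]
        return files

    # -- coexpr ------------------------------------------------------------
    @_stage("coexpr")
    def _():
        norm = results["normalize"]["normalized"]
        ex = bundle.expression
        logx = np.log1p(norm)
        beta, sft = pick_soft_threshold(logx)
        dissim = tom_dissimilarity(adjacency(logx, beta))
        assignment = detect_modules(
            dissim, logx, min_module_size=rc.min_module_size,
            cut_height=rc.cut_height, beta=beta,
        )
        trait_cols = [c for c in bundle.traits.columns if c != "taxon"]
        traits = bundle.traits.loc[ex["samples"], trait_cols]
        species = [ex["sample_species"][s] for s in ex["samples"]]
        assoc = module_trait_assoc(
            assignment.eigengenes, traits, species,
            r2_threshold=rc.module_r2_threshold,
            p_threshold=rc.module_p_threshold,
        )
        hubs = hub_genes(
            logx, assignment, traits, assoc,
            kme_threshold=rc.kme_threshold, gs_threshold=rc.gs_threshold,
        )
        hub_ids = hubs.loc[hubs["hub"], "gene"].tolist()
        results["coexpr"] = {
            "beta": beta,
            "sft": sft,
            "assignment": assignment,
            "assoc": assoc,
            "hubs": hubs,
            "hub_ids": hub_ids,
        }
        # expression-space divergence over hub genes (29 retained axes)
        if hub_ids:
            expr_traits = np.log1p(norm.loc[hub_ids]).T
            expr_traits["taxon"] = [ex["sample_taxon"][s] for s in expr_traits.index]
            ph = phenospace_analysis(
                expr_traits,
                bundle.tree,
                reference=cfg["phenospace"]["reference"],
                n_axes=cfg["coexpr"]["expression_axes"],
                n_draws=cfg["phenospace"]["n_draws"],
                rng=np.random.default_rng(stage_keys["coexpr"]),
            )
            results["expression_space"] = ph
        files = []
        if write_files:
            p = outdir / "coexpr"
            p.mkdir(exist_ok=True)
            pd.DataFrame(
                {"gene": assignment.genes, "module": assignment.labels}
            ).to_csv(p / "assignment.tsv", sep="\t", index=False)
            assignment.eigengenes.to_csv(p / "eigengenes.tsv", sep="\t")
            write_results(assoc, p / "assoc.tsv")
            write_results(hubs, p / "hubs.tsv")
            files = [str(p)]
        return files

    # -- sweep -------------------------------------------------------------
    @_stage("sweep")
    def _():
        scans = {}
        for taxon in SWEEP_TAXA:
            sites = bundle.sites_by_taxon[taxon]
            wsfs = windows_from_sites(sites, bundle.windows)
            scans[taxon] = scan_windows(wsfs)
        results["sweep"] = scans
        files = []
        if write_files:
            p = outdir / "sweep"
            p.mkdir(exist_ok=True)
            for taxon, df in scans.items():
                write_results(df, p / f"scan_{taxon}.tsv")
            files = [str(p)]
        return files

    # -- enrich ------------------------------------------------------------
    @_stage("enrich")
    def _():
        hub_ids = set(results["coexpr"]["hub_ids"])
        hub_models = [g for g in bundle.genes if g.gene_id in hub_ids]
        enr, diversity, gene_tests = {}, {}, {}
        keys = stage_keys["enrich"].spawn(len(SWEEP_TAXA))
        classified = classify_windows(bundle.windows, hub_models)
        for taxon, key in zip(SWEEP_TAXA, keys):
            scan = results["sweep"][taxon]
            selected = top_outliers(scan, rc.outlier_fraction)
            enr[taxon] = region_enrichment(
                selected,
                scan[scan["flag"] == "ok"],
                hub_models,
                n_permutations=rc.n_permutations,
                rng=np.random.default_rng(key),
                classified=classified[
                    classified["window_id"].isin(scan.loc[scan["flag"] == "ok",
                                                          "window_id"])
                ].reset_index(drop=True),
            )
            if hub_models:
                diversity[taxon] = hub_region_diversity(hub_models, scan)
            candidates = hub_models[: cfg["enrich"]["n_candidate_genes"]]
            tests = {}
            gkeys = key.spawn(max(1, len(candidates)))
            for gene, gk in zip(candidates, gkeys):
                tests[gene.gene_id] = gene_clr_test(
                    gene, scan, bundle.genes,
                    n_permutations=rc.n_permutations,
                    rng=np.random.default_rng(gk),
                )
            gene_tests[taxon] = tests
        results["enrichment"] = enr
        results["diversity"] = diversity
        results["gene_tests"] = gene_tests
        files = []
        if write_files:
            p = outdir / "enrich"
            p.mkdir(exist_ok=True)
            rows = [
                (taxon, r.region_class, r.empirical_proportion,
                 float(np.mean(r.null)), r.percentile, r.call)
                for taxon, res in enr.items()
                for r in res.values()
            ]
            write_results(
                pd.DataFrame(
                    rows,
                    columns=["taxon", "region_class", "empirical",
                             "null_mean", "percentile", "call"],
                ),
                p / "enrichment.tsv",
            )
            grows = [
                (taxon, gid, t.region_class, t.empirical, t.percentile,
                 t.significant, t.testable)
                for taxon, tests in gene_tests.items()
                for gid, per_cls in tests.items()
                for t in per_cls.values()
            ]
            write_results(
                pd.DataFrame(
                    grows,
                    columns=["taxon", "gene", "region_class", "empirical_clr",
                             "percentile", "significant", "testable"],
                ),
                p / "gene_tests.tsv",
            )
            files = [str(p)]
        return files

    if write_files:
        manifest.write(outdir / "manifest.json")
    results["manifest"] = manifest
    return results
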