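"""Ground-truth generators: phenotypes, expression, polymorphism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altadapt.core_io import read_vcf, tile_windows
from altadapt.sweepscan import folded_neutral_sfs, pi_window, windows_from_sites
from altadapt.synthetic_data import (
    DEFAULT_TAXA,
    ModuleSpec,
    PhenotypeModel,
    default_tree,
    simulate_bundle,
    simulate_expression,
    simulate_phenotypes,
    simulate_polymorphism,
    plan_sweep_windows,
    write_vcf,
)
from altadapt.xnorm import conserved_genes, scaling_factors


class TestPhenotypes:
    def test_no_shifts_no_bm_collapses_to_shared_mean(self):
        model = PhenotypeModel(
            shifts={t: (0.0,) * 5 for t in DEFAULT_TAXA},
            bm_rate=(0.0,) * 5,
            within_sd=(1e-9,) * 5,
            within_corr=0.0,
        )
        traits, _ = simulate_phenotypes(model=model, rng=0)
        spread = traits.groupby("taxon").mean(numeric_only=True).std()
        assert (spread < 1e-6).all()

    def test_colonizer_shift_separates_on_pc1(self):
        from altadapt.phenospace import phylo_pca

        model = PhenotypeModel(
            shifts={
                "L_tree_sparrow": (0.0,) * 5,
                "H_tree_sparrow": (3 * 0.08, 0, 0, 0, 0),  # +3 SD on trait 1
                "WR_snowfinch": (0.0,) * 5,
                "RN_snowfinch": (0.0,) * 5,
            },
            bm_rate=(0.0,) * 5,
        )
        traits, _ = simulate_phenotypes(model=model, rng=1)
        res = phylo_pca(traits, default_tree())
        scores = res.individual_scores
        colon = scores.loc[scores["taxon"] == "H_tree_sparrow", "PC1"]
        others = scores.loc[scores["taxon"] != "H_tree_sparrow", "PC1"]
        # group-mean computation confirms the separation direction
        assert abs(colon.mean() - others.mean()) > 2 * others.std()

    def test_seeded_runs_bitwise_identical(self):
        t1, _ = simulate_phenotypes(rng=42)
        t2, _ = simulate_phenotypes(rng=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_non_positive_definite_covariance_rejected(self):
        model = PhenotypeModel(within_corr=1.2)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_phenotypes(model=model, rng=0)

    def test_default_group_means_in_study_units(self):
        traits, truth = simulate_phenotypes(rng=3)
        means = traits.groupby("taxon").mean(numeric_only=True)
        # ratio-scale trait around 1.3, area around 50-80 um^2
        assert 0.7 < means.loc["L_tree_sparrow", "heart_ratio"] < 1.6
        assert means.loc["H_tree_sparrow", "heart_ratio"] > means.loc[
            "WR_snowfinch", "heart_ratio"
        ]
        assert means.loc["WR_snowfinch", "capillary_density"] > means.loc[
            "H_tree_sparrow", "capillary_density"
        ]


class TestExpression:
    def test_unit_scales_low_noise_recovers_unit_factors(self):
        traits, _ = simulate_phenotypes(rng=0)
        ex = simulate_expression(
            traits,
            n_genes=600,
            n_conserved=200,
            species_scales={"treesparrow": 1, "wrsnowfinch": 1, "rnsnowfinch": 1},
            conserved_noise_sd=1e-8,
            rng=1,
        )
        ortho = ex["orthologs"]
        parts = []
        for sp, mat in ex["expr"].items():
            sub = mat.loc[ortho[sp]]
            sub.index = ortho["treesparrow"]
            parts.append(sub)
        merged = pd.concat(parts, axis=1)[ex["samples"]]
        cons = ex["truth"]["conserved_genes"]
        f = scaling_factors(merged, ex["sample_species"], cons, "treesparrow")
        assert all(abs(v - 1) < 1e-6 for v in f.values())

    def test_planted_scales_recovered_via_conserved_cv_filter(self):
        traits, _ = simulate_phenotypes(rng=0)
        ex = simulate_expression(traits, n_genes=800, n_conserved=300, rng=2)
        ortho = ex["orthologs"]
        parts = []
        for sp, mat in ex["expr"].items():
            sub = mat.loc[ortho[sp]]
            sub.index = ortho["treesparrow"]
            parts.append(sub)
        merged = pd.concat(parts, axis=1)[ex["samples"]]
        cons = conserved_genes(merged, 0.3)
        f = scaling_factors(merged, ex["sample_species"], cons, "treesparrow")
        for sp, scale in ex["truth"]["species_scales"].items():
            assert f[sp] == pytest.approx(1.0 / scale, rel=0.05)

    def test_noiseless_module_gene_tracks_latent_factor(self):
        traits, _ = simulate_phenotypes(rng=0)
        mod = ModuleSpec("m1", 30, "heart_ratio", a=0.9,
                         loading_range=(1.0, 1.0), noise_sd=1e-6)
        ex = simulate_expression(traits, n_genes=400, n_conserved=100,
                                 modules=[mod], rng=3)
        genes = ex["truth"]["modules"][0]["genes"]
        mat = ex["expr"]["treesparrow"]
        g = np.log(mat.loc[genes[0], :].to_numpy(dtype=float))
        h = np.log(mat.loc[genes[1], :].to_numpy(dtype=float))
        assert abs(np.corrcoef(g, h)[0, 1]) > 0.999

    def test_module_budget_checked(self):
        traits, _ = simulate_phenotypes(rng=0)
        with pytest.raises(ValueError, match="exceed"):
            simulate_expression(traits, n_genes=100, n_conserved=50,
                                modules=[ModuleSpec("m", 100, "heart_ratio")],
                                rng=0)

    def test_null_module_association_not_inflated(self):
        # a = 0: module factors decoupled from traits; mixed-model p-values
        # should not pile up near zero
        from altadapt.coexpr import gene_trait_model

        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            traits, _ = simulate_phenotypes(rng=rng)
            mod = ModuleSpec("m", 10, "heart_ratio", a=0.0)
            ex = simulate_expression(traits, n_genes=60, n_conserved=20,
                                     n_extra_per_species=0, modules=[mod],
                                     rng=rng)
            genes = ex["truth"]["modules"][0]["genes"]
            ortho = ex["orthologs"]
            parts = []
            for sp, mat in ex["expr"].items():
                sub = mat.loc[ortho[sp]]
                sub.index = ortho["treesparrow"]
                parts.append(sub)
            merged = pd.concat(parts, axis=1)[ex["samples"]]
            y = np.log(merged.loc[genes[0]].to_numpy(dtype=float))
            x = traits.loc[ex["samples"], "heart_ratio"].to_numpy(dtype=float)
            species = [ex["sample_species"][s] for s in ex["samples"]]
            _, _, p = gene_trait_model(y, x, species)
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_deterministic(self):
        traits, _ = simulate_phenotypes(rng=0)
        e1 = simulate_expression(traits, n_genes=500, n_conserved=200, rng=9)
        e2 = simulate_expression(traits, n_genes=500, n_conserved=200, rng=9)
        for sp in e1["expr"]:
            pd.testing.assert_frame_equal(e1["expr"][sp], e2["expr"][sp])


class TestPolymorphism:
    def test_neutral_genome_sfs_matches_generating_law(self):
        n = 22
        contigs = {"c1": 1_000_000}
        sites, _ = simulate_polymorphism(contigs, n_chrom=n, rng=5)
        assert len(sites) > 8000
        counts = np.bincount(sites["minor_count"] - 1, minlength=n // 2)
        q = folded_neutral_sfs(n)
        chi2, p = stats.chisquare(counts, q * counts.sum())
        assert p > 0.01

    def test_sweep_windows_lose_diversity(self):
        contigs = {"c1": 400_000}
        wins = tile_windows(contigs, 2000)
        sweeps = wins["window_id"].tolist()[:50]
        sites, truth = simulate_polymorphism(
            contigs, wins, sweep_windows=sweeps, rng=6
        )
        wsfs = {w.window_id: w for w in windows_from_sites(sites, wins)}
        pis = {wid: pi_window(w) for wid, w in wsfs.items()}
        neutral_median = np.median(
            [v for k, v in pis.items() if k not in set(sweeps)]
        )
        frac_lower = np.mean([pis[k] < neutral_median for k in sweeps])
        assert frac_lower >= 0.95

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            simulate_polymorphism({"c": 10_000}, n_chrom=2, rng=0)

    def test_vcf_bytes_reproducible(self, tmp_path):
        contigs = {"c1": 50_000}
        sites, _ = simulate_polymorphism(contigs, rng=7)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(sites, contigs, p1, "tax", rng=11)
        write_vcf(sites, contigs, p2, "tax", rng=11)
        assert p1.read_bytes() == p2.read_bytes()

    def test_vcf_roundtrip_preserves_folded_counts(self, tmp_path):
        contigs = {"c1": 60_000}
        sites, _ = simulate_polymorphism(contigs, rng=8)
        path = tmp_path / "t.vcf"
        write_vcf(sites, contigs, path, "tax", rng=1)
        back = read_vcf(path)
        assert len(back) == len(sites)
        merged = sites.merge(back, on=["chrom", "pos"], suffixes=("_in", "_out"))
        folded_in = np.minimum(merged["minor_count_in"],
                               22 - merged["minor_count_in"])
        assert (merged["minor_count_out"] == folded_in).all()

    def test_plan_sweeps_overweights_hub_windows(self):
        wins = tile_windows({"c": 2_000_000}, 2000)
        hub_ids = set(wins["window_id"][:200])   # 20% of windows
        hits = []
        for seed in range(30):
            chosen = plan_sweep_windows(wins, hub_ids, fraction=0.02,
                                        hub_weight=3.0, rng=seed)
            hits.append(np.mean([c in hub_ids for c in chosen]))
        # expected hub share = 3*0.2 / (3*0.2 + 0.8) ~ 0.43 vs base 0.2
        assert 0.3 < np.mean(hits) < 0.55


class TestBundle:
    def test_bundle_links_all_layers(self, tmp_path):
        b = simulate_bundle(
            5,
            contig_lengths={"c1": 300_000, "c2": 300_000},
            n_genes=1000,
            n_conserved=300,
            n_placed_genes=30,
        )
        assert set(b.sites_by_taxon) == {
            "H_tree_sparrow", "WR_snowfinch", "RN_snowfinch"
        }
        placed = {g.gene_id for g in b.genes}
        hubs = set(b.truth["expression"]["planted_hubs"])
        assert hubs <= placed | hubs  # hubs were prioritised for placement
        assert len(b.truth["hub_flank_windows"]) > 0
        for taxon, truth in b.truth["polymorphism"].items():
            assert truth["sweep_windows"]

    def test_bundle_write_and_truth_serialization(self, tmp_path):
        import json

        b = simulate_bundle(5, contig_lengths={"c1": 200_000},
                            n_genes=950, n_conserved=300, n_placed_genes=9)
        from altadapt.synthetic_data import write_bundle

        write_bundle(b, tmp_path, seed=5)
        expected = {"tree.nwk", "phenotypes.tsv", "genome.gff3", "truth.json"}
        names = {p.name for p in tmp_path.iterdir()}
        assert expected <= names
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == 5
        assert "planted_hubs" in truth["expression"]
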