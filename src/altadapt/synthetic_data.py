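"""Synthetic phenotype, expression, and polymorphism data with known truth.

Every generator emulates the structure of a four-taxon high-elevation bird
study — two native sister taxa (snowfinches), a recent colonizer, and a
low-elevation reference population of the colonizer's species — so that
every downstream stage (morphospace divergence, cross-species
normalization, co-expression modules, sweep scans, enrichment) can be
tested against planted ground truth without any external data.

Generators are pure functions of (parameters, seed): a fixed seed
reproduces outputs bitwise.  The truth record serialized with each bundle
is sufficient to score recovery without re-reading generator internals.

Default conditions: sample sizes 9/8/9/7 (low-elevation reference,
colonizer, and the two natives), five correlated cardiovascular traits with
taxon-specific adaptive shifts on top of Brownian motion, three planted
trait-coupled co-expression modules among the orthologs plus a conserved
low-CV gene block, species-level expression scale offsets, and per-taxon
polymorphism (n = 22 chromosomes) with sweeps planted preferentially in
hub-gene flanking windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import GenomicInterval, GeneModel, build_gene_model, tile_windows
from .sweepscan import folded_neutral_sfs

__all__ = [
    "DEFAULT_TREE",
    "DEFAULT_TAXA",
    "TAXON_SPECIES",
    "PhenotypeModel",
    "ModuleSpec",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_polymorphism",
    "plan_sweep_windows",
    "write_vcf",
    "place_genes",
    "write_gff",
    "SyntheticBundle",
    "simulate_bundle",
]

# Four taxa: two native snowfinches (sisters), the colonizer and its
# low-elevation source population (same species, split ~2,600 yr ago).
# Branch lengths in Myr; total depth 8.7.
DEFAULT_TREE = (
    "((WR_snowfinch:5.7,RN_snowfinch:5.7):3.0,"
    "(H_tree_sparrow:0.0026,L_tree_sparrow:0.0026):8.6974);"
)
DEFAULT_TAXA = ("L_tree_sparrow", "H_tree_sparrow", "RN_snowfinch", "WR_snowfinch")

# genome-level species (the two tree-sparrow taxa share a genome)
TAXON_SPECIES = {
    "L_tree_sparrow": "treesparrow",
    "H_tree_sparrow": "treesparrow",
    "WR_snowfinch": "wrsnowfinch",
    "RN_snowfinch": "rnsnowfinch",
}
SPECIES_PREFIX = {"treesparrow": "PMO", "wrsnowfinch": "OTA", "rnsnowfinch": "PRU"}

DEFAULT_N_PER_TAXON = {
    "L_tree_sparrow": 9,
    "H_tree_sparrow": 8,
    "RN_snowfinch": 9,
    "WR_snowfinch": 7,
}
# RNA libraries: fewer low-elevation samples
DEFAULT_SAMPLES_PER_TAXON = {
    "L_tree_sparrow": 6,
    "H_tree_sparrow": 8,
    "RN_snowfinch": 9,
    "WR_snowfinch": 7,
}


def default_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=DEFAULT_TREE, schema="newick")


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeModel:
    """Trait model: Brownian rates, taxon shifts, within-taxon covariance.

    Units mimic the study traits: heart mass / body mass (x1000 ratio),
    cardiomyocyte cross-sectional area (um^2), capillary density
    (capillaries / mm^2), and the two residual traits.
    """

    traits: tuple[str, ...] = (
        "heart_ratio",
        "myocyte_area",
        "capillary_density",
        "myocyte_resid",
        "capillary_resid",
    )
    base: tuple[float, ...] = (1.34, 52.64, 3864.0, -0.037, 0.0)
    within_sd: tuple[float, ...] = (0.08, 6.0, 250.0, 0.09, 200.0)
    within_corr: float = 0.3
    bm_rate: tuple[float, ...] | None = None   # per-trait; default 0.3*sd BM depth
    shifts: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "L_tree_sparrow": (0.0, 0.0, 0.0, 0.0, 0.0),
            "H_tree_sparrow": (0.23, 27.0, 416.0, 0.371, 300.0),
            "WR_snowfinch": (-0.38, 3.85, 1755.0, -0.183, 1500.0),
            "RN_snowfinch": (-0.03, 8.70, 1565.0, -0.031, 1400.0),
        }
    )

    def p_matrix(self) -> np.ndarray:
        sd = np.asarray(self.within_sd)
        K = len(sd)
        corr = np.full((K, K), self.within_corr)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sd, sd)


def simulate_phenotypes(
    tree: dendropy.Tree | None = None,
    n_per_taxon: Mapping[str, int] | None = None,
    model: PhenotypeModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Individuals-by-traits table: BM taxon means + shifts + P-matrix noise.

    Taxon means are a multivariate Brownian draw on the tree (independent
    rates per trait) plus the taxon's adaptive shift; individuals add
    multivariate normal within-taxon noise.  Returns (TraitMatrix, truth).
    """
    from .phenospace import tree_vcv

    tree = tree if tree is not None else default_tree()
    n_per_taxon = dict(n_per_taxon or DEFAULT_N_PER_TAXON)
    model = model or PhenotypeModel()
    rng = np.random.default_rng(rng)
    taxa = list(n_per_taxon)
    K = len(model.traits)
    P = model.p_matrix()
    try:
        Lp = np.linalg.cholesky(P) if np.any(P) else np.zeros((K, K))
    except np.linalg.LinAlgError as exc:
        raise ValueError("within-taxon covariance is not positive definite") from exc

    C = tree_vcv(tree, taxa)
    Lc = np.linalg.cholesky(C)
    depth = float(np.max(np.diag(C)))
    rates = (
        np.asarray(model.bm_rate)
        if model.bm_rate is not None
        else (0.3 * np.asarray(model.within_sd)) ** 2 / depth
    )
    # BM deviations: per trait k, dev ~ MVN(0, rates[k] * C) over taxa
    z = rng.standard_normal((len(taxa), K))
    bm_dev = Lc @ z * np.sqrt(rates)

    rows, index = [], []
    means = {}
    for i, taxon in enumerate(taxa):
        mu = (
            np.asarray(model.base)
            + bm_dev[i]
            + np.asarray(model.shifts.get(taxon, np.zeros(K)))
        )
        means[taxon] = mu
        noise = rng.standard_normal((n_per_taxon[taxon], K)) @ Lp.T
        for j in range(n_per_taxon[taxon]):
            rows.append([taxon] + list(mu + noise[j]))
            index.append(f"{taxon}_{j + 1}")
    traits = pd.DataFrame(rows, columns=["taxon", *model.traits], index=index)
    truth = {
        "taxon_means": {t: list(map(float, m)) for t, m in means.items()},
        "shifts": {t: list(map(float, s)) for t, s in model.shifts.items()},
        "bm_rate": list(map(float, rates)),
        "within_sd": list(map(float, model.within_sd)),
        "traits": list(model.traits),
    }
    return traits, truth


# ---------------------------------------------------------------------------
# expression


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    The module's latent factor per sample is a * z(trait) + sqrt(1-a^2) *
    noise; member genes follow the factor with per-gene loadings drawn in
    loading_range, on a lognormal TPM scale.  Genes whose loading is at
    least hub_loading are recorded as planted hubs.
    """

    name: str
    n_genes: int
    trait: str
    a: float = 0.85
    loading_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.2
    hub_loading: float = 0.8


def default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("module1", 100, "capillary_density"),
        ModuleSpec("module2", 100, "heart_ratio"),
        ModuleSpec("module3", 100, "myocyte_resid"),
    ]


DEFAULT_SPECIES_SCALES = {
    "treesparrow": 1.0,
    "wrsnowfinch": 1.0 / 1.298,
    "rnsnowfinch": 1.0 / 1.374,
}


def simulate_expression(
    traits: pd.DataFrame,
    samples_per_taxon: Mapping[str, int] | None = None,
    n_genes: int = 2000,
    modules: Sequence[ModuleSpec] | None = None,
    species_scales: Mapping[str, float] | None = None,
    n_conserved: int = 600,
    n_extra_per_species: int = 100,
    conserved_noise_sd: float = 0.05,
    background_noise_sd: float = 0.6,
    factor_scale: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """TPM-like expression per species with planted modules and scale offsets.

    Samples are the first samples_per_taxon individuals of each taxon in
    `traits` (the same birds carry phenotype and expression).  The ortholog
    catalogue has n_genes genes laid out as [conserved | module blocks |
    background]; each species additionally gets n_extra_per_species
    species-specific genes with no reciprocal hits.  All TPMs of a species
    are multiplied by its scale offset, which downstream normalization
    should invert.

    Returns dict with per-species matrices (species gene ids), the true
    ortholog map, tabular hit files for RBH calling, sample metadata, and
    the truth record.
    """
    rng = np.random.default_rng(rng)
    samples_per_taxon = dict(samples_per_taxon or DEFAULT_SAMPLES_PER_TAXON)
    modules = list(modules) if modules is not None else default_modules()
    species_scales = dict(species_scales or DEFAULT_SPECIES_SCALES)
    n_module = sum(m.n_genes for m in modules)
    if n_conserved + n_module > n_genes:
        raise ValueError(
            f"conserved ({n_conserved}) + module ({n_module}) genes exceed "
            f"n_genes ({n_genes})"
        )

    samples, sample_taxon = [], {}
    for taxon, n_s in samples_per_taxon.items():
        ids = [i for i in traits.index if traits.loc[i, "taxon"] == taxon][:n_s]
        if len(ids) < n_s:
            raise ValueError(f"not enough {taxon} individuals in traits table")
        samples += ids
        for s in ids:
            sample_taxon[s] = taxon
    sample_species = {s: TAXON_SPECIES[t] for s, t in sample_taxon.items()}
    n_samples = len(samples)

    # ortholog ids per species
    ortho = pd.DataFrame(
        {
            sp: [f"{pref}_{i:06d}" for i in range(1, n_genes + 1)]
            for sp, pref in SPECIES_PREFIX.items()
        }
    )

    base = rng.lognormal(mean=3.0, sigma=1.2, size=n_genes)
    log_x = np.zeros((n_genes, n_samples))

    gene_module = np.array([""] * n_genes, dtype=object)
    loading = np.zeros(n_genes)
    conserved_idx = np.arange(n_conserved)
    gene_module[conserved_idx] = "conserved"
    log_x[conserved_idx] = rng.normal(
        0.0, conserved_noise_sd, size=(n_conserved, n_samples)
    )

    trait_z = {}
    for m in modules:
        v = traits.loc[samples, m.trait].to_numpy(dtype=float)
        trait_z[m.trait] = (v - v.mean()) / v.std(ddof=0)

    pos = n_conserved
    factors = {}
    for m in modules:
        idx = np.arange(pos, pos + m.n_genes)
        pos += m.n_genes
        f = m.a * trait_z[m.trait] + np.sqrt(1 - m.a**2) * rng.standard_normal(
            n_samples
        )
        factors[m.name] = f
        lam = rng.uniform(*m.loading_range, size=m.n_genes)
        loading[idx] = lam
        gene_module[idx] = m.name
        log_x[idx] = factor_scale * np.outer(lam, f) + rng.normal(
            0.0, m.noise_sd, size=(m.n_genes, n_samples)
        )
    bg_idx = np.arange(pos, n_genes)
    log_x[bg_idx] = rng.normal(0.0, background_noise_sd, size=(len(bg_idx), n_samples))

    tpm = base[:, None] * np.exp(log_x)

    # per-species matrices with species gene ids + species-specific extras
    expr_by_species: dict[str, pd.DataFrame] = {}
    for sp in SPECIES_PREFIX:
        cols = [s for s in samples if sample_species[s] == sp]
        mat = pd.DataFrame(tpm[:, [samples.index(c) for c in cols]],
                           index=ortho[sp], columns=cols)
        extra_ids = [
            f"{SPECIES_PREFIX[sp]}_X{i:04d}" for i in range(1, n_extra_per_species + 1)
        ]
        extra = pd.DataFrame(
            rng.lognormal(3.0, 1.2, size=(n_extra_per_species, 1))
            * np.exp(rng.normal(0, background_noise_sd,
                                size=(n_extra_per_species, len(cols)))),
            index=extra_ids, columns=cols,
        )
        mat = pd.concat([mat, extra]) * species_scales[sp]
        expr_by_species[sp] = mat

    hits = _make_hit_tables(ortho, rng)

    hub_flags = (loading >= np.array(
        [next((m.hub_loading for m in modules if m.name == mod), np.inf)
         if mod not in ("", "conserved") else np.inf for mod in gene_module]
    ))
    truth = {
        "species_scales": {k: float(v) for k, v in species_scales.items()},
        "n_genes": n_genes,
        "conserved_genes": ortho["treesparrow"][conserved_idx].tolist(),
        "modules": [
            {
                "name": m.name,
                "trait": m.trait,
                "a": m.a,
                "genes": ortho["treesparrow"][gene_module == m.name].tolist(),
            }
            for m in modules
        ],
        "gene_module": {
            g: mod for g, mod in zip(ortho["treesparrow"], gene_module) if mod
        },
        "loading": {
            g: float(l)
            for g, l, mod in zip(ortho["treesparrow"], loading, gene_module)
            if mod not in ("", "conserved")
        },
        "planted_hubs": ortho["treesparrow"][hub_flags].tolist(),
        "factor_scale": factor_scale,
    }
    return {
        "expr": expr_by_species,
        "orthologs": ortho,
        "hits": hits,
        "samples": samples,
        "sample_taxon": sample_taxon,
        "sample_species": sample_species,
        "truth": truth,
    }


def _make_hit_tables(
    ortho: pd.DataFrame, rng: np.random.Generator
) -> dict[tuple[str, str], pd.DataFrame]:
    """Reciprocal tabular hit files between the pivot and the other species.

    True ortholog pairs get strong mutual hits; decoy rows (second-best
    hits, sub-threshold e-values or identities) exercise the RBH filters.
    """
    pivot = "treesparrow"
    out = {}
    n = len(ortho)
    for sp in SPECIES_PREFIX:
        if sp == pivot:
            continue
        q = ortho[pivot].to_numpy()
        s = ortho[sp].to_numpy()
        bits = rng.uniform(300, 900, size=n).round(1)
        pid = rng.uniform(55, 95, size=n).round(2)
        ev = 10.0 ** rng.uniform(-180, -20, size=n)
        fwd = pd.DataFrame(
            {"query": q, "subject": s, "pident": pid, "evalue": ev,
             "bitscore": bits, "length": rng.integers(300, 2000, size=n)}
        )
        rev = fwd.rename(columns={"query": "subject", "subject": "query"})[
            ["query", "subject", "pident", "evalue", "bitscore", "length"]
        ]
        # decoys: weaker off-diagonal hits and threshold-failing rows
        k = max(5, n // 50)
        pick = rng.choice(n, size=k, replace=False)
        decoy = pd.DataFrame(
            {
                "query": q[pick],
                "subject": s[(pick + 1) % n],
                "pident": rng.uniform(40, 90, size=k).round(2),
                "evalue": 10.0 ** rng.uniform(-15, -11, size=k),
                "bitscore": bits[pick] - rng.uniform(50, 150, size=k).round(1),
                "length": rng.integers(200, 900, size=k),
            }
        )
        weak = pd.DataFrame(
            {
                "query": q[pick],
                "subject": s[(pick + 2) % n],
                "pident": rng.uniform(10, 29.9, size=k).round(2),
                "evalue": 10.0 ** rng.uniform(-300, -200, size=k),
                "bitscore": rng.uniform(900, 1200, size=k).round(1),
                "length": rng.integers(200, 900, size=k),
            }
        )
        out[(pivot, sp)] = pd.concat([fwd, decoy, weak], ignore_index=True)
        out[(sp, pivot)] = rev.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# genome and polymorphism


def place_genes(
    contig_lengths: Mapping[str, int],
    gene_ids: Sequence[str],
    gene_length: int = 4000,
    spacing: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> list[GeneModel]:
    """Lay genes on contigs at regular spacing with random strands."""
    rng = np.random.default_rng(rng)
    genes = []
    ids = list(gene_ids)
    i = 0
    for chrom, length in contig_lengths.items():
        start = spacing // 2
        while start + gene_length < length and i < len(ids):
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + gene_length, strand)
            genes.append(build_gene_model(ids[i], body, length))
            i += 1
            start += spacing
        if i >= len(ids):
            break
    if i < len(ids):
        raise ValueError(
            f"contigs too small: placed {i} of {len(ids)} genes"
        )
    return genes


def write_gff(
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            b = g.body
            fh.write(
                f"{b.chrom}\taltadapt\tgene\t{b.start + 1}\t{b.end}\t.\t"
                f"{b.strand}\t.\tID={g.gene_id}\n"
            )


def plan_sweep_windows(
    windows: pd.DataFrame,
    hub_flank_ids: set[str],
    fraction: float = 0.01,
    hub_weight: float = 3.0,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Choose sweep windows, over-weighting hub-gene flank windows.

    Windows whose ids are in hub_flank_ids are hub_weight times more likely
    to carry a planted sweep; the total count is fraction * N (>= 1).
    """
    rng = np.random.default_rng(rng)
    ids = windows["window_id"].to_numpy()
    w = np.where(np.isin(ids, list(hub_flank_ids)), hub_weight, 1.0)
    k = max(1, int(round(fraction * len(ids))))
    chosen = rng.choice(ids, size=k, replace=False, p=w / w.sum())
    return sorted(chosen.tolist())


SWEEP_ESCAPE_PROB = 0.02


def _sweep_sfs(n: int, w: float, p_escape: float = SWEEP_ESCAPE_PROB) -> np.ndarray:
    """Post-sweep folded spectrum: neutral mixed (weight w) with the
    hitchhiking-escape conditional at a small escape probability.

    The escape conditional concentrates on singletons and other rare
    classes — escapee variants stay rare while hitchhiked variants reach
    high frequency and fold back into the low minor-count classes — which
    is the classic folded sweep signature.
    """
    from .sweepscan import CLRScanner

    q = folded_neutral_sfs(n)
    distorted = CLRScanner(n, q).class_distribution(p_escape)
    return (1 - w) * q + w * distorted


def simulate_polymorphism(
    contig_lengths: Mapping[str, int],
    windows: pd.DataFrame | None = None,
    n_chrom: int = 22,
    theta: float = 0.003,
    sweep_windows: Sequence[str] = (),
    f_s: float = 0.2,
    w: float = 0.8,
    window_size: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Independent-site polymorphism with planted sweep windows.

    Neutral windows: S ~ Poisson(a1 * theta * L) segregating sites with
    folded minor counts from the neutral spectrum ∝ 1/j + 1/(n-j).  Sweep
    windows: S reduced by factor f_s and counts drawn from the neutral
    spectrum mixed (weight w) with an escape-distorted spectrum.  Sites are
    independent (no linkage), matching the composite-likelihood use.

    Returns (sites table with chrom/pos/minor_count/n_called, truth).
    """
    if n_chrom < 4:
        raise ValueError("n_chrom must be >= 4 (Tajima constants undefined)")
    rng = np.random.default_rng(rng)
    if windows is None:
        windows = tile_windows(contig_lengths, window_size)
    a1 = float((1.0 / np.arange(1, n_chrom)).sum())
    q_neutral = folded_neutral_sfs(n_chrom)
    q_sweep = _sweep_sfs(n_chrom, w)
    sweep_set = set(sweep_windows)
    j_classes = np.arange(1, n_chrom // 2 + 1)
    chroms, poss, counts = [], [], []
    for row in windows.itertuples(index=False):
        L = row.end - row.start
        is_sweep = row.window_id in sweep_set
        lam = a1 * theta * L * (f_s if is_sweep else 1.0)
        S = rng.poisson(lam)
        if S == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(row.start, row.end), size=min(S, L), replace=False)
        )
        jc = rng.choice(j_classes, size=pos.size, p=q_sweep if is_sweep else q_neutral)
        chroms += [row.chrom] * pos.size
        poss.append(pos)
        counts.append(jc)
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(poss) if poss else np.empty(0, int),
            "minor_count": np.concatenate(counts) if counts else np.empty(0, int),
        }
    )
    sites["n_called"] = n_chrom
    sites.attrs["n"] = n_chrom
    truth = {
        "theta": theta,
        "n_chrom": n_chrom,
        "f_s": f_s,
        "w": w,
        "sweep_windows": sorted(sweep_set),
    }
    return sites, truth


def write_vcf(
    sites: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    path: str | Path,
    taxon: str = "taxon",
    rng: np.random.Generator | int | None = None,
) -> None:
    """Write per-site minor-allele records as a diploid VCF v4.2.

    The minor allele is written as ALT; its j copies are placed on random
    chromosomes (seeded, hence byte-reproducible).
    """
    rng = np.random.default_rng(rng)
    n = int(sites.attrs.get("n") or sites["n_called"].max())
    if n % 2:
        raise ValueError("diploid VCF needs an even chromosome count")
    n_ind = n // 2
    names = [f"{taxon}_s{i + 1}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=altadapt-synthetic\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        order = sites.sort_values(["chrom", "pos"], kind="mergesort")
        for row in order.itertuples(index=False):
            alleles = np.zeros(n, dtype=int)
            carriers = rng.choice(n, size=int(row.minor_count), replace=False)
            alleles[carriers] = 1
            gts = "\t".join(
                f"{alleles[2 * i]}/{alleles[2 * i + 1]}" for i in range(n_ind)
            )
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# bundle orchestration


@dataclass
class SyntheticBundle:
    tree: dendropy.Tree
    traits: pd.DataFrame
    expression: dict
    genes: list[GeneModel]
    contig_lengths: dict[str, int]
    windows: pd.DataFrame
    sites_by_taxon: dict[str, pd.DataFrame]
    truth: dict


DEFAULT_CONTIGS = {f"chr{i}": 800_000 for i in range(1, 6)}
SWEEP_TAXA = ("H_tree_sparrow", "WR_snowfinch", "RN_snowfinch")


def simulate_bundle(
    seed: int,
    contig_lengths: Mapping[str, int] | None = None,
    n_genes: int = 2000,
    n_placed_genes: int = 200,
    window_size: int = 2000,
    sweep_fraction: float = 0.01,
    hub_weight: float = 3.0,
    n_chrom: int = 22,
    theta: float = 0.003,
    f_s: float = 0.2,
    w: float = 0.8,
    modules: Sequence[ModuleSpec] | None = None,
    n_per_taxon: Mapping[str, int] | None = None,
    samples_per_taxon: Mapping[str, int] | None = None,
    n_conserved: int = 600,
) -> SyntheticBundle:
    """Generate the full linked dataset: phenotypes, expression, genome, VCFs.

    Placed genes include every planted-hub gene (so sweep planting near hub
    flanks is possible) padded with background genes.  Sweeps are planted in
    each high-elevation taxon with hub-flank windows hub_weight-fold
    enriched.
    """
    from .core_io import classify_windows

    ss = np.random.SeedSequence(seed)
    keys = ss.spawn(6)
    contig_lengths = dict(contig_lengths or DEFAULT_CONTIGS)
    tree = default_tree()

    traits, pheno_truth = simulate_phenotypes(
        tree, n_per_taxon, rng=np.random.default_rng(keys[0])
    )
    expression = simulate_expression(
        traits,
        samples_per_taxon=samples_per_taxon,
        n_genes=n_genes,
        modules=modules,
        n_conserved=n_conserved,
        rng=np.random.default_rng(keys[1]),
    )
    etruth = expression["truth"]

    hubs = list(etruth["planted_hubs"])
    background = [
        g
        for g in expression["orthologs"]["treesparrow"]
        if g not in set(etruth["gene_module"])
    ]
    # hub genes are placed first so sweeps can be planted near their flanks;
    # background genes pad out the catalogue up to n_placed_genes
    placed_ids = (hubs + background)[:n_placed_genes]
    genes = place_genes(
        contig_lengths, placed_ids, rng=np.random.default_rng(keys[2])
    )
    windows = tile_windows(contig_lengths, window_size)
    classified = classify_windows(windows, genes)
    hub_set = set(hubs)
    hub_flank = set()
    for cls in ("upstream", "downstream"):
        col = classified[cls + "_genes"]
        for wid, names in zip(classified["window_id"], col):
            if names and hub_set & set(names.split(",")):
                hub_flank.add(wid)

    sites_by_taxon = {}
    sweep_truth = {}
    sweep_keys = keys[3].spawn(len(SWEEP_TAXA))
    for taxon, key in zip(SWEEP_TAXA, sweep_keys):
        sub = key.spawn(2)
        sweeps = plan_sweep_windows(
            windows, hub_flank, sweep_fraction, hub_weight,
            rng=np.random.default_rng(sub[0]),
        )
        sites, truth = simulate_polymorphism(
            contig_lengths, windows, n_chrom, theta, sweeps, f_s, w,
            window_size, rng=np.random.default_rng(sub[1]),
        )
        sites_by_taxon[taxon] = sites
        sweep_truth[taxon] = truth

    truth = {
        "seed": seed,
        "phenotypes": pheno_truth,
        "expression": etruth,
        "polymorphism": sweep_truth,
        "placed_genes": placed_ids,
        "hub_flank_windows": sorted(hub_flank),
    }
    return SyntheticBundle(
        tree=tree,
        traits=traits,
        expression=expression,
        genes=genes,
        contig_lengths=contig_lengths,
        windows=windows,
        sites_by_taxon=sites_by_taxon,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path, seed: int = 0) -> None:
    """Serialize a bundle: tree.nwk, phenotypes.tsv, expr_*.tsv, hits_*.tsv,
    genome.gff3, <taxon>.vcf, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(bundle.tree.as_string(schema="newick").strip() + "\n")
    bundle.traits.to_csv(outdir / "phenotypes.tsv", sep="\t")
    for sp, mat in bundle.expression["expr"].items():
        mat.to_csv(outdir / f"expr_{sp}.tsv", sep="\t")
    for (a, b), df in bundle.expression["hits"].items():
        df.to_csv(outdir / f"hits_{a}_{b}.tsv", sep="\t", header=False, index=False)
    write_gff(bundle.genes, bundle.contig_lengths, outdir / "genome.gff3")
    vcf_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for taxon, sites in bundle.sites_by_taxon.items():
        write_vcf(sites, bundle.contig_lengths, outdir / f"{taxon}.vcf",
                  taxon, rng=vcf_rng)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
        fh.write("\n")
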