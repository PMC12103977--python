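"""Phylogenetic PCA morphospaces and total standardized variation (TSV).

The analysis quantifies how far each high-elevation taxon has moved in a
multivariate trait space (5 cardiovascular phenotypes, or the expression of
hub genes) relative to a low-elevation reference, while accounting for
phylogenetic non-independence of taxa.

Model: traits evolve by multivariate Brownian motion on a rooted tree with
branch lengths.  The expected among-taxon covariance is C[i, j] = shared
root-to-tip branch length of taxa i and j.  The evolutionary trait covariance
is estimated by GLS,

    a = (1' C^-1 1)^-1 1' C^-1 X          (phylogenetic mean vector)
    R = (X - a)' C^-1 (X - a) / (t - 1)   (t taxa)

and the eigenvectors of R define the principal axes.  Taxon means and
individuals are scored by projecting centred values onto those axes.

Divergence ("total standardized variation") of a taxon T from a reference is
the per-axis reference-SD-standardized Euclidean distance

    TSV(x) = sqrt( sum_k ((x_k - mu_ref,k) / sigma_ref,k)^2 )

evaluated over Monte-Carlo draws x ~ Normal(mu_T, sigma_T) per axis (the
taxon's P-matrix approximated by independent per-axis normals), reported as
mean +/- SD over draws.  Pairwise taxon contrasts use Tukey HSD on draw sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .stats_util import tukey_hsd

__all__ = [
    "tree_vcv",
    "phylo_pca",
    "mc_effect_sizes",
    "total_standardized_variation",
    "compare_taxa",
    "MorphospaceResult",
    "TSVResult",
    "phenospace_analysis",
]


def tree_vcv(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion variance-covariance matrix among the named tips.

    C[i, j] is the branch length shared by the root-to-tip paths of i and j
    (the depth of their MRCA); C[i, i] is the tip's root-to-tip depth.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    tips = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label.replace(" ", "_") if leaf.taxon else None
        tips[label] = leaf
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    t = len(taxa)
    C = np.zeros((t, t))
    for i, a in enumerate(taxa):
        C[i, i] = tips[a].root_distance
        for j in range(i + 1, t):
            b = taxa[j]
            d = pdm.patristic_distance(tips[a].taxon, tips[b].taxon)
            shared = 0.5 * (tips[a].root_distance + tips[b].root_distance - d)
            C[i, j] = C[j, i] = shared
    if np.linalg.matrix_rank(C) < t or np.linalg.cond(C) > 1e12:
        raise np.linalg.LinAlgError(
            f"singular Brownian covariance for taxa {list(taxa)}; "
            "check for zero-length terminal branch pairs"
        )
    return C


@dataclass
class MorphospaceResult:
    taxa: list[str]
    traits: list[str]
    loadings: pd.DataFrame            # traits x axes, orthonormal columns
    eigenvalues: np.ndarray
    gls_mean: np.ndarray              # phylogenetic mean per trait
    taxon_scores: pd.DataFrame        # taxa x axes
    individual_scores: pd.DataFrame   # individuals x axes, + taxon column
    n_axes: int
    scaled: bool
    trait_center: np.ndarray = field(default=None)
    trait_scale: np.ndarray = field(default=None)


def phylo_pca(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    taxon_col: str = "taxon",
    scale: bool = True,
    n_axes: int | None = None,
) -> MorphospaceResult:
    """Phylogenetic PCA of an individuals-by-traits table.

    `traits` holds one row per individual with a taxon-label column; all
    other columns are trait values.  When scale=True traits are z-scored
    across individuals first (recommended when traits mix units).  The PCA
    itself operates on taxon means under the Brownian model; individuals are
    projected onto the resulting axes to form morphospace clouds.

    n_axes caps the retained axes at min(K, N_individuals - 1, n_axes).
    """
    trait_cols = [c for c in traits.columns if c != taxon_col]
    if len(trait_cols) < 2:
        raise ValueError("need >= 2 trait columns")
    if traits[taxon_col].isna().any():
        raise ValueError("missing taxon labels")
    X_ind = traits[trait_cols].to_numpy(dtype=float)
    center = X_ind.mean(axis=0)
    scale_v = X_ind.std(axis=0, ddof=1) if scale else np.ones(len(trait_cols))
    if scale and (scale_v == 0).any():
        bad = [trait_cols[i] for i in np.flatnonzero(scale_v == 0)]
        raise ValueError(f"constant traits cannot be scaled: {bad}")
    Z_ind = (X_ind - center) / scale_v
    groups = traits[taxon_col].to_numpy()
    taxa = list(pd.unique(groups))
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValueError("every taxon needs >= 2 individuals")
    Xm = np.vstack([Z_ind[groups == t].mean(axis=0) for t in taxa])

    C = tree_vcv(tree, taxa)
    Cinv = np.linalg.inv(C)
    one = np.ones((len(taxa), 1))
    a = (one.T @ Cinv @ Xm) / float((one.T @ Cinv @ one).item())   # 1 x K
    Xc = Xm - a
    R = Xc.T @ Cinv @ Xc / (len(taxa) - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # sign convention: the largest-magnitude loading of each axis is positive
    for k in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, k]))
        if evecs[i, k] < 0:
            evecs[:, k] *= -1

    cap = min(len(trait_cols), len(traits) - 1)
    if n_axes is not None:
        cap = min(cap, n_axes)
    evecs = evecs[:, :cap]
    evals = evals[:cap]
    axes = [f"PC{k + 1}" for k in range(cap)]

    taxon_scores = (Xm - a) @ evecs
    ind_scores = (Z_ind - a) @ evecs
    ind_df = pd.DataFrame(ind_scores, columns=axes, index=traits.index)
    ind_df[taxon_col] = groups
    return MorphospaceResult(
        taxa=taxa,
        traits=trait_cols,
        loadings=pd.DataFrame(evecs, index=trait_cols, columns=axes),
        eigenvalues=evals,
        gls_mean=center + a.ravel() * scale_v,   # original trait units
        taxon_scores=pd.DataFrame(taxon_scores, index=taxa, columns=axes),
        individual_scores=ind_df,
        n_axes=cap,
        scaled=scale,
        trait_center=center,
        trait_scale=scale_v,
    )


def mc_effect_sizes(
    result: MorphospaceResult,
    n_draws: int = 5000,
    rng: np.random.Generator | int | None = None,
    taxon_col: str = "taxon",
) -> dict[str, np.ndarray]:
    """Monte-Carlo draw matrices (n_draws x axes) per taxon.

    Per-axis score means and SDs are estimated from each taxon's individual
    scores and draws are independent normals per axis, approximating the
    within-taxon P-matrix in score space.
    """
    rng = np.random.default_rng(rng)
    axes = [c for c in result.individual_scores.columns if c != taxon_col]
    draws = {}
    for taxon, grp in result.individual_scores.groupby(taxon_col, sort=False):
        S = grp[axes].to_numpy(dtype=float)
        if S.shape[0] < 2:
            raise ValueError(f"taxon {taxon!r} has < 2 individuals; SD undefined")
        mu = S.mean(axis=0)
        sd = S.std(axis=0, ddof=1)
        draws[taxon] = rng.normal(mu, sd, size=(n_draws, len(axes)))
    return draws


@dataclass
class TSVResult:
    taxon: str
    reference: str
    values: np.ndarray   # one TSV per Monte-Carlo draw
    mean: float
    sd: float


def total_standardized_variation(
    draws: np.ndarray,
    reference_scores: np.ndarray,
    taxon: str = "",
    reference: str = "",
    pooled_sd: np.ndarray | None = None,
) -> TSVResult:
    """TSV of a taxon's draw cloud relative to a reference score cloud.

    Each draw is standardized per axis by the reference mean and SD and its
    Euclidean norm taken; pass pooled_sd to standardize by a pooled SD
    instead of the reference's own.
    """
    ref = np.asarray(reference_scores, dtype=float)
    mu_ref = ref.mean(axis=0)
    sd_ref = pooled_sd if pooled_sd is not None else ref.std(axis=0, ddof=1)
    if np.any(sd_ref == 0):
        bad = np.flatnonzero(sd_ref == 0).tolist()
        raise ValueError(
            f"reference SD is zero on axes {bad}; drop those axes first"
        )
    z = (np.asarray(draws, dtype=float) - mu_ref) / sd_ref
    tsv = np.sqrt((z**2).sum(axis=1))
    return TSVResult(taxon, reference, tsv, float(tsv.mean()), float(tsv.std(ddof=1)))


def compare_taxa(tsv_results: Mapping[str, TSVResult] | Sequence[TSVResult]) -> pd.DataFrame:
    """Tukey HSD over the TSV draw distributions of several taxa."""
    if not isinstance(tsv_results, Mapping):
        tsv_results = {r.taxon: r for r in tsv_results}
    return tukey_hsd({k: v.values for k, v in tsv_results.items()})


def phenospace_analysis(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    reference: str,
    taxon_col: str = "taxon",
    scale: bool = True,
    n_axes: int | None = None,
    n_draws: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Full morphospace workflow: PCA, draws, TSV vs reference, HSD table.

    Any taxon may serve as reference, so native-vs-native contrasts are
    expressed by re-running with reference set to one of the natives.
    """
    res = phylo_pca(traits, tree, taxon_col=taxon_col, scale=scale, n_axes=n_axes)
    draws = mc_effect_sizes(res, n_draws=n_draws, rng=rng, taxon_col=taxon_col)
    ref_scores = res.individual_scores.loc[
        res.individual_scores[taxon_col] == reference,
        [c for c in res.individual_scores.columns if c != taxon_col],
    ].to_numpy(dtype=float)
    tsv = {
        taxon: total_standardized_variation(d, ref_scores, taxon, reference)
        for taxon, d in draws.items()
        if taxon != reference
    }
    hsd = compare_taxa(tsv) if len(tsv) >= 2 else None
    return {"pca": res, "draws": draws, "tsv": tsv, "hsd": hsd}
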