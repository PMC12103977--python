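"""Weighted co-expression networks, modules, eigengenes, and hub genes.

Follows the weighted gene correlation network approach: an unsigned
adjacency a_ij = |cor(x_i, x_j)|^beta with beta chosen for approximate
scale-free topology, topological overlap (TOM) similarity, average-linkage
clustering of TOM dissimilarity with a static branch cut, module eigengenes
as the first principal component of each module, and a linear mixed model
(random species intercept) linking module expression to phenotypes.  Hub
genes are module members with high module membership (K_ME, correlation
with the eigengene) and high gene significance (GS, |correlation| with a
trait the module is significantly associated with).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "pick_soft_threshold",
    "adjacency",
    "tom_dissimilarity",
    "detect_modules",
    "module_trait_assoc",
    "hub_genes",
    "gene_trait_model",
    "ModuleAssignment",
]


def adjacency(expr: pd.DataFrame, beta: int, signed: bool = False) -> np.ndarray:
    """Soft adjacency between gene rows; zero diagonal.

    Unsigned (default): |cor|^beta.  Signed: ((1 + cor)/2)^beta, which keeps
    anti-correlated genes apart.
    """
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    a = ((1 + cor) / 2) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) vs log10(mean connectivity) over connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        sel = k[which == b]
        if sel.size == 0:
            continue
        xs.append(np.log10(sel.mean()))
        ys.append(np.log10(sel.size / k.size))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = range(1, 21),
    rsq_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose connectivity distribution fits scale-free topology.

    For each candidate beta the whole-network connectivity k_i = sum_j a_ij
    is computed and the fit R^2 of the log-log degree distribution taken;
    the smallest beta reaching rsq_target is returned, else the argmax with
    a warning.  Deterministic given the matrix.
    """
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.abs(np.nan_to_num(cor, nan=0.0))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in powers:
        k = (cor**beta).sum(axis=1)
        rows.append((beta, _scale_free_fit(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["beta", "sft_r2", "mean_k"])
    hit = table[table["sft_r2"] >= rsq_target]
    if hit.empty:
        best = int(table.loc[table["sft_r2"].idxmax(), "beta"])
        warnings.warn(
            f"no power reaches scale-free fit {rsq_target}; using argmax beta={best}"
        )
        return best, table
    return int(hit["beta"].iloc[0]), table


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); diagonal
    TOM is 1 so the dissimilarity has a zero diagonal.
    """
    n = adj.shape[0]
    if n < 3:
        raise ValueError("need >= 3 genes for topological overlap")
    k = adj.sum(axis=1)
    shared = adj @ adj
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + adj) / (kmin + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return 1.0 - tom


@dataclass
class ModuleAssignment:
    genes: list[str]
    labels: np.ndarray                # 0 = unassigned
    eigengenes: pd.DataFrame          # samples x modules ("ME1", ...)
    var_explained: dict[str, float]   # PC1 variance share per module
    beta: int | None = None

    def module_genes(self, module: str) -> list[str]:
        m = int(module.lstrip("ME"))
        return [g for g, l in zip(self.genes, self.labels) if l == m]


def _eigengene(block: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm PC1 over samples of a genes x samples block (genes z-scored).

    Sign is flipped so the mean gene-eigengene correlation is positive.
    """
    z = stats.zscore(block, axis=1, ddof=1)
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    cors = np.array([np.corrcoef(g, pc1)[0, 1] for g in z])
    if np.nanmean(cors) < 0:
        pc1 = -pc1
    var_exp = float(s[0] ** 2 / (s**2).sum())
    return pc1, var_exp


def detect_modules(
    dissim: np.ndarray,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    beta: int | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of TOM dissimilarity with a static branch cut.

    Branches are cut at `cut_height`, clusters smaller than min_module_size
    are sent to module 0 (unassigned), and surviving modules are relabelled
    1..M by decreasing size.  Each module's eigengene is the first principal
    component of its standardized expression.
    """
    genes = list(expr.index)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(len(genes), dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].sort_values(ascending=False)
    for new, old in enumerate(keep.index, start=1):
        labels[raw == old] = new
    eig, var_exp = {}, {}
    X = expr.to_numpy(dtype=float)
    for m in range(1, labels.max() + 1 if labels.size else 0):
        block = X[labels == m]
        pc1, ve = _eigengene(block)
        eig[f"ME{m}"] = pc1
        var_exp[f"ME{m}"] = ve
    eig_df = pd.DataFrame(eig, index=expr.columns)
    return ModuleAssignment(genes, labels, eig_df, var_exp, beta=beta)


# ---------------------------------------------------------------------------
# mixed-model association


def _mixed_fit(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Random-intercept ML fit of y ~ x + (1|group); returns (slope, R2m, p).

    p comes from a likelihood-ratio test against the trait-free model;
    marginal R^2 is the fixed-effect variance share
    var(Xb) / (var(Xb) + var(random intercept) + var(residual)).
    Falls back to OLS (with a warning) when there are < 3 groups or < 6
    samples, where the random intercept is not estimable.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n_groups = len(set(groups))
    if n_groups < 3 or y.size < 6:
        warnings.warn("too few species/samples for a mixed model; using OLS")
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        return float(fit.params[1]), float(fit.rsquared), float(fit.pvalues[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = sm.add_constant(x)
        full = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        null = sm.MixedLM(y, np.ones((y.size, 1)), groups=groups).fit(reml=False)
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lr, df=1))
    slope = float(full.fe_params[1])
    fixed = X @ full.fe_params
    var_f = float(np.var(fixed))
    var_re = float(np.asarray(full.cov_re)[0, 0])
    var_resid = float(full.scale)
    r2m = var_f / (var_f + var_re + var_resid)
    return slope, r2m, p


def module_trait_assoc(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    species: Sequence[str],
    r2_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Module-trait associations by a random-species-intercept mixed model.

    eigengenes and traits are samples x modules / samples x traits with a
    shared row order; species gives the per-sample random-effect grouping.
    A module-trait pair is "significant" when marginal R^2 exceeds
    r2_threshold and the likelihood-ratio p falls below p_threshold.
    """
    if list(eigengenes.index) != list(traits.index):
        raise ValueError("eigengene and trait tables must share sample order")
    groups = np.asarray(species)
    rows = []
    for module in eigengenes.columns:
        y = eigengenes[module].to_numpy(float)
        for trait in traits.columns:
            x = traits[trait].to_numpy(float)
            slope, r2, p = _mixed_fit(y, x, groups)
            rows.append((module, trait, slope, r2, p, y.size))
    out = pd.DataFrame(
        rows, columns=["module", "trait", "slope", "r2_marginal", "p", "n"]
    )
    out["significant"] = (out["r2_marginal"] > r2_threshold) & (
        out["p"] < p_threshold
    )
    return out


def gene_trait_model(
    gene_expr: Sequence[float],
    trait: Sequence[float],
    species: Sequence[str],
) -> tuple[float, float, float]:
    """Per-gene expression-trait mixed model; returns (slope, marginal R2, p)."""
    return _mixed_fit(np.asarray(gene_expr, float), np.asarray(trait, float),
                      np.asarray(species))


def hub_genes(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    traits: pd.DataFrame,
    assoc: pd.DataFrame,
    kme_threshold: float = 0.8,
    gs_threshold: float = 0.2,
    signed_gs: bool = False,
) -> pd.DataFrame:
    """Hub-gene table: K_ME and GS per assigned gene with the hub call.

    K_ME = Pearson correlation of the gene's expression with its own module
    eigengene.  GS = max over the module's significant traits of the
    |correlation| between gene expression and trait (signed_gs keeps the
    sign and thresholds the raw value).  Modules without a significant trait
    fall back to all traits.  hub iff K_ME > kme and GS > gs.
    """
    sig_traits = {
        m: list(grp.loc[grp["significant"], "trait"])
        for m, grp in assoc.groupby("module")
    }
    X = expr.to_numpy(dtype=float)
    T = traits.to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(assignment.genes):
        m = assignment.labels[i]
        if m == 0:
            continue
        me = f"ME{m}"
        kme = float(np.corrcoef(X[i], assignment.eigengenes[me])[0, 1])
        use = sig_traits.get(me) or list(traits.columns)
        cors = [
            float(np.corrcoef(X[i], T[:, traits.columns.get_loc(t)])[0, 1])
            for t in use
        ]
        gs = max(cors) if signed_gs else max(abs(c) for c in cors)
        rows.append((gene, me, kme, gs, kme > kme_threshold and gs > gs_threshold))
    return pd.DataFrame(rows, columns=["gene", "module", "kme", "gs", "hub"])
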