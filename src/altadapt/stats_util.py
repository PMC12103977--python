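"""Small-sample statistics used throughout the pipeline.

Pairwise t-tests with Benjamini-Hochberg FDR, OLS residualisation of one
trait against another, rank and correlation tests, Tukey HSD over groups of
draws, and hypergeometric over-representation analysis on GMT gene sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "group_compare",
    "residualize",
    "pearson",
    "wilcoxon_rank_sum",
    "tukey_hsd",
    "ora",
    "read_gmt",
]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided t-tests for group pairs with BH correction across the family.

    Student's (equal-variance) t by default; set equal_var=False for Welch.
    Zero variance in both groups with equal means yields p = 1 by convention.
    """
    if pairs is None:
        pairs = list(itertools.combinations(values_by_group, 2))
    rows = []
    for g1, g2 in pairs:
        a = np.asarray(values_by_group[g1], dtype=float)
        b = np.asarray(values_by_group[g2], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"need >= 2 values per group ({g1!r} vs {g2!r})")
        if a.std() == 0 and b.std() == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append((g1, g2, a.mean(), b.mean(), float(t), float(p)))
    out = pd.DataFrame(
        rows, columns=["group1", "group2", "mean1", "mean2", "t", "p"]
    )
    out["q"] = bh_fdr(out["p"])
    return out


@dataclass
class Residualization:
    residuals: np.ndarray
    slope: float
    intercept: float


def residualize(y: Sequence[float], x: Sequence[float]) -> Residualization:
    """OLS residuals of y against x over all individuals pooled.

    Used to derive residual traits, e.g. cardiomyocyte size after removing
    its allometric dependence on heart mass.  Residuals are mean-zero and
    orthogonal to x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        slope, intercept = 0.0, y.mean()
    else:
        slope, intercept, *_ = stats.linregress(x, y)
    resid = y - (slope * x + intercept)
    return Residualization(resid, float(slope), float(intercept))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float))[0])


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test; returns (U, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey honest-significant-difference test over named groups of draws.

    Each group is treated as one sample in a one-way layout.  When applied
    to Monte-Carlo draw sets the draws are pseudo-replicates, so p-values
    index separation of simulated distributions rather than of raw data.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[k], float) for k in names]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            (
                names[i],
                names[j],
                arrays[i].mean() - arrays[j].mean(),
                float(res.pvalue[i, j]),
            )
        )
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def ora(
    hub: set[str],
    universe: set[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of `hub` in each gene set.

    P(X >= k) for k = |hub ∩ set| drawn from a universe of size N with
    |set ∩ universe| marked genes and |hub| draws; BH correction across sets.
    Sets with no gene in the universe are skipped with a warning.
    """
    if not hub <= universe:
        raise ValueError("hub genes must be a subset of the universe")
    N, n_draw = len(universe), len(hub)
    rows = []
    for name, genes in gene_sets.items():
        in_univ = genes & universe
        if not in_univ:
            warnings.warn(f"gene set {name!r} has no genes in the universe; skipped")
            continue
        k = len(hub & in_univ)
        p = float(stats.hypergeom.sf(k - 1, N, len(in_univ), n_draw))
        rows.append((name, len(in_univ), k, p))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if not out.empty:
        out["q"] = bh_fdr(out["p"])
    else:
        out["q"] = []
    return out
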