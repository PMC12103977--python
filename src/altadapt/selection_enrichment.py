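"""Permutation tests linking sweep outliers to hub-gene regions.

Two bespoke resampling tests:

* region_enrichment — are top-CLR windows over-represented in hub-gene
  genic / upstream / downstream regions?  The null resamples the same
  number of windows uniformly (without replacement) from all scored
  windows 1,000 times and recomputes the overlap proportion; the empirical
  proportion is called significant past the 95th (or 99th) null percentile.
* gene_clr_test — per candidate gene, is the maximum CLR over windows
  overlapping its genic/upstream/downstream region higher than expected?
  The null resamples the same number of windows from the pooled
  class-matched gene-associated windows of ALL genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import REGION_CLASSES, GeneModel, classify_windows
from .sweepscan import background_compare

__all__ = [
    "EnrichmentResult",
    "GeneCLRTest",
    "region_enrichment",
    "gene_clr_test",
    "hub_region_diversity",
]


@dataclass
class EnrichmentResult:
    region_class: str
    empirical_proportion: float
    null: np.ndarray
    percentile: float           # fraction of null draws below the empirical value
    call: str                   # "ns", ">95th", ">99th"


def _call(percentile: float) -> str:
    if percentile > 0.99:
        return ">99th"
    if percentile > 0.95:
        return ">95th"
    return "ns"


def _sample_windows(
    rng: np.random.Generator, n_total: int, k: int, n_perm: int,
    replace: bool = False,
) -> np.ndarray:
    """(n_perm, k) index matrix of uniform draws, without replacement by
    default."""
    if replace:
        return rng.integers(0, n_total, size=(n_perm, k))
    keys = rng.random((n_perm, n_total))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def region_enrichment(
    selected: pd.DataFrame,
    all_windows: pd.DataFrame,
    hub_genes: Sequence[GeneModel],
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    classes: Sequence[str] = REGION_CLASSES + ("regulatory",),
    classified: pd.DataFrame | None = None,
    replace: bool = False,
) -> dict[str, EnrichmentResult]:
    """Enrichment of the selected window set in hub-gene region classes.

    empirical proportion = |selected ∩ class| / |selected|; the null draws
    |selected| windows uniformly without replacement from all windows.
    The `regulatory` class is the union of upstream and downstream.
    """
    if selected.empty:
        raise ValueError("selected window set is empty")
    if len(all_windows) < len(selected):
        raise ValueError("selected set larger than the window universe")
    if not set(selected["window_id"]) <= set(all_windows["window_id"]):
        raise ValueError("selected windows must come from the window universe")
    rng = np.random.default_rng(rng)
    if classified is None:
        classified = classify_windows(
            all_windows[["window_id", "chrom", "start", "end"]], hub_genes
        )
    k = len(selected)
    sel_mask = classified["window_id"].isin(set(selected["window_id"])).to_numpy()
    idx_mat = _sample_windows(rng, len(classified), k, n_permutations, replace)
    out = {}
    for cls in classes:
        in_cls = classified[cls].to_numpy()
        empirical = float(in_cls[sel_mask].mean())
        null = in_cls[idx_mat].mean(axis=1)
        percentile = float((null < empirical).mean())
        out[cls] = EnrichmentResult(cls, empirical, null, percentile, _call(percentile))
    return out


@dataclass
class GeneCLRTest:
    gene_id: str
    region_class: str
    empirical: float
    null: np.ndarray
    percentile: float
    significant: bool
    n_windows: int
    testable: bool = True


def gene_clr_test(
    gene: GeneModel,
    scan: pd.DataFrame,
    all_genes: Sequence[GeneModel],
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    aggregator: str = "max",
    classified: pd.DataFrame | None = None,
) -> dict[str, GeneCLRTest]:
    """Constrained permutation test of one gene's CLR per region class.

    The empirical summary is the max (or mean) CLR over scored windows
    overlapping the gene's genic/upstream/downstream region; the null
    resamples the same number of windows from the pooled class-matched
    windows of all genes (the permutation universe is constrained to
    gene-associated windows).  Significant iff empirical > 95th percentile.
    """
    rng = np.random.default_rng(rng)
    agg = {"max": np.max, "mean": np.mean}[aggregator]
    scored = scan[scan["flag"] == "ok"].reset_index(drop=True)
    if classified is None:
        classified = classify_windows(
            scored[["window_id", "chrom", "start", "end"]], list(all_genes)
        )
    clr = scored["clr"].to_numpy()
    out = {}
    for cls in REGION_CLASSES:
        pool = clr[classified[cls].to_numpy()]
        region = gene.region(cls)
        if region is None:
            out[cls] = GeneCLRTest(gene.gene_id, cls, np.nan,
                                   np.empty(0), np.nan, False, 0, False)
            continue
        hit = (
            (scored["chrom"] == region.chrom)
            & (scored["start"] < region.end)
            & (region.start < scored["end"])
        ).to_numpy()
        k = int(hit.sum())
        if k == 0 or pool.size < k:
            out[cls] = GeneCLRTest(gene.gene_id, cls, np.nan,
                                   np.empty(0), np.nan, False, k, False)
            continue
        empirical = float(agg(clr[hit]))
        idx = _sample_windows(rng, pool.size, k, n_permutations)
        null = agg(pool[idx], axis=1) if aggregator == "max" else pool[idx].mean(axis=1)
        percentile = float((null < empirical).mean())
        out[cls] = GeneCLRTest(
            gene.gene_id, cls, empirical, null, percentile,
            percentile > 0.95, k,
        )
    return out


def hub_region_diversity(
    hub_genes: Sequence[GeneModel],
    scan: pd.DataFrame,
    classes: Sequence[str] = REGION_CLASSES,
) -> pd.DataFrame:
    """Wilcoxon comparison of pi and Tajima's D in hub regions vs background.

    For each region class, windows overlapping any hub gene's region of
    that class are compared against all remaining scored windows.
    """
    scored = scan[scan["flag"] == "ok"].reset_index(drop=True)
    classified = classify_windows(
        scored[["window_id", "chrom", "start", "end"]], list(hub_genes)
    )
    rows = []
    for cls in classes:
        region = scored[classified[cls].to_numpy()]
        if region.empty:
            continue
        cmp = background_compare(region, scored)
        cmp.insert(0, "region_class", cls)
        rows.append(cmp)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
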