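"""Ortholog calling and cross-species expression normalization.

Orthologs come from reciprocal best hits (RBH) between species pairs of
tabular homology hits, extended to three species by intersecting pairwise
maps through a pivot species.  Expression (TPM) is then put on a common
scale using "conserved" genes — genes whose TPM varies little across all
samples of all species (coefficient of variation <= 0.3) — by a gene-wise
median-of-ratios scaling factor against a reference species.
"""

from __future__ import annotations

import warnings
from functools import reduce
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_hits",
    "best_hits",
    "rbh_pair",
    "rbh_orthologs",
    "conserved_genes",
    "scaling_factors",
    "apply_scaling",
    "counts_to_tpm",
]

HIT_COLUMNS = ["query", "subject", "pident", "evalue", "bitscore", "length"]


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read 6-column tabular homology hits (BLAST outfmt-6-like subset)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return df


def best_hits(
    hits: pd.DataFrame, evalue_max: float = 1e-10, identity_min: float = 30.0
) -> pd.Series:
    """Best subject per query after filtering.

    Hits must satisfy e-value strictly below evalue_max AND identity at or
    above identity_min.  Best = highest bitscore; ties broken by lower
    e-value, then lexicographic subject id.  Duplicate (query, subject) rows
    keep their best-scoring copy.
    """
    ok = hits[(hits["evalue"] < evalue_max) & (hits["pident"] >= identity_min)]
    if ok.empty:
        return pd.Series(dtype=object)
    ranked = ok.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    top = ranked.drop_duplicates("query", keep="first")
    return top.set_index("query")["subject"]


def rbh_pair(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_max: float = 1e-10,
    identity_min: float = 30.0,
    names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Reciprocal best hits between two species' hit tables.

    A pair (a, b) is kept iff b is a's best hit in hits_ab and a is b's best
    hit in hits_ba.
    """
    ab = best_hits(hits_ab, evalue_max, identity_min)
    ba = best_hits(hits_ba, evalue_max, identity_min)
    rows = [
        (a, b)
        for a, b in ab.items()
        if ba.get(b) == a
    ]
    if not rows:
        warnings.warn(f"no reciprocal best hits between {names[0]} and {names[1]}")
    return pd.DataFrame(rows, columns=list(names))


def rbh_orthologs(
    pair_hits: Mapping[tuple[str, str], pd.DataFrame],
    pivot: str,
    evalue_max: float = 1e-10,
    identity_min: float = 30.0,
) -> pd.DataFrame:
    """Multi-species ortholog map via RBH pairs intersected through a pivot.

    pair_hits maps directed species pairs (query_species, subject_species)
    to hit tables; both directions are required for every species paired
    with the pivot.  Returns one row per ortholog group with one gene-id
    column per species; ids are unique within each column.
    """
    others = sorted(
        {a for a, b in pair_hits if b == pivot}
        | {b for a, b in pair_hits if a == pivot}
    )
    if not others:
        raise ValueError(f"no species paired with pivot {pivot!r}")
    maps = []
    for sp in others:
        fwd = pair_hits.get((pivot, sp))
        rev = pair_hits.get((sp, pivot))
        if fwd is None or rev is None:
            raise ValueError(f"need hits in both directions for {pivot}<->{sp}")
        maps.append(
            rbh_pair(fwd, rev, evalue_max, identity_min, names=(pivot, sp))
        )
    merged = reduce(lambda l, r: l.merge(r, on=pivot, how="inner"), maps)
    for col in merged.columns:
        if merged[col].duplicated().any():
            dupes = merged[col][merged[col].duplicated()].tolist()[:3]
            raise ValueError(f"non-unique ortholog ids in {col}: {dupes}")
    return merged.reset_index(drop=True)


def conserved_genes(
    expr: pd.DataFrame, cv_threshold: float = 0.3, log_scale: bool = False
) -> list[str]:
    """Genes with coefficient of variation <= threshold across ALL samples.

    CV = population SD / mean per gene over every sample of every species.
    Genes with zero mean are excluded.  log_scale computes the CV on
    log1p-transformed values instead of raw TPM.
    """
    vals = expr.to_numpy(dtype=float)
    if log_scale:
        vals = np.log1p(vals)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    keep = expr.index[cv <= cv_threshold].tolist()
    if not keep:
        raise ValueError(
            f"no gene passes CV <= {cv_threshold}; raise cv_threshold or "
            "check the expression units"
        )
    return keep


def scaling_factors(
    expr: pd.DataFrame,
    sample_species: Mapping[str, str],
    conserved: Sequence[str],
    reference: str,
    method: str = "median_of_ratios",
) -> dict[str, float]:
    """Per-species factors putting conserved-gene medians on the reference scale.

    For each non-reference species s, the gene-wise ratio
    median(TPM in reference samples) / median(TPM in species-s samples) is
    computed over conserved genes and summarized by its median
    (method="median_of_ratios", default) or by the ratio of pooled medians
    (method="pooled").  Conserved genes with a zero median in any species are
    dropped from the computation with a warning.  The reference factor is 1.
    """
    species = sorted(set(sample_species.values()))
    if reference not in species:
        raise ValueError(f"reference {reference!r} not among species {species}")
    cols_by_sp = {
        sp: [c for c in expr.columns if sample_species[c] == sp] for sp in species
    }
    sub = expr.loc[list(conserved)]
    if sub.empty:
        raise ValueError("conserved gene set is empty")
    med = {sp: sub[cols_by_sp[sp]].median(axis=1) for sp in species}
    factors = {reference: 1.0}
    for sp in species:
        if sp == reference:
            continue
        ok = (med[reference] > 0) & (med[sp] > 0)
        n_drop = int((~ok).sum())
        if n_drop:
            warnings.warn(
                f"{n_drop} conserved genes with zero median dropped for {sp}"
            )
        if not ok.any():
            raise ValueError(f"no usable conserved genes for species {sp!r}")
        if method == "median_of_ratios":
            factors[sp] = float((med[reference][ok] / med[sp][ok]).median())
        elif method == "pooled":
            factors[sp] = float(med[reference][ok].median() / med[sp][ok].median())
        else:
            raise ValueError(f"unknown method {method!r}")
    return factors


def apply_scaling(
    expr: pd.DataFrame,
    factors: Mapping[str, float],
    sample_species: Mapping[str, str],
) -> pd.DataFrame:
    """Multiply each species' columns by its factor (within-species ratios kept)."""
    out = expr.copy().astype(float)
    for col in out.columns:
        out[col] = out[col] * factors[sample_species[col]]
    return out


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Convenience counts -> TPM conversion (reads per kb, scaled to 1e6)."""
    rpk = counts.div(lengths.loc[counts.index] / 1e3, axis=0)
    return rpk.div(rpk.sum(axis=0), axis=1) * 1e6
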