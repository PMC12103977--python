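"""Genomic intervals, window tiling, and readers/writers for standard formats.

Coordinates are 0-based half-open internally.  GFF3 (1-based closed) is
converted on read.  Window classification against gene models is multi-label:
a window receives every region class (genic / upstream / downstream) it
overlaps by at least one base, and is intergenic only if it overlaps none.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RunConfig",
    "build_gene_model",
    "read_vcf",
    "read_gff",
    "read_newick",
    "read_matrix",
    "write_matrix",
    "write_results",
    "tile_windows",
    "classify_window",
    "classify_windows",
    "check_chrom_consistency",
]

REGION_CLASSES = ("genic", "upstream", "downstream")
FLANK_BP = 2000


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene body plus its 2-kb regulatory flanks.

    Flanks abut the body, are oriented with respect to strand (upstream is
    5' of the body), and are truncated at contig edges; a flank squeezed to
    zero length is None.
    """

    gene_id: str
    body: GenomicInterval
    upstream_flank: GenomicInterval | None
    downstream_flank: GenomicInterval | None

    def region(self, cls: str) -> GenomicInterval | None:
        if cls == "genic":
            return self.body
        if cls == "upstream":
            return self.upstream_flank
        if cls == "downstream":
            return self.downstream_flank
        raise KeyError(cls)


def build_gene_model(
    gene_id: str,
    body: GenomicInterval,
    contig_length: int | None = None,
    flank: int = FLANK_BP,
) -> GeneModel:
    """Attach strand-aware upstream/downstream flanks to a gene body."""
    right_end = contig_length if contig_length is not None else body.end + flank
    left = None
    if body.start > 0:
        left = GenomicInterval(
            body.chrom, max(0, body.start - flank), body.start, body.strand
        )
    right = None
    if body.end < right_end:
        right = GenomicInterval(
            body.chrom, body.end, min(right_end, body.end + flank), body.strand
        )
    if body.strand == "-":
        up, down = right, left
    else:
        up, down = left, right
    return GeneModel(gene_id, body, up, down)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    window_size: sweep-scan window in bp (non-overlapping tiling).
    outlier_fraction: top fraction of CLR scores called selected.
    n_permutations: resamples for every permutation null.
    n_mc_draws: Monte-Carlo draws per taxon for morphospace effect sizes.
    cv_threshold: coefficient-of-variation cutoff for conserved genes.
    kme_threshold / gs_threshold: hub-gene calling rule.
    module_r2_threshold / module_p_threshold: significant-module rule.
    rbh_evalue / rbh_identity_pct: reciprocal-best-hit filters.
    """

    window_size: int = 2000
    outlier_fraction: float = 0.01
    n_permutations: int = 1000
    n_mc_draws: int = 5000
    cv_threshold: float = 0.3
    kme_threshold: float = 0.8
    gs_threshold: float = 0.2
    module_r2_threshold: float = 0.3
    module_p_threshold: float = 0.05
    rbh_evalue: float = 1e-10
    rbh_identity_pct: float = 30.0
    min_module_size: int = 30
    cut_height: float = 0.99
    random_seed: int = 0

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for name in ("outlier_fraction", "cv_threshold", "kme_threshold",
                     "gs_threshold", "module_r2_threshold", "module_p_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_permutations < 1 or self.n_mc_draws < 1:
            raise ValueError("permutation/draw counts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# window tiling and classification


def tile_windows(
    contig_lengths: Mapping[str, int], window_size: int
) -> pd.DataFrame:
    """Tile every contig with non-overlapping half-open windows.

    The terminal window of a contig may be shorter than window_size.  Returns
    a DataFrame with columns window_id, chrom, start, end covering every base
    exactly once.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, length in contig_lengths.items():
        starts = np.arange(0, length, window_size)
        ends = np.minimum(starts + window_size, length)
        for s, e in zip(starts, ends):
            rows.append((f"{chrom}:{s}-{e}", chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["window_id", "chrom", "start", "end"])


def classify_window(
    window: GenomicInterval, genes: Sequence[GeneModel]
) -> dict[str, list[str]]:
    """Region classes a window overlaps, with contributing gene ids.

    Multi-label: the window may be simultaneously genic for one gene and
    upstream of another.  Returns {class: sorted gene ids}; an empty dict
    means intergenic.
    """
    out: dict[str, list[str]] = {}
    for gm in genes:
        for cls in REGION_CLASSES:
            region = gm.region(cls)
            if region is not None and window.overlaps(region):
                out.setdefault(cls, []).append(gm.gene_id)
    return {cls: sorted(ids) for cls, ids in sorted(out.items())}


def classify_windows(
    windows: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Vectorised classification of a window table against gene models.

    Adds boolean columns genic/upstream/downstream/intergenic and a
    `regulatory` convenience column (upstream or downstream).
    """
    win_chroms = set(windows["chrom"])
    gene_chroms = {g.body.chrom for g in genes}
    orphan = gene_chroms - win_chroms
    n = len(windows)
    flags = {cls: np.zeros(n, dtype=bool) for cls in REGION_CLASSES}
    gene_lists: dict[str, list[list[str]]] = {
        cls: [[] for _ in range(n)] for cls in REGION_CLASSES
    }
    by_chrom = {c: grp for c, grp in windows.groupby("chrom")}
    for gm in genes:
        grp = by_chrom.get(gm.body.chrom)
        if grp is None:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = grp.index.to_numpy()
        for cls in REGION_CLASSES:
            region = gm.region(cls)
            if region is None:
                continue
            hit = (starts < region.end) & (region.start < ends)
            for i in idx[hit]:
                flags[cls][i] = True
                gene_lists[cls][i].append(gm.gene_id)
    out = windows.copy()
    for cls in REGION_CLASSES:
        out[cls] = flags[cls]
        out[cls + "_genes"] = [",".join(sorted(g)) for g in gene_lists[cls]]
    out["regulatory"] = out["upstream"] | out["downstream"]
    out["intergenic"] = ~(out["genic"] | out["regulatory"])
    if orphan and not any(
        g.body.chrom in win_chroms for g in genes
    ):
        raise ValueError(
            "no gene contig matches any window contig; unmatched contigs: "
            + ", ".join(sorted(orphan))
        )
    return out


def check_chrom_consistency(
    chroms_a: Iterable[str], chroms_b: Iterable[str], what: str = "inputs"
) -> None:
    """Raise if two inputs share no contig names, listing the mismatches."""
    a, b = set(chroms_a), set(chroms_b)
    if a and b and not (a & b):
        raise ValueError(
            f"inconsistent contig naming between {what}: "
            f"{sorted(a)[:5]} vs {sorted(b)[:5]}"
        )


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str | Path, taxon: str | None = None) -> pd.DataFrame:
    """Read biallelic SNPs from a VCF into per-site minor-allele records.

    Returns a DataFrame with columns chrom, pos (0-based), minor_count,
    n_called, plus attrs {"n": max observed chromosome count, "taxon": taxon}.
    Minor-allele counts are computed over non-missing alleles only; sites that
    are monomorphic among called alleles, or entirely missing, are dropped.
    """
    from cyvcf2 import VCF

    path = str(path)
    rows = []
    try:
        vcf = VCF(path)
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue
            gts = np.asarray(
                [g[:2] for g in var.genotypes], dtype=float
            ).ravel()
            called = gts[gts >= 0]
            n_called = called.size
            if n_called == 0:
                continue
            alt = int(called.sum())
            minor = min(alt, n_called - alt)
            if minor == 0:
                continue
            rows.append((var.CHROM, var.POS - 1, minor, n_called))
    except Exception as exc:  # cyvcf2 raises on malformed input
        raise ValueError(f"failed to parse VCF {path}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "pos", "minor_count", "n_called"])
    if df.empty:
        warnings.warn(f"no biallelic polymorphic SNPs found in {path}")
        df.attrs["n"] = 0
    else:
        df.attrs["n"] = int(df["n_called"].max())
    df.attrs["taxon"] = taxon
    return df


_GFF_ID_RE = re.compile(r"ID=([^;]+)")


def read_gff(path: str | Path) -> tuple[list[GeneModel], dict[str, int]]:
    """Read gene features from GFF3 into GeneModels with 2-kb flanks.

    1-based closed GFF coordinates become 0-based half-open.  Contig lengths
    are taken from ##sequence-region pragmas where present (used to truncate
    flanks at contig edges).  Duplicate gene ids raise.
    """
    contig_lengths: dict[str, int] = {}
    raw: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF line in {path}: {line!r}")
            chrom, _, feat, start, end, _, strand, _, attrs = parts[:9]
            if feat != "gene":
                continue
            m = _GFF_ID_RE.search(attrs)
            gid = m.group(1) if m else f"{chrom}:{start}-{end}"
            raw.append((chrom, int(start) - 1, int(end), strand, gid))
    seen: set[str] = set()
    genes = []
    for chrom, start, end, strand, gid in raw:
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        body = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
        genes.append(
            build_gene_model(gid, body, contig_lengths.get(chrom))
        )
    return genes, contig_lengths


def read_bed(path: str | Path) -> list[GeneModel]:
    """Alternative gene input: BED (already 0-based half-open)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            gid = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            genes.append(
                build_gene_model(gid, GenomicInterval(chrom, start, end, strand))
            )
    return genes


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree; every edge must carry a branch length."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"branch without length above node "
                f"{edge.head_node.taxon or edge.head_node} in {path}"
            )
    return tree


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix with a header row and first-column row ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_results(
    obj, path: str | Path, config: RunConfig | None = None, seed: int | None = None
) -> None:
    """Write a result table (TSV) or mapping (JSON envelope with provenance)."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
        return
    envelope = {
        "config_hash": config.hash() if config is not None else None,
        "seed": seed,
        "result": obj,
    }
    with open(path, "w") as fh:
        json.dump(envelope, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")
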