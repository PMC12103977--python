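"""SFS-based selective-sweep scan with windowed diversity statistics.

Polymorphism is summarised per non-overlapping 2-kb window as a folded site
frequency spectrum (minor-allele counts; no outgroup polarisation).  Three
statistics are computed per window:

* CLR — a composite likelihood ratio contrasting a hitchhiking ("escape")
  model of the local SFS against the genome-wide background spectrum.  A
  sweep centred at the window midpoint lets each of the n sampled lineages
  escape via recombination with probability p_e = 1 - exp(-alpha * d) at
  distance d; the B ~ Binomial(n, p_e) escapees plus one ancestral lineage
  (onto which the n - B hitchhikers collapse) carry pre-sweep variation
  drawn from the background spectrum downsampled hypergeometrically to
  m = min(B + 1, n) lineages.  CLR = 2 ln(max_alpha CL(alpha) / CL(neutral)),
  composited over sites; alpha indexes sweep intensity.
* pi — nucleotide diversity, mean pairwise differences per site.
* Tajima's D — normalised difference of pi-based and Watterson estimators.

Windows with no segregating sites are flagged and excluded from ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .stats_util import wilcoxon_rank_sum

__all__ = [
    "WindowSFS",
    "folded_neutral_sfs",
    "windows_from_sites",
    "background_sfs",
    "CLRScanner",
    "default_alpha_grid",
    "pi_window",
    "tajimas_d",
    "tajima_constants",
    "top_outliers",
    "scan_windows",
    "background_compare",
]


@dataclass
class WindowSFS:
    """Folded SFS of one genomic window."""

    window_id: str
    chrom: str
    start: int
    end: int
    n: int                       # chromosomes sampled
    positions: np.ndarray        # site positions (0-based, within window)
    counts: np.ndarray           # minor-allele counts, 1..n//2

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size and (
            self.counts.min() < 1 or self.counts.max() > self.n // 2
        ):
            raise ValueError(
                f"minor counts outside 1..{self.n // 2} in {self.window_id}"
            )

    @property
    def S(self) -> int:
        return int(self.counts.size)

    @property
    def length(self) -> int:
        return self.end - self.start


def folded_neutral_sfs(n: int) -> np.ndarray:
    """Expected folded neutral spectrum, q_j ∝ (1/j + 1/(n-j)) / (1 + [j = n-j])."""
    j = np.arange(1, n // 2 + 1)
    w = (1.0 / j + 1.0 / (n - j)) / (1.0 + (j == n - j))
    return w / w.sum()


def windows_from_sites(
    sites: pd.DataFrame, windows: pd.DataFrame, n: int | None = None
) -> list[WindowSFS]:
    """Bin per-site minor-allele records into tiled windows.

    `sites` needs columns chrom, pos, minor_count (read_vcf output);
    `windows` is a tile_windows table.  n defaults to the sites table's
    recorded maximum chromosome count.
    """
    if n is None:
        n = sites.attrs.get("n") or int(sites["n_called"].max())
    out = []
    by_chrom = dict(tuple(sites.groupby("chrom"))) if len(sites) else {}
    for row in windows.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            pos = np.empty(0, int)
            cnt = np.empty(0, int)
        else:
            sel = (grp["pos"] >= row.start) & (grp["pos"] < row.end)
            pos = grp.loc[sel, "pos"].to_numpy()
            cnt = grp.loc[sel, "minor_count"].to_numpy()
            cnt = np.minimum(cnt, n - cnt)  # re-fold against the global n
            keep = cnt >= 1
            pos, cnt = pos[keep], cnt[keep]
        out.append(
            WindowSFS(row.window_id, row.chrom, row.start, row.end, n, pos, cnt)
        )
    return out


def background_sfs(
    windows: Sequence[WindowSFS], n: int | None = None, pseudocount: float = 0.5
) -> np.ndarray:
    """Genome-wide folded spectrum, pseudocount-smoothed and normalised."""
    if n is None:
        if not windows:
            raise ValueError("no windows")
        n = windows[0].n
    counts = np.zeros(n // 2, dtype=float)
    for w in windows:
        if w.S:
            counts += np.bincount(w.counts - 1, minlength=n // 2)[: n // 2]
    counts += pseudocount
    return counts / counts.sum()


def default_alpha_grid(
    alpha_min: float = 1e-5, alpha_max: float = 1e-1, per_decade: int = 12
) -> np.ndarray:
    """Log-spaced sweep-intensity grid in per-bp units (neutral limit added
    separately by the scanner)."""
    decades = np.log10(alpha_max / alpha_min)
    n = int(round(decades * per_decade)) + 1
    return np.logspace(np.log10(alpha_min), np.log10(alpha_max), n)


def _unfold(q: np.ndarray, n: int) -> np.ndarray:
    """Symmetric unfolded spectrum u_k (k = 1..n-1) consistent with folded q."""
    u = np.zeros(n - 1)
    for j in range(1, n // 2 + 1):
        if j == n - j:
            u[j - 1] = q[j - 1]
        else:
            u[j - 1] += q[j - 1] / 2.0
            u[n - j - 1] += q[j - 1] / 2.0
    return u


def escape_mixture_matrix(q: np.ndarray, n: int) -> np.ndarray:
    """P(folded class | B escapees) for B = 0..n under the escape model.

    Returns M of shape (n+1, n//2 + 1); column 0 collects the monomorphic
    outcomes, columns 1..n//2 the folded polymorphic classes.  Row B mixes
    over the background-derived pre-sweep configuration of the
    m = min(B+1, n) pre-sweep lineages (hypergeometric downsampling of an
    unfolded symmetric spectrum), with the n - B hitchhikers inheriting the
    ancestral lineage's allele.
    """
    u = _unfold(q, n)
    M = np.zeros((n + 1, n // 2 + 1))
    ks = np.arange(1, n)
    for B in range(n + 1):
        m = min(B + 1, n)
        for k, uk in zip(ks, u):
            # derived count h among the m pre-sweep lineages
            h = np.arange(max(0, m - (n - k)), min(m, k) + 1)
            ph = stats.hypergeom.pmf(h, n, k, m)
            if B >= n:
                obs = h  # no hitchhikers; sample = pre-sweep lineages
                for c, pc in zip(obs, ph):
                    jf = min(c, n - c)
                    M[B, jf] += uk * pc
            else:
                # ancestral lineage is one of the m, derived w.p. h/m
                p_anc = h / m
                c_anc = h - 1 + (n - B)   # ancestral derived
                c_esc = h                 # ancestral ancestral-state
                for ca, ce, pa, pc in zip(c_anc, c_esc, p_anc, ph):
                    M[B, min(ca, n - ca)] += uk * pc * pa
                    M[B, min(ce, n - ce)] += uk * pc * (1 - pa)
    return M


@dataclass
class CLRResult:
    window_id: str
    clr: float
    alpha_hat: float
    S: int
    scored: bool


class CLRScanner:
    """Composite-likelihood-ratio scanner for a fixed n and background SFS.

    Precomputes the escape mixture matrix once; `score` evaluates one
    window across the alpha grid (the effective-neutral point p_e = 1 is
    always included, so CLR >= 0 for every scored window).
    """

    def __init__(
        self,
        n: int,
        background: np.ndarray,
        alpha_grid: np.ndarray | None = None,
    ):
        if n < 4:
            raise ValueError("need n >= 4 chromosomes")
        self.n = n
        self.bg = np.asarray(background, dtype=float)
        if self.bg.size != n // 2 or np.any(self.bg <= 0):
            raise ValueError("background must have n//2 strictly positive classes")
        self.alphas = (
            default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid)
        )
        self.M = escape_mixture_matrix(self.bg, n)          # (n+1, n//2+1)
        self._log_binom = gammaln(n + 1) - gammaln(np.arange(n + 1) + 1) - gammaln(
            n - np.arange(n + 1) + 1
        )

    def _binom_pmf(self, p_e: np.ndarray) -> np.ndarray:
        """Binomial(n, p_e) pmf over B for an array of escape probabilities.

        Returns shape p_e.shape + (n+1,), exact at p_e in {0, 1}.
        """
        B = np.arange(self.n + 1)
        p = np.clip(p_e, 1e-300, 1.0)[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logpmf = (
                self._log_binom
                + B * np.log(p)
                + (self.n - B) * np.log1p(-np.clip(p, 0, 1 - 1e-16))
            )
        pmf = np.exp(logpmf)
        exact1 = np.isclose(p_e, 1.0)
        if np.any(exact1):
            pmf[exact1] = 0.0
            pmf[exact1, self.n] = 1.0
        return pmf

    def class_distribution(self, p_e: float) -> np.ndarray:
        """Folded polymorphic-class distribution at one escape probability."""
        pmf = self._binom_pmf(np.asarray([p_e]))[0]
        mix = pmf @ self.M
        poly = mix[1:]
        return poly / poly.sum()

    def score(self, w: WindowSFS) -> CLRResult:
        if w.S == 0:
            return CLRResult(w.window_id, np.nan, np.nan, 0, False)
        mid = 0.5 * (w.start + w.end)
        d = np.maximum(np.abs(w.positions - mid), 1.0)        # (S,)
        p_e = 1.0 - np.exp(-np.outer(d, self.alphas))         # (S, A)
        pmf = self._binom_pmf(p_e)                            # (S, A, n+1)
        mix = pmf @ self.M                                    # (S, A, n//2+1)
        poly = mix[..., 1:]
        poly = poly / poly.sum(axis=-1, keepdims=True)
        site_p = np.take_along_axis(
            poly, (w.counts - 1)[:, None, None], axis=-1
        )[..., 0]                                             # (S, A)
        loglik = np.log(np.clip(site_p, 1e-300, None)).sum(axis=0)  # (A,)
        log_neutral = np.log(self.bg[w.counts - 1]).sum()
        best = int(np.argmax(loglik))
        clr = 2.0 * max(0.0, float(loglik[best] - log_neutral))
        alpha_hat = float(self.alphas[best]) if loglik[best] > log_neutral else np.inf
        return CLRResult(w.window_id, clr, alpha_hat, w.S, True)


# ---------------------------------------------------------------------------
# diversity statistics


def pi_window(w: WindowSFS, length: int | None = None) -> float:
    """Nucleotide diversity per site: sum_sites 2 j (n - j) / (n (n-1)) / L."""
    L = length if length is not None else w.length
    if w.S == 0:
        return 0.0
    j = w.counts.astype(float)
    n = w.n
    return float((2.0 * j * (n - j) / (n * (n - 1))).sum() / L)


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for sample size n."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(w: WindowSFS) -> float:
    """Tajima's D of one window; NaN when S = 0 (undefined)."""
    if w.S == 0:
        return np.nan
    c = tajima_constants(w.n)
    S = w.S
    j = w.counts.astype(float)
    n = w.n
    pi_hat = float((2.0 * j * (n - j) / (n * (n - 1))).sum())  # pairwise-diff units
    denom = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return float((pi_hat - S / c["a1"]) / denom)


# ---------------------------------------------------------------------------
# orchestration


def scan_windows(
    windows: Sequence[WindowSFS],
    alpha_grid: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score every window: CLR, alpha_hat, pi, Tajima's D, S, flags.

    The background spectrum defaults to the genome-wide pooled folded SFS of
    the supplied windows.
    """
    if not windows:
        raise ValueError("no windows to scan")
    n = windows[0].n
    bg = background if background is not None else background_sfs(windows, n)
    scanner = CLRScanner(n, bg, alpha_grid)
    rows = []
    for w in windows:
        r = scanner.score(w)
        rows.append(
            (
                w.window_id, w.chrom, w.start, w.end, w.S,
                r.clr, r.alpha_hat, pi_window(w), tajimas_d(w),
                "ok" if r.scored else "no_sites",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["window_id", "chrom", "start", "end", "S", "clr",
                 "alpha_hat", "pi", "tajimas_d", "flag"],
    )


def top_outliers(scan: pd.DataFrame, fraction: float = 0.01) -> pd.DataFrame:
    """Windows in the top `fraction` of CLR scores among scored windows.

    The threshold is the score of the ceil(fraction * N)-th best window;
    ties at the threshold are all included, so the selected set has at
    least ceil(fraction * N) members.
    """
    scored = scan[scan["flag"] == "ok"]
    if scored.empty:
        raise ValueError("no scored windows")
    k = max(1, int(np.ceil(fraction * len(scored))))
    thresh = np.sort(scored["clr"].to_numpy())[::-1][k - 1]
    return scored[scored["clr"] >= thresh]


def background_compare(
    region_windows: pd.DataFrame,
    all_windows: pd.DataFrame,
    statistics: Sequence[str] = ("pi", "tajimas_d"),
) -> pd.DataFrame:
    """Wilcoxon rank-sum of window statistics in a region set vs the rest.

    `region_windows` rows must be a subset (by window_id) of `all_windows`;
    the comparison set is every other scored window.
    """
    region_ids = set(region_windows["window_id"])
    rest = all_windows[~all_windows["window_id"].isin(region_ids)]
    rows = []
    for stat in statistics:
        a = region_windows[stat].dropna().to_numpy()
        b = rest[stat].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            rows.append((stat, np.nan, np.nan, a.size, b.size))
            continue
        u, p = wilcoxon_rank_sum(a, b)
        rows.append((stat, u, p, a.size, b.size))
    return pd.DataFrame(
        rows, columns=["statistic", "W", "p", "n_region", "n_background"]
    )
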