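"""Windowed popgen statistics and the CLR sweep model, against oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altadapt.sweepscan import (
    CLRScanner,
    WindowSFS,
    background_compare,
    background_sfs,
    default_alpha_grid,
    escape_mixture_matrix,
    folded_neutral_sfs,
    pi_window,
    scan_windows,
    tajima_constants,
    tajimas_d,
    top_outliers,
    windows_from_sites,
)


def make_window(counts, n, L=2000, positions=None, wid="w0"):
    counts = np.asarray(counts, int)
    if positions is None:
        positions = np.linspace(10, L - 10, len(counts)).astype(int)
    return WindowSFS(wid, "c", 0, L, n, positions, counts)


# ---------------------------------------------------------------------------
# independent oracles


def pi_oracle_from_haplotypes(counts, n, L):
    """Average pairwise differences per site, counting all haplotype pairs."""
    total = 0
    for j in counts:
        hap = np.zeros(n, int)
        hap[:j] = 1
        diffs = sum(
            hap[a] != hap[b] for a in range(n) for b in range(a + 1, n)
        )
        total += diffs
    return total / math.comb(n, 2) / L


def tajimas_d_oracle(counts, n):
    """Independent re-derivation of Tajima's D from first principles."""
    S = len(counts)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    pi_hat = sum(2 * j * (n - j) for j in counts) / (n * (n - 1))
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def escape_class_prob_oracle(n, q, p_e):
    """Brute-force enumeration of the folded post-sweep class distribution."""
    # symmetric unfolded spectrum
    u = np.zeros(n + 1)
    for j in range(1, n // 2 + 1):
        if j == n - j:
            u[j] = q[j - 1]
        else:
            u[j] += q[j - 1] / 2
            u[n - j] += q[j - 1] / 2
    out = np.zeros(n // 2 + 1)
    for B in range(n + 1):
        pB = math.comb(n, B) * p_e**B * (1 - p_e) ** (n - B)
        m = min(B + 1, n)
        for k in range(1, n):
            if u[k] == 0:
                continue
            for h in range(max(0, m - (n - k)), min(m, k) + 1):
                ph = (
                    math.comb(k, h) * math.comb(n - k, m - h) / math.comb(n, m)
                )
                if B >= n:
                    out[min(h, n - h)] += pB * u[k] * ph
                else:
                    c_anc = h - 1 + (n - B)
                    out[min(c_anc, n - c_anc)] += pB * u[k] * ph * h / m
                    out[min(h, n - h)] += pB * u[k] * ph * (1 - h / m)
    return out


# ---------------------------------------------------------------------------


class TestPi:
    def test_monomorphic_window(self):
        assert pi_window(make_window([], 4)) == 0.0

    def test_worked_example(self):
        # n=4, minor counts {1,2}, L=100: pi*L = 1/2 + 2/3 = 7/6
        w = make_window([1, 2], 4, L=100)
        assert pi_window(w) * 100 == pytest.approx(7 / 6, rel=1e-12)
        assert pi_window(w) == pytest.approx(0.011667, abs=1e-6)

    def test_doubling_length_halves_pi(self):
        w1 = make_window([1, 2, 1], 6, L=100)
        w2 = make_window([1, 2, 1], 6, L=200)
        assert pi_window(w1) == pytest.approx(2 * pi_window(w2))

    def test_matches_haplotype_pair_oracle(self, rng):
        for _ in range(100):
            n = int(rng.choice([4, 6, 10, 22]))
            S = int(rng.integers(0, 30))
            counts = rng.integers(1, n // 2 + 1, size=S)
            L = int(rng.integers(500, 3000))
            w = make_window(counts, n, L=L,
                            positions=np.sort(rng.choice(L, S, replace=False)))
            assert pi_window(w) == pytest.approx(
                pi_oracle_from_haplotypes(counts, n, L), rel=1e-12
            )


class TestTajimasD:
    def test_worked_example(self):
        # n=4, S=2, classes {1,2}: a1=11/6, theta_W=12/11, pi_hat=7/6, D ~ +0.59
        w = make_window([1, 2], 4)
        c = tajima_constants(4)
        assert c["a1"] == pytest.approx(11 / 6)
        assert tajimas_d(w) == pytest.approx(0.59, abs=0.01)

    def test_excess_singletons_negative(self):
        w = make_window([1] * 30, 10)
        assert tajimas_d(w) < 0

    def test_intermediate_frequencies_positive(self):
        w = make_window([5] * 10, 10)
        assert tajimas_d(w) > 0

    def test_undefined_cases(self):
        assert np.isnan(tajimas_d(make_window([], 6)))
        with pytest.raises(ValueError):
            tajima_constants(3)

    def test_matches_independent_oracle(self, rng):
        for _ in range(100):
            n = int(rng.choice([4, 6, 10, 22]))
            S = int(rng.integers(1, 40))
            counts = rng.integers(1, n // 2 + 1, size=S)
            w = make_window(counts, n)
            assert tajimas_d(w) == pytest.approx(
                tajimas_d_oracle(counts, n), abs=1e-9
            )


class TestBackgroundSfs:
    def test_all_singletons_concentrates_on_class_one(self):
        wins = [make_window([1] * 50, 8, wid=f"w{i}") for i in range(4)]
        q = background_sfs(wins)
        assert q[0] > 0.98
        assert (q > 0).all()

    def test_neutral_simulation_matches_generating_law(self, rng):
        n = 22
        q_true = folded_neutral_sfs(n)
        counts = rng.choice(np.arange(1, n // 2 + 1), size=10_000, p=q_true)
        wins = [make_window(counts, n, wid="big")]
        q_est = background_sfs(wins, pseudocount=0.5)
        obs = np.bincount(counts - 1, minlength=n // 2)
        chi2, p = stats.chisquare(obs, q_true * len(counts))
        assert p > 0.01
        assert np.abs(q_est - q_true).max() < 0.02

    def test_deterministic(self):
        wins = [make_window([1, 2, 3], 8)]
        assert np.array_equal(background_sfs(wins), background_sfs(wins))


class TestEscapeModel:
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_class_distribution_sums_to_one_exactly(self, n, rng):
        q = rng.dirichlet(np.ones(n // 2))
        q = np.clip(q, 1e-3, None)
        q /= q.sum()
        M = escape_mixture_matrix(q, n)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8])
    @pytest.mark.parametrize("p_e", [1e-4, 0.05, 0.3, 0.7, 1.0])
    def test_matches_brute_force_enumeration(self, n, p_e, rng):
        q = rng.dirichlet(np.ones(n // 2))
        q = np.clip(q, 1e-3, None)
        q /= q.sum()
        oracle = escape_class_prob_oracle(n, q, p_e)
        poly = oracle[1:] / oracle[1:].sum()
        ours = CLRScanner(n, q).class_distribution(p_e)
        assert np.allclose(ours, poly, atol=1e-10)

    def test_neutral_limit_recovers_background(self):
        n = 10
        q = folded_neutral_sfs(n)
        ours = CLRScanner(n, q).class_distribution(1.0)
        assert np.allclose(ours, q, atol=1e-12)


class TestClr:
    def test_nonnegative_everywhere(self, rng):
        n = 22
        q = folded_neutral_sfs(n)
        scanner = CLRScanner(n, q)
        for _ in range(50):
            S = int(rng.integers(1, 40))
            counts = rng.integers(1, n // 2 + 1, size=S)
            w = make_window(counts, n,
                            positions=np.sort(rng.choice(2000, S, replace=False)))
            assert scanner.score(w).clr >= 0

    def test_window_matching_background_scores_near_zero(self):
        # empirical folded SFS equal to bg: 7 singletons + 3 doubletons vs
        # bg (0.7, 0.3)
        n = 4
        q = np.array([0.7, 0.3])
        scanner = CLRScanner(n, q)
        # classes interleaved in position so neither class clusters at the
        # window center
        w = make_window([1, 2, 1, 1, 2, 1, 1, 2, 1, 1], n)
        assert scanner.score(w).clr < 0.5

    def test_single_singleton_near_center_scores_positive(self):
        # spec-style worked case: one site, n=4, bg (0.7, 0.3), j=1 at small d
        n = 4
        q = np.array([0.7, 0.3])
        scanner = CLRScanner(n, q)
        w = WindowSFS("w", "c", 0, 2000, n, np.array([995]), np.array([1]))
        res = scanner.score(w)
        assert res.clr > 0
        # brute-force check: some alpha has class-1 probability above bg
        d = 5.0
        best = max(
            escape_class_prob_oracle(n, q, 1 - math.exp(-a * d))[1]
            / (escape_class_prob_oracle(n, q, 1 - math.exp(-a * d))[1:].sum())
            for a in default_alpha_grid()
        )
        assert best > q[0]
        assert res.clr == pytest.approx(2 * math.log(best / q[0]), rel=1e-6)

    def test_no_sites_flagged_not_scored(self):
        n = 8
        scanner = CLRScanner(n, folded_neutral_sfs(n))
        res = scanner.score(make_window([], n))
        assert not res.scored

    def test_neutral_genome_median_below_one(self, rng):
        n = 22
        q = folded_neutral_sfs(n)
        scanner = CLRScanner(n, q)
        clrs = []
        for _ in range(300):
            S = rng.poisson(22)
            if S == 0:
                continue
            counts = rng.choice(np.arange(1, n // 2 + 1), size=S, p=q)
            w = make_window(counts, n,
                            positions=np.sort(rng.choice(2000, S, replace=False)))
            clrs.append(scanner.score(w).clr)
        assert np.median(clrs) < 1.0


class TestTopOutliers:
    def _scan_frame(self, scores):
        return pd.DataFrame(
            {
                "window_id": [f"w{i}" for i in range(len(scores))],
                "clr": scores,
                "flag": ["ok"] * len(scores),
            }
        )

    def test_exact_count_with_distinct_scores(self, rng):
        scores = rng.permutation(np.arange(1000, dtype=float))
        sel = top_outliers(self._scan_frame(scores), 0.01)
        assert len(sel) == 10
        assert sel["clr"].min() >= np.sort(scores)[-10]

    def test_ties_at_threshold_all_included(self):
        scores = np.zeros(1000)
        scores[:12] = 99.0
        sel = top_outliers(self._scan_frame(scores), 0.01)
        assert len(sel) == 12

    def test_unscored_windows_excluded(self):
        df = self._scan_frame(np.arange(100, dtype=float))
        df.loc[99, "flag"] = "no_sites"
        sel = top_outliers(df, 0.01)
        assert "w99" not in set(sel["window_id"])


class TestBackgroundCompare:
    def test_identical_value_sets_give_p_one(self):
        df = pd.DataFrame(
            {
                "window_id": [f"w{i}" for i in range(40)],
                "pi": np.tile([1.0, 2.0], 20),
                "tajimas_d": np.tile([0.5, -0.5], 20),
            }
        )
        region = df.iloc[:20]   # same {1, 2} value multiset as the rest
        res = background_compare(region, df).set_index("statistic")
        assert res.loc["pi", "p"] > 0.9

    def test_shifted_region_detected(self, rng):
        pi_bg = rng.lognormal(0, 0.3, 500)
        pi_rg = rng.lognormal(-1.0, 0.3, 40)
        df = pd.DataFrame(
            {
                "window_id": [f"w{i}" for i in range(540)],
                "pi": np.concatenate([pi_rg, pi_bg]),
                "tajimas_d": rng.normal(0, 1, 540),
            }
        )
        res = background_compare(df.iloc[:40], df).set_index("statistic")
        assert res.loc["pi", "p"] < 0.01
        assert res.loc["tajimas_d", "p"] > 0.001

    def test_random_subset_calibrated(self, rng):
        ps = []
        for _ in range(100):
            vals = rng.normal(0, 1, 200)
            df = pd.DataFrame(
                {
                    "window_id": [f"w{i}" for i in range(200)],
                    "pi": vals,
                    "tajimas_d": vals,
                }
            )
            pick = rng.choice(200, 30, replace=False)
            res = background_compare(df.iloc[pick], df)
            ps.append(res.set_index("statistic").loc["pi", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestScanIntegration:
    def test_scan_windows_from_sites(self, rng):
        from altadapt.core_io import tile_windows
        from altadapt.synthetic_data import simulate_polymorphism

        contigs = {"c1": 100_000}
        wins = tile_windows(contigs, 2000)
        sites, _ = simulate_polymorphism(contigs, wins, rng=rng)
        wsfs = windows_from_sites(sites, wins)
        scan = scan_windows(wsfs)
        assert len(scan) == 50
        ok = scan[scan["flag"] == "ok"]
        assert (ok["clr"] >= 0).all()
        assert (ok["pi"] >= 0).all()
        assert ok["S"].mean() > 10
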