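"""Sum-of-z-scores signature scoring, median split, Spearman and Welch tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pbscreen.signature_scores import (
    compare_groups,
    correlate,
    median_split,
    signature_score,
)
from pbscreen.sim_screen import ExprSimConfig, loading_for_spearman, simulate_expression


def matrix_from(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return df


def brute_force_spearman(x, y):
    """Mid-rank rho from first principles (oracle)."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSignatureScore:
    def test_hand_computed_z_scores(self):
        """Gene (1,2,3): population sd sqrt(2/3), z = (-1.2247, 0, 1.2247)."""
        m = matrix_from({"g": [1.0, 2.0, 3.0]})
        scores, cov = signature_score(m, ["g"])
        expected = (np.array([1, 2, 3]) - 2.0) / math.sqrt(2.0 / 3.0)
        assert np.allclose(scores.to_numpy(), expected, atol=1e-12)
        assert scores.iloc[1] == 0.0  # the sample at the gene mean
        assert cov.used == ("g",)

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(41)
        m = pd.DataFrame(rng.normal(size=(30, 25)),
                         index=[f"g{i}" for i in range(30)],
                         columns=[f"S{i}" for i in range(25)])
        scores, _ = signature_score(m, [f"g{i}" for i in range(0, 30, 3)])
        assert abs(scores.sum()) < 1e-9

    def test_invariance_to_gene_order_and_extra_genes(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.normal(size=(10, 8)),
                         index=[f"g{i}" for i in range(10)],
                         columns=[f"S{i}" for i in range(8)])
        sig = ["g1", "g4", "g7"]
        s1, _ = signature_score(m, sig)
        s2, _ = signature_score(m, list(reversed(sig)))
        s3, _ = signature_score(m.iloc[::-1], sig)
        assert np.allclose(s1, s2) and np.allclose(s1, s3)

    def test_location_shift_of_one_gene_leaves_scores_unchanged(self):
        rng = np.random.default_rng(43)
        m = pd.DataFrame(rng.normal(size=(5, 12)),
                         index=list("abcde"), columns=[f"S{i}" for i in range(12)])
        base, _ = signature_score(m, ["a", "b"])
        m2 = m.copy()
        m2.loc["a"] += 100.0
        shifted, _ = signature_score(m2, ["a", "b"])
        assert np.allclose(base, shifted, atol=1e-9)

    def test_coverage_reports_missing_and_constant_genes(self):
        m = matrix_from({"g": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        scores, cov = signature_score(m, ["g", "flat", "absent"])
        assert cov.missing == ("absent",) and cov.zero_variance == ("flat",)

    def test_errors(self):
        m = matrix_from({"g": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no signature genes"):
            signature_score(m, ["other"])
        single = pd.DataFrame({"S0": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            signature_score(single, ["g"])


class TestMedianSplit:
    def test_even_split(self):
        m = matrix_from({"g": [1.0, 2.0, 3.0, 4.0]})
        high, low = median_split(m, "g")
        assert set(high) == {"S2", "S3"} and set(low) == {"S0", "S1"}

    def test_tie_at_median_goes_low(self):
        m = matrix_from({"g": [1.0, 2.0, 3.0]})
        high, low = median_split(m, "g")
        assert set(high) == {"S2"} and set(low) == {"S0", "S1"}

    def test_constant_gene_all_low(self, caplog):
        m = matrix_from({"g": [2.0, 2.0, 2.0]})
        with caplog.at_level("WARNING"):
            high, low = median_split(m, "g")
        assert high == [] and len(low) == 3 and caplog.records

    def test_absent_gene_errors(self):
        with pytest.raises(KeyError):
            median_split(matrix_from({"g": [1.0, 2.0]}), "missing")


class TestCorrelate:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert correlate(x, [2.0, 4.0, 6.0, 8.0, 10.0]).rho == pytest.approx(1.0)
        assert correlate(x, [10.0, 8.0, 6.0, 4.0, 2.0]).rho == pytest.approx(-1.0)

    def test_mid_rank_ties_against_brute_force_and_scipy(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [10.0, 20.0, 30.0, 40.0]
        res = correlate(x, y)
        assert res.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_p_matches_full_enumeration(self):
        """n <= 10 p-value equals the two-sided pairing-permutation fraction."""
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5]
        res = correlate(x, y)
        assert res.method == "exact"
        rhos = [
            brute_force_spearman(x, list(perm))
            for perm in itertools.permutations(y)
        ]
        expected = sum(abs(r) >= abs(res.rho) - 1e-12 for r in rhos) / len(rhos)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(44)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = correlate(x, y)
        assert res.method == "t-approx"
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def scores(self, values):
        return pd.Series(values, index=[f"S{i}" for i in range(len(values))])

    def test_identical_groups_null_result(self):
        s = self.scores([1.0, 2.0, 1.0, 2.0])
        res = compare_groups(s, ["S0", "S1"], ["S2", "S3"])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_constants_flagged_degenerate(self):
        s = self.scores([2.0, 2.0, 2.0, 5.0, 5.0, 5.0])
        res = compare_groups(s, ["S3", "S4", "S5"], ["S0", "S1", "S2"])
        assert res.degenerate and res.p_value == 0.0 and res.t_statistic == math.inf

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(45)
        vals = rng.normal(size=20)
        s = self.scores(list(vals))
        high, low = [f"S{i}" for i in range(10)], [f"S{i}" for i in range(10, 20)]
        res = compare_groups(s, high, low)
        t, p = stats.ttest_ind(vals[:10], vals[10:], equal_var=False)
        assert res.t_statistic == pytest.approx(t) and res.p_value == pytest.approx(p)

    def test_small_group_errors(self):
        s = self.scores([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            compare_groups(s, ["S0"], ["S1", "S2"])


class TestSyntheticCohort:
    def test_directional_split_recovers_planted_factor(self):
        """High-target samples score higher when the factor loading is positive."""
        wins = 0
        for seed in range(100):
            cfg = ExprSimConfig(n_genes=60, n_samples=40, signature_size=10,
                                latent_loading=1.0, noise_sd=1.0, seed=seed)
            matrix, truth = simulate_expression(cfg)
            scores, _ = signature_score(matrix, list(truth.signature_genes))
            high, low = median_split(matrix, cfg.target_gene_label)
            if scores.loc[high].mean() > scores.loc[low].mean():
                wins += 1
        assert wins >= 95

    def test_zero_loading_means_zero_population_rho(self):
        _, truth = simulate_expression(ExprSimConfig(latent_loading=0.0, seed=1))
        assert truth.population_spearman == 0.0

    def test_noise_free_coupling_is_perfectly_monotone(self):
        cfg = ExprSimConfig(n_genes=30, n_samples=50, signature_size=5,
                            latent_loading=2.0, noise_sd=0.0, seed=2)
        matrix, truth = simulate_expression(cfg)
        scores, _ = signature_score(matrix, list(truth.signature_genes))
        res = correlate(matrix.loc[cfg.target_gene_label].to_numpy(), scores.to_numpy())
        assert res.rho == pytest.approx(1.0)

    def test_loading_inversion_round_trips(self):
        from pbscreen.sim_screen import population_spearman

        a = loading_for_spearman(0.6, signature_size=20, noise_sd=1.0)
        assert population_spearman(a, 1.0, 20) == pytest.approx(0.6, abs=1e-10)
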