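import math

import numpy as np
import pytest
from scipy import stats

from refmirna import (
    ContractError,
    SimSpec,
    normfinder,
    normfinder_decompose,
    normfinder_singlegroup,
    normfinder_stability,
    simulate_ct,
)
from conftest import make_table, random_table


def brute_decompose(table):
    """Independent oracle: the decomposition written as explicit loops.

    Steps: grand-mean centering per candidate, per-sample across-candidate
    centering, group deviation means, centered variances, the k/(k-2)
    method-of-moments correction, the deviation-variance estimate and the
    shrinkage factor.
    """
    k, n = table.n_candidates, table.n_samples
    groups = table.groups
    # (1) center candidates
    z = [[table.ct[i, j] - sum(table.ct[i]) / n for j in range(n)] for i in range(k)]
    # (2) center samples across candidates
    x = [
        [z[i][j] - sum(z[ii][j] for ii in range(k)) / k for j in range(n)]
        for i in range(k)
    ]
    d_hat, s2, sigma2, n_g = {}, {}, {}, {}
    for g in groups:
        cols = [j for j, s in enumerate(table.samples) if table.group_of[s] == g]
        n_g[g] = len(cols)
        for i in range(k):
            vals = [x[i][j] for j in cols]
            mean = sum(vals) / len(vals)
            d_hat[(i, g)] = mean                                    # (3)
            s2[(i, g)] = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)  # (4)
        total = sum(s2[(i, g)] for i in range(k))
        for i in range(k):                                          # (5)
            sigma2[(i, g)] = max(0.0, (k / (k - 2)) * (s2[(i, g)] - total / (k * (k - 1))))
    d_values = [d_hat[(i, g)] for i in range(k) for g in groups]
    mean_d = sum(d_values) / len(d_values)
    var_d = sum((v - mean_d) ** 2 for v in d_values) / (len(d_values) - 1)
    mean_ratio = sum(sigma2[(i, g)] / n_g[g] for i in range(k) for g in groups) / (
        k * len(groups)
    )
    gamma2 = max(0.0, var_d - mean_ratio)                           # (6)
    d_tilde = {
        key: d_hat[key] * gamma2 / (gamma2 + sigma2[key] / n_g[key[1]])
        if gamma2 + sigma2[key] / n_g[key[1]] > 0
        else 0.0
        for key in d_hat
    }                                                               # (7)
    rho = {}
    for i in range(k):
        rho[i] = sum(
            abs(d_tilde[(i, g)]) + math.sqrt(sigma2[(i, g)] / n_g[g]) for g in groups
        ) / len(groups)
    return d_hat, s2, sigma2, d_tilde, gamma2, rho


class TestDecomposition:
    def test_zero_noise_table_is_fully_degenerate(self):
        ct = np.tile(np.array([[20.0], [24.0], [28.0]]), (1, 6))
        table = make_table(ct)
        decomp = normfinder_decompose(table)
        assert np.allclose(decomp.sigma2, 0.0)
        assert np.allclose(decomp.d_hat, 0.0)
        assert np.allclose(normfinder_stability(decomp).values, 0.0)

    def test_matches_step_by_step_oracle(self, rng):
        table = random_table(rng, k=5, n=8)
        decomp = normfinder_decompose(table)
        d_hat, s2, sigma2, d_tilde, gamma2, rho = brute_decompose(table)
        for gi, g in enumerate(decomp.groups):
            for i in range(table.n_candidates):
                assert decomp.d_hat[i, gi] == pytest.approx(d_hat[(i, g)], abs=1e-9)
                assert decomp.s2[i, gi] == pytest.approx(s2[(i, g)], abs=1e-9)
                assert decomp.sigma2[i, gi] == pytest.approx(sigma2[(i, g)], abs=1e-9)
                assert decomp.d_tilde[i, gi] == pytest.approx(d_tilde[(i, g)], abs=1e-9)
        assert decomp.gamma2_d == pytest.approx(gamma2, abs=1e-9)
        stability = normfinder_stability(decomp)
        for i, cand in enumerate(table.candidates):
            assert stability[cand] == pytest.approx(rho[i], abs=1e-9)

    def test_hand_toy_3x6(self):
        table = make_table(
            [
                [20.0, 20.4, 20.2, 21.0, 21.2, 20.8],
                [24.1, 24.0, 24.5, 24.2, 24.0, 24.4],
                [28.3, 27.9, 28.0, 29.0, 28.6, 29.2],
            ]
        )
        decomp = normfinder_decompose(table)
        d_hat, s2, sigma2, d_tilde, gamma2, rho = brute_decompose(table)
        for gi, g in enumerate(decomp.groups):
            for i in range(3):
                assert decomp.d_hat[i, gi] == pytest.approx(d_hat[(i, g)], abs=1e-12)
        stability = normfinder_stability(decomp)
        for i, cand in enumerate(table.candidates):
            assert stability[cand] == pytest.approx(rho[i], abs=1e-12)

    def test_invariants(self, rng):
        for _ in range(10):
            table = random_table(rng, k=6, n=10)
            decomp = normfinder_decompose(table)
            assert (decomp.sigma2 >= 0).all()
            assert (decomp.s2 >= 0).all()
            assert decomp.gamma2_d >= 0
            # deviations sum to zero within each group by construction
            assert np.allclose(decomp.d_hat.sum(axis=0), 0.0, atol=1e-9)
            # shrinkage never inflates
            assert (np.abs(decomp.d_tilde) <= np.abs(decomp.d_hat) + 1e-12).all()

    def test_loading_shift_cancels_exactly(self, rng):
        table = random_table(rng)
        shifted = table.shifted(per_sample=rng.normal(0, 2, table.n_samples))
        a = normfinder_decompose(table)
        b = normfinder_decompose(shifted)
        np.testing.assert_allclose(a.d_hat, b.d_hat, atol=1e-10)
        np.testing.assert_allclose(a.sigma2, b.sigma2, atol=1e-10)
        np.testing.assert_allclose(
            normfinder_stability(a).values, normfinder_stability(b).values, atol=1e-10
        )

    def test_contract_errors(self, rng):
        two_cand = random_table(rng, k=2, n=6)
        with pytest.raises(ContractError):
            normfinder_decompose(two_cand)
        single_group = make_table(
            rng.uniform(18, 30, (4, 6)), groups=("G1", "G1")
        )
        with pytest.raises(ContractError, match="single.?group"):
            normfinder_decompose(single_group)


class TestStabilityBehaviour:
    def test_shifted_candidate_has_largest_deviation(self):
        """A 2-cycle group shift dominates |d_hat| in >= 99/100 seeded runs."""
        hits = 0
        for seed in range(100):
            spec = SimSpec(
                sigma=(0.3,) * 7, delta=(0, 0, 0, 0, 0, 0, 2.0), seed=seed
            )
            table, _ = simulate_ct(spec)
            decomp = normfinder_decompose(table)
            worst = int(np.argmax(np.abs(decomp.d_hat).max(axis=1)))
            hits += worst == 6
        assert hits >= 99

    def test_symmetric_candidates_get_equal_rho(self):
        ct = np.array(
            [
                [20.0, 21.0, 20.0, 21.0, 20.0, 21.0],
                [30.0, 31.0, 30.0, 31.0, 30.0, 31.0],
                [25.0, 25.5, 26.0, 25.0, 25.5, 26.0],
            ]
        )
        table = make_table(ct)
        rho = normfinder(table)
        assert rho["A"] == pytest.approx(rho["B"], abs=1e-12)

    def test_parameter_recovery_rank_correlation(self):
        """The expected stability ranking recovers the true disorder order:
        Spearman(true disorder, mean rho over 200 seeded runs) >= 0.9."""
        sigma = (0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3)
        n_rep = 200
        rho_sum = np.zeros(len(sigma))
        for seed in range(n_rep):
            spec = SimSpec(sigma=sigma, delta=(0,) * 7, seed=seed)
            table, truth = simulate_ct(spec)
            rho_sum += normfinder(table).loc[spec.candidates].values
        corr = stats.spearmanr(truth["disorder"], rho_sum / n_rep).statistic
        assert corr >= 0.9


class TestSingleGroup:
    def test_zero_noise(self):
        ct = np.tile(np.array([[20.0], [24.0], [28.0]]), (1, 6))
        table = make_table(ct, groups=("G1", "G1"))
        rho = normfinder_singlegroup(table)
        assert np.allclose(rho.values, 0.0)

    def test_noisy_candidate_ranked_last(self):
        """sigma = 1.5 vs 0.3 background: last place in >= 99/100 runs."""
        hits = 0
        for seed in range(100):
            spec = SimSpec(
                k=5, sigma=(0.3, 0.3, 0.3, 0.3, 1.5), delta=(0,) * 5, seed=seed
            )
            table, _ = simulate_ct(spec)
            rho = normfinder_singlegroup(table)
            hits += rho.idxmax() == "cand05"
        assert hits >= 99

    def test_matches_pooled_oracle(self, rng):
        table = random_table(rng, k=4, n=6)
        merged = make_table(table.ct, groups=("G1", "G1"))
        rho = normfinder_singlegroup(merged)
        # oracle: same formulas with a single group containing every sample
        _, _, sigma2, _, _, _ = brute_decompose(merged)
        for i, cand in enumerate(merged.candidates):
            assert rho[cand] == pytest.approx(math.sqrt(sigma2[(i, "G1")]), abs=1e-9)
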