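import numpy as np
import pytest

from ebcov import (
    BlockStructure,
    SampleSummary,
    build_prior,
    estimate,
    estimate_lambda,
    make_truth,
    draw,
    frobenius_distance,
    pearson,
    apply_block_mask,
    posterior_mean,
)
from ebcov.estimator import LAMBDA_MAX, LAMBDA_MIN

from conftest import random_correlation


def cov2cor(M):
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


class TestEstimateLambda:
    def test_zero_discrepancy_returns_lambda_max(self, rng):
        R = random_correlation(rng, 5)
        assert estimate_lambda(R, R.copy()) == LAMBDA_MAX

    @pytest.mark.parametrize("r", [0.2, 0.5, -0.4])
    def test_identity_prior_constant_discrepancy_closed_form(self, r):
        # d_bar = r^2, v_bar = 1  ->  lambda = 1/r^2 - 3
        p = 6
        R = np.full((p, p), r)
        np.fill_diagonal(R, 1.0)
        lam = estimate_lambda(R, np.eye(p))
        assert lam == pytest.approx(
            np.clip(1.0 / r**2 - 3.0, LAMBDA_MIN, LAMBDA_MAX)
        )

    def test_matches_explicit_double_loop_over_pairs(self):
        scenario = make_truth(p=10, block_sizes=(5, 5), rho_within=0.7, seed=1)
        for seed in range(100):
            X = draw(scenario, 15, seed=seed).X
            summary = SampleSummary.from_data(X)
            z = build_prior(summary.R_sample, scenario.structure).z
            lam = estimate_lambda(summary.R_sample, z)
            num = den = cnt = 0.0
            for i in range(10):  # brute-force pairwise oracle
                for j in range(i + 1, 10):
                    num += (1 - z[i, j] ** 2) ** 2
                    den += (summary.R_sample[i, j] - z[i, j]) ** 2
                    cnt += 1
            expected = np.clip((num / cnt) / (den / cnt) - 3.0, LAMBDA_MIN, LAMBDA_MAX)
            assert lam == pytest.approx(expected, rel=1e-12)

    def test_needs_at_least_two_variables(self):
        with pytest.raises(ValueError, match="p >= 2"):
            estimate_lambda(np.eye(1), np.eye(1))


class TestPosteriorMean:
    def test_equal_weight_blend_halves_correlation(self, rng):
        p, n = 4, 12
        X = rng.standard_normal((n, p))
        summary = SampleSummary.from_data(X)
        structure = BlockStructure.from_blocks(p, [[i] for i in range(p)])
        prior = build_prior(summary.R_sample, structure)  # identity prior
        est = posterior_mean(summary, prior, lambda_=float(n))
        assert np.allclose(est.R_eb, (summary.R_sample + np.eye(p)) / 2.0)

    def test_matches_direct_formula_oracle(self, rng):
        X = rng.standard_normal((20, 8))
        summary = SampleSummary.from_data(X)
        structure = BlockStructure.from_blocks(8, [[0, 1, 2, 3], [4, 5, 6, 7]])
        prior = build_prior(summary.R_sample, structure)
        lam = 7.3
        est = posterior_mean(summary, prior, lam)
        oracle = cov2cor((lam * prior.z + summary.S) / (lam + summary.n))
        assert np.allclose(est.R_eb, oracle, atol=1e-12)

    def test_limits_recover_prior_and_sample(self, rng):
        X = rng.standard_normal((10, 5))
        summary = SampleSummary.from_data(X)
        structure = BlockStructure.from_blocks(5, [[0, 1, 2], [3, 4]])
        prior = build_prior(summary.R_sample, structure)
        near_prior = posterior_mean(summary, prior, 1e9).R_eb
        assert np.allclose(near_prior, prior.z, atol=1e-6)
        near_sample = posterior_mean(summary, prior, 1e-9).R_eb
        assert np.allclose(near_sample, summary.R_sample, atol=1e-6)

    def test_rejects_nonpositive_lambda_and_bad_shapes(self, rng):
        X = rng.standard_normal((10, 4))
        summary = SampleSummary.from_data(X)
        structure = BlockStructure.from_blocks(3, [[0, 1, 2]])
        prior = build_prior(np.eye(3), structure)
        with pytest.raises(ValueError, match="lambda"):
            posterior_mean(summary, prior, 0.0)
        with pytest.raises(ValueError, match="dimensions"):
            posterior_mean(summary, prior, 1.0)


class TestEstimatePipeline:
    def test_shrinks_within_blocks_toward_gamma_and_between_toward_zero(
        self, default_scenario
    ):
        X = draw(default_scenario, 15, seed=2).X
        est = estimate(X, "groups", structure=default_scenario.structure)
        R = SampleSummary.from_data(X).R_sample
        z = est.prior.z
        within = default_scenario.structure.same_block_mask(include_diagonal=False)
        off = ~np.eye(50, dtype=bool)
        assert np.all(
            np.abs(est.R_eb[within] - z[within]) <= np.abs(R[within] - z[within]) + 1e-9
        )
        between = off & ~within
        assert np.all(np.abs(est.R_eb[between]) <= np.abs(R[between]) + 1e-9)

    def test_known_groups_beat_pearson_within_blocks_on_average(self):
        scenario = make_truth(seed=0)
        diffs = []
        for seed in range(100):
            X = draw(scenario, 10, seed=seed).X
            eb = estimate(X, "groups", structure=scenario.structure).R_eb
            pe = apply_block_mask(pearson(X).R_hat, scenario.structure).R_hat
            args = (scenario.Sigma_true, "blocks", scenario.structure)
            diffs.append(
                frobenius_distance(pe, *args) - frobenius_distance(eb, *args)
            )
        assert np.mean(diffs) > 0  # EB closer to truth within blocks

    def test_extreme_threshold_gives_singleton_prior(self, rng):
        X = rng.standard_normal((12, 6))  # weak, unstructured data
        est = estimate(X, "threshold", threshold=0.99)
        assert np.array_equal(est.prior.z, np.eye(6))
        R = SampleSummary.from_data(X).R_sample
        w = est.prior_weight
        assert np.allclose(est.R_eb, cov2cor(w * np.eye(6) + (1 - w) * R), atol=1e-10)

    def test_permutation_equivariance(self, rng):
        scenario = make_truth(p=12, block_sizes=(4, 4, 4), seed=9)
        X = draw(scenario, 15, seed=10).X
        perm = list(rng.permutation(12))
        P = np.eye(12)[perm]
        for mode, kwargs in [
            ("groups", {"structure": scenario.structure}),
            ("threshold", {"threshold": 0.5}),
            ("aic", {}),
        ]:
            k = dict(kwargs)
            if mode == "groups":
                k["structure"] = scenario.structure.permute(perm)
            ref = estimate(X, mode, **kwargs).R_eb
            permuted = estimate(X @ P, mode, **k).R_eb
            assert np.allclose(P @ permuted @ P.T, ref, atol=1e-10)

    def test_input_validation(self, rng):
        X = rng.standard_normal((10, 4))
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match=r"\b2\b"):
            estimate(X, "threshold", threshold=0.5)
        with pytest.raises(ValueError, match="samples"):
            estimate(rng.standard_normal((2, 4)), "threshold", threshold=0.5)
        with pytest.raises(ValueError, match="threshold"):
            estimate(rng.standard_normal((10, 4)), "threshold")

    def test_positive_definite_and_bounded_output(self, default_scenario):
        X = draw(default_scenario, 10, seed=4).X
        est = estimate(X, "groups", structure=default_scenario.structure)
        assert np.linalg.eigvalsh(est.R_eb)[0] > 0
        assert np.all(np.abs(est.R_eb) <= 1.0 + 1e-12)
        assert np.allclose(np.diag(est.R_eb), 1.0)
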