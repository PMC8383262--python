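import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funfanova import (
    PairedFunctionalSample,
    RepeatedMeasuresFANOVA,
    make_bspline_basis,
    paired_summary,
    permutation_test,
    statistic_cn,
    statistic_dn,
    statistic_en,
)
from funfanova.repeated import DegenerateKernelError

from .conftest import random_paired_sample
from .oracles import (
    cn_trapezoid,
    dn_en_pointwise,
    naive_permutation_distribution,
    pointwise_kernel,
)


def constant_curve_sample(basis):
    """n=4, X_j1 = 0, X_j2 = 1 + eps_j with eps = (1, -1, 1, -1)."""
    eps = np.array([1.0, -1.0, 1.0, -1.0])
    A1 = np.zeros((4, basis.n_basis))
    A2 = np.ones((4, basis.n_basis)) * (1.0 + eps)[:, None]
    return PairedFunctionalSample(
        basis=basis, coeff_cond1=A1, coeff_cond2=A2, unit_ids=list("abcd")
    )


class TestPairedSummary:
    def test_identical_conditions(self, cubic7, rng):
        A = rng.standard_normal((6, 7))
        s = paired_summary(
            PairedFunctionalSample(
                basis=cubic7, coeff_cond1=A, coeff_cond2=A.copy(),
                unit_ids=[f"u{i}" for i in range(6)],
            )
        )
        assert np.allclose(s.mean_diff, 0)
        assert np.allclose(s.cov1, s.cov2)
        assert np.allclose(s.cov1, s.crosscov)

    def test_hand_computed_two_unit_case(self):
        basis = make_bspline_basis((0, 1), 4, 4)  # p = 2 not possible; use p=4
        A1 = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        A2 = np.zeros((2, 4))
        s = paired_summary(
            PairedFunctionalSample(
                basis=basis, coeff_cond1=A1, coeff_cond2=A2, unit_ids=["a", "b"]
            )
        )
        assert np.allclose(s.mean_diff, [0.5, 0.5, 0.0, 0.0])
        assert np.allclose(s.cov2, 0.0)

    def test_kernel_matches_pointwise_sample_formula(self, cubic7, rng):
        sample = random_paired_sample(cubic7, 9, rng)
        s = paired_summary(sample)
        grid = np.linspace(0, 1, 37)
        Phi = sample.basis.design_matrix(grid)
        K_alg = np.einsum("gp,pq,gq->g", Phi, s.kernel_coefficient_matrix(), Phi)
        K_dir = pointwise_kernel(sample, grid)
        assert np.abs(K_alg - K_dir).max() < 1e-9

    def test_single_unit_rejected(self, cubic7):
        sample = PairedFunctionalSample(
            basis=cubic7, coeff_cond1=np.ones((1, 7)), coeff_cond2=np.ones((1, 7)),
            unit_ids=["a"],
        )
        with pytest.raises(ValueError):
            paired_summary(sample)


class TestStatistics:
    def test_constant_curve_closed_forms(self, cubic20):
        sample = constant_curve_sample(cubic20)
        s = paired_summary(sample)
        # mean difference is -1 everywhere, K = var(eps diffs) = 4/3
        assert statistic_cn(s, cubic20.gram) == pytest.approx(4.0, abs=1e-8)
        assert statistic_dn(s, cubic20, 1001) == pytest.approx(3.0, abs=1e-8)
        assert statistic_en(s, cubic20, 1001) == pytest.approx(3.0, abs=1e-8)

    def test_zero_when_conditions_equal_with_unit_variation(self, cubic7, rng):
        # equal mean functions but non-degenerate unit-level differences
        A1 = rng.standard_normal((8, 7))
        A2 = A1 + rng.standard_normal((8, 7))
        A2 -= A2.mean(axis=0) - A1.mean(axis=0)  # force equal column means
        sample = PairedFunctionalSample(
            basis=cubic7, coeff_cond1=A1, coeff_cond2=A2,
            unit_ids=[f"u{i}" for i in range(8)],
        )
        s = paired_summary(sample)
        assert statistic_cn(s, cubic7.gram) == pytest.approx(0.0, abs=1e-16)
        assert statistic_dn(s, cubic7) == pytest.approx(0.0, abs=1e-16)
        assert statistic_en(s, cubic7) == pytest.approx(0.0, abs=1e-16)

    def test_cn_matches_trapezoid_oracle(self, cubic20, rng):
        # grid fine enough that the trapezoid rule itself is below 1e-8
        for _ in range(3):
            sample = random_paired_sample(cubic20, 7, rng)
            s = paired_summary(sample)
            cn = statistic_cn(s, cubic20.gram)
            assert cn == pytest.approx(cn_trapezoid(sample, 200_001), rel=1e-8)

    def test_dn_en_match_pointwise_oracle(self, cubic20, rng):
        for _ in range(5):
            sample = random_paired_sample(cubic20, 7, rng)
            s = paired_summary(sample)
            dn_ref, en_ref = dn_en_pointwise(sample, 1001)
            assert statistic_dn(s, cubic20, 1001) == pytest.approx(dn_ref, rel=1e-6)
            assert statistic_en(s, cubic20, 1001) == pytest.approx(en_ref, rel=1e-6)

    def test_dn_grid_refinement_stability(self, cubic20, rng):
        sample = random_paired_sample(cubic20, 10, rng)
        s = paired_summary(sample)
        coarse = statistic_dn(s, cubic20, 1001)
        fine = statistic_dn(s, cubic20, 100_001)
        assert coarse == pytest.approx(fine, rel=1e-6)

    def test_en_equals_dn_for_constant_ratio(self, cubic20):
        # on the unit domain a constant ratio makes sup equal the integral
        sample = constant_curve_sample(cubic20)
        s = paired_summary(sample)
        assert statistic_en(s, cubic20) == pytest.approx(
            statistic_dn(s, cubic20), rel=1e-9
        )

    def test_degenerate_kernel_raises(self, cubic7):
        A1 = np.tile(np.arange(7.0), (4, 1))
        sample = PairedFunctionalSample(
            basis=cubic7, coeff_cond1=A1 + 1.0, coeff_cond2=A1,
            unit_ids=list("abcd"),
        )
        s = paired_summary(sample)  # identical differences -> K = 0
        with pytest.raises(DegenerateKernelError):
            statistic_dn(s, cubic7)

    def test_gram_shape_mismatch(self, cubic7, rng):
        s = paired_summary(random_paired_sample(cubic7, 5, rng))
        with pytest.raises(ValueError):
            statistic_cn(s, np.eye(9))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_nonnegativity_and_exchange_invariance(self, cubic7, seed):
        rng = np.random.default_rng(seed)
        sample = random_paired_sample(cubic7, 6, rng)
        swapped = PairedFunctionalSample(
            basis=cubic7,
            coeff_cond1=sample.coeff_cond2,
            coeff_cond2=sample.coeff_cond1,
            unit_ids=sample.unit_ids,
        )
        for stat in (
            lambda s: statistic_cn(paired_summary(s), cubic7.gram),
            lambda s: statistic_dn(paired_summary(s), cubic7, 201),
            lambda s: statistic_en(paired_summary(s), cubic7, 201),
        ):
            v, v_swapped = stat(sample), stat(swapped)
            assert v >= 0
            assert v == pytest.approx(v_swapped, rel=1e-9)


class TestPermutationTest:
    def test_identical_pairs_give_p_one(self, cubic7, rng):
        A = rng.standard_normal((5, 7))
        sample = PairedFunctionalSample(
            basis=cubic7, coeff_cond1=A, coeff_cond2=A.copy(),
            unit_ids=[f"u{i}" for i in range(5)],
        )
        res = permutation_test(sample, "cn", n_perm=2000, seed=3)
        assert res.p_value == 1.0

    def test_exhaustive_enumeration_for_five_units(self, cubic7, rng):
        sample = random_paired_sample(cubic7, 5, rng)
        for stat in ("cn", "dn", "en"):
            res = permutation_test(sample, stat, n_perm=2000, seed=0, grid_size=301)
            assert res.exhaustive
            assert res.n_perm == 32
            assert (res.p_value * 32) == pytest.approx(round(res.p_value * 32))

    def test_matches_naive_enumeration_oracle(self, cubic7, rng):
        sample = random_paired_sample(cubic7, 4, rng)
        res = permutation_test(sample, "cn", n_perm=100, seed=0)
        ref = naive_permutation_distribution(
            sample, lambda s: statistic_cn(paired_summary(s), cubic7.gram)
        )
        obs = statistic_cn(paired_summary(sample), cubic7.gram)
        assert res.p_value == pytest.approx(np.mean(ref >= obs))

    def test_dn_en_vectorized_replicates_match_naive(self, cubic7, rng):
        sample = random_paired_sample(cubic7, 4, rng)
        for stat_name, stat_fn in [
            ("dn", lambda s: statistic_dn(paired_summary(s), cubic7, 301)),
            ("en", lambda s: statistic_en(paired_summary(s), cubic7, 301)),
        ]:
            res = permutation_test(sample, stat_name, n_perm=100, seed=0, grid_size=301)
            ref = naive_permutation_distribution(sample, stat_fn)
            obs = stat_fn(sample)
            assert res.observed == pytest.approx(obs, rel=1e-10)
            assert res.p_value == pytest.approx(np.mean(ref >= obs - 1e-12))

    def test_sampled_replicates_are_seed_deterministic(self, cubic20, rng):
        sample = random_paired_sample(cubic20, 12, rng)
        r1 = permutation_test(sample, "dn", n_perm=150, seed=42, grid_size=301)
        r2 = permutation_test(sample, "dn", n_perm=150, seed=42, grid_size=301)
        assert not r1.exhaustive
        assert r1.p_value == r2.p_value

    def test_add_one_correction(self, cubic7, rng):
        sample = random_paired_sample(cubic7, 5, rng)
        plain = permutation_test(sample, "cn", n_perm=2000, seed=1)
        corrected = permutation_test(sample, "cn", n_perm=2000, seed=1, add_one=True)
        assert corrected.p_value == pytest.approx(
            (1 + plain.p_value * plain.n_perm) / (1 + plain.n_perm)
        )


class TestModelInterface:
    def test_fit_returns_all_statistics_and_summary(self, cubic7, rng):
        sample = random_paired_sample(cubic7, 6, rng)
        res = RepeatedMeasuresFANOVA(sample).fit(n_perm=64, seed=5, grid_size=201)
        assert set(res.tests) == {"cn", "dn", "en"}
        text = res.summary()
        assert "C_n" in text and "D_n" in text and "E_n" in text
        d = res.to_dict()
        assert all(0 <= d[s]["p_value"] <= 1 for s in d)

    def test_power_increases_with_mean_shift(self, cubic20):
        # same GP deviations, growing mean shift delta * sin(2 pi t)
        from funfanova import GPConfig, rejection_rate

        rates = []
        for delta in (0.0, 2.0):
            config = GPConfig(
                mean_functions={2: (lambda t, d=delta: d * np.sin(2 * np.pi * t))},
                cross_condition_corr=0.5,
                noise_sd=0.1,
            )
            rep = rejection_rate(
                config, n_units=15, statistics=("dn",), n_sim=60,
                n_perm=100, seed=7, grid_size=201,
            )
            rates.append(rep.rejection_rate["dn"])
        assert rates[1] > rates[0]
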