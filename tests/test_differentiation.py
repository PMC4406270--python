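import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from clinescan import (
    SyntheticTruth,
    benjamini_yekutieli,
    combine_across_loci,
    exact_g_homogeneity,
    linearized_theta,
    pairwise_theta,
    simulate_transect,
    theta_permutation_test,
    wc_theta,
)
from clinescan._exact import contingency_enumeration_p

from .conftest import make_dataset
from .oracles import dataset_to_nested, wc_theta_literal


def fixed_difference_dataset(n=20):
    return make_dataset([[[("A", "A")]] * n, [[("B", "B")]] * n])


class TestWcTheta:
    def test_fixed_difference_is_one(self):
        assert wc_theta(fixed_difference_dataset()).theta == pytest.approx(1.0)

    def test_panmixia_near_zero(self):
        rng = np.random.default_rng(0)
        loci = []
        for _ in range(50):
            freqs = rng.dirichlet(np.ones(4))
            loci.append(
                [
                    [tuple(sorted(rng.choice(4, 2, p=freqs) + 1)) for _ in range(200)]
                    for _ in range(2)
                ]
            )
        # assemble one dataset with 50 loci, 2 colonies of 200
        genos = [
            [[loci[li][ci][ind] for li in range(50)] for ind in range(200)]
            for ci in range(2)
        ]
        ds = make_dataset(genos)
        assert abs(wc_theta(ds).theta) < 0.01

    def test_hand_dataset_matches_literal_transcription(self):
        genos = [
            [[("A", "A"), ("X", "Y")], [("A", "B"), ("X", "X")], [("B", "B"), ("Y", "Y")],
             [("A", "B"), ("X", "Y")], [("A", "A"), ("Y", "Y")]],
            [[("B", "B"), ("X", "X")], [("A", "B"), ("X", "X")], [("B", "C"), ("X", "Y")],
             [("C", "C"), ("X", "X")], [("B", "B"), ("X", "Y")]],
        ]
        ds = make_dataset(genos)
        assert wc_theta(ds).theta == pytest.approx(
            wc_theta_literal(dataset_to_nested(ds)), abs=1e-12
        )

    def test_haploid_locus_matches_literal_transcription(self):
        genos = [
            [[("H1",)], [("H1",)], [("H2",)], [("H3",)], [("H1",)]],
            [[("H2",)], [("H2",)], [("H2",)], [("H1",)], [("H3",)]],
            [[("H3",)], [("H3",)], [("H1",)], [("H2",)], [("H3",)]],
        ]
        ds = make_dataset(genos, ploidy=1)
        assert wc_theta(ds).theta == pytest.approx(
            wc_theta_literal(dataset_to_nested(ds)), abs=1e-12
        )

    def test_multilocus_sums_components_not_ratios(self):
        genos = [
            [[("A", "A"), ("X", "X")], [("A", "B"), ("X", "Y")], [("A", "A"), ("Y", "Y")]],
            [[("B", "B"), ("Y", "Y")], [("A", "B"), ("X", "Y")], [("B", "B"), ("X", "Y")]],
        ]
        ds = make_dataset(genos)
        res = wc_theta(ds)
        mean_of_ratios = np.mean(list(res.per_locus.values()))
        a = sum(v[0] for v in res.components.values())
        t = sum(v[1] for v in res.components.values())
        assert res.theta == pytest.approx(a / t, abs=1e-14)
        assert res.theta != pytest.approx(mean_of_ratios, abs=1e-6)

    def test_invariant_to_allele_relabeling_and_colony_order(self):
        genos = [
            [[("A", "B")], [("A", "A")], [("B", "B")]],
            [[("B", "B")], [("A", "B")], [("B", "B")]],
        ]
        ds = make_dataset(genos)
        relabel = {"A": "Q", "B": "Z"}
        genos2 = [[[tuple(relabel[a] for a in g[0])] for g in col] for col in genos]
        ds2 = make_dataset(genos2)
        ds3 = make_dataset(genos[::-1])
        assert wc_theta(ds).theta == pytest.approx(wc_theta(ds2).theta, abs=1e-14)
        assert wc_theta(ds).theta == pytest.approx(wc_theta(ds3).theta, abs=1e-14)

    def test_drift_calibration_against_two_t(self):
        """Two colonies drifted at t from one pool give theta near 2t."""
        t = 0.02
        thetas = []
        for seed in range(8):
            truth = SyntheticTruth(
                n_colonies=2, n_per_colony=100, n_micro_loci=20,
                pool_divergence_fst=0.0, drift_fst=t, seed=100 + seed,
            )
            thetas.append(wc_theta(simulate_transect(truth).dataset).theta)
        assert abs(np.mean(thetas) - 2 * t) < 0.05

    def test_pairwise_matrix_matches_per_pair_calls(self, small_transect):
        ds = small_transect.dataset
        pw = pairwise_theta(ds)
        for i in range(3):
            for j in range(i + 1, 4):
                direct = wc_theta(ds, colonies=[i, j]).theta
                assert pw.theta[i, j] == pytest.approx(direct, abs=1e-12)


class TestThetaPermutation:
    def test_maximal_theta_gives_minimal_p(self):
        p = theta_permutation_test(fixed_difference_dataset(), n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_colony_reordering_leaves_p_unchanged(self):
        ds = fixed_difference_dataset(6)
        p1 = theta_permutation_test(ds, n_perm=100, seed=3)
        p2 = theta_permutation_test(ds.subset(colonies=[1, 0]), n_perm=100, seed=3)
        assert p1 == p2

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 150
        for rep in range(n_rep):
            genos = [
                [[tuple(sorted(rng.integers(1, 4, 2))) for _ in range(2)] for _ in range(12)]
                for _ in range(2)
            ]
            ds = make_dataset(genos)
            p = theta_permutation_test(ds, n_perm=100, seed=int(rng.integers(2**31)))
            if p <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09


class TestLinearizedTheta:
    @pytest.mark.parametrize(
        "theta,expected", [(0.0, 0.0), (0.5, 1.0), (0.018, 0.018 / 0.982), (-0.02, -0.02 / 1.02)]
    )
    def test_values(self, theta, expected):
        assert linearized_theta(theta) == pytest.approx(expected)

    def test_theta_one_rejected(self):
        with pytest.raises(ValueError):
            linearized_theta(1.0)


class TestExactGHomogeneity:
    def test_two_by_two_matches_enumeration(self):
        genos = [
            [[("A", "A")], [("A", "B")], [("A", "A")], [("A", "A")], [("A", "B")]],
            [[("B", "B")], [("A", "B")], [("B", "B")], [("A", "B")], [("B", "B")]],
        ]
        ds = make_dataset(genos)
        res = exact_g_homogeneity(ds, (0, 1), 0, seed=5, n_batches=150, batch_len=60, burn_in=1500)
        table = np.array([[8, 2], [2, 8]])  # allele copies x colony
        p_exact, _ = contingency_enumeration_p(table)
        assert abs(res.p_value - p_exact) <= 3 * res.mc_error

    def test_monomorphic_pair_is_no_information(self):
        genos = [[[("A", "A")]] * 3, [[("A", "A")]] * 3]
        assert exact_g_homogeneity(make_dataset(genos), (0, 1), 0) is None

    def test_empty_colony_is_no_information(self):
        genos = [[[("A", "B")], [("A", "A")]], [[None], [None]]]
        assert exact_g_homogeneity(make_dataset(genos), (0, 1), 0) is None

    def test_identical_frequencies_rarely_significant(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(120):
            freqs = rng.dirichlet(np.ones(3))
            genos = [
                [[tuple(sorted(rng.choice(3, 2, p=freqs) + 1))] for _ in range(25)]
                for _ in range(2)
            ]
            res = exact_g_homogeneity(
                make_dataset(genos), (0, 1), 0,
                seed=int(rng.integers(2**31)), n_batches=60, batch_len=25, burn_in=500,
            )
            if res is not None:
                ps.append(res.p_value)
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.08
        assert 0.4 <= ps.mean() <= 0.65


class TestFisherCombination:
    def test_single_locus_identity(self):
        assert combine_across_loci([0.37]) == pytest.approx(0.37, abs=1e-12)

    def test_two_half_pvalues(self):
        # X = -2(ln .5 + ln .5) = 2.7726, df=4 -> 0.5966
        assert combine_across_loci([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    def test_all_ones_combine_to_one(self):
        assert combine_across_loci([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = combine_across_loci([0.0, 0.5], chain_draws=999)
        assert 0 < p < 0.01


class TestBenjaminiYekutieli:
    def test_single_test_reduces_to_alpha(self):
        rej, thr = benjamini_yekutieli([0.04], alpha=0.05)
        assert rej.tolist() == [True] and thr == pytest.approx(0.05)
        rej, _ = benjamini_yekutieli([0.06], alpha=0.05)
        assert rej.tolist() == [False]

    def test_m4_thresholds(self):
        # c(4) = 25/12; per-rank thresholds i * 0.05 / (4 * 25/12) = i * 0.006
        rej, thr = benjamini_yekutieli([0.005, 0.011, 0.03, 0.9], alpha=0.05)
        assert rej.tolist() == [True, True, False, False]
        assert thr == pytest.approx(2 * 0.006)

    def test_all_ones_no_rejections(self):
        rej, thr = benjamini_yekutieli([1.0] * 5, alpha=0.05)
        assert not rej.any() and thr == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            benjamini_yekutieli([], alpha=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_and_never_beats_bh(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.uniform(0, 0.02, 3), rng.uniform(0, 1, 12)])
        rng.shuffle(p)
        rej, _ = benjamini_yekutieli(p, alpha=0.05)
        sm_rej = multipletests(p, alpha=0.05, method="fdr_by")[0]
        np.testing.assert_array_equal(rej, sm_rej)
        bh_rej = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert rej.sum() <= bh_rej.sum()
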