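import numpy as np
import pytest

from clinescan import (
    AdmixtureConfig,
    SyntheticTruth,
    align_labels,
    delta_k,
    ln_prob_data,
    per_locus_q,
    run_admixture,
    simulate_transect,
)
from clinescan.admixture import LocusNotFittableError

from .conftest import make_dataset


def _block_error(q, true_q):
    """Mean |q - truth| after resolving the arbitrary cluster polarity."""
    return min(
        np.abs(q[:, 0] - true_q).mean(),
        np.abs(q[:, 1] - true_q).mean() if q.shape[1] > 1 else np.inf,
    )


class TestSampler:
    def test_k1_forces_unit_q(self, two_pool_blocks):
        cfg = AdmixtureConfig(K=1, n_sweeps=50, burn_in=10, seed=0)
        res = run_admixture(two_pool_blocks.dataset, cfg)
        np.testing.assert_allclose(res.q_mean, 1.0)
        assert np.isfinite(res.ln_prob_data)

    def test_two_pool_recovery(self, two_pool_blocks):
        cfg = AdmixtureConfig(K=2, n_sweeps=400, burn_in=150, seed=1)
        res = run_admixture(two_pool_blocks.dataset, cfg)
        assert _block_error(res.q_mean, two_pool_blocks.true_q) < 0.1

    def test_q_rows_sum_to_one_and_trace_finite(self, two_pool_blocks):
        cfg = AdmixtureConfig(K=3, n_sweeps=120, burn_in=40, seed=2)
        res = run_admixture(two_pool_blocks.dataset, cfg)
        np.testing.assert_allclose(res.q_mean.sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(res.loglik_trace).all()

    def test_metropolis_acceptance_rates_reasonable(self, two_pool_blocks):
        cfg = AdmixtureConfig(K=2, n_sweeps=300, burn_in=100, seed=3)
        res = run_admixture(two_pool_blocks.dataset, cfg)
        for name, rate in res.acceptance.items():
            assert 0.1 < rate < 0.9, f"{name} acceptance {rate}"

    def test_duplicating_individuals_leaves_q_stable(self):
        truth = SyntheticTruth(
            n_colonies=2, n_per_colony=25, width_km=1e-3, n_micro_loci=10,
            pool_divergence_fst=0.35, drift_fst=0.0, seed=4,
        )
        syn = simulate_transect(truth)
        ds = syn.dataset
        doubled = make_doubled(ds)
        cfg = AdmixtureConfig(K=2, n_sweeps=400, burn_in=150, seed=5)
        q1 = run_admixture(ds, cfg).q_mean
        q2 = run_admixture(doubled, cfg).q_mean[: ds.n_individuals]
        err1 = _block_error(q1, syn.true_q)
        err2 = _block_error(q2, syn.true_q)
        assert abs(err1 - err2) < 0.05

    def test_recovery_improves_with_divergence(self):
        errs = {}
        for F in (0.1, 0.3):
            truth = SyntheticTruth(
                n_colonies=2, n_per_colony=40, width_km=1e-3, n_micro_loci=12,
                pool_divergence_fst=F, drift_fst=0.0, seed=6,
            )
            syn = simulate_transect(truth)
            cfg = AdmixtureConfig(K=2, n_sweeps=300, burn_in=100, seed=7)
            errs[F] = _block_error(run_admixture(syn.dataset, cfg).q_mean, syn.true_q)
        assert errs[0.3] < errs[0.1]

    def test_uncorrelated_model_also_recovers(self, two_pool_blocks):
        cfg = AdmixtureConfig(
            K=2, n_sweeps=300, burn_in=100, seed=8, frequency_model="uncorrelated"
        )
        res = run_admixture(two_pool_blocks.dataset, cfg)
        assert _block_error(res.q_mean, two_pool_blocks.true_q) < 0.1

    def test_k_exceeding_individuals_rejected(self, two_pool_blocks):
        with pytest.raises(ValueError):
            run_admixture(two_pool_blocks.dataset, AdmixtureConfig(K=1000, n_sweeps=10, burn_in=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AdmixtureConfig(K=0)
        with pytest.raises(ValueError):
            AdmixtureConfig(n_sweeps=10, burn_in=10)
        with pytest.raises(ValueError):
            AdmixtureConfig(frequency_model="other")


def make_doubled(ds):
    from clinescan import GenotypeDataset

    calls = [np.vstack([c, c]) for c in ds.calls]
    colony_of = np.concatenate([ds.colony_of, ds.colony_of])
    individuals = ds.individuals + [f"{i}_dup" for i in ds.individuals]
    return GenotypeDataset(ds.loci, ds.colonies, calls, colony_of, individuals)


class TestLnProbData:
    def test_constant_trace(self):
        assert ln_prob_data([5.0, 5.0, 5.0], 0) == 5.0

    def test_sample_variance_convention(self):
        # {0, 2}: mean 1 minus half the (ddof=1) variance 2 -> 0
        assert ln_prob_data([0.0, 2.0], 0) == pytest.approx(0.0)

    def test_affine_shift(self):
        trace = np.array([1.0, 3.0, 2.0, 4.0])
        assert ln_prob_data(trace + 7, 0) == pytest.approx(ln_prob_data(trace, 0) + 7)

    def test_empty_post_burnin_rejected(self):
        with pytest.raises(ValueError):
            ln_prob_data([1.0, 2.0], 5)


class TestDeltaK:
    def test_hand_values(self):
        lnp = {1: [-100.0, -100.0], 2: [-52.0, -48.0], 3: [-45.0, -45.0 + 1e-9]}
        tab = delta_k(lnp)
        sd2 = np.std([-52.0, -48.0], ddof=1)
        expect = abs(-45.0 - 2 * (-50.0) + (-100.0)) / sd2
        assert tab.delta_k[2] == pytest.approx(expect, rel=1e-6)

    def test_linear_scores_give_no_preference(self):
        lnp = {k: [-100.0 + 10 * k - 1, -100.0 + 10 * k + 1] for k in range(1, 5)}
        tab = delta_k(lnp)
        assert all(v == 0 for v in tab.delta_k.values())
        assert tab.tie

    def test_zero_sd_flagged_and_excluded(self):
        lnp = {1: [-100.0, -99.0], 2: [-50.0, -50.0], 3: [-45.0, -44.0], 4: [-44.0, -43.0]}
        tab = delta_k(lnp)
        assert np.isnan(tab.delta_k[2])
        assert tab.selected_k in (3,)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            delta_k({1: [-1.0, -2.0], 3: [-1.0, -2.0], 4: [-1.0, -2.0]})
        with pytest.raises(ValueError):
            delta_k({1: [-1.0], 2: [-1.0], 3: [-1.0]})

    def test_selects_two_clusters_on_two_pool_data(self, two_pool_blocks):
        lnp = {}
        for K in range(1, 5):
            lnp[K] = [
                run_admixture(
                    two_pool_blocks.dataset,
                    AdmixtureConfig(K=K, n_sweeps=250, burn_in=100, seed=10 * K + r),
                ).ln_prob_data
                for r in range(3)
            ]
        assert delta_k(lnp).selected_k == 2


class TestAlignment:
    def test_manual_swap_restored(self, two_pool_blocks):
        cfg = AdmixtureConfig(K=2, n_sweeps=150, burn_in=50, seed=11)
        ref = run_admixture(two_pool_blocks.dataset, cfg)
        from dataclasses import replace

        swapped = replace(ref, q_mean=ref.q_mean[:, ::-1], p_mean=[p[::-1] for p in ref.p_mean])
        (aligned,) = align_labels(ref, [swapped])
        np.testing.assert_allclose(aligned.q_mean, ref.q_mean)

    def test_self_alignment_identity(self, two_pool_blocks):
        cfg = AdmixtureConfig(K=2, n_sweeps=100, burn_in=40, seed=12)
        ref = run_admixture(two_pool_blocks.dataset, cfg)
        (aligned,) = align_labels(ref, [ref])
        np.testing.assert_array_equal(aligned.q_mean, ref.q_mean)

    def test_replicates_concordant_after_alignment(self, two_pool_blocks):
        runs = [
            run_admixture(
                two_pool_blocks.dataset,
                AdmixtureConfig(K=2, n_sweeps=300, burn_in=120, seed=20 + r),
            )
            for r in range(3)
        ]
        aligned = align_labels(runs[0], runs)
        q = np.stack([a.q_mean for a in aligned])
        assert q.std(axis=0).mean() < 0.05

    def test_dimension_mismatch_rejected(self, two_pool_blocks):
        c2 = AdmixtureConfig(K=2, n_sweeps=60, burn_in=20, seed=0)
        c3 = AdmixtureConfig(K=3, n_sweeps=60, burn_in=20, seed=0)
        r2 = run_admixture(two_pool_blocks.dataset, c2)
        r3 = run_admixture(two_pool_blocks.dataset, c3)
        with pytest.raises(ValueError):
            align_labels(r2, [r3])


class TestPerLocusQ:
    def test_fixed_difference_locus_separates_terminal_colonies(self):
        truth = SyntheticTruth(
            n_colonies=4, n_per_colony=20, width_km=200.0, center_km=1500.0,
            n_micro_loci=1, alleles_per_locus=(2,), pool_divergence_fst=0.9,
            drift_fst=0.0, seed=13,
        )
        syn = simulate_transect(truth)
        cfg = AdmixtureConfig(K=2, n_sweeps=300, burn_in=100, seed=14)
        q = per_locus_q(syn.dataset, cfg, 0)
        west = syn.dataset.members(0)
        east = syn.dataset.members(3)
        assert q[west].mean() > 0.8
        assert q[east].mean() < 0.2

    def test_near_monomorphic_locus_flagged(self):
        genos = [[[("A", "A")]] * 10 + [[("A", "B")]]]
        ds = make_dataset(genos)
        with pytest.raises(LocusNotFittableError):
            per_locus_q(ds, AdmixtureConfig(K=2, n_sweeps=50, burn_in=10), 0)

    def test_orientation_is_data_driven(self, two_pool_blocks):
        cfg1 = AdmixtureConfig(K=2, n_sweeps=300, burn_in=100, seed=15)
        cfg2 = AdmixtureConfig(K=2, n_sweeps=300, burn_in=100, seed=99)
        q1 = per_locus_q(two_pool_blocks.dataset, cfg1, 0)
        q2 = per_locus_q(two_pool_blocks.dataset, cfg2, 0)
        # different chains, same polarity anchor: strongly concordant, never flipped
        assert np.corrcoef(q1, q2)[0, 1] > 0.5

    def test_requires_k2(self, two_pool_blocks):
        with pytest.raises(ValueError):
            per_locus_q(two_pool_blocks.dataset, AdmixtureConfig(K=3, n_sweeps=50, burn_in=10), 0)
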