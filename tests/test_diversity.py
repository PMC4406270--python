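import numpy as np
import pytest

from clinescan import TestNotDefinedError as NotDefinedError
from clinescan import (
    diversity_summary,
    ewens_watterson_slatkin,
    expected_heterozygosity,
    f_is,
    genotypic_ld_test,
    hwe_exact_test,
    rbar_d,
)
from clinescan._exact import contingency_enumeration_p, hwe_enumeration_p
from clinescan.diversity import genotype_count_matrix

from .conftest import make_dataset
from .oracles import hwe_brute_force_p


class TestExpectedHeterozygosity:
    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity([1.0], 10) == 0.0

    def test_two_even_alleles_n100(self):
        assert expected_heterozygosity([0.5, 0.5], 100) == pytest.approx(100 / 99 * 0.5)

    def test_label_permutation_invariance(self):
        p = [0.5, 0.3, 0.2]
        assert expected_heterozygosity(p, 40) == pytest.approx(
            expected_heterozygosity(p[::-1], 40)
        )

    def test_requires_two_copies(self):
        with pytest.raises(ValueError):
            expected_heterozygosity([1.0], 1)


class TestFis:
    def test_all_heterozygotes_negative(self):
        ds = make_dataset([[[("A", "B")]] * 10])
        assert f_is(ds, 0, 0) < 0

    def test_hardy_weinberg_proportions_near_zero(self):
        # 2 alleles at 0.5: 25/50/25 of n=100 is exactly HW
        genos = [[("A", "A")]] * 25 + [[("A", "B")]] * 50 + [[("B", "B")]] * 25
        ds = make_dataset([genos])
        assert abs(f_is(ds, 0, 0)) < 0.02

    def test_hand_dataset_matches_direct_formula(self):
        genos = [("A", "A")] * 3 + [("A", "B")] * 2 + [("B", "B")] * 4 + [("A", "C")]
        ds = make_dataset([[[g] for g in genos]])
        n = 20
        p = np.array([9, 10, 1]) / n
        he = n / (n - 1) * (1 - (p**2).sum())
        ho = 3 / 10
        assert f_is(ds, 0, 0) == pytest.approx(1 - ho / he, abs=1e-12)

    def test_haploid_locus_rejected(self):
        ds = make_dataset([[[("H1",)], [("H2",)]]], ploidy=1)
        with pytest.raises(ValueError):
            f_is(ds, 0, 0)


class TestHWEExact:
    def test_two_homozygotes_hand_enumeration(self):
        # allele counts 2A 2B: arrays {AA,BB} (prob 1/3) and {AB,AB} (2/3)
        G = np.array([[1, 0], [0, 1]])
        res = hwe_exact_test(G)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(1 / 3)

    def test_most_probable_array_gives_p_one(self):
        G = np.array([[0, 2], [0, 0]])  # the 2/3-probability array of the same counts
        assert hwe_exact_test(G).p_value == pytest.approx(1.0)

    def test_monomorphic_is_not_defined(self):
        with pytest.raises(NotDefinedError):
            hwe_exact_test(np.array([[5, 0], [0, 0]]))

    def test_enumeration_matches_brute_force_matchings(self):
        genotypes = [("A", "A"), ("A", "B"), ("B", "C"), ("C", "C")]
        ds = make_dataset([[[g] for g in genotypes]])
        G = genotype_count_matrix(ds, 0, 0)
        p_pkg, _ = hwe_enumeration_p(G)
        assert p_pkg == pytest.approx(hwe_brute_force_p(genotypes), abs=1e-12)

    def test_chain_agrees_with_enumeration_on_five_alleles(self):
        rng = np.random.default_rng(3)
        G = np.zeros((5, 5), dtype=int)
        for _ in range(12):
            a, b = sorted(rng.integers(0, 5, 2))
            G[a, b] += 1
        exact = hwe_exact_test(G, enumeration_max_alleles=6)
        chain = hwe_exact_test(
            G, seed=0, n_batches=150, batch_len=100, burn_in=2000,
            enumeration_max_alleles=5,
        )
        assert chain.method == "markov_chain" and chain.mc_error is not None
        assert abs(chain.p_value - exact.p_value) <= 3 * chain.mc_error


class TestGenotypicLD:
    def test_perfect_covariation_is_significant(self):
        rng = np.random.default_rng(0)
        genos = []
        for _ in range(20):
            g = tuple(sorted(rng.integers(1, 4, 2)))
            genos.append([g, g])  # locus 2 copies locus 1
        ds = make_dataset([genos])
        res = genotypic_ld_test(ds, 0, (0, 1), seed=1, n_batches=100, batch_len=50, burn_in=1000)
        assert res.p_value <= 0.01

    def test_chain_matches_exhaustive_on_small_table(self):
        genos = [
            [("A", "A"), ("X", "Y")],
            [("A", "A"), ("X", "X")],
            [("A", "B"), ("X", "Y")],
            [("A", "B"), ("X", "X")],
            [("A", "A"), ("X", "Y")],
            [("A", "B"), ("X", "Y")],
        ]
        ds = make_dataset([genos])
        res = genotypic_ld_test(ds, 0, (0, 1), seed=2, n_batches=150, batch_len=60, burn_in=1500)
        # same table, enumerated exactly
        keys1 = [tuple(sorted(g[0])) for g in genos]
        keys2 = [tuple(sorted(g[1])) for g in genos]
        u1, u2 = sorted(set(keys1)), sorted(set(keys2))
        T = np.zeros((len(u1), len(u2)), dtype=int)
        for k1, k2 in zip(keys1, keys2):
            T[u1.index(k1), u2.index(k2)] += 1
        p_exact, _ = contingency_enumeration_p(T)
        assert abs(res.p_value - p_exact) <= 3 * res.mc_error

    def test_monomorphic_locus_not_defined(self):
        genos = [[("A", "A"), ("X", "Y")], [("A", "A"), ("X", "X")], [("A", "A"), ("Y", "Y")]]
        ds = make_dataset([genos])
        with pytest.raises(NotDefinedError):
            genotypic_ld_test(ds, 0, (0, 1))

    def test_independent_loci_type_i_error_controlled(self):
        """Null calibration: the exact conditional test is valid (conservative).

        Genotype-class tables are sparse, so the discrete null makes the
        p-values stochastically larger than uniform; the binding property
        is that the rejection rate never exceeds the nominal level.
        """
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(150):
            genos = [
                [tuple(sorted(rng.integers(1, 5, 2))), tuple(sorted(rng.integers(1, 5, 2)))]
                for _ in range(30)
            ]
            ds = make_dataset([genos])
            try:
                res = genotypic_ld_test(ds, 0, (0, 1), seed=int(rng.integers(2**31)),
                                        n_batches=60, batch_len=25, burn_in=500)
            except NotDefinedError:
                continue
            ps.append(res.p_value)
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.07  # valid at the 5% level
        assert 0.45 <= ps.mean() <= 0.65  # near-calibrated, conservative side


class TestRbarD:
    def test_perfect_association_is_one(self):
        rng = np.random.default_rng(1)
        genos = []
        for _ in range(12):
            g = tuple(sorted(rng.integers(1, 4, 2)))
            genos.append([g, g])
        ds = make_dataset([genos])
        val, _ = rbar_d(ds, 0, n_permutations=19)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_locus_and_individual_order(self):
        rng = np.random.default_rng(2)
        genos = [
            [tuple(sorted(rng.integers(1, 4, 2))), tuple(sorted(rng.integers(1, 3, 2)))]
            for _ in range(10)
        ]
        ds = make_dataset([genos])
        v1, _ = rbar_d(ds, 0, n_permutations=0)
        ds_swapped = make_dataset([[list(reversed(g)) for g in genos]])
        v2, _ = rbar_d(ds_swapped, 0, n_permutations=0)
        perm = rng.permutation(10)
        ds_perm = make_dataset([[genos[i] for i in perm]])
        v3, _ = rbar_d(ds_perm, 0, n_permutations=0)
        assert v1 == pytest.approx(v2) == pytest.approx(v3)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(300):
            genos = [
                [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(3)] for _ in range(15)
            ]
            try:
                v, _ = rbar_d(make_dataset([genos]), 0, n_permutations=0)
            except ValueError:
                continue
            vals.append(v)
        assert abs(np.mean(vals)) < 0.02

    def test_needs_two_polymorphic_loci(self):
        ds = make_dataset([[[("A", "A"), ("X", "Y")]] * 5])
        with pytest.raises(ValueError):
            rbar_d(ds, 0, n_permutations=9)


class TestEwensWattersonSlatkin:
    def test_monomorphic_and_all_singletons(self):
        F, p = ewens_watterson_slatkin([10])
        assert (F, p) == (1.0, 1.0)
        F, p = ewens_watterson_slatkin([1] * 6)
        assert p == 1.0

    def test_hand_enumeration_n10_k2(self):
        # partitions {9,1}..{5,5} with conditional ESF weights 1/(n1 n2 prod a_j!)
        from fractions import Fraction

        w = {
            (9, 1): Fraction(1, 9), (8, 2): Fraction(1, 16), (7, 3): Fraction(1, 21),
            (6, 4): Fraction(1, 24), (5, 5): Fraction(1, 50),
        }
        expect = float(w[(5, 5)] / sum(w.values()))
        F, p = ewens_watterson_slatkin([5, 5])
        assert F == pytest.approx(0.5)
        assert p == pytest.approx(expect, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ewens_watterson_slatkin([5, 0])

    def test_monte_carlo_close_to_enumeration(self):
        counts = [12, 5, 2, 1]
        _, p_enum = ewens_watterson_slatkin(counts)
        _, p_mc = ewens_watterson_slatkin(counts, seed=4, n_mc=4000, enumeration_cap=1)
        assert abs(p_mc - p_enum) < 0.05


class TestSummary:
    def test_summary_columns_populated(self, small_transect):
        rows = diversity_summary(small_transect.dataset, n_permutations=19)
        assert len(rows) == small_transect.dataset.n_colonies
        for r in rows:
            assert 0 <= r.expected_heterozygosity <= 1
            assert 0 <= r.haplotype_diversity <= 1
            assert r.mean_alleles_per_locus >= 1
            assert -1 <= r.f_is <= 1
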