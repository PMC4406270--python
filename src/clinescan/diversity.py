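"""Within-colony variation and per-colony tests.

Covers the per-colony column block of a classic colony survey table:
mean alleles per locus, unbiased gene diversity (expected heterozygosity
for microsatellites, haplotype diversity for mtDNA), F_IS, the
multilocus linkage-disequilibrium index r_bar_d, Hardy-Weinberg and
genotypic-equilibrium exact tests, and the Ewens-Watterson-Slatkin
neutrality test on haplotype configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import _exact
from ._exact import TestNotDefinedError, TestResult
from .popdata import MISSING, GenotypeDataset, allele_frequencies

__all__ = [
    "TestResult",
    "TestNotDefinedError",
    "DiversitySummary",
    "expected_heterozygosity",
    "f_is",
    "genotype_count_matrix",
    "hwe_exact_test",
    "genotypic_ld_test",
    "rbar_d",
    "ewens_watterson_slatkin",
    "diversity_summary",
]


def expected_heterozygosity(freqs, n: int) -> float:
    """Unbiased gene diversity (n/(n-1)) * (1 - sum p_i^2).

    ``n`` is the number of gene copies sampled; for a haploid locus the
    same quantity is the haplotype diversity h.
    """
    if n < 2:
        raise ValueError("expected heterozygosity needs at least 2 gene copies")
    p = np.asarray(freqs, dtype=float)
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def f_is(ds: GenotypeDataset, colony, locus) -> float:
    """Inbreeding coefficient 1 - H_o/H_e for one colony x diploid locus.

    Returns NaN when H_e = 0 (monomorphic: F_IS undefined).
    """
    ci = ds.colony_index(colony) if isinstance(colony, str) else colony
    li = ds.locus_index(locus) if isinstance(locus, str) else locus
    if ds.loci[li].ploidy != 2:
        raise ValueError("F_IS is defined for diploid loci only")
    calls = ds.calls[li][ds.members(ci)]
    ok = calls[:, 0] != MISSING
    calls = calls[ok]
    if calls.shape[0] < 2:
        raise ValueError("F_IS needs at least 2 genotyped individuals")
    n = 2 * calls.shape[0]
    counts = np.bincount(calls.ravel(), minlength=ds.loci[li].n_alleles)
    he = expected_heterozygosity(counts / n, n)
    if he == 0:
        return float("nan")
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    return 1.0 - ho / he


def genotype_count_matrix(ds: GenotypeDataset, colony, locus) -> np.ndarray:
    """Upper-triangular genotype count matrix for one colony x diploid locus."""
    ci = ds.colony_index(colony) if isinstance(colony, str) else colony
    li = ds.locus_index(locus) if isinstance(locus, str) else locus
    locus_obj = ds.loci[li]
    if locus_obj.ploidy != 2:
        raise ValueError("genotype counts require a diploid locus")
    calls = ds.calls[li][ds.members(ci)]
    calls = calls[calls[:, 0] != MISSING]
    k = locus_obj.n_alleles
    G = np.zeros((k, k), dtype=np.int64)
    lo = calls.min(axis=1)
    hi = calls.max(axis=1)
    np.add.at(G, (lo, hi), 1)
    return G


def hwe_exact_test(
    genotype_counts: np.ndarray,
    seed: int = 0,
    n_batches: int = 1000,
    batch_len: int = 1000,
    burn_in: int = 10000,
    enumeration_max_alleles: int = 5,
) -> TestResult:
    """Exact Hardy-Weinberg test on a genotype count array.

    The null is Levene's conditional distribution of genotype arrays
    given allele counts; P is the total probability of arrays no more
    probable than the observed one.  Complete enumeration is used when
    fewer than ``enumeration_max_alleles`` alleles are observed,
    otherwise a partner-swap Markov chain with the given batching.
    """
    G = np.triu(np.asarray(genotype_counts, dtype=np.int64))
    m = _exact.allele_counts_from_array(G)
    observed_alleles = int((m > 0).sum())
    if observed_alleles < 2:
        raise TestNotDefinedError("Hardy-Weinberg test undefined for a monomorphic locus")
    keep = m > 0
    G = G[np.ix_(keep, keep)]
    if observed_alleles < enumeration_max_alleles:
        p, log_obs = _exact.hwe_enumeration_p(G)
        return TestResult(statistic=log_obs, p_value=p, method="enumeration")
    rng = np.random.default_rng(seed)
    p, se, log_obs = _exact.hwe_chain_p(G, rng, n_batches, batch_len, burn_in)
    return TestResult(
        statistic=log_obs, p_value=p, method="markov_chain", mc_error=se, n_batches=n_batches
    )


def genotypic_ld_test(
    ds: GenotypeDataset,
    colony,
    locus_pair,
    seed: int = 0,
    n_batches: int = 1000,
    batch_len: int = 1000,
    burn_in: int = 10000,
) -> TestResult:
    """Genotypic-equilibrium test for one colony and a pair of loci.

    Builds the contingency table of single-locus genotype classes and
    estimates Pr(G >= G_obs) over margin-fixed tables with a
    label-permutation Markov chain (log-likelihood-ratio statistic).
    """
    ci = ds.colony_index(colony) if isinstance(colony, str) else colony
    l1, l2 = (ds.locus_index(l) if isinstance(l, str) else l for l in locus_pair)
    rows = ds.members(ci)
    g1 = ds.calls[l1][rows]
    g2 = ds.calls[l2][rows]
    ok = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    g1, g2 = g1[ok], g2[ok]
    if g1.shape[0] < 2:
        raise TestNotDefinedError("need at least 2 complete two-locus genotypes")

    def classes(g):
        keys = [tuple(sorted(row)) for row in g]
        uniq = sorted(set(keys))
        return np.array([uniq.index(k) for k in keys]), len(uniq)

    a, na = classes(g1)
    b, nb = classes(g2)
    if na < 2 or nb < 2:
        raise TestNotDefinedError("both loci must be polymorphic in the colony")
    table = np.zeros((na, nb), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    rng = np.random.default_rng(seed)
    p, se, g_obs = _exact.contingency_chain_p(table, rng, n_batches, batch_len, burn_in)
    return TestResult(statistic=g_obs, p_value=p, method="markov_chain", mc_error=se, n_batches=n_batches)


def _locus_distance_vectors(ds: GenotypeDataset, rows: np.ndarray) -> list[np.ndarray]:
    """Per polymorphic locus, the pairwise allele-difference counts d_l.

    For diploids d in {0,1,2}: the number of allele copies not shared
    between two individuals, i.e. half the L1 distance between their
    allele-count vectors.  Pairs with missing data at the locus get NaN.
    """
    out = []
    for locus, calls in zip(ds.loci, ds.calls):
        g = calls[rows]
        valid = g[:, 0] != MISSING
        counts = np.zeros((rows.size, locus.n_alleles))
        for copy in range(locus.ploidy):
            codes = g[:, copy]
            okc = codes != MISSING
            counts[np.flatnonzero(okc), codes[okc]] += 1
        seen = np.unique(g[valid])
        if seen.size < 2:
            continue
        i, j = np.triu_indices(rows.size, 1)
        d = np.abs(counts[i] - counts[j]).sum(axis=1) / 2.0
        d[~(valid[i] & valid[j])] = np.nan  # pairs involving missing data
        out.append(d)
    return out


def rbar_d(
    ds: GenotypeDataset,
    colony,
    seed: int = 0,
    n_permutations: int = 999,
) -> tuple[float, float]:
    """Multilocus linkage disequilibrium r_bar_d for one colony.

    r_bar_d = sum_{j<k} cov(d_j, d_k) / sum_{j<k} sqrt(var d_j var d_k)
    over the pairwise-individual allele-difference variables, with a
    permutation p-value obtained by shuffling genotypes among
    individuals independently per locus.
    """
    ci = ds.colony_index(colony) if isinstance(colony, str) else colony
    rows = ds.members(ci)
    if rows.size < 3:
        raise ValueError("r_bar_d needs at least 3 individuals")

    def stat(dvecs) -> float:
        D = np.array(dvecs)
        ok = ~np.isnan(D).any(axis=0)
        D = D[:, ok]
        C = np.cov(D)
        v = np.sqrt(np.diag(C))
        iu = np.triu_indices(D.shape[0], 1)
        denom = (v[iu[0]] * v[iu[1]]).sum()
        if denom == 0:
            return float("nan")
        return float(C[iu].sum() / denom)

    dvecs = _locus_distance_vectors(ds, rows)
    if len(dvecs) < 2:
        raise ValueError("r_bar_d needs at least 2 polymorphic loci")
    obs = stat(dvecs)

    rng = np.random.default_rng(seed)
    sub = ds.subset(colonies=[ci])
    hits = 0
    for _ in range(n_permutations):
        perm_calls = [c[rng.permutation(rows.size)] for c in sub.calls]
        perm_ds = GenotypeDataset(sub.loci, sub.colonies, perm_calls, sub.colony_of, sub.individuals)
        if stat(_locus_distance_vectors(perm_ds, np.arange(rows.size))) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return obs, p


# ---------------------------------------------------------------------------
# Ewens-Watterson-Slatkin neutrality test
# ---------------------------------------------------------------------------


def _partitions(n: int, k: int):
    """Partitions of n into exactly k positive parts, non-increasing order."""

    def rec(n, k, mx):
        if k == 1:
            if 1 <= n <= mx:
                yield (n,)
            return
        for first in range(min(n - k + 1, mx), 0, -1):
            for rest in rec(n - first, k - 1, first):
                yield (first,) + rest

    yield from rec(n, k, n)


def _count_partitions(n: int, k: int) -> int:
    # p(n, k) = p(n-1, k-1) + p(n-k, k)
    P = np.zeros((n + 1, k + 1), dtype=object)
    P[0, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, min(i, k) + 1):
            P[i, j] = P[i - 1, j - 1] + P[i - j, j]
    return int(P[n, k])


def _esf_weight(parts) -> Fraction:
    """Unnormalised conditional ESF weight of an allele configuration.

    Given (n, k) the conditional probability of the unordered
    configuration {n_1..n_k} is proportional to 1/(prod n_i * prod_j a_j!)
    where a_j counts parts of size j; theta cancels.
    """
    denom = 1
    for p in parts:
        denom *= p
    mult = {}
    for p in parts:
        mult[p] = mult.get(p, 0) + 1
    for m in mult.values():
        denom *= math.factorial(m)
    return Fraction(1, denom)


def ewens_watterson_slatkin(
    allele_counts,
    seed: int = 0,
    n_mc: int = 100000,
    enumeration_cap: int = 10**6,
) -> tuple[float, float]:
    """Slatkin's exact neutrality test on an allele (haplotype) configuration.

    Returns ``(F_obs, p)`` where F_obs = sum (n_i/n)^2 is the sample
    homozygosity and p is the total conditional Ewens-sampling-formula
    probability of configurations no more probable than the observed
    one, given (n, k).  Full partition enumeration when the number of
    partitions of n into k parts is at most ``enumeration_cap``;
    otherwise rejection-sampled Monte Carlo with ``n_mc`` draws.
    """
    counts = [int(c) for c in allele_counts]
    if any(c <= 0 for c in counts):
        raise ValueError("allele counts must be positive")
    n = sum(counts)
    k = len(counts)
    F_obs = sum((c / n) ** 2 for c in counts)
    obs = tuple(sorted(counts, reverse=True))
    if k == 1 or k == n:
        return F_obs, 1.0

    if _count_partitions(n, k) <= enumeration_cap:
        w_obs = _esf_weight(obs)
        tail = Fraction(0)
        total = Fraction(0)
        for parts in _partitions(n, k):
            w = _esf_weight(parts)
            total += w
            if w <= w_obs:
                tail += w
        return F_obs, float(tail / total)

    # Monte Carlo: Chinese-restaurant draws at theta_hat solving E[K] = k,
    # kept only when K = k -- an exact sample of the conditional law.
    from scipy.optimize import brentq

    def mean_k(theta):
        i = np.arange(n)
        return (theta / (theta + i)).sum()

    theta_hat = brentq(lambda t: mean_k(t) - k, 1e-6, 1e6)
    rng = np.random.default_rng(seed)
    w_obs = float(_esf_weight(obs))
    hits = kept = 0
    batch = max(1, n_mc // 20)
    while kept < n_mc:
        for _ in range(batch):
            tables = []
            for i in range(n):
                r = rng.random() * (theta_hat + i)
                if r < theta_hat:
                    tables.append(1)
                else:
                    # choose an occupied table proportional to its size
                    x = r - theta_hat
                    for t in range(len(tables)):
                        x -= tables[t]
                        if x < 0:
                            tables[t] += 1
                            break
            if len(tables) == k:
                kept += 1
                if float(_esf_weight(tuple(sorted(tables, reverse=True)))) <= w_obs * (1 + 1e-12):
                    hits += 1
                if kept >= n_mc:
                    break
    return F_obs, hits / kept


# ---------------------------------------------------------------------------
# Per-colony summary table
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-colony variation summary (the survey-table column block)."""

    colony: str
    n_individuals: int
    mean_alleles_per_locus: float
    expected_heterozygosity: float
    haplotype_diversity: float
    f_is: float
    rbar_d_value: float = float("nan")
    rbar_d_p: float = float("nan")
    per_locus: dict = field(default_factory=dict)


def diversity_summary(
    ds: GenotypeDataset,
    seed: int = 0,
    n_permutations: int = 199,
    with_rbar_d: bool = True,
) -> list[DiversitySummary]:
    """Summarise every colony: alleles/locus, H_e, h, F_IS and r_bar_d.

    F_IS per colony is the across-locus combination 1 - sum H_o / sum H_e
    (loci weighted by their gene-diversity denominator).
    """
    aft = allele_frequencies(ds)
    diploid = [i for i, l in enumerate(ds.loci) if l.ploidy == 2]
    haploid = [i for i, l in enumerate(ds.loci) if l.ploidy == 1]
    out = []
    for ci, colony in enumerate(ds.colonies):
        rows = ds.members(ci)
        per_locus = {}
        n_all, he_vals, h_vals = [], [], []
        ho_sum = he_sum = 0.0
        for li in diploid + haploid:
            locus = ds.loci[li]
            cnt = aft.counts[li][ci]
            ncop = int(cnt.sum())
            if ncop < 2:
                continue
            he = expected_heterozygosity(cnt / ncop, ncop)
            k = int((cnt > 0).sum())
            per_locus[locus.name] = {"n_alleles": k, "gene_diversity": he, "n_copies": ncop}
            if li in diploid:
                n_all.append(k)
                he_vals.append(he)
                calls = ds.calls[li][rows]
                ok = calls[:, 0] != MISSING
                if ok.sum() >= 2 and he > 0:
                    ho_sum += float((calls[ok, 0] != calls[ok, 1]).mean())
                    he_sum += he
            else:
                h_vals.append(he)
        # 1 - sum(Ho)/sum(He): each locus's ratio weighted by its H_e denominator
        fis = 1.0 - ho_sum / he_sum if he_sum > 0 else float("nan")
        summ = DiversitySummary(
            colony=colony.name,
            n_individuals=int(rows.size),
            mean_alleles_per_locus=float(np.mean(n_all)) if n_all else float("nan"),
            expected_heterozygosity=float(np.mean(he_vals)) if he_vals else float("nan"),
            haplotype_diversity=float(np.mean(h_vals)) if h_vals else float("nan"),
            f_is=fis,
            per_locus=per_locus,
        )
        if with_rbar_d and len(diploid) >= 2 and rows.size >= 3:
            try:
                summ.rbar_d_value, summ.rbar_d_p = rbar_d(
                    ds.subset(loci=diploid), ci, seed=seed + ci, n_permutations=n_permutations
                )
            except ValueError:
                pass
        out.append(summ)
    return out
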