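"""Population differentiation: Weir-Cockerham theta and exact homogeneity tests.

theta is the variance-component estimator of F_ST: for diploid loci the
1984 components a (among populations), b (among individuals within
populations) and c (within individuals) are computed per allele, summed
over alleles and loci, and theta = sum(a) / sum(a + b + c).  Haploid
(mtDNA) loci use the two-level analogue with no within-individual
component.  Estimates can be slightly negative by sampling and are
reported as computed.

Significance machinery: permutation tests for theta > 0, Markov-chain
exact G tests of allele/haplotype frequency homogeneity between colony
pairs, Fisher combination across loci, and the Benjamini-Yekutieli
step-up correction for simultaneous testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import _exact
from ._exact import TestResult
from .popdata import MISSING, GenotypeDataset

__all__ = [
    "ThetaResult",
    "HomogeneityResult",
    "wc_theta",
    "pairwise_theta",
    "theta_permutation_test",
    "linearized_theta",
    "exact_g_homogeneity",
    "pairwise_homogeneity",
    "combine_across_loci",
    "benjamini_yekutieli",
]


@dataclass
class ThetaResult:
    theta: float
    per_locus: dict
    components: dict  # locus -> (a_sum, total_sum)
    n_colonies: int
    p_value: float | None = None
    n_permutations: int | None = None


@dataclass
class PairwiseTheta:
    labels: list
    theta: np.ndarray  # symmetric, NaN diagonal
    p_values: np.ndarray | None = None
    n_permutations: int | None = None


# ---------------------------------------------------------------------------
# per-(colony, locus) sufficient statistics
# ---------------------------------------------------------------------------


def _locus_stats(ds: GenotypeDataset, li: int, colony_of: np.ndarray | None = None):
    """n_i, allele frequencies p_ia and heterozygote frequencies h_ia per colony.

    For haploid loci h is None and n_i counts gene copies; for diploid
    loci n_i counts genotyped individuals.
    """
    locus = ds.loci[li]
    calls = ds.calls[li]
    co = ds.colony_of if colony_of is None else colony_of
    r = ds.n_colonies
    A = locus.n_alleles
    if locus.ploidy == 1:
        ok = calls[:, 0] != MISSING
        cnt = np.zeros((r, A))
        np.add.at(cnt, (co[ok], calls[ok, 0]), 1)
        n = cnt.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = cnt / n[:, None]
        return n, p, None
    ok = calls[:, 0] != MISSING
    cnt = np.zeros((r, A))
    het = np.zeros((r, A))
    for copy in (0, 1):
        np.add.at(cnt, (co[ok], calls[ok, copy]), 1)
    hrows = ok & (calls[:, 0] != calls[:, 1])
    for copy in (0, 1):
        np.add.at(het, (co[hrows], calls[hrows, copy]), 1)
    n = np.zeros(r)
    np.add.at(n, co[ok], 1)
    with np.errstate(invalid="ignore"):
        p = cnt / (2 * n[:, None])
        h = het / n[:, None]
    return n, p, h


def _diploid_components(n, p, h):
    """Weir-Cockerham (1984) a, b, c summed over alleles for one locus.

    ``n``: individuals per population (length r, zeros dropped);
    ``p``: allele frequency matrix (r x A); ``h``: heterozygote
    frequency matrix (r x A).
    """
    use = n > 0
    n, p, h = n[use], p[use], h[use]
    r = n.size
    if r < 2 or n.sum() <= r:  # need nbar > 1
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _haploid_components(n, p):
    """Two-level (among/within populations) components for a haploid locus."""
    use = n > 0
    n, p = n[use], p[use]
    r = n.size
    ntot = n.sum()
    if r < 2 or ntot <= r:
        return 0.0, 0.0
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / ntot
    msp = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n[:, None] * (p * (1 - p))).sum(axis=0) / (ntot - r)
    a = (msp - msg) / nc
    return float(a.sum()), float(msg.sum())


def wc_theta(ds: GenotypeDataset, colonies=None, loci=None) -> ThetaResult:
    """Weir-Cockerham theta over the given colonies and loci.

    The multi-locus estimate sums variance components over alleles and
    loci before taking the ratio (never a mean of per-locus ratios).
    Colonies with zero gene copies at every requested locus are excluded
    with a warning.
    """
    sub = ds if colonies is None and loci is None else ds.subset(colonies, loci)
    # drop colonies with no data anywhere
    has_data = np.zeros(sub.n_colonies, dtype=bool)
    for locus, calls in zip(sub.loci, sub.calls):
        ok = calls[:, 0] != MISSING
        has_data |= np.bincount(sub.colony_of, weights=ok, minlength=sub.n_colonies) > 0
    if not has_data.all():
        dropped = [c.name for c, h in zip(sub.colonies, has_data) if not h]
        warnings.warn(f"colonies with no data excluded from theta: {dropped}")
        sub = sub.subset(colonies=list(np.flatnonzero(has_data)))
    if sub.n_colonies < 2:
        raise ValueError("theta needs at least 2 colonies with data")

    per_locus, components = {}, {}
    A = T = 0.0
    for li, locus in enumerate(sub.loci):
        n, p, h = _locus_stats(sub, li)
        if locus.ploidy == 2:
            a, b, c = _diploid_components(n, p, h)
            tot = a + b + c
        else:
            a, within = _haploid_components(n, p)
            tot = a + within
        components[locus.name] = (a, tot)
        per_locus[locus.name] = a / tot if tot != 0 else float("nan")
        A += a
        T += tot
    theta = A / T if T != 0 else float("nan")
    return ThetaResult(theta=theta, per_locus=per_locus, components=components, n_colonies=sub.n_colonies)


def theta_permutation_test(
    ds: GenotypeDataset,
    colonies=None,
    loci=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for theta > 0.

    Individuals (whole multilocus genotypes; haplotypes travel with the
    individual) are permuted among colonies; p = (1 + #{theta_perm >=
    theta_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    sub = ds if colonies is None and loci is None else ds.subset(colonies, loci)
    obs = _theta_value(sub, sub.colony_of)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = sub.colony_of[rng.permutation(sub.n_individuals)]
        if _theta_value(sub, perm) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _theta_value(ds: GenotypeDataset, colony_of: np.ndarray) -> float:
    A = T = 0.0
    for li, locus in enumerate(ds.loci):
        n, p, h = _locus_stats(ds, li, colony_of)
        if locus.ploidy == 2:
            a, b, c = _diploid_components(n, p, h)
            T += a + b + c
        else:
            a, within = _haploid_components(n, p)
            T += a + within
        A += a
    return A / T if T != 0 else float("nan")


def pairwise_theta(
    ds: GenotypeDataset,
    loci=None,
    n_perm: int = 0,
    seed: int = 0,
) -> PairwiseTheta:
    """theta for every colony pair (optionally with permutation p-values)."""
    sub = ds if loci is None else ds.subset(loci=loci)
    r = sub.n_colonies
    mat = np.full((r, r), np.nan)
    pmat = np.full((r, r), np.nan) if n_perm else None
    for i in range(r):
        for j in range(i + 1, r):
            pair = sub.subset(colonies=[i, j])
            try:
                res = wc_theta(pair)
            except ValueError:
                continue
            mat[i, j] = mat[j, i] = res.theta
            if n_perm:
                p = theta_permutation_test(pair, n_perm=n_perm, seed=seed + 7919 * i + j)
                pmat[i, j] = pmat[j, i] = p
    return PairwiseTheta(
        labels=[c.name for c in sub.colonies], theta=mat, p_values=pmat,
        n_permutations=n_perm or None,
    )


def linearized_theta(theta):
    """Rousset's linearisation theta / (1 - theta); negative values pass through."""
    t = np.asarray(theta, dtype=float)
    if np.any(t == 1):
        raise ValueError("linearized theta undefined at theta = 1")
    out = t / (1 - t)
    return float(out) if np.isscalar(theta) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Exact G tests of frequency homogeneity
# ---------------------------------------------------------------------------


def exact_g_homogeneity(
    ds: GenotypeDataset,
    colony_pair,
    locus,
    seed: int = 0,
    n_batches: int = 1000,
    batch_len: int = 1000,
    burn_in: int = 10000,
) -> TestResult | None:
    """Exact test of allele/haplotype frequency homogeneity for one colony pair.

    Contingency table of allele copy counts x colony; Markov chain over
    margin-fixed tables with the G ordering.  Returns None ("no
    information") when the pooled pair is monomorphic or a colony has no
    data at the locus.
    """
    ci, cj = (ds.colony_index(c) if isinstance(c, str) else c for c in colony_pair)
    li = ds.locus_index(locus) if isinstance(locus, str) else locus
    locus_obj = ds.loci[li]
    table = np.zeros((locus_obj.n_alleles, 2), dtype=np.int64)
    for col, c in enumerate((ci, cj)):
        calls = ds.calls[li][ds.members(c)]
        for copy in range(locus_obj.ploidy):
            codes = calls[:, copy]
            ok = codes != MISSING
            np.add.at(table[:, col], codes[ok], 1)
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return None
    rng = np.random.default_rng(seed)
    p, se, g_obs = _exact.contingency_chain_p(table, rng, n_batches, batch_len, burn_in)
    return TestResult(statistic=g_obs, p_value=p, method="markov_chain", mc_error=se, n_batches=n_batches)


def combine_across_loci(pvalues, chain_draws: int = 10**6) -> float:
    """Fisher's method across informative loci: X = -2 sum ln p ~ chi2(2m).

    Zero p-values are clamped at 1/(chain_draws + 1) with a warning
    (a chain can never certify p = 0).
    """
    ps = [p for p in pvalues if p is not None and not np.isnan(p)]
    if not ps:
        raise ValueError("no informative locus to combine")
    ps = np.asarray(ps, dtype=float)
    if (ps == 0).any():
        warnings.warn("zero p-values clamped before Fisher combination")
        ps = np.maximum(ps, 1.0 / (chain_draws + 1))
    X = -2.0 * np.log(ps).sum()
    return float(sps.chi2.sf(X, 2 * ps.size))


@dataclass
class HomogeneityResult:
    """Pairwise frequency-homogeneity tests across a dataset.

    ``per_locus_p[(i, j)][locus]`` holds raw exact-test p-values;
    ``combined_p`` the across-microsatellite Fisher combination;
    ``mtdna_p`` the haploid locus alone; ``*_significant`` the flags
    after Benjamini-Yekutieli correction at ``alpha``.
    """

    labels: list
    per_locus_p: dict
    combined_p: dict
    mtdna_p: dict
    alpha: float
    combined_significant: dict = field(default_factory=dict)
    mtdna_significant: dict = field(default_factory=dict)


def pairwise_homogeneity(
    ds: GenotypeDataset,
    seed: int = 0,
    n_batches: int = 200,
    batch_len: int = 100,
    burn_in: int = 2000,
    alpha: float = 0.05,
) -> HomogeneityResult:
    """Exact G tests for every colony pair, combined across loci and BY-corrected."""
    msat = [i for i, l in enumerate(ds.loci) if l.ploidy == 2]
    mt = [i for i, l in enumerate(ds.loci) if l.ploidy == 1]
    r = ds.n_colonies
    per_locus_p, combined, mtp = {}, {}, {}
    for i in range(r):
        for j in range(i + 1, r):
            row = {}
            for li in msat:
                res = exact_g_homogeneity(
                    ds, (i, j), li, seed=seed + 104729 * i + 1299721 * j + li,
                    n_batches=n_batches, batch_len=batch_len, burn_in=burn_in,
                )
                row[ds.loci[li].name] = res.p_value if res else None
            per_locus_p[(i, j)] = row
            informative = [p for p in row.values() if p is not None]
            combined[(i, j)] = (
                combine_across_loci(informative, chain_draws=n_batches * batch_len)
                if informative
                else float("nan")
            )
            if mt:
                res = exact_g_homogeneity(
                    ds, (i, j), mt[0], seed=seed + 15485863 + 104729 * i + j,
                    n_batches=n_batches, batch_len=batch_len, burn_in=burn_in,
                )
                mtp[(i, j)] = res.p_value if res else float("nan")
    out = HomogeneityResult(
        labels=[c.name for c in ds.colonies],
        per_locus_p=per_locus_p,
        combined_p=combined,
        mtdna_p=mtp,
        alpha=alpha,
    )
    for target, flags in ((combined, out.combined_significant), (mtp, out.mtdna_significant)):
        keys = [k for k, v in target.items() if not np.isnan(v)]
        if keys:
            rej, _ = benjamini_yekutieli([target[k] for k in keys], alpha)
            for k, f in zip(keys, rej):
                flags[k] = bool(f)
    return out


def benjamini_yekutieli(pvalues, alpha: float = 0.05):
    """Benjamini-Yekutieli step-up FDR control under arbitrary dependence.

    Rejects all sorted p_(1..i*) where i* is the largest i with
    p_(i) <= i * alpha / (m * c(m)), c(m) = sum_{j=1..m} 1/j.  Returns
    ``(reject_flags, threshold)`` in the input order, where ``threshold``
    is the realised rejection threshold i* * alpha / (m * c(m)) (0.0
    when nothing is rejected).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = p.size
    cm = (1.0 / np.arange(1, m + 1)).sum()
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    crit = ranks * alpha / (m * cm)
    passed = np.flatnonzero(p[order] <= crit)
    reject = np.zeros(m, dtype=bool)
    if passed.size == 0:
        return reject, 0.0
    i_star = passed[-1]
    reject[order[: i_star + 1]] = True
    return reject, float(crit[i_star])
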