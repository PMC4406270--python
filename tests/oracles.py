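"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity by a different route from the package
(literal formula transcription, brute-force enumeration, plain-loop
permutation), so agreement is evidence of correctness rather than of
shared code.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, literal transcription
# ---------------------------------------------------------------------------


def wc_theta_literal(colony_genotypes_by_locus):
    """theta from a literal step-by-step transcription of the 1984 formulas.

    ``colony_genotypes_by_locus`` is a list over loci; each entry is a
    list over colonies of genotype lists.  A diploid genotype is a
    2-tuple of allele labels, a haploid one a 1-tuple; None is missing.
    Components are accumulated over alleles and loci; theta is the final
    ratio sum(a) / sum(a + b + c).
    """
    sum_a = 0.0
    sum_total = 0.0
    for colonies in colony_genotypes_by_locus:
        ploidy = None
        for col in colonies:
            for g in col:
                if g is not None:
                    ploidy = len(g)
                    break
            if ploidy:
                break
        if ploidy == 2:
            a, total = _diploid_locus_literal(colonies)
        else:
            a, total = _haploid_locus_literal(colonies)
        sum_a += a
        sum_total += total
    return sum_a / sum_total


def _diploid_locus_literal(colonies):
    data = [[g for g in col if g is not None] for col in colonies]
    data = [col for col in data if len(col) > 0]
    r = len(data)
    if r < 2:
        return 0.0, 0.0
    alleles = sorted({a for col in data for g in col for a in g})
    n = [len(col) for col in data]
    nbar = sum(n) / r
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    sum_a = sum_b = sum_c = 0.0
    for allele in alleles:
        p = []
        h = []
        for col in data:
            # bool() before adding: numpy bool_ + bool_ is logical-or
            copies = sum(int(bool(g[0] == allele)) + int(bool(g[1] == allele)) for g in col)
            hets = sum(1 for g in col if (allele in g) and g[0] != g[1])
            p.append(copies / (2 * len(col)))
            h.append(hets / len(col))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        sum_a += a
        sum_b += b
        sum_c += c
    return sum_a, sum_a + sum_b + sum_c


def _haploid_locus_literal(colonies):
    data = [[g[0] for g in col if g is not None] for col in colonies]
    data = [col for col in data if len(col) > 0]
    r = len(data)
    if r < 2:
        return 0.0, 0.0
    alleles = sorted({a for col in data for a in col})
    n = [len(col) for col in data]
    ntot = sum(n)
    if ntot <= r:
        return 0.0, 0.0
    nc = (ntot - sum(ni * ni for ni in n) / ntot) / (r - 1)
    sum_a = sum_w = 0.0
    for allele in alleles:
        p = [sum(1 for a in col if a == allele) / len(col) for col in data]
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / ntot
        msp = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / (r - 1)
        msg = sum(ni * pi * (1 - pi) for ni, pi in zip(n, p)) / (ntot - r)
        sum_a += (msp - msg) / nc
        sum_w += msg
    return sum_a, sum_a + sum_w


def dataset_to_nested(ds, loci=None):
    """Convert a GenotypeDataset to the nested-list form the oracle reads."""
    from clinescan.popdata import MISSING

    loc_idx = range(len(ds.loci)) if loci is None else loci
    nested = []
    for li in loc_idx:
        locus = ds.loci[li]
        per_colony = []
        for ci in range(ds.n_colonies):
            rows = ds.members(ci)
            genos = []
            for i in rows:
                call = ds.calls[li][i]
                if call[0] == MISSING:
                    genos.append(None)
                else:
                    genos.append(tuple(locus.alleles[a] for a in call))
            per_colony.append(genos)
        nested.append(per_colony)
    return nested


# ---------------------------------------------------------------------------
# brute-force exact tests
# ---------------------------------------------------------------------------


def hwe_brute_force_p(genotypes):
    """Exact Levene-ordering p by enumerating every perfect matching.

    ``genotypes`` is a list of 2-tuples of allele labels (tiny n only).
    The null law is a uniformly random matching of the labelled gene
    copies; array probabilities are matching counts over the total.
    """
    copies = [a for g in genotypes for a in g]
    n2 = len(copies)
    counts = Counter()

    def matchings(items):
        if not items:
            yield ()
            return
        first = items[0]
        for k in range(1, len(items)):
            pair = tuple(sorted((first, items[k])))
            rest = items[1:k] + items[k + 1 :]
            for m in matchings(rest):
                yield (pair,) + m

    for m in matchings(copies):
        counts[tuple(sorted(m))] += 1
    total = sum(counts.values())
    obs = tuple(sorted(tuple(sorted(g)) for g in genotypes))
    p_obs = counts[obs]
    tail = sum(v for v in counts.values() if v <= p_obs)
    return tail / total


def g_stat_plain(table):
    t = np.asarray(table, dtype=float)
    n = t.sum()
    g = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            if t[i, j] > 0:
                e = t[i].sum() * t[:, j].sum() / n
                g += 2 * t[i, j] * math.log(t[i, j] / e)
    return g


def contingency_brute_force_p(table):
    """Pr(G >= G_obs) by enumerating every permutation of column labels."""
    T = np.asarray(table, dtype=int)
    rows = [i for i in range(T.shape[0]) for _ in range(T[i].sum())]
    cols = [j for i in range(T.shape[0]) for j in range(T.shape[1]) for _ in range(T[i, j])]
    g_obs = g_stat_plain(T)
    hits = total = 0
    for perm in itertools.permutations(cols):
        M = np.zeros_like(T)
        for r, c in zip(rows, perm):
            M[r, c] += 1
        total += 1
        if g_stat_plain(M) >= g_obs - 1e-9:
            hits += 1
    return hits / total


def mantel_exact_p(A, B):
    """Exact one-tailed Mantel p over all n! relabelings, plain loops."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]

    def pair_r(X, Y):
        xs, ys = [], []
        for i in range(n):
            for j in range(i + 1, n):
                xs.append(X[i][j])
                ys.append(Y[i][j])
        xs, ys = np.array(xs), np.array(ys)
        return float(np.corrcoef(xs, ys)[0, 1])

    r_obs = pair_r(A, B)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        Bp = B[np.ix_(perm, perm)]
        total += 1
        if pair_r(A, Bp) >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / total
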