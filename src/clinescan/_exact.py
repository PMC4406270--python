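"""Exact conditional tests: enumeration and Markov-chain machinery.

Two families of conditional null distributions are handled:

* Levene's distribution of a diploid genotype array given its allele
  counts (Hardy-Weinberg exact tests).  This is exactly the law induced
  by a uniformly random perfect matching of the 2n gene copies, so the
  Markov chain walks on explicit matchings: pick two genotype pairs,
  re-match their four copies uniformly over the three perfect matchings.
  The stationary law is uniform over matchings and projects to Levene.

* The multiple hypergeometric distribution of a contingency table given
  both margins (genic G tests, genotypic-disequilibrium tests).  This is
  the law induced by uniformly permuting one margin's item labels against
  the other, so the chain is a random-transposition walk on the label
  vector.

Enumeration paths use exact Fraction arithmetic so enumeration p-values
are exact rational sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "TestResult",
    "TestNotDefinedError",
    "levene_log_prob",
    "enumerate_genotype_arrays",
    "hwe_enumeration_p",
    "hwe_chain_p",
    "g_statistic",
    "enumerate_tables",
    "count_tables",
    "table_log_prob",
    "contingency_enumeration_p",
    "contingency_chain_p",
]

_LOG_TIE_TOL = 1e-9


class TestNotDefinedError(ValueError):
    """The requested test is undefined for this input (e.g. monomorphic data)."""


@dataclass
class TestResult:
    """Outcome of an exact or Markov-chain conditional test.

    ``mc_error`` is the batch standard error of the p estimate and is
    present iff ``method == "markov_chain"``.
    """

    statistic: float
    p_value: float
    method: str
    mc_error: float | None = None
    n_batches: int | None = None


# ---------------------------------------------------------------------------
# Levene / Hardy-Weinberg
# ---------------------------------------------------------------------------


def _genotype_cells(G: np.ndarray):
    k = G.shape[0]
    return [(i, j) for i in range(k) for j in range(i, k)]


def allele_counts_from_array(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G)
    return G.sum(axis=0) + G.sum(axis=1) - np.diag(G) + np.diag(G)  # = row+col sums


def levene_log_prob(G: np.ndarray) -> float:
    """Log conditional probability of genotype array ``G`` given its allele counts.

    ``G`` is a k x k upper-triangular (or symmetric-upper) count matrix;
    cell (i, j), i <= j, counts individuals with unordered genotype {i, j}.
    """
    G = np.asarray(G)
    k = G.shape[0]
    n = int(sum(G[i, j] for i in range(k) for j in range(i, k)))
    m = [int(2 * G[i, i] + sum(G[min(i, j), max(i, j)] for j in range(k) if j != i)) for i in range(k)]
    h = int(sum(G[i, j] for i in range(k) for j in range(i + 1, k)))
    lp = math.lgamma(n + 1) + sum(math.lgamma(mi + 1) for mi in m)
    lp += h * math.log(2) - math.lgamma(2 * n + 1)
    lp -= sum(math.lgamma(G[i, j] + 1) for i in range(k) for j in range(i, k))
    return lp


def _levene_fraction(G: np.ndarray, log=False) -> Fraction:
    """Exact rational Levene probability (for enumeration paths)."""
    k = G.shape[0]
    n = int(sum(G[i, j] for i in range(k) for j in range(i, k)))
    m = [int(2 * G[i, i] + sum(G[min(i, j), max(i, j)] for j in range(k) if j != i)) for i in range(k)]
    h = int(sum(G[i, j] for i in range(k) for j in range(i + 1, k)))
    num = math.factorial(n) * 2**h
    for mi in m:
        num *= math.factorial(mi)
    den = math.factorial(2 * n)
    for i in range(k):
        for j in range(i, k):
            den *= math.factorial(int(G[i, j]))
    return Fraction(num, den)


def enumerate_genotype_arrays(allele_counts):
    """Yield every genotype array consistent with the given allele copy counts."""
    m = [int(x) for x in allele_counts]
    k = len(m)
    G = np.zeros((k, k), dtype=np.int64)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx, remaining):
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yield G.copy()
            return
        i, j = cells[idx]
        if i == j:
            hi = remaining[i] // 2
        else:
            hi = min(remaining[i], remaining[j])
        # cells are emitted row-major; once we pass allele i's last cell its
        # remainder must be zero, which the final check enforces.
        for c in range(hi + 1):
            G[i, j] = c
            if i == j:
                remaining[i] -= 2 * c
            else:
                remaining[i] -= c
                remaining[j] -= c
            if remaining[i] >= 0 and remaining[j] >= 0:
                yield from rec(idx + 1, remaining)
            if i == j:
                remaining[i] += 2 * c
            else:
                remaining[i] += c
                remaining[j] += c
        G[i, j] = 0

    yield from rec(0, m)


def hwe_enumeration_p(G_obs: np.ndarray) -> tuple[float, float]:
    """Exact Levene-probability-ordering p for a genotype array.

    Returns ``(p, log_prob_obs)``; p sums the conditional probabilities of
    all arrays no more probable than the observed one (exact rationals).
    """
    G_obs = np.asarray(G_obs)
    m = allele_counts_from_array(np.triu(G_obs))
    f_obs = _levene_fraction(G_obs)
    total = Fraction(0)
    tail = Fraction(0)
    for arr in enumerate_genotype_arrays(m):
        f = _levene_fraction(arr)
        total += f
        if f <= f_obs:
            tail += f
    p = tail / total  # total is 1 by construction; kept for safety
    return float(p), float(math.log(f_obs))


def _pairs_from_array(G: np.ndarray) -> list[list[int]]:
    pairs = []
    k = G.shape[0]
    for i in range(k):
        for j in range(i, k):
            pairs.extend([i, j] for _ in range(int(G[i, j])))
    return pairs


def hwe_chain_p(
    G_obs: np.ndarray,
    rng: np.random.Generator,
    n_batches: int = 1000,
    batch_len: int = 1000,
    burn_in: int = 10000,
) -> tuple[float, float, float]:
    """Partner-swap Markov chain estimate of the Levene-ordering p.

    Returns ``(p, mc_error, log_prob_obs)`` where ``mc_error`` is the
    standard error of the batch means.
    """
    G_obs = np.triu(np.asarray(G_obs))
    log_obs = levene_log_prob(G_obs)
    pairs = _pairs_from_array(G_obs)
    n = len(pairs)
    if n < 2:
        raise TestNotDefinedError("need at least two individuals for the chain")
    k = G_obs.shape[0]
    G = np.triu(G_obs).astype(np.int64).copy()
    # running log-probability differs from levene_log_prob by a constant;
    # track the varying terms (heterozygote count and cell factorials).
    h = int(sum(G[i, j] for i in range(k) for j in range(i + 1, k)))
    log_state = h * math.log(2) - sum(
        math.lgamma(G[i, j] + 1) for i in range(k) for j in range(i, k)
    )
    const = log_obs - (
        (sum(G_obs[i, j] for i in range(k) for j in range(i + 1, k))) * math.log(2)
        - sum(math.lgamma(G_obs[i, j] + 1) for i in range(k) for j in range(i, k))
    )

    def cell(a, b):
        return (a, b) if a <= b else (b, a)

    total_steps = burn_in + n_batches * batch_len
    idx1 = rng.integers(0, n, size=total_steps)
    idx2 = rng.integers(0, n - 1, size=total_steps)
    idx2 = np.where(idx2 >= idx1, idx2 + 1, idx2)
    which = rng.integers(0, 3, size=total_steps)

    batch_hits = np.zeros(n_batches)
    step = 0
    log_state_ref = log_state  # running value; updated in place below

    def apply_move(u, v, choice):
        nonlocal log_state_ref
        a, b = pairs[u]
        c, d = pairs[v]
        if choice == 0:
            new_u, new_v = (a, b), (c, d)
        elif choice == 1:
            new_u, new_v = (a, c), (b, d)
        else:
            new_u, new_v = (a, d), (b, c)
        old_u, old_v = cell(a, b), cell(c, d)
        nu, nv = cell(*new_u), cell(*new_v)
        if {old_u, old_v} == {nu, nv} and (old_u, old_v) == (nu, nv):
            return
        delta = 0.0
        for i, j in (old_u, old_v):
            delta -= (i != j) * math.log(2)
            delta += math.lgamma(G[i, j] + 1)
            G[i, j] -= 1
            delta -= math.lgamma(G[i, j] + 1)
        for i, j in (nu, nv):
            delta += (i != j) * math.log(2)
            delta += math.lgamma(G[i, j] + 1)
            G[i, j] += 1
            delta -= math.lgamma(G[i, j] + 1)
        log_state_ref += delta
        pairs[u][0], pairs[u][1] = nu
        pairs[v][0], pairs[v][1] = nv

    for b in range(-1, n_batches):
        steps = burn_in if b < 0 else batch_len
        hits = 0
        for _ in range(steps):
            apply_move(int(idx1[step]), int(idx2[step]), int(which[step]))
            if log_state_ref + const <= log_obs + _LOG_TIE_TOL:
                hits += 1
            step += 1
        if b >= 0:
            batch_hits[b] = hits / batch_len
    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else float("nan")
    return p, se, log_obs


# ---------------------------------------------------------------------------
# Contingency tables: G statistic, multiple hypergeometric
# ---------------------------------------------------------------------------


def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic G = 2 sum O ln(O/E) for an r x c table."""
    T = np.asarray(table, dtype=float)
    n = T.sum()
    if n == 0:
        return 0.0
    E = np.outer(T.sum(axis=1), T.sum(axis=0)) / n
    mask = T > 0
    return float(2.0 * (T[mask] * np.log(T[mask] / E[mask])).sum())


def table_log_prob(table: np.ndarray) -> float:
    """Log multiple-hypergeometric probability of a table given both margins."""
    T = np.asarray(table, dtype=np.int64)
    n = int(T.sum())
    lp = sum(math.lgamma(r + 1) for r in T.sum(axis=1))
    lp += sum(math.lgamma(c + 1) for c in T.sum(axis=0))
    lp -= math.lgamma(n + 1)
    lp -= sum(math.lgamma(v + 1) for v in T.ravel())
    return lp


def _table_fraction(T: np.ndarray) -> Fraction:
    n = int(T.sum())
    num = 1
    for r in T.sum(axis=1):
        num *= math.factorial(int(r))
    for c in T.sum(axis=0):
        num *= math.factorial(int(c))
    den = math.factorial(n)
    for v in T.ravel():
        den *= math.factorial(int(v))
    return Fraction(num, den)


def enumerate_tables(row_margins, col_margins):
    """Yield every nonnegative integer table with the given margins."""
    rows = [int(r) for r in row_margins]
    cols = [int(c) for c in col_margins]
    R, C = len(rows), len(cols)
    T = np.zeros((R, C), dtype=np.int64)

    def rec(r, remaining_cols):
        if r == R - 1:
            if all(rc >= 0 for rc in remaining_cols) and sum(remaining_cols) == rows[r]:
                T[r] = remaining_cols
                yield T.copy()
            return

        def fill(c, left):
            if c == C - 1:
                if 0 <= left <= remaining_cols[c]:
                    T[r, c] = left
                    remaining_cols[c] -= left
                    yield from rec(r + 1, remaining_cols)
                    remaining_cols[c] += left
                return
            for v in range(min(left, remaining_cols[c]) + 1):
                T[r, c] = v
                remaining_cols[c] -= v
                yield from fill(c + 1, left - v)
                remaining_cols[c] += v

        yield from fill(0, rows[r])

    yield from rec(0, cols)


def count_tables(row_margins, col_margins, cap: int = 10**6) -> int:
    """Count margin-consistent tables (stopping early at ``cap``)."""
    cnt = 0
    for _ in enumerate_tables(row_margins, col_margins):
        cnt += 1
        if cnt >= cap:
            return cnt
    return cnt


def contingency_enumeration_p(table: np.ndarray, statistic=g_statistic) -> tuple[float, float]:
    """Exact Pr(stat >= stat_obs) over margin-fixed tables (rational sum)."""
    T = np.asarray(table, dtype=np.int64)
    s_obs = statistic(T)
    tail = Fraction(0)
    total = Fraction(0)
    for cand in enumerate_tables(T.sum(axis=1), T.sum(axis=0)):
        f = _table_fraction(cand)
        total += f
        if statistic(cand) >= s_obs - 1e-9:
            tail += f
    return float(tail / total), s_obs


def contingency_chain_p(
    table: np.ndarray,
    rng: np.random.Generator,
    n_batches: int = 1000,
    batch_len: int = 1000,
    burn_in: int = 10000,
    statistic=g_statistic,
) -> tuple[float, float, float]:
    """Transposition-walk estimate of Pr(stat >= stat_obs) given both margins.

    Items carry the row labels; their column labels are permuted by random
    transpositions, whose stationary law induces the multiple
    hypergeometric on tables.  Returns ``(p, mc_error, stat_obs)``.
    """
    T = np.asarray(table, dtype=np.int64).copy()
    s_obs = statistic(T)
    rows = np.repeat(np.arange(T.shape[0]), T.sum(axis=1))
    cols = np.concatenate([np.repeat(np.arange(T.shape[1]), T[r]) for r in range(T.shape[0])])
    n = rows.shape[0]
    if n < 2:
        raise TestNotDefinedError("contingency chain needs at least two items")

    total_steps = burn_in + n_batches * batch_len
    u = rng.integers(0, n, size=total_steps)
    v = rng.integers(0, n - 1, size=total_steps)
    v = np.where(v >= u, v + 1, v)

    batch_hits = np.zeros(n_batches)
    step = 0
    for b in range(-1, n_batches):
        steps = burn_in if b < 0 else batch_len
        hits = 0
        for _ in range(steps):
            i, j = int(u[step]), int(v[step])
            ci, cj = cols[i], cols[j]
            if ci != cj:
                T[rows[i], ci] -= 1
                T[rows[i], cj] += 1
                T[rows[j], cj] -= 1
                T[rows[j], ci] += 1
                cols[i], cols[j] = cj, ci
            if statistic(T) >= s_obs - 1e-9:
                hits += 1
            step += 1
        if b >= 0:
            batch_hits[b] = hits / batch_len
    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else float("nan")
    return p, se, s_obs
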