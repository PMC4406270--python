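"""Bayesian model-based admixture clustering of multilocus genotypes.

The model assigns each gene copy a cluster of origin z; individual i
carries an admixture vector q_i on the K-simplex (symmetric
Dirichlet(alpha) prior) and cluster k carries allele frequencies p_kl
per locus.  Two frequency priors are available:

* ``uncorrelated``: p_kl ~ Dirichlet(lambda), fully conjugate;
* ``correlated`` (F-model): p_kl ~ Dirichlet(P_l * (1 - F_k)/F_k)
  around shared ancestral frequencies P_l, with per-cluster drift
  F_k ~ Uniform(0, 1).  P_l and F_k are Metropolis-updated; alpha is
  Metropolis-updated on the log scale.

Posterior means of q are the coancestry coefficients; the per-K model
score is the standard mean(L) - var(L)/2 summary of the data
log-likelihood trace, feeding the Evanno Delta-K table for choosing K.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .popdata import MISSING, GenotypeDataset

__all__ = [
    "AdmixtureConfig",
    "AdmixtureResult",
    "DeltaKTable",
    "LocusNotFittableError",
    "run_admixture",
    "ln_prob_data",
    "delta_k",
    "align_labels",
    "per_locus_q",
]


class LocusNotFittableError(ValueError):
    """Single-locus cline input cannot be produced for this locus."""


@dataclass(frozen=True)
class AdmixtureConfig:
    """Sampler settings.  Sweep counts default to desk scale; raise them
    (with ``burn_in < n_sweeps``) for production-length chains."""

    K: int = 2
    n_sweeps: int = 600
    burn_in: int = 200
    frequency_model: str = "correlated"
    alpha: float = 1.0
    alpha_proposal_sd: float = 0.3
    alpha_max: float = 10.0
    lambda_: float = 1.0
    f_proposal_sd: float = 0.3
    ancestral_proposal_conc: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("need 0 <= burn_in < n_sweeps")
        if self.frequency_model not in ("correlated", "uncorrelated"):
            raise ValueError("frequency_model must be 'correlated' or 'uncorrelated'")


@dataclass
class AdmixtureResult:
    q_mean: np.ndarray  # (n_individuals, K)
    p_mean: list  # per locus, (K, n_alleles)
    loglik_trace: np.ndarray
    ln_prob_data: float
    alpha_trace: np.ndarray
    config: AdmixtureConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.q_mean.shape[1]


def _prepare(ds: GenotypeDataset, loci, include_haploid: bool):
    if loci is None:
        idx = [
            i
            for i, l in enumerate(ds.loci)
            if l.ploidy == 2 or include_haploid
        ]
    else:
        idx = [ds.locus_index(l) if isinstance(l, str) else l for l in loci]
    idx = [i for i in idx if len(np.unique(ds.calls[i][ds.calls[i] != MISSING])) >= 2]
    if not idx:
        raise ValueError("no polymorphic locus available for clustering")
    n = ds.n_individuals
    L = len(idx)
    A = max(ds.loci[i].n_alleles for i in idx)
    codes = np.full((n, 2, L), MISSING, dtype=np.int64)
    n_alleles = np.zeros(L, dtype=int)
    for col, li in enumerate(idx):
        locus = ds.loci[li]
        n_alleles[col] = locus.n_alleles
        codes[:, : locus.ploidy, col] = ds.calls[li]
    mask = codes != MISSING
    return idx, codes, mask, n_alleles, A


def run_admixture(
    ds: GenotypeDataset,
    config: AdmixtureConfig,
    loci=None,
    include_haploid: bool = False,
) -> AdmixtureResult:
    """Gibbs sampler for the admixture model; reproducible from ``config.seed``.

    By default only diploid (microsatellite) loci enter the clustering;
    the haploid mtDNA locus is admitted with ``include_haploid=True``
    and contributes a single gene copy.
    """
    if config.K > ds.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    idx, codes, mask, n_alleles, A = _prepare(ds, loci, include_haploid)
    n, _, L = codes.shape
    K = config.K
    rng = np.random.default_rng(config.seed)

    safe_codes = np.where(mask, codes, 0)

    # initial state
    q = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
    p = np.zeros((K, L, A))
    anc = np.zeros((L, A))
    for l in range(L):
        anc[l, : n_alleles[l]] = rng.dirichlet(np.full(n_alleles[l], config.lambda_))
        for k in range(K):
            p[k, l, : n_alleles[l]] = rng.dirichlet(np.full(n_alleles[l], 1.0))
    F = rng.uniform(0.01, 0.2, size=K)
    alpha = config.alpha

    larange = np.arange(L)
    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L, A))
    logliks = np.empty(config.n_sweeps)
    alphas = np.empty(config.n_sweeps)
    acc = {"alpha": 0, "F": 0, "ancestral": 0}
    prop = {"alpha": 0, "F": 0, "ancestral": 0}

    def dirichlet_logpdf(x, a):
        # both restricted to valid alleles; x > 0 a.s.
        return gammaln(a.sum()) - gammaln(a).sum() + ((a - 1) * np.log(x)).sum()

    for sweep in range(config.n_sweeps):
        # copy-origin weights w[i, c, l, k] = q[i, k] * p[k, l, a(i,c,l)]
        pv = p[:, larange[None, None, :], safe_codes]  # (K, n, 2, L)
        w = np.moveaxis(pv, 0, -1) * q[:, None, None, :]  # (n, 2, L, K)
        tot = w.sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = float(np.log(np.where(mask, tot, 1.0)).sum())
        logliks[sweep] = loglik
        alphas[sweep] = alpha

        if K > 1:
            u = rng.random(size=tot.shape) * tot
            z = (w.cumsum(axis=-1) < u[..., None]).sum(axis=-1)
            z = np.minimum(z, K - 1)
        else:
            z = np.zeros(tot.shape, dtype=np.int64)

        # q update: Dirichlet(alpha + per-individual origin counts)
        cnt_q = np.zeros((n, K))
        for k in range(K):
            cnt_q[:, k] = ((z == k) & mask).sum(axis=(1, 2))
        if K > 1:
            g = rng.gamma(alpha + cnt_q)
            q = g / g.sum(axis=1, keepdims=True)

        # allele count per (k, l, a)
        cnt_p = np.zeros((K, L, A))
        flat_l = np.broadcast_to(larange[None, None, :], codes.shape)
        for k in range(K):
            sel = (z == k) & mask
            cnt = np.bincount(
                flat_l[sel] * A + safe_codes[sel], minlength=L * A
            ).reshape(L, A)
            cnt_p[k] = cnt

        # p update
        for l in range(L):
            al = n_alleles[l]
            for k in range(K):
                if config.frequency_model == "correlated":
                    base = anc[l, :al] * (1 - F[k]) / F[k]
                else:
                    base = np.full(al, config.lambda_)
                p[k, l, :al] = rng.dirichlet(base + cnt_p[k, l, :al])
                p[k, l, :al] = np.maximum(p[k, l, :al], 1e-300)

        if config.frequency_model == "correlated":
            # ancestral frequencies: Metropolis with a Dirichlet proposal
            for l in range(L):
                al = n_alleles[l]
                cur = anc[l, :al]
                conc = config.ancestral_proposal_conc
                prop_vec = rng.dirichlet(conc * cur + 1e-3)
                prop_vec = np.maximum(prop_vec, 1e-12)
                prop_vec = prop_vec / prop_vec.sum()

                def target(x):
                    t = (config.lambda_ - 1) * np.log(x).sum()
                    for k in range(K):
                        t += dirichlet_logpdf(p[k, l, :al], x * (1 - F[k]) / F[k])
                    return t

                lr = target(prop_vec) - target(cur)
                lr += dirichlet_logpdf(cur, conc * prop_vec + 1e-3)
                lr -= dirichlet_logpdf(prop_vec, conc * cur + 1e-3)
                prop["ancestral"] += 1
                if math.log(rng.random()) < lr:
                    anc[l, :al] = prop_vec
                    acc["ancestral"] += 1
            # drift parameters F_k: Metropolis on the logit scale
            for k in range(K):
                logit = math.log(F[k] / (1 - F[k]))
                cand = 1 / (1 + math.exp(-(logit + rng.normal(0, config.f_proposal_sd))))
                cand = min(max(cand, 1e-6), 1 - 1e-6)

                def f_target(f):
                    t = math.log(f * (1 - f))  # Jacobian of the logit transform
                    for l in range(L):
                        al = n_alleles[l]
                        t += dirichlet_logpdf(p[k, l, :al], anc[l, :al] * (1 - f) / f)
                    return t

                prop["F"] += 1
                if math.log(rng.random()) < f_target(cand) - f_target(F[k]):
                    F[k] = cand
                    acc["F"] += 1

        # alpha: Metropolis on the log scale, Uniform(0, alpha_max) prior
        if K > 1:
            cand = alpha * math.exp(rng.normal(0, config.alpha_proposal_sd))
            if cand < config.alpha_max:

                def alpha_target(a):
                    t = n * (gammaln(K * a) - K * gammaln(a))
                    t += (a - 1) * np.log(np.maximum(q, 1e-300)).sum()
                    return t + math.log(a)  # Jacobian for the log-scale walk

                prop["alpha"] += 1
                if math.log(rng.random()) < alpha_target(cand) - alpha_target(alpha):
                    alpha = cand
                    acc["alpha"] += 1

        if sweep >= config.burn_in:
            q_sum += q
            p_sum += p

    kept = config.n_sweeps - config.burn_in
    q_mean = q_sum / kept
    p_mean = [p_sum[:, l, : n_alleles[l]] / kept for l in range(L)]
    rates = {k: (acc[k] / prop[k] if prop[k] else float("nan")) for k in acc}
    return AdmixtureResult(
        q_mean=q_mean,
        p_mean=p_mean,
        loglik_trace=logliks,
        ln_prob_data=ln_prob_data(logliks, config.burn_in),
        alpha_trace=alphas,
        config=config,
        acceptance=rates,
    )


def ln_prob_data(loglik_trace, burn_in: int) -> float:
    """Model-choice score mean(L) - var(L)/2 over the post-burn-in trace.

    The variance is the sample variance (ddof=1), the convention the
    Delta-K literature assumes.
    """
    t = np.asarray(loglik_trace, dtype=float)[burn_in:]
    if t.size == 0:
        raise ValueError("empty post-burn-in trace")
    if t.size == 1:
        return float(t[0])
    return float(t.mean() - t.var(ddof=1) / 2.0)


@dataclass
class DeltaKTable:
    ks: list
    mean_ln_prob: dict
    sd_ln_prob: dict
    delta_k: dict  # interior K -> Delta K (NaN when sd == 0)
    selected_k: int | None
    tie: bool = False


def delta_k(ln_prob_by_k: dict) -> DeltaKTable:
    """Evanno Delta-K table from replicate model scores per K.

    Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K only; K with zero replicate spread are
    flagged and excluded from the argmax.
    """
    ks = sorted(ln_prob_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need at least 3 consecutive K values")
    if any(len(ln_prob_by_k[k]) < 2 for k in ks):
        raise ValueError("need at least 2 replicates per K")
    mean = {k: float(np.mean(ln_prob_by_k[k])) for k in ks}
    sd = {k: float(np.std(ln_prob_by_k[k], ddof=1)) for k in ks}
    dk = {}
    for k in ks[1:-1]:
        second = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        dk[k] = second / sd[k] if sd[k] > 0 else float("nan")
    defined = {k: v for k, v in dk.items() if not np.isnan(v)}
    if not defined:
        return DeltaKTable(ks, mean, sd, dk, None, tie=True)
    best = max(defined.values())
    winners = [k for k, v in defined.items() if v == best]
    return DeltaKTable(ks, mean, sd, dk, winners[0], tie=len(winners) > 1 or best == 0)


def align_labels(reference: AdmixtureResult, others) -> list:
    """Resolve label switching: permute each run's clusters to the reference.

    Exhaustive search over the K! permutations minimising the summed
    squared difference of q to the reference; deterministic.
    """
    K = reference.K
    aligned = []
    for run in others:
        if run.K != K or run.q_mean.shape != reference.q_mean.shape:
            raise ValueError("runs must share K and individuals")
        best_perm, best_cost = None, np.inf
        for perm in itertools.permutations(range(K)):
            cost = float(((run.q_mean[:, perm] - reference.q_mean) ** 2).sum())
            if cost < best_cost:
                best_cost, best_perm = cost, perm
        aligned.append(
            replace(
                run,
                q_mean=run.q_mean[:, best_perm],
                p_mean=[pm[list(best_perm)] for pm in run.p_mean],
            )
        )
    return aligned


def per_locus_q(
    ds: GenotypeDataset,
    config: AdmixtureConfig,
    locus,
    min_minor_count: int = 2,
) -> np.ndarray:
    """Single-locus coancestry toward the 'western' cluster (cline input).

    Runs the K=2 sampler on the one-locus dataset and orients clusters so
    cluster 1 is the one with the higher mean q in the westernmost
    colony; returns each individual's q toward that cluster.  Raises
    :class:`LocusNotFittableError` for (near-)monomorphic loci.
    """
    if config.K != 2:
        raise ValueError("per-locus coancestry requires K = 2")
    li = ds.locus_index(locus) if isinstance(locus, str) else locus
    calls = ds.calls[li]
    codes = calls[calls != MISSING]
    counts = np.bincount(codes, minlength=ds.loci[li].n_alleles)
    nz = counts[counts > 0]
    if nz.size < 2 or np.sort(nz)[-2] < min_minor_count:
        raise LocusNotFittableError(
            f"locus {ds.loci[li].name!r} is (near-)monomorphic; cline not fittable"
        )
    res = run_admixture(ds, config, loci=[li], include_haploid=True)
    west = int(np.argmin([c.position_km for c in ds.colonies]))
    members = ds.members(west)
    west_mean = res.q_mean[members].mean(axis=0)
    col = int(np.argmax(west_mean))
    return res.q_mean[:, col]
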