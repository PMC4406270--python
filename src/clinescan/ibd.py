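"""Isolation by distance: Mantel tests and reduced-major-axis regression.

Under limited dispersal at migration-drift equilibrium, linearised
theta/(1-theta) increases with geographic separation.  The association
between the genetic and geographic distance matrices is assessed with a
one-tailed Mantel permutation test; the slope is estimated by reduced
major axis (RMA) regression, slope = sign(r) * sd(y)/sd(x), appropriate
when both variables carry error, with bootstrap confidence intervals
obtained by resampling colonies (not pairs, which are non-independent).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceMatrix",
    "IbdResult",
    "mantel_test",
    "rma_fit",
    "rma_bootstrap_ci",
    "ibd_analysis",
    "regional_ibd",
    "slope_ratio",
    "pooled_pairs_slope",
]


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        i, j = np.triu_indices(self.n, 1)
        return self.values[i, j]

    def subset(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    @classmethod
    def from_positions(cls, colonies) -> "DistanceMatrix":
        pos = np.array([c.position_km for c in colonies], dtype=float)
        return cls(tuple(c.name for c in colonies), np.abs(pos[:, None] - pos[None, :]))

    @classmethod
    def from_square_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("square distance matrix must have matching row/column labels")
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


@dataclass
class IbdResult:
    r: float
    Z: float
    p: float
    slope: float
    intercept: float
    slope_ci: tuple | None
    n_pairs: int
    note: str = ""


def _pair_r(A: np.ndarray, B: np.ndarray, iu) -> float:
    a, b = A[iu], B[iu]
    return float(np.corrcoef(a, b)[0, 1])


def mantel_test(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_randomizations: int = 10000,
    seed: int = 0,
    exhaustive: bool | None = None,
):
    """One-tailed Mantel test of matrix association.

    Z = sum_{i<j} A_ij B_ij and r is the Pearson correlation over the
    n(n-1)/2 off-diagonal pairs.  The permutation distribution permutes
    one matrix's row/column order; p is the greater-tail proportion.
    When ``exhaustive`` (default: automatically for n <= 7) all n!
    relabelings are enumerated and p is exact; otherwise p = (1 +
    #{r_perm >= r_obs}) / (R + 1) over R random permutations, the
    identity included.
    """
    if genetic.labels != geographic.labels:
        raise ValueError("matrices must share the same labels in the same order")
    n = genetic.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 colonies")
    A, B = genetic.values, geographic.values
    iu = np.triu_indices(n, 1)
    if np.ptp(A[iu]) == 0 or np.ptp(B[iu]) == 0:
        raise ValueError("constant matrix: correlation undefined")
    r_obs = _pair_r(A, B, iu)
    Z = float((A[iu] * B[iu]).sum())
    if exhaustive is None:
        exhaustive = math.factorial(n) <= n_randomizations or n <= 7
    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            Bp = B[np.ix_(perm, perm)]
            total += 1
            if _pair_r(A, Bp, iu) >= r_obs - 1e-12:
                hits += 1
        return r_obs, Z, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_randomizations):
        perm = rng.permutation(n)
        if _pair_r(A, B[np.ix_(perm, perm)], iu) >= r_obs - 1e-12:
            hits += 1
    return r_obs, Z, (1 + hits) / (n_randomizations + 1)


def rma_fit(x, y) -> tuple[float, float]:
    """Reduced-major-axis line: slope = sign(r) * sd(y)/sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("RMA fit needs at least 3 pairs")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r) if r != 0 else sy / sx
    return slope, float(y.mean() - slope * x.mean())


def rma_bootstrap_ci(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_retries: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the RMA slope, resampling colonies.

    Colonies (matrix nodes) are resampled with replacement and the
    induced pairwise sets rebuilt, dropping self-pairs; draws yielding
    fewer than 3 distinct colonies or degenerate variances are redrawn
    (bounded retries).
    """
    if genetic.labels != geographic.labels:
        raise ValueError("matrices must share labels")
    n = genetic.n
    if n < 4:
        raise ValueError("bootstrap needs at least 4 colonies")
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries):
            take = rng.integers(0, n, size=n)
            if np.unique(take).size < 3:
                continue
            i, j = np.triu_indices(n, 1)
            keep = take[i] != take[j]
            x = geographic.values[take[i][keep], take[j][keep]]
            y = genetic.values[take[i][keep], take[j][keep]]
            if x.size < 3 or x.std() == 0 or y.std() == 0:
                continue
            slopes[b], _ = rma_fit(x, y)
            break
        else:
            raise RuntimeError("bootstrap failed to draw a usable resample")
    lo, hi = np.quantile(slopes, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def _ibd_for_pairs(genetic, geographic, n_randomizations, seed, with_ci, n_boot):
    iu = np.triu_indices(genetic.n, 1)
    x = geographic.values[iu]
    y = genetic.values[iu]
    r, Z, p = mantel_test(genetic, geographic, n_randomizations, seed)
    slope, intercept = rma_fit(x, y)
    ci = rma_bootstrap_ci(genetic, geographic, n_boot=n_boot, seed=seed + 1) if with_ci else None
    return IbdResult(r=r, Z=Z, p=p, slope=slope, intercept=intercept, slope_ci=ci, n_pairs=x.size)


def log_distances(geographic: DistanceMatrix) -> DistanceMatrix:
    """Log-transform off-diagonal distances (all must be positive)."""
    v = geographic.values.copy()
    off = ~np.eye(geographic.n, dtype=bool)
    if (v[off] <= 0).any():
        raise ValueError("log-distance transform requires positive off-diagonal distances")
    v[off] = np.log(v[off])
    return DistanceMatrix(geographic.labels, v)


def ibd_analysis(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_randomizations: int = 10000,
    seed: int = 0,
    with_ci: bool = True,
    n_boot: int = 1000,
    log_distance: bool = False,
) -> IbdResult:
    """Full IBD analysis on one pair set: Mantel test + RMA fit (+ slope CI).

    Distances are used untransformed by default; ``log_distance=True``
    regresses on log distance instead.
    """
    if log_distance:
        geographic = log_distances(geographic)
    return _ibd_for_pairs(genetic, geographic, n_randomizations, seed, with_ci, n_boot)


def regional_ibd(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    regions: dict,
    n_randomizations: int = 10000,
    seed: int = 0,
    with_ci: bool = False,
    n_boot: int = 1000,
) -> dict:
    """IBD analysis within each named colony subset.

    ``regions`` maps region name -> list of colony labels.  Regions with
    fewer than 4 colonies are flagged (``note='insufficient colonies'``)
    rather than fitted.  Returns region name -> IbdResult; compare
    slopes across regions with :func:`slope_ratio`.
    """
    out = {}
    for k, (name, labels) in enumerate(regions.items()):
        missing = [l for l in labels if l not in genetic.labels]
        if missing:
            raise ValueError(f"region {name!r} references unknown colonies: {missing}")
        if len(labels) < 4:
            out[name] = IbdResult(
                r=float("nan"), Z=float("nan"), p=float("nan"), slope=float("nan"),
                intercept=float("nan"), slope_ci=None,
                n_pairs=len(labels) * (len(labels) - 1) // 2,
                note="insufficient colonies",
            )
            continue
        out[name] = _ibd_for_pairs(
            genetic.subset(labels), geographic.subset(labels),
            n_randomizations, seed + 31 * k, with_ci, n_boot,
        )
    return out


def slope_ratio(results: dict, inside: str, outside: str) -> float:
    """Ratio of the RMA slopes of two named regional results."""
    return results[inside].slope / results[outside].slope


def pooled_pairs_slope(genetic: DistanceMatrix, geographic: DistanceMatrix, regions: list) -> float:
    """RMA slope over the union of within-region pair sets (cross-region pairs excluded).

    Used for 'outside the cline zone' contrasts where pairs spanning the
    zone would measure the cline itself rather than background IBD.
    """
    xs, ys = [], []
    for labels in regions:
        if len(labels) < 2:
            continue
        g = genetic.subset(labels)
        d = geographic.subset(labels)
        iu = np.triu_indices(len(labels), 1)
        xs.append(d.values[iu])
        ys.append(g.values[iu])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, _ = rma_fit(x, y)
    return slope
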