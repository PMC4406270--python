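"""Geographic cline fitting on quantitative traits along a 1-D transect.

A cline in trait y at transect position x (km) is modelled as

    y_i ~ Normal(mu(x_i), sigma^2),
    mu(x) = mu_W + (mu_E - mu_W) / (1 + exp(-4 (x - c) / w)),

with center c (inflection position) and width w defined by the
hybrid-zone convention w = (mu_E - mu_W) / (maximum slope), giving the
factor 4 in the exponent.  Traits are per-individual coancestry
coefficients (q in [0, 1]) or correspondence-analysis axis-1 haplotype
scores treated as quantitative data.

For fixed (c, w) the tail means are profiled out by linear least squares
and sigma^2 by its MLE, so the optimiser works on (c, log w) only, from
a multistart grid (the likelihood surface is multimodal in c for weak
clines).  Coincidence of cline centers across traits -- the tension-zone
prediction -- is tested by a likelihood-ratio comparison of a
shared-center model against independent per-trait fits
(chi2 = 2 * (sum free - shared), df = n_traits - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "TraitSeries",
    "ClineFit",
    "CoincidenceResult",
    "sigmoid",
    "ca_haplotype_scores",
    "fit_cline",
    "coincidence_lrt",
    "cline_report",
]


@dataclass
class TraitSeries:
    """Per-individual trait values with their colony transect positions."""

    name: str
    positions_km: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.positions_km = np.asarray(self.positions_km, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_km.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if not np.isfinite(self.positions_km).all():
            raise ValueError("positions must be finite")
        if np.unique(self.positions_km).size < 2:
            raise ValueError("need at least 2 distinct positions")


@dataclass
class ClineFit:
    name: str
    center_km: float
    width_km: float
    mu_west: float
    mu_east: float
    sigma2: float
    loglik: float
    converged: bool
    n_starts_used: int


@dataclass
class CoincidenceResult:
    loglik_free: float
    loglik_shared: float
    chi2: float
    df: int
    p: float
    shared_center_km: float
    traits_used: list
    traits_excluded: list


def sigmoid(x, center, width):
    """Sigmoid ancestry profile 1 / (1 + exp(-4 (x - c) / w))."""
    return expit(4.0 * (np.asarray(x, dtype=float) - center) / width)


# ---------------------------------------------------------------------------
# correspondence analysis of haplotypes
# ---------------------------------------------------------------------------


@dataclass
class CAScores:
    haplotype_scores: dict  # haplotype label -> axis-1 standard coordinate
    individual_scores: np.ndarray  # NaN where the haplotype call is missing
    inertia_fraction: float


def ca_haplotype_scores(ds, locus=None) -> CAScores:
    """Axis-1 correspondence-analysis scores for haplotypes.

    Performs CA of the colony x haplotype contingency table (singular
    decomposition of the standardised residual matrix); haplotypes take
    their axis-1 standard coordinates and each individual inherits its
    haplotype's score.  The sign is orientation-normalised so the
    haplotype commonest in the westernmost colony scores negative.
    ``inertia_fraction`` is axis 1's share of the total inertia.
    """
    from .popdata import MISSING

    if locus is None:
        hap = [i for i, l in enumerate(ds.loci) if l.ploidy == 1]
        if not hap:
            raise ValueError("dataset has no haploid locus")
        locus = hap[0]
    li = ds.locus_index(locus) if isinstance(locus, str) else locus
    locus_obj = ds.loci[li]
    calls = ds.calls[li][:, 0]
    ok = calls != MISSING
    if ok.sum() < 3:
        raise ValueError("need at least 3 scored individuals")
    N = np.zeros((ds.n_colonies, locus_obj.n_alleles))
    np.add.at(N, (ds.colony_of[ok], calls[ok]), 1)
    col_used = N.sum(axis=0) > 0
    row_used = N.sum(axis=1) > 0
    N = N[np.ix_(row_used, col_used)]
    if N.shape[1] < 2:
        raise ValueError("need at least 2 observed haplotypes")
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    inertia = s**2
    nontrivial = inertia > 1e-12 * inertia.max()
    inertia_fraction = float(inertia[0] / inertia[nontrivial].sum())
    # column standard coordinates on axis 1
    gamma = Vt[0] / np.sqrt(c)

    labels = [lab for lab, used in zip(locus_obj.alleles, col_used) if used]
    scores = dict(zip(labels, gamma))

    # orientation: commonest haplotype of the westernmost colony scores negative
    west = int(np.argmin([col.position_km for col in ds.colonies]))
    west_calls = calls[(ds.colony_of == west) & ok]
    if west_calls.size:
        modal = np.bincount(west_calls).argmax()
        modal_label = locus_obj.alleles[modal]
        if modal_label in scores and scores[modal_label] > 0:
            scores = {k: -v for k, v in scores.items()}
    individual = np.full(ds.n_individuals, np.nan)
    for lab, sc in scores.items():
        individual[ok & (calls == locus_obj.code_of(lab))] = sc
    return CAScores(haplotype_scores=scores, individual_scores=individual,
                    inertia_fraction=inertia_fraction)


# ---------------------------------------------------------------------------
# maximum-likelihood cline fitting
# ---------------------------------------------------------------------------


def _profiled_nll(params, x, y):
    """Negative log-likelihood at (c, log w) with mu_W, mu_E, sigma^2 profiled out."""
    c, logw = params
    w = np.exp(logw)
    s = sigmoid(x, c, w)
    X = np.column_stack([1.0 - s, s])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = y.size
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    nll = 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return nll, coef, sigma2


def _nll_only(params, x, y):
    return _profiled_nll(params, x, y)[0]


def _start_grid(x, n_centers=21, n_widths=5):
    lo, hi = float(x.min()), float(x.max())
    span = max(hi - lo, 1e-6)
    centers = np.linspace(lo, hi, n_centers)
    widths = np.geomspace(span / 100, span, n_widths)
    return [(c, np.log(w)) for c in centers for w in widths], span, lo, hi


def fit_cline(
    trait: TraitSeries,
    n_centers: int = 21,
    n_widths: int = 5,
    n_refine: int = 3,
) -> ClineFit:
    """Maximum-likelihood sigmoidal cline fit for one trait.

    Evaluates the profiled likelihood on a multistart grid of centers
    across the transect and widths over decades, then refines the best
    starts by bounded quasi-Newton.  Deterministic given the options.
    """
    x, y = trait.positions_km, trait.values
    if y.std() == 0:
        raise ValueError("trait variance is zero; cline not fittable")
    starts, span, lo, hi = _start_grid(x, n_centers, n_widths)
    scored = sorted(starts, key=lambda s: _nll_only(s, x, y))
    bounds = [(lo - span, hi + span), (np.log(span / 1000), np.log(10 * span))]
    best, success = None, False
    used = 0
    for s0 in scored[:n_refine]:
        used += 1
        res = optimize.minimize(
            _nll_only, np.array(s0), args=(x, y), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
            success = bool(res.success)
    nll, coef, sigma2 = _profiled_nll(best.x, x, y)
    c, w = float(best.x[0]), float(np.exp(best.x[1]))
    return ClineFit(
        name=trait.name,
        center_km=c,
        width_km=w,
        mu_west=float(coef[0]),
        mu_east=float(coef[1]),
        sigma2=sigma2,
        loglik=-float(nll),
        converged=success and np.isfinite(nll),
        n_starts_used=used,
    )


def coincidence_lrt(traits, n_centers: int = 21, n_widths: int = 5) -> CoincidenceResult:
    """Likelihood-ratio test of cline-center coincidence across traits.

    Free model: independent fit per trait (log-likelihoods summed).
    Shared model: one common center, all other parameters per trait.
    chi2 = 2 (free - shared) clamped at 0, df = n_traits - 1.  Traits
    that cannot be fitted are excluded with a warning and df reduced.
    """
    usable, excluded, fits = [], [], []
    for t in traits:
        try:
            fits.append(fit_cline(t, n_centers, n_widths))
            usable.append(t)
        except ValueError as exc:
            warnings.warn(f"trait {t.name!r} excluded from coincidence test: {exc}")
            excluded.append(t.name)
    if len(usable) < 2:
        raise ValueError("coincidence test needs at least 2 fittable traits")
    free_ll = sum(f.loglik for f in fits)

    xs = [t.positions_km for t in usable]
    ys = [t.values for t in usable]

    def shared_nll(params):
        c = params[0]
        return sum(
            _nll_only((c, logw), x, y) for logw, x, y in zip(params[1:], xs, ys)
        )

    allx = np.concatenate(xs)
    lo, hi = float(allx.min()), float(allx.max())
    span = max(hi - lo, 1e-6)
    bounds = [(lo - span, hi + span)] + [
        (np.log(span / 1000), np.log(10 * span)) for _ in usable
    ]
    starts = [np.concatenate([[np.mean([f.center_km for f in fits])],
                              [np.log(f.width_km) for f in fits]])]
    for f in fits:
        starts.append(np.concatenate([[f.center_km], [np.log(g.width_km) for g in fits]]))
    best = None
    for s0 in starts:
        res = optimize.minimize(shared_nll, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    shared_ll = -float(best.fun)
    chi2 = 2.0 * (free_ll - shared_ll)
    if chi2 < 0:
        if chi2 < -1e-6 * max(1.0, abs(free_ll)):
            warnings.warn("shared-center likelihood exceeded free fits; clamping chi2 at 0")
        chi2 = 0.0
    df = len(usable) - 1
    return CoincidenceResult(
        loglik_free=free_ll,
        loglik_shared=shared_ll,
        chi2=chi2,
        df=df,
        p=float(chi2_dist.sf(chi2, df)),
        shared_center_km=float(best.x[0]),
        traits_used=[t.name for t in usable],
        traits_excluded=excluded,
    )


def cline_report(fits, landmarks) -> "pandas.DataFrame":
    """Tabulate fitted clines against landmark colonies.

    ``landmarks`` maps colony name -> position_km (or is a list of
    Colony).  Each converged fit is reported with its center expressed
    relative to the nearest landmark (signed km, west negative); the
    table also carries the max - min spread of converged centers.
    """
    import pandas as pd

    if not isinstance(landmarks, dict):
        landmarks = {c.name: c.position_km for c in landmarks}
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fit to report")
    names = list(landmarks)
    pos = np.array([landmarks[n] for n in names])
    rows = []
    spread = max(f.center_km for f in conv) - min(f.center_km for f in conv)
    for f in conv:
        k = int(np.argmin(np.abs(pos - f.center_km)))
        rows.append(
            {
                "trait": f.name,
                "center_km": f.center_km,
                "width_km": f.width_km,
                "mu_west": f.mu_west,
                "mu_east": f.mu_east,
                "nearest_landmark": names[k],
                "offset_km": f.center_km - pos[k],
                "center_spread_km": spread,
            }
        )
    return pd.DataFrame(rows)
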