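"""Synthetic colony transects with the structure the analysis assumes.

The generator emulates a linear arrangement of seabird breeding colonies
sampled along ~3000 km of coastline: two diverged gene pools (a western
and an eastern lineage in secondary contact) joined by a sigmoidal
ancestry cline, with additional per-colony genetic drift.  Both
divergence processes use the Balding-Nichols Dirichlet parameterisation,
so each knob maps directly onto a theta-scale expectation:

* pool divergence: each pool's allele frequencies are drawn from a
  Dirichlet centred on a common ancestral vector with concentration
  (1 - F)/F, giving expected between-pool differentiation ~ F;
* colony drift: each colony's frequencies are drawn the same way around
  its expected cline mixture with parameter ``drift_fst``.

Genotypes are two independent allele draws per locus (Hardy-Weinberg
within colonies); the mtDNA locus is haploid with one haplotype draw per
individual.  All generating parameters are recorded in
:class:`SyntheticTruth` so recovery can be asserted against them, and a
fixed seed reproduces the dataset byte-for-byte through Genepop output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cline import TraitSeries, sigmoid
from .popdata import Colony, GenotypeDataset, Locus

__all__ = [
    "SyntheticTruth",
    "SyntheticDataset",
    "draw_pool_frequencies",
    "simulate_transect",
    "simulate_null_shared_center",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters for a synthetic transect.

    Defaults mirror the study conditions the pipeline targets: 17
    colonies of ~40 individuals along a ~3000 km transect, 12
    microsatellite loci with up to 8 alleles, a 14-haplotype mtDNA
    locus, two pools at F ~ 0.25 divergence joined by a 600 km cline
    centred mid-transect, and mild per-colony drift.
    """

    center_km: float = 1500.0
    width_km: float = 600.0
    n_colonies: int = 17
    n_per_colony: int = 40
    transect_km: float = 3000.0
    positions_km: tuple | None = None
    n_micro_loci: int = 12
    alleles_per_locus: tuple | None = None  # drawn in 2..8 from seed when None
    n_haplotypes: int = 14
    pool_divergence_fst: float = 0.25
    drift_fst: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.width_km <= 0:
            raise ValueError("width_km must be positive")
        for name in ("pool_divergence_fst", "drift_fst"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.positions_km is not None:
            pos = tuple(float(p) for p in self.positions_km)
            if len(pos) != self.n_colonies:
                raise ValueError("positions_km length must equal n_colonies")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("positions must be strictly increasing")
            object.__setattr__(self, "positions_km", pos)

    def resolved_positions(self) -> np.ndarray:
        if self.positions_km is not None:
            return np.asarray(self.positions_km, dtype=float)
        return np.linspace(0.0, self.transect_km, self.n_colonies)


@dataclass
class SyntheticDataset:
    dataset: GenotypeDataset
    truth: SyntheticTruth
    true_q: np.ndarray  # per-individual true eastern-ancestry proportion


def _balding_nichols(rng, base: np.ndarray, F: float) -> np.ndarray:
    """Dirichlet draw centred on ``base`` with concentration (1-F)/F."""
    if base.size == 1:
        return np.ones(1)
    if F == 0:
        return base.copy()
    draw = rng.dirichlet(np.maximum(base, 1e-9) * (1 - F) / F)
    return np.maximum(draw, 1e-12) / np.maximum(draw, 1e-12).sum()


def draw_pool_frequencies(n_loci, alleles_per_locus, pool_divergence_fst, seed):
    """Allele frequencies for two diverged pools at each of ``n_loci`` loci.

    A common ancestral vector per locus is drawn from a flat Dirichlet;
    each pool's vector is a Balding-Nichols draw around it at divergence
    ``pool_divergence_fst``.  F = 0 returns identical pools; monomorphic
    loci are fixed in both.  Returns ``(west, east)`` lists of arrays.
    """
    if not 0 <= pool_divergence_fst < 1:
        raise ValueError("pool divergence must lie in [0, 1)")
    if np.isscalar(alleles_per_locus):
        alleles_per_locus = [int(alleles_per_locus)] * n_loci
    if any(a < 1 for a in alleles_per_locus):
        raise ValueError("each locus needs at least one allele")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    west, east = [], []
    for a in alleles_per_locus:
        if a == 1:
            anc = np.ones(1)
        else:
            anc = rng.dirichlet(np.ones(a))
        west.append(_balding_nichols(rng, anc, pool_divergence_fst))
        east.append(_balding_nichols(rng, anc, pool_divergence_fst))
    return west, east


def simulate_transect(truth: SyntheticTruth) -> SyntheticDataset:
    """Generate a full colony dataset from the given truth; seed-reproducible."""
    rng = np.random.default_rng(truth.seed)
    positions = truth.resolved_positions()
    if truth.alleles_per_locus is not None:
        n_alleles = list(truth.alleles_per_locus)
    else:
        n_alleles = list(rng.integers(2, 9, size=truth.n_micro_loci))
    all_counts = n_alleles + [truth.n_haplotypes]
    west, east = draw_pool_frequencies(
        len(all_counts), all_counts, truth.pool_divergence_fst, rng
    )

    colonies = [Colony(f"C{i + 1:02d}", float(p)) for i, p in enumerate(positions)]
    loci = [
        Locus(f"ms{j + 1:02d}", 2, tuple(range(1, a + 1))) for j, a in enumerate(n_alleles)
    ]
    loci.append(Locus("mtDNA", 1, tuple(range(1, truth.n_haplotypes + 1))))

    q_col = sigmoid(positions, truth.center_km, truth.width_km)
    n = truth.n_colonies * truth.n_per_colony
    colony_of = np.repeat(np.arange(truth.n_colonies), truth.n_per_colony)
    true_q = q_col[colony_of]
    individuals = [
        f"{colonies[c].name}_{i + 1:03d}"
        for c in range(truth.n_colonies)
        for i in range(truth.n_per_colony)
    ]

    calls = [np.empty((n, locus.ploidy), dtype=np.int64) for locus in loci]
    for ci in range(truth.n_colonies):
        rows = np.flatnonzero(colony_of == ci)
        for li, locus in enumerate(loci):
            mix = (1 - q_col[ci]) * west[li] + q_col[ci] * east[li]
            freq = _balding_nichols(rng, mix, truth.drift_fst)
            draws = rng.choice(locus.n_alleles, size=(rows.size, locus.ploidy), p=freq)
            calls[li][rows] = draws
    ds = GenotypeDataset(loci, colonies, calls, colony_of, individuals)
    return SyntheticDataset(dataset=ds, truth=truth, true_q=true_q)


def simulate_null_shared_center(
    truth: SyntheticTruth,
    n_traits: int,
    seed: int,
    centers=None,
    widths=None,
    mu_tails=(0.0, 1.0),
    sigma: float = 0.1,
) -> list[TraitSeries]:
    """Gaussian quantitative traits whose means follow sigmoids with one center.

    Individuals sit at the truth's colony positions; each trait t has
    mean mu_W + (mu_E - mu_W) * sigmoid(x; c_t, w_t) plus Normal(0,
    sigma^2) noise.  By default every c_t equals ``truth.center_km``
    (the shared-center null used to calibrate the coincidence LRT);
    pass ``centers`` to displace them for power studies.  Widths may
    differ per trait via ``widths``.
    """
    if n_traits < 2:
        raise ValueError("coincidence is undefined for a single trait")
    rng = np.random.default_rng(seed)
    positions = np.repeat(truth.resolved_positions(), truth.n_per_colony)
    if centers is None:
        centers = [truth.center_km] * n_traits
    if widths is None:
        widths = [truth.width_km] * n_traits
    if len(centers) != n_traits or len(widths) != n_traits:
        raise ValueError("centers/widths must have one entry per trait")
    mu_w, mu_e = mu_tails
    traits = []
    for t in range(n_traits):
        mean = mu_w + (mu_e - mu_w) * sigmoid(positions, centers[t], widths[t])
        values = mean + rng.normal(0.0, sigma, size=positions.size)
        traits.append(TraitSeries(name=f"trait{t + 1}", positions_km=positions, values=values))
    return traits
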