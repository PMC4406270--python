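"""Colony-structured genotype data and Genepop-format I/O.

The containers here are the hub of the pipeline: every downstream
statistic -- diversity summaries, Weir-Cockerham theta, admixture
clustering, cline fitting -- consumes a :class:`GenotypeDataset`.
Microsatellite loci are diploid with integer allele labels; the
mitochondrial locus is haploid, its "alleles" being haplotype codes.

Allele identity is the literal label; no size binning is applied.
Transect coordinates are 1-D kilometre positions supplied with the
colony table (no geographic computation happens here).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "Locus",
    "Colony",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_colony_table",
    "write_colony_table",
    "allele_frequencies",
    "pool_colonies",
]


class GenepopParseError(ValueError):
    """Raised when a Genepop file violates the dialect this parser accepts."""


@dataclass(frozen=True)
class Locus:
    """A single locus: diploid (ploidy=2) microsatellite or haploid (ploidy=1) mtDNA.

    ``alleles`` is the ordered registry of distinct allele labels; calls are
    stored as indices into it.
    """

    name: str
    ploidy: int
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"locus {self.name!r}: ploidy must be 1 or 2, got {self.ploidy}")
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r}: allele labels must be unique")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def code_of(self, label) -> int:
        return self.alleles.index(label)


@dataclass(frozen=True)
class Colony:
    """A breeding colony with its position (km) along the 1-D coastal transect."""

    name: str
    position_km: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.position_km):
            raise ValueError(f"colony {self.name!r}: position must be finite")


class GenotypeDataset:
    """Individuals x loci genotype calls, grouped by colony.

    Parameters
    ----------
    loci : sequence of Locus
    colonies : sequence of Colony
        Colony names must be unique.
    calls : sequence of int arrays
        One array per locus, shape ``(n_individuals, ploidy)``.  Entries are
        indices into the locus allele registry, or :data:`MISSING` (-1).  A
        diploid call with either allele missing is treated as wholly missing
        and normalised to ``(-1, -1)``.
    colony_of : int array, shape (n_individuals,)
        Colony index per individual.
    individuals : sequence of str, optional
        Individual identifiers; autogenerated if omitted.
    """

    def __init__(self, loci, colonies, calls, colony_of, individuals=None):
        self.loci: list[Locus] = list(loci)
        self.colonies: list[Colony] = list(colonies)
        names = [c.name for c in self.colonies]
        if len(set(names)) != len(names):
            raise ValueError("colony names must be unique")
        self.colony_of = np.asarray(colony_of, dtype=np.intp)
        n = self.colony_of.shape[0]
        if self.colony_of.size and (self.colony_of.min() < 0 or self.colony_of.max() >= len(self.colonies)):
            raise ValueError("colony_of contains an index outside the colony list")
        if individuals is None:
            individuals = [f"ind{i + 1}" for i in range(n)]
        self.individuals = list(individuals)
        if len(self.individuals) != n:
            raise ValueError("individuals and colony_of lengths differ")
        if len(calls) != len(self.loci):
            raise ValueError("one call array per locus required")
        self.calls: list[np.ndarray] = []
        for locus, arr in zip(self.loci, calls):
            a = np.array(arr, dtype=np.int32)
            if a.shape != (n, locus.ploidy):
                raise ValueError(
                    f"locus {locus.name!r}: calls must have shape {(n, locus.ploidy)}, got {a.shape}"
                )
            if a.size and (a.max() >= locus.n_alleles or a.min() < MISSING):
                raise ValueError(f"locus {locus.name!r}: allele code out of range")
            if locus.ploidy == 2:
                partial = (a == MISSING).any(axis=1)
                a[partial] = MISSING
            self.calls.append(a)

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    def colony_index(self, name: str) -> int:
        for i, c in enumerate(self.colonies):
            if c.name == name:
                return i
        raise KeyError(f"unknown colony {name!r}")

    def locus_index(self, name: str) -> int:
        for i, l in enumerate(self.loci):
            if l.name == name:
                return i
        raise KeyError(f"unknown locus {name!r}")

    def colony_sizes(self) -> np.ndarray:
        return np.bincount(self.colony_of, minlength=self.n_colonies)

    def members(self, colony) -> np.ndarray:
        """Indices of the individuals belonging to ``colony`` (name or index)."""
        if isinstance(colony, str):
            colony = self.colony_index(colony)
        return np.flatnonzero(self.colony_of == colony)

    def positions(self) -> np.ndarray:
        return np.array([c.position_km for c in self.colonies], dtype=float)

    # -- restructuring -------------------------------------------------

    def subset(self, colonies=None, loci=None) -> "GenotypeDataset":
        """Restrict to the named colonies and/or loci (order as given)."""
        if colonies is None:
            col_idx = list(range(self.n_colonies))
        else:
            col_idx = [self.colony_index(c) if isinstance(c, str) else c for c in colonies]
        if loci is None:
            loc_idx = list(range(len(self.loci)))
        else:
            loc_idx = [self.locus_index(l) if isinstance(l, str) else l for l in loci]
        keep = np.isin(self.colony_of, col_idx)
        remap = {old: new for new, old in enumerate(col_idx)}
        new_colony_of = np.array([remap[c] for c in self.colony_of[keep]], dtype=np.intp)
        return GenotypeDataset(
            [self.loci[i] for i in loc_idx],
            [self.colonies[i] for i in col_idx],
            [self.calls[i][keep] for i in loc_idx],
            new_colony_of,
            [ind for ind, k in zip(self.individuals, keep) if k],
        )

    def with_colonies(self, colonies) -> "GenotypeDataset":
        """Replace colony metadata (e.g. attach transect positions), by order."""
        colonies = list(colonies)
        if len(colonies) != self.n_colonies:
            raise ValueError("replacement colony list has the wrong length")
        return GenotypeDataset(self.loci, colonies, self.calls, self.colony_of, self.individuals)

    def equals(self, other: "GenotypeDataset") -> bool:
        """Structural equality on labels and calls (allele registry order ignored)."""
        if [l.name for l in self.loci] != [l.name for l in other.loci]:
            return False
        if [(c.name, c.position_km) for c in self.colonies] != [
            (c.name, c.position_km) for c in other.colonies
        ]:
            return False
        if self.individuals != other.individuals or not np.array_equal(self.colony_of, other.colony_of):
            return False
        for ls, lo, cs, co in zip(self.loci, other.loci, self.calls, other.calls):
            if ls.ploidy != lo.ploidy:
                return False
            for row_s, row_o in zip(cs, co):
                lab_s = sorted(MISSING if a == MISSING else ls.alleles[a] for a in row_s)
                lab_o = sorted(MISSING if a == MISSING else lo.alleles[a] for a in row_o)
                if lab_s != lab_o:
                    return False
        return True


@dataclass
class AlleleFrequencyTable:
    """Allele copy counts per (colony, locus); the substrate for every statistic.

    ``counts[l]`` has shape ``(n_colonies, n_alleles_l)`` and holds integer
    gene-copy counts, so pooling colonies is exact integer addition.
    """

    loci: list[Locus]
    colonies: list[Colony]
    counts: list[np.ndarray]

    def n(self, colony: int, locus: int) -> int:
        """Number of gene copies sampled (ploidy x non-missing individuals)."""
        return int(self.counts[locus][colony].sum())

    def freq(self, colony: int, locus: int) -> np.ndarray:
        """Relative frequencies; empty vector when no copies were sampled."""
        c = self.counts[locus][colony]
        tot = c.sum()
        if tot == 0:
            return np.empty(0)
        return c / tot

    def to_frame(self):
        import pandas as pd

        rows = []
        for li, locus in enumerate(self.loci):
            for ci, colony in enumerate(self.colonies):
                c = self.counts[li][ci]
                tot = c.sum()
                for ai, label in enumerate(locus.alleles):
                    rows.append(
                        {
                            "colony": colony.name,
                            "locus": locus.name,
                            "allele": label,
                            "count": int(c[ai]),
                            "frequency": c[ai] / tot if tot else np.nan,
                            "n_copies": int(tot),
                        }
                    )
        return pd.DataFrame(rows)


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Count allele copies per (colony, locus) over non-missing calls."""
    counts = []
    for locus, calls in zip(ds.loci, ds.calls):
        cnt = np.zeros((ds.n_colonies, locus.n_alleles), dtype=np.int64)
        for copy in range(locus.ploidy):
            codes = calls[:, copy]
            ok = codes != MISSING
            np.add.at(cnt, (ds.colony_of[ok], codes[ok]), 1)
        counts.append(cnt)
    return AlleleFrequencyTable(list(ds.loci), list(ds.colonies), counts)


def pool_colonies(ds: GenotypeDataset, names, new_name: str, new_position_km: float) -> GenotypeDataset:
    """Merge the named colonies into one (e.g. the Spencer Gulf composite sample).

    Individuals are reassigned to the pooled colony, which takes the list
    position of the first pooled colony; all other colonies are untouched.
    """
    idx = [ds.colony_index(n) for n in names]
    first = min(range(len(idx)), key=lambda k: idx[k])
    anchor = idx[first]
    pooled = Colony(new_name, new_position_km)
    new_colonies, remap = [], {}
    for i, c in enumerate(ds.colonies):
        if i == anchor:
            remap[i] = len(new_colonies)
            new_colonies.append(pooled)
        elif i in idx:
            continue
        else:
            remap[i] = len(new_colonies)
            new_colonies.append(c)
    for i in idx:
        remap[i] = remap[anchor]
    new_colony_of = np.array([remap[c] for c in ds.colony_of], dtype=np.intp)
    return GenotypeDataset(ds.loci, new_colonies, ds.calls, new_colony_of, ds.individuals)


# ---------------------------------------------------------------------------
# Genepop I/O
#
# Dialect: title line; locus names one per line (or comma-separated on one
# line); "POP" separators; individual lines "id , 0101 0202 ...".  Per-allele
# encoding is 2 or 3 digits, detected per locus from the first non-missing
# call; "00"/"000" is missing.  Haploid loci use single codes.
# ---------------------------------------------------------------------------


def _is_pop_line(line: str) -> bool:
    return line.strip().lower() == "pop"


def read_genepop(path) -> GenotypeDataset:
    """Parse a Genepop file into a :class:`GenotypeDataset`.

    One colony per POP block, named ``pop1..popN`` with position 0 (attach
    real names/positions via :meth:`GenotypeDataset.with_colonies`).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if len(lines) < 3:
        raise GenepopParseError("file too short to be a Genepop file")
    # title
    body = lines[1:]
    locus_names: list[str] = []
    pos = 0
    while pos < len(body) and not _is_pop_line(body[pos][1]):
        chunk = body[pos][1].strip()
        locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        pos += 1
    if not locus_names:
        raise GenepopParseError("no locus names before first POP line")
    if pos == len(body):
        raise GenepopParseError("no POP line found")

    n_loci = len(locus_names)
    digits = [None] * n_loci  # per-locus encoding width, detected lazily
    ploidy = [None] * n_loci
    pop_calls: list[list[list[tuple]]] = []  # per pop, per individual, per locus labels
    indiv_ids: list[list[str]] = []
    cur = None
    for lineno, line in body[pos:]:
        if _is_pop_line(line):
            if cur is not None and not cur:
                raise GenepopParseError(f"line {lineno}: empty POP block")
            cur = []
            pop_calls.append(cur)
            indiv_ids.append([])
            continue
        if cur is None:
            raise GenepopParseError(f"line {lineno}: genotype data before first POP")
        if "," in line:
            ident, geno = line.split(",", 1)
            ident = ident.strip()
        else:
            raise GenepopParseError(f"line {lineno}: expected 'id , genotypes'")
        tokens = geno.split()
        if len(tokens) != n_loci:
            raise GenepopParseError(
                f"line {lineno}: expected {n_loci} genotype fields, found {len(tokens)}"
            )
        row = []
        for li, tok in enumerate(tokens):
            if not tok.isdigit():
                raise GenepopParseError(f"line {lineno}: non-numeric genotype {tok!r}")
            if len(tok) in (2, 3):
                pl, width = 1, len(tok)
            elif len(tok) in (4, 6):
                pl, width = 2, len(tok) // 2
            else:
                raise GenepopParseError(f"line {lineno}: genotype {tok!r} has invalid width")
            if ploidy[li] is None:
                ploidy[li], digits[li] = pl, width
            elif (ploidy[li], digits[li]) != (pl, width):
                raise GenepopParseError(
                    f"line {lineno}: locus {locus_names[li]!r} mixes "
                    f"{digits[li]}-digit and {width}-digit (or ploidy) encodings"
                )
            labels = tuple(int(tok[k * width : (k + 1) * width]) for k in range(pl))
            if pl == 2 and (labels[0] == 0) != (labels[1] == 0):
                labels = (0, 0)  # partial call treated as missing
            row.append(labels)
        cur.append(row)
        indiv_ids[-1].append(ident)
    if cur is not None and not cur:
        raise GenepopParseError("trailing empty POP block")
    if not pop_calls:
        raise GenepopParseError("no POP blocks found")

    # build allele registries from observed labels (sorted, deterministic)
    loci = []
    for li, name in enumerate(locus_names):
        seen = set()
        for pop in pop_calls:
            for row in pop:
                seen.update(a for a in row[li] if a != 0)
        if not seen:
            seen = {1}  # locus never scored; placeholder allele
        loci.append(Locus(name, ploidy[li] or 2, tuple(sorted(seen))))

    colonies = [Colony(f"pop{p + 1}", 0.0) for p in range(len(pop_calls))]
    colony_of = np.concatenate(
        [np.full(len(pop), p, dtype=np.intp) for p, pop in enumerate(pop_calls)]
    )
    individuals = [i for ids in indiv_ids for i in ids]
    calls = []
    for li, locus in enumerate(loci):
        code = {lab: k for k, lab in enumerate(locus.alleles)}
        arr = np.full((len(individuals), locus.ploidy), MISSING, dtype=np.int32)
        r = 0
        for pop in pop_calls:
            for row in pop:
                arr[r] = [MISSING if a == 0 else code[a] for a in row[li]]
                r += 1
        calls.append(arr)
    return GenotypeDataset(loci, colonies, calls, colony_of, individuals)


def write_genepop(ds: GenotypeDataset, path, title: str = "clinescan dataset") -> None:
    """Write a dataset in Genepop format (2- or 3-digit codes as labels require)."""
    widths = []
    for locus in ds.loci:
        mx = max(locus.alleles)
        if mx > 999 or min(locus.alleles) < 1:
            raise ValueError(f"locus {locus.name!r}: allele labels must be in 1..999 for Genepop")
        widths.append(3 if mx > 99 else 2)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in ds.loci:
            fh.write(locus.name + "\n")
        for ci in range(ds.n_colonies):
            fh.write("POP\n")
            for i in ds.members(ci):
                toks = []
                for locus, calls, w in zip(ds.loci, ds.calls, widths):
                    labels = [
                        0 if a == MISSING else locus.alleles[a] for a in calls[i]
                    ]
                    toks.append("".join(f"{lab:0{w}d}" for lab in labels))
                fh.write(f"{ds.individuals[i]} , " + " ".join(toks) + "\n")


def read_colony_table(path) -> list[Colony]:
    """Read a delimited colony table with header columns ``name`` and ``position_km``."""
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if not sample.strip():
            raise ValueError(f"{path}: empty colony table")
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not {"name", "position_km"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: header must contain 'name' and 'position_km'")
        colonies = []
        seen = set()
        for row in reader:
            name = row["name"].strip()
            if name in seen:
                raise ValueError(f"duplicate colony name {name!r}")
            seen.add(name)
            try:
                pos = float(row["position_km"])
            except ValueError as exc:
                raise ValueError(f"colony {name!r}: non-numeric position {row['position_km']!r}") from exc
            colonies.append(Colony(name, pos))
    if not colonies:
        raise ValueError(f"{path}: colony table has a header but no rows")
    return colonies


def write_colony_table(colonies, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tposition_km\n")
        for c in colonies:
            fh.write(f"{c.name}\t{c.position_km:g}\n")
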