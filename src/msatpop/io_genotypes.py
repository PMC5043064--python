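"""Genotype data model and file I/O.

Codominant diploid multilocus genotypes are held in a
:class:`GenotypeDataset`: an individuals x loci x 2 integer array of
allele sizes (base pairs), with 0 as the missing sentinel, plus
per-individual population and species labels. Readers/writers cover the
GENEPOP text dialect (2- or 3-digit fixed-width allele codes) and a
long-format CSV. :func:`allele_frequencies` builds the per-(population,
locus) frequency table that every downstream estimator reads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Missing-allele sentinel. A genotype is either fully typed (both
#: alleles positive) or fully missing (both 0); half-missing calls are
#: rejected at parse time.
MISSING = 0


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files; names the offending line."""


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with population and species labels.

    Parameters
    ----------
    individuals : list of str
        Individual identifiers, one per row of ``calls``.
    populations : list of str
        Population code for each individual (e.g. ``"CHN.QLH"``).
    species : list of str
        Species label for each individual.
    loci : list of str
        Ordered locus names; unique and non-empty.
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Integer allele sizes in base pairs; 0 encodes missing. Each
        genotype is stored sorted so the pair is unordered.
    """

    individuals: list[str]
    populations: list[str]
    species: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        n, l = self.calls.shape[:2]
        if not (len(self.individuals) == len(self.populations) == len(self.species) == n):
            raise ValueError("individuals/populations/species lengths must match calls")
        if len(self.loci) != l:
            raise ValueError("loci length must match calls")
        if not self.loci:
            raise ValueError("locus list must be non-empty")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        if np.any(self.calls < 0):
            raise ValueError("allele sizes must be positive or 0 (missing)")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise ValueError("half-missing genotypes are not allowed")
        # normalize unordered pairs
        self.calls = np.sort(self.calls, axis=2)

    # -- basic structure -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def population_order(self) -> list[str]:
        """Unique population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def species_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.populations:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def indices_of(self, population: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.populations) if p == population])
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in dataset")
        return idx

    def subset(self, *, populations: list[str] | None = None,
               species: str | None = None) -> "GenotypeDataset":
        keep = np.ones(self.n_individuals, dtype=bool)
        if populations is not None:
            popset = set(populations)
            keep &= np.array([p in popset for p in self.populations])
        if species is not None:
            keep &= np.array([s == species for s in self.species])
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            raise ValueError("subset selects no individuals")
        return GenotypeDataset(
            [self.individuals[i] for i in idx],
            [self.populations[i] for i in idx],
            [self.species[i] for i in idx],
            list(self.loci),
            self.calls[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.species == other.species
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleFrequencyTable:
    """Per-(population, locus) allele counts and frequencies.

    ``counts[(pop, locus)]`` maps allele size -> number of gene copies
    among fully typed individuals; ``gene_count`` is twice the typed
    individual count and frequencies are counts normalized by it.
    """

    populations: list[str]
    loci: list[str]
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)
    typed: dict[tuple[str, str], int] = field(default_factory=dict)

    def gene_count(self, population: str, locus: str) -> int:
        return 2 * self.typed[(population, locus)]

    def typed_n(self, population: str, locus: str) -> int:
        return self.typed[(population, locus)]

    def allele_counts(self, population: str, locus: str) -> dict[int, int]:
        return self.counts[(population, locus)]

    def freqs(self, population: str, locus: str) -> dict[int, float]:
        c = self.counts[(population, locus)]
        g = self.gene_count(population, locus)
        if g == 0:
            return {}
        return {a: k / g for a, k in c.items()}

    def alleles(self, locus: str) -> list[int]:
        """All allele sizes seen at a locus across populations, sorted."""
        out: set[int] = set()
        for p in self.populations:
            out.update(self.counts[(p, locus)])
        return sorted(out)


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Tabulate allele counts per (population, locus).

    A genotype contributes both gene copies or none: missing genotypes
    are excluded entirely, so gene_count = 2 x typed individuals. A
    (population, locus) cell with no typed individuals yields an empty
    count map (not an error).
    """
    table = AlleleFrequencyTable(ds.population_order(), list(ds.loci))
    for pop in table.populations:
        idx = ds.indices_of(pop)
        for j, locus in enumerate(ds.loci):
            g = ds.calls[idx, j, :]
            typed = g[g[:, 0] != MISSING]
            counts: dict[int, int] = {}
            for a in typed.ravel().tolist():
                counts[a] = counts.get(a, 0) + 1
            table.counts[(pop, locus)] = counts
            table.typed[(pop, locus)] = typed.shape[0]
    return table


# ---------------------------------------------------------------------------
# GENEPOP format
# ---------------------------------------------------------------------------

def _detect_digits(code: str) -> int:
    if len(code) % 2 or len(code) not in (4, 6):
        raise ValueError(f"cannot infer allele digit width from code {code!r}")
    return len(code) // 2


def _infer_pop_code(name: str) -> tuple[str, str]:
    """Split ``"<pop>_<id>"`` into (pop, id); names without an
    underscore map to (name, name)."""
    if "_" in name:
        pop, rest = name.split("_", 1)
        return pop, rest
    return name, name


def read_genepop(path: str | Path, allele_digits: int | None = None,
                 species: str | None = None,
                 pop_names: list[str] | None = None) -> GenotypeDataset:
    """Read a GENEPOP file.

    The dialect: a title line; locus names one per line (or one
    comma-separated line); population blocks delimited by lines equal to
    ``pop`` (case-insensitive); individual lines ``name , a1a2 a1a2 ...``
    with fixed-width 2- or 3-digit allele codes, ``00``/``000`` missing.
    Digit width is auto-detected from the first genotype unless
    ``allele_digits`` is given.

    GENEPOP carries no explicit population names. If ``pop_names`` is
    not supplied, the code for each block is inferred from the final
    individual's name: the part before the first underscore (the whole
    name if there is none), matching this package's writer which emits
    names as ``<pop>_<individual>``. Species labels are not part of the
    format; ``species`` applies to the whole file (default the title
    line's first token).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    title = lines[0].strip()

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(tok.strip() for tok in chunk.split(",") if tok.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no 'pop' line found")
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first 'pop'")

    blocks: list[list[tuple[str, list[str], int]]] = []
    current: list[tuple[str, list[str], int]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            if current is not None:
                if not current:
                    raise GenotypeParseError(f"{path}:{lineno + 1}: empty population block")
                blocks.append(current)
            current = []
            continue
        if current is None:
            raise GenotypeParseError(f"{path}:{lineno + 1}: data before first 'pop'")
        if "," not in raw:
            raise GenotypeParseError(f"{path}:{lineno + 1}: missing ',' separator")
        name, _, geno_part = raw.partition(",")
        codes = geno_part.split()
        current.append((name.strip(), codes, lineno + 1))
    if current:
        blocks.append(current)
    if not blocks:
        raise GenotypeParseError(f"{path}: no individuals")

    digits = allele_digits
    if digits is None:
        digits = _detect_digits(blocks[0][0][1][0])
    if digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")

    individuals: list[str] = []
    populations: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    sp = species if species is not None else (title.split()[0] if title else "unspecified")
    for b, block in enumerate(blocks):
        if pop_names is not None:
            pop = pop_names[b]
        else:
            pop = _infer_pop_code(block[-1][0])[0]
        for name, codes, lineno in block:
            if len(codes) != len(loci):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(loci)} genotypes, got {len(codes)}")
            row: list[tuple[int, int]] = []
            for code, locus in zip(codes, loci):
                if len(code) != 2 * digits:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: genotype code {code!r} at locus "
                        f"{locus} is not {2 * digits} digits")
                try:
                    a1 = int(code[:digits])
                    a2 = int(code[digits:])
                except ValueError:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: non-numeric genotype code {code!r}") from None
                if (a1 == 0) != (a2 == 0):
                    raise GenotypeParseError(
                        f"{path}:{lineno}: half-missing genotype {code!r} at locus {locus}")
                row.append((a1, a2))
            ind_id = name
            if pop_names is None and name.startswith(pop + "_"):
                ind_id = name[len(pop) + 1:]
            individuals.append(ind_id)
            populations.append(pop)
            calls.append(row)
    arr = np.array(calls, dtype=np.int32)
    return GenotypeDataset(individuals, populations, [sp] * len(individuals), loci, arr)


def write_genepop(ds: GenotypeDataset, path: str | Path,
                  allele_digits: int = 3, title: str | None = None) -> None:
    """Write a GENEPOP file that re-parses to an identical dataset.

    Individual lines are named ``<pop>_<individual>`` so the reader can
    recover population codes without a sidecar. Raises if any allele
    size does not fit in ``allele_digits`` digits.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    limit = 10 ** allele_digits - 1
    if int(ds.calls.max(initial=0)) > limit:
        raise ValueError(
            f"allele size {int(ds.calls.max())} does not fit in {allele_digits} digits")
    path = Path(path)
    out = [title if title is not None else (ds.species[0] if ds.species else "msatpop dataset")]
    out.extend(ds.loci)
    pops = ds.population_order()
    for pop in pops:
        out.append("pop")
        for i in ds.indices_of(pop):
            codes = " ".join(
                f"{a1:0{allele_digits}d}{a2:0{allele_digits}d}"
                for a1, a2 in ds.calls[i].tolist()
            )
            out.append(f"{pop}_{ds.individuals[i]} , {codes}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------

_CSV_COLS = ["individual", "population", "species", "locus", "allele1", "allele2"]


def read_long_csv(path: str | Path) -> GenotypeDataset:
    """Read a long-format CSV with one row per (individual, locus).

    Columns: individual, population, species, locus, allele1, allele2.
    Missing alleles are empty strings, ``NA`` or ``0``; a genotype must
    be fully typed or fully missing. Duplicate (individual, locus) rows
    are an error. Individuals appear in first-seen order, loci in
    first-seen order.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_COLS:
            raise GenotypeParseError(
                f"{path}: expected columns {_CSV_COLS}, got {reader.fieldnames}")
        # individuals are identified by (name, population): ids need only
        # be unique within a population
        ind_index: dict[tuple[str, str], int] = {}
        ind_meta: list[tuple[str, str, str]] = []
        loci_index: dict[str, int] = {}
        cells: dict[tuple[int, int], tuple[int, int]] = {}
        for lineno, row in enumerate(reader, start=2):
            ind = row["individual"].strip()
            pop = row["population"].strip()
            sp = row["species"].strip()
            locus = row["locus"].strip()
            ikey = (ind, pop)
            if ikey not in ind_index:
                ind_index[ikey] = len(ind_meta)
                ind_meta.append((ind, pop, sp))
            elif ind_meta[ind_index[ikey]][2] != sp:
                raise GenotypeParseError(
                    f"{path}:{lineno}: individual {ind!r} has conflicting labels")
            if locus not in loci_index:
                loci_index[locus] = len(loci_index)
            key = (ind_index[ikey], loci_index[locus])
            if key in cells:
                raise GenotypeParseError(
                    f"{path}:{lineno}: duplicate row for ({ind!r}, {locus!r})")

            def parse(v: str) -> int:
                v = v.strip()
                if v in ("", "NA", "na", "0"):
                    return MISSING
                return int(v)

            a1, a2 = parse(row["allele1"]), parse(row["allele2"])
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeParseError(
                    f"{path}:{lineno}: half-missing genotype for ({ind!r}, {locus!r})")
            cells[key] = (a1, a2)
    if not cells:
        raise GenotypeParseError(f"{path}: no data rows")
    n, l = len(ind_meta), len(loci_index)
    arr = np.zeros((n, l, 2), dtype=np.int32)
    for (i, j), (a1, a2) in cells.items():
        arr[i, j] = (a1, a2)
    individuals = [m[0] for m in ind_meta]
    loci = list(loci_index)
    pops = [m[1] for m in ind_meta]
    sps = [m[2] for m in ind_meta]
    return GenotypeDataset(individuals, pops, sps, loci, arr)


def write_long_csv(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the long-format CSV; missing genotypes as empty cells."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLS)
        for i in range(ds.n_individuals):
            for j, locus in enumerate(ds.loci):
                a1, a2 = (int(v) for v in ds.calls[i, j])
                w.writerow([
                    ds.individuals[i], ds.populations[i], ds.species[i], locus,
                    "" if a1 == MISSING else a1, "" if a2 == MISSING else a2,
                ])
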