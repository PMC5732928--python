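"""Core domain types and file I/O.

The pipeline works on three in-memory containers:

* :class:`GenotypeMatrix` — diploid multilocus microsatellite genotypes
  (integer allele codes, typically fragment lengths in bp);
* :class:`SampleMetadata` — per-individual collection site and sex;
* :class:`HaplotypeAlignment` — an aligned set of mtDNA control-region
  sequences with the haplotype collapse and per-site mutation classes.

File formats: GenePop (``.gen``) for genotypes, FASTA for alignments and a
``id,site,sex`` sidecar CSV for metadata (GenePop has no sex field).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: Allele code used for a missing call.  GenePop writes "000"/"0000"/"000000".
MISSING = 0

DNA_ALPHABET = set("ACGTN-")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

VALID_SEX = {"F", "M", "U"}


class ParseError(ValueError):
    """Raised on malformed input files; message carries the line number."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid allele calls.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with positive integer
    allele codes, canonicalized so that ``calls[..., 0] <= calls[..., 1]``.
    A missing call is ``(0, 0)``; half-missing calls are not representable
    (the GenePop dialect has none).
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if len(self.individuals) < 1 or len(self.loci) < 1:
            raise ValueError("need at least 1 individual and 1 locus")
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs")
        if np.any(self.calls < 0):
            raise ValueError("allele codes must be positive (0 = missing)")
        # one allele of a pair missing and the other not is malformed
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("half-missing genotype call")
        self.calls = np.sort(self.calls, axis=2)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(list(ids), list(self.loci), self.calls[idx].copy())

    def allele_counts(self, locus: str | int) -> dict[int, int]:
        """Counts of each allele at a locus (missing calls excluded)."""
        j = locus if isinstance(locus, int) else self.locus_index(locus)
        col = self.calls[:, j, :].ravel()
        col = col[col != MISSING]
        alleles, counts = np.unique(col, return_counts=True)
        return dict(zip(alleles.tolist(), counts.tolist()))

    def allele_freqs(self, locus: str | int) -> dict[int, float]:
        counts = self.allele_counts(locus)
        total = sum(counts.values())
        if total == 0:
            return {}
        return {a: c / total for a, c in counts.items()}


@dataclass
class SampleMetadata:
    """Per-individual site label and sex (``F``/``M``/``U``)."""

    site: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.site:
            self.sex.setdefault(ind, "U")
        bad = {s for s in self.sex.values() if s not in VALID_SEX}
        if bad:
            raise ValueError(f"invalid sex codes {bad}; expected F/M/U")

    @property
    def individuals(self) -> list[str]:
        return list(self.site)

    def populations(self) -> list[str]:
        """Distinct site labels in first-appearance order."""
        return list(dict.fromkeys(self.site.values()))

    def members(self, population: str) -> list[str]:
        return [i for i, s in self.site.items() if s == population]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleMetadata":
        site: dict[str, str] = {}
        sex: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames:
                raise ParseError(f"{path}: metadata CSV needs an 'id' column")
            for row in reader:
                ind = row["id"].strip()
                site[ind] = row.get("site", "").strip() or "unknown"
                sex[ind] = (row.get("sex", "") or "U").strip().upper() or "U"
        return cls(site, sex)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "site", "sex"])
            for ind in self.site:
                writer.writerow([ind, self.site[ind], self.sex.get(ind, "U")])


# ---------------------------------------------------------------------------
# HaplotypeAlignment
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeAlignment:
    """Aligned mtDNA sequences with haplotype collapse and site classes.

    Sites carrying a gap (``-``) or ambiguous base (``N``) in *any* sequence
    are excluded from polymorphism counting, diversity statistics and network
    construction (complete deletion).  The haplotype collapse itself uses the
    full sequence strings, so two sequences differing only at an excluded
    site remain distinct haplotypes.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        bad = set().union(*(set(s) for s in self.sequences.values())) - DNA_ALPHABET
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")
        self._build()

    def _build(self) -> None:
        ids = list(self.sequences)
        seqs = [self.sequences[i] for i in ids]
        arr = np.array([list(s) for s in seqs])
        self.length = arr.shape[1]
        # complete deletion: drop columns with any gap or N
        clean = ~np.any((arr == "-") | (arr == "N"), axis=0)
        self.usable_sites = np.flatnonzero(clean)
        # haplotype collapse on exact full-length identity, IDs 1..h in
        # order of first appearance
        hap_of: dict[str, int] = {}
        self.haplotype_index: dict[str, int] = {}
        for ind, s in zip(ids, seqs):
            if s not in hap_of:
                hap_of[s] = len(hap_of) + 1
            self.haplotype_index[ind] = hap_of[s]
        self.haplotypes = list(hap_of)  # haplotype id i -> self.haplotypes[i-1]
        # polymorphic usable sites and per-mutation transition/transversion
        self.polymorphic_sites: list[int] = []
        self.site_classes: dict[int, list[str]] = {}
        sub = arr[:, self.usable_sites]
        for col_i, site in enumerate(self.usable_sites):
            states, counts = np.unique(sub[:, col_i], return_counts=True)
            if len(states) < 2:
                continue
            self.polymorphic_sites.append(int(site))
            major = states[np.argmax(counts)]
            classes = []
            for st in states:
                if st == major:
                    continue
                same_class = ({st, major} <= PURINES) or ({st, major} <= PYRIMIDINES)
                classes.append("transition" if same_class else "transversion")
            self.site_classes[int(site)] = classes

    # -- summaries ---------------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_segregating_sites(self) -> int:
        return len(self.polymorphic_sites)

    def mutation_counts(self) -> tuple[int, int]:
        """(transitions, transversions) summed over polymorphic sites.

        A site with ``s`` observed states carries ``s - 1`` mutations, each
        classified against the site's majority base.
        """
        ts = sum(c.count("transition") for c in self.site_classes.values())
        tv = sum(c.count("transversion") for c in self.site_classes.values())
        return ts, tv

    def haplotype_frequencies(self) -> np.ndarray:
        counts = np.zeros(self.n_haplotypes, dtype=int)
        for h in self.haplotype_index.values():
            counts[h - 1] += 1
        return counts

    def site_matrix(self) -> np.ndarray:
        """Character matrix restricted to usable polymorphic sites."""
        ids = list(self.sequences)
        arr = np.array([list(self.sequences[i]) for i in ids])
        return arr[:, self.polymorphic_sites]

    def subset(self, ids: Sequence[str]) -> "HaplotypeAlignment":
        return HaplotypeAlignment({i: self.sequences[i] for i in ids})


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------


def _decode_genotype(token: str, lineno: int) -> tuple[int, int]:
    if len(token) not in (4, 6) or not token.isdigit():
        raise ParseError(
            f"line {lineno}: genotype {token!r} is not a 4- or 6-digit string"
        )
    w = len(token) // 2
    a, b = int(token[:w]), int(token[w:])
    if (a == 0) != (b == 0):
        raise ParseError(f"line {lineno}: half-missing genotype {token!r}")
    return (a, b) if a <= b else (b, a)


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Read a GenePop file.

    Populations are named ``pop1..popK`` unless sample IDs carry a common
    site prefix; the ID before the comma is used verbatim as the individual
    ID and the POP block index provides the site label.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short for a GenePop file")
    # locus names: lines after the title until the first POP, possibly
    # comma-separated on a single line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP")
    if i == len(lines):
        raise ParseError(f"{path}: no POP block found")

    individuals: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    site: dict[str, str] = {}
    pop_no = 0
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_no += 1
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'id , genotypes...'")
        ind, _, rest = line.partition(",")
        ind = ind.strip()
        if ind in site:
            raise ParseError(f"line {lineno}: duplicate individual ID {ind!r}")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        individuals.append(ind)
        calls.append([_decode_genotype(t, lineno) for t in tokens])
        site[ind] = f"pop{pop_no}"
    if not individuals:
        raise ParseError(f"{path}: no individuals")
    matrix = GenotypeMatrix(individuals, loci, np.array(calls))
    return matrix, SampleMetadata(site)


def write_genepop(
    matrix: GenotypeMatrix,
    path: str | Path,
    metadata: SampleMetadata | None = None,
    title: str = "riverkin export",
    digits: int = 3,
) -> None:
    """Write a GenePop file (3-digit allele encoding by default)."""
    if digits not in (2, 3):
        raise ValueError("GenePop supports 2- or 3-digit encodings")
    limit = 10**digits
    if np.any(matrix.calls >= limit):
        raise ValueError(f"allele code >= {limit} cannot be encoded with {digits} digits")
    if metadata is None:
        groups: dict[str, list[str]] = {"pop1": list(matrix.individuals)}
    else:
        groups = {}
        for ind in matrix.individuals:
            groups.setdefault(metadata.site[ind], []).append(ind)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        for members in groups.values():
            fh.write("POP\n")
            for ind in members:
                row = matrix.calls[matrix.individuals.index(ind)]
                tokens = [f"{a:0{digits}d}{b:0{digits}d}" for a, b in row]
                fh.write(f"{ind} , " + " ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_alignment(path: str | Path) -> HaplotypeAlignment:
    """Read an aligned FASTA file into a :class:`HaplotypeAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    seqs = {r.id: str(r.seq).upper() for r in records}
    if len(seqs) != len(records):
        raise ParseError(f"{path}: duplicate sequence IDs")
    return HaplotypeAlignment(seqs)


def write_fasta_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, seq in alignment.sequences.items():
            fh.write(f">{ind}\n{seq}\n")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Holm's step-down multiple-testing correction.

    Sort p-values ascending and reject ``p_(i)`` while
    ``p_(i) <= alpha / (m - i + 1)`` (1-based ``i``), stopping at the first
    failure.  Decisions are returned in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject.tolist()
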