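"""Reference allele libraries and genotype calling from diploid consensus reads.

Sequence-based typing of the DLA class II loci (DRB1, DQA1, DQB1) amplifies a
fixed-size fragment per locus and direct-sequences it, so each dog yields one
consensus string per locus in which heterozygous positions appear as IUPAC
ambiguity codes.  Calling a genotype means finding the unordered pair of
reference alleles whose position-wise union reproduces the consensus exactly.

The reference universe is an :class:`AlleleLibrary`: per locus, named alleles
of identical length over A/C/G/T.  A call is one of

``homozygous``
    the consensus has no ambiguity code and equals one library allele;
``heterozygous``
    exactly one known-known pair explains the consensus;
``ambiguous``
    several known-known pairs explain it (all are reported, none is chosen);
``novel``
    no known pair explains it.  For an unambiguous consensus the closest
    known alleles (minimum Hamming distance, ties kept) and the mismatch
    positions are reported; for an ambiguous consensus compatible with
    exactly one known allele, the forced complement sequence of the
    hypothesised new allele is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import BASES, IUPAC_SYMBOLS, base_set, is_ambiguous

DEFAULT_LOCI = ("DRB1", "DQA1", "DQB1")
#: Amplicon lengths of the three canine DLA class II loci.
DEFAULT_LOCUS_LENGTHS = {"DRB1": 290, "DQA1": 312, "DQB1": 372}


class LibraryError(ValueError):
    """Malformed allele library (duplicates, mixed lengths, bad characters)."""


class LengthMismatchError(ValueError):
    """Consensus length does not match the library length for its locus."""


class UnknownLocusError(KeyError):
    """Locus absent from the library."""


@dataclass
class AlleleLibrary:
    """Per-locus ordered map from allele name to ungapped A/C/G/T sequence."""

    loci: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, locus: str, name: str, seq: str) -> None:
        seq = seq.upper()
        if any(c not in BASES for c in seq):
            bad = sorted({c for c in seq if c not in BASES})
            raise LibraryError(
                f"{locus}|{name}: reference alleles must be unambiguous A/C/G/T "
                f"(found {','.join(bad)})"
            )
        table = self.loci.setdefault(locus, {})
        if name in table:
            raise LibraryError(f"duplicate allele name at {locus}: {name}")
        if table:
            expected = len(next(iter(table.values())))
            if len(seq) != expected:
                raise LibraryError(
                    f"mixed sequence lengths at {locus}: {name} has {len(seq)}, "
                    f"expected {expected}"
                )
        if seq in table.values():
            other = next(n for n, s in table.items() if s == seq)
            raise LibraryError(f"duplicate sequence at {locus}: {name} equals {other}")
        table[name] = seq

    def alleles(self, locus: str) -> dict[str, str]:
        try:
            return self.loci[locus]
        except KeyError:
            raise UnknownLocusError(f"locus not in library: {locus}") from None

    def length(self, locus: str) -> int:
        table = self.alleles(locus)
        if not table:
            raise LibraryError(f"empty library for locus {locus}")
        return len(next(iter(table.values())))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AlleleLibrary) and self.loci == other.loci


@dataclass(frozen=True)
class ConsensusSequence:
    """One dog x locus diploid consensus over the 15 IUPAC symbols."""

    dog_id: str
    locus: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = sorted({c for c in self.seq if c not in IUPAC_SYMBOLS})
        if bad:
            raise ValueError(
                f"{self.dog_id}|{self.locus}: invalid symbols {','.join(bad)}"
            )

    @property
    def has_ambiguity(self) -> bool:
        return any(is_ambiguous(c) for c in self.seq)


@dataclass(frozen=True)
class GenotypeCall:
    """Result of calling one consensus against the library."""

    dog_id: str
    locus: str
    status: str  # homozygous | heterozygous | ambiguous | novel | missing
    alleles: Optional[tuple[str, str]] = None
    candidates: Optional[tuple[tuple[str, str], ...]] = None
    mismatch_positions: Optional[tuple[int, ...]] = None
    closest_alleles: Optional[tuple[str, ...]] = None
    known_allele: Optional[str] = None
    inferred_complement: Optional[str] = None

    @property
    def is_called(self) -> bool:
        """True when a definite allele pair was assigned."""
        return self.status in ("homozygous", "heterozygous")


def pair_explains(consensus: str, a1: str, a2: str, *, allow_n: bool = True) -> bool:
    """True iff the position-wise union of a1 and a2 equals the consensus.

    Every unambiguous consensus position forces a1 == a2 == consensus there;
    every two-base ambiguity must be exactly the pair {a1, a2}.  With
    ``allow_n`` (default) an N in the consensus matches any allele pair at
    that position; strict mode treats N like any other set and therefore
    never matches a two-allele union.
    """
    if not (len(consensus) == len(a1) == len(a2)):
        raise LengthMismatchError(
            f"lengths differ: consensus {len(consensus)}, alleles {len(a1)}/{len(a2)}"
        )
    for c, x, y in zip(consensus, a1, a2):
        if allow_n and c == "N":
            continue
        if base_set(c) != frozenset((x, y)):
            return False
    return True


def _closest_alleles(seq: str, table: dict[str, str]) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Closest library alleles by Hamming distance; ties all reported.

    Mismatch positions are those of the lexicographically first closest allele.
    """
    best: list[str] = []
    best_d = None
    for name in sorted(table):
        d = sum(1 for a, b in zip(seq, table[name]) if a != b)
        if best_d is None or d < best_d:
            best, best_d = [name], d
        elif d == best_d:
            best.append(name)
    first = table[best[0]]
    positions = tuple(i for i, (a, b) in enumerate(zip(seq, first)) if a != b)
    return tuple(best), positions


def _compatible_alleles(consensus: str, table: dict[str, str], allow_n: bool) -> list[str]:
    """Known alleles that could be one strand of the consensus."""
    out = []
    for name in sorted(table):
        seq = table[name]
        ok = True
        for c, x in zip(consensus, seq):
            if allow_n and c == "N":
                continue
            s = base_set(c)
            if x not in s or len(s) > 2:
                ok = False
                break
        if ok:
            out.append(name)
    return out


def _force_complement(consensus: str, allele: str, allow_n: bool) -> Optional[str]:
    """Base-by-base complement strand implied by consensus = allele U x."""
    out = []
    for c, x in zip(consensus, allele):
        if allow_n and c == "N":
            return None  # complement base not determined
        s = base_set(c)
        if len(s) == 1:
            out.append(x)
        else:
            (other,) = s - {x}
            out.append(other)
    return "".join(out)


def call_genotype(
    consensus: ConsensusSequence, library: AlleleLibrary, *, allow_n: bool = True
) -> GenotypeCall:
    """Call one dog x locus genotype against the reference library.

    See the module docstring for the call taxonomy.  Candidate lists are
    sorted lexicographically by allele-name pair, so output does not depend
    on library insertion order.
    """
    table = library.alleles(consensus.locus)
    if not table:
        raise LibraryError(f"empty library for locus {consensus.locus}")
    if len(consensus.seq) != library.length(consensus.locus):
        raise LengthMismatchError(
            f"{consensus.dog_id}|{consensus.locus}: consensus length "
            f"{len(consensus.seq)} != library length {library.length(consensus.locus)}"
        )
    seq = consensus.seq
    ambiguous = consensus.has_ambiguity if allow_n else any(
        is_ambiguous(c) for c in seq
    )

    if not ambiguous:
        for name in sorted(table):
            if table[name] == seq:
                return GenotypeCall(
                    consensus.dog_id, consensus.locus, "homozygous", (name, name)
                )
        closest, positions = _closest_alleles(seq, table)
        return GenotypeCall(
            consensus.dog_id,
            consensus.locus,
            "novel",
            mismatch_positions=positions,
            closest_alleles=closest,
        )

    # Same-allele pairs are included: with N as a wildcard a homozygote can
    # explain a consensus whose only ambiguity symbols are N.
    explaining = []
    for n1, n2 in combinations_with_replacement(sorted(table), 2):
        if pair_explains(seq, table[n1], table[n2], allow_n=allow_n):
            explaining.append((n1, n2))
    if len(explaining) == 1:
        n1, n2 = explaining[0]
        status = "homozygous" if n1 == n2 else "heterozygous"
        return GenotypeCall(consensus.dog_id, consensus.locus, status, (n1, n2))
    if len(explaining) >= 2:
        return GenotypeCall(
            consensus.dog_id,
            consensus.locus,
            "ambiguous",
            candidates=tuple(sorted(explaining)),
        )

    # No known-known pair: hypothesise a novel allele paired with one known.
    compatible = _compatible_alleles(seq, table, allow_n)
    if len(compatible) == 1:
        complement = _force_complement(seq, table[compatible[0]], allow_n)
        return GenotypeCall(
            consensus.dog_id,
            consensus.locus,
            "novel",
            known_allele=compatible[0],
            inferred_complement=complement,
        )
    return GenotypeCall(consensus.dog_id, consensus.locus, "novel")


def call_cohort(
    consensuses: Iterable[ConsensusSequence],
    library: AlleleLibrary,
    *,
    allow_n: bool = True,
) -> list[GenotypeCall]:
    """Call every consensus; order follows the input."""
    return [call_genotype(c, library, allow_n=allow_n) for c in consensuses]


# ---------------------------------------------------------------------------
# Tabular round-trip for genotype calls (the calls.tsv interchange format)
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Iterable[GenotypeCall]):
    """Genotype calls as a DataFrame with the calls.tsv columns."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "dog_id": c.dog_id,
                "locus": c.locus,
                "status": c.status,
                "allele1": c.alleles[0] if c.alleles else "",
                "allele2": c.alleles[1] if c.alleles else "",
                "candidates": ";".join(
                    "/".join(p) for p in (c.candidates or ())
                ),
                "mismatch_positions": ",".join(
                    str(i) for i in (c.mismatch_positions or ())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dog_id", "locus", "status", "allele1", "allele2",
            "candidates", "mismatch_positions",
        ],
    )


def frame_to_calls(frame) -> list[GenotypeCall]:
    """Rebuild GenotypeCall objects from a calls.tsv DataFrame."""
    out = []
    for row in frame.itertuples(index=False):
        alleles = None
        if isinstance(row.allele1, str) and row.allele1:
            alleles = (row.allele1, row.allele2)
        candidates = None
        if isinstance(row.candidates, str) and row.candidates:
            candidates = tuple(
                tuple(p.split("/")) for p in row.candidates.split(";")
            )
        mismatches = None
        if isinstance(row.mismatch_positions, str) and row.mismatch_positions:
            mismatches = tuple(int(i) for i in row.mismatch_positions.split(","))
        out.append(
            GenotypeCall(
                str(row.dog_id), str(row.locus), row.status,
                alleles=alleles, candidates=candidates,
                mismatch_positions=mismatches,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTA I/O.  Library headers are "locus|allele"; consensus headers "dog|locus".
# ---------------------------------------------------------------------------

def load_allele_library(path: str | Path) -> AlleleLibrary:
    library = AlleleLibrary()
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise LibraryError(f"library header must be 'locus|allele': {rec.id!r}")
        locus, name = rec.id.split("|", 1)
        library.add(locus, name, str(rec.seq))
    if not library.loci:
        raise LibraryError(f"no FASTA records in {path}")
    return library


def write_allele_library(library: AlleleLibrary, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{locus}|{name}", description="")
        for locus, table in library.loci.items()
        for name, seq in table.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_consensus_fasta(path: str | Path) -> list[ConsensusSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"consensus header must be 'dog|locus': {rec.id!r}")
        dog_id, locus = rec.id.split("|", 1)
        out.append(ConsensusSequence(dog_id, locus, str(rec.seq)))
    return out


def write_consensus_fasta(
    consensuses: Iterable[ConsensusSequence], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=f"{c.dog_id}|{c.locus}", description="")
        for c in consensuses
    ]
    SeqIO.write(records, str(path), "fasta")
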