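"""Three-locus haplotype inference anchored on fully homozygous dogs.

The DLA class II region is tightly linked, so DRB1/DQA1/DQB1 alleles travel
as haplotype blocks.  With unphased per-locus genotypes, phase is recovered
by Clark's parsimony procedure restricted to three loci:

1. *Iteration 0* — every dog homozygous at all three loci has a single
   possible phase; its haplotype seeds the known set ``H``.
2. *Sweeps* — for each still-unresolved dog, enumerate the 2^(h-1) phase
   decompositions (h = number of heterozygous loci).  If exactly one
   decomposition uses two haplotypes already in ``H``, accept it.  Failing
   that, if exactly one decomposition uses exactly one known haplotype,
   accept it and add the new complement to ``H``.  Repeat to fixpoint.

Dogs never resolved — and dogs with ambiguous, novel or missing locus calls
— are reported as ``unidentified`` and contribute two copies to the
"Unidentified" row of the count table, mirroring how unresolved animals are
retained rather than forced in published DLA studies.  Ties are never broken
silently: if several decompositions survive a rule, the dog simply waits for
the next sweep.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Optional

import pandas as pd

from .allele_typing import DEFAULT_LOCI, GenotypeCall

UNIDENTIFIED = "Unidentified"


class IncompleteGenotypeError(ValueError):
    """A dog is missing a called genotype at one of the loci."""


@dataclass(frozen=True, order=True)
class Haplotype:
    """Ordered allele triple, one allele per locus (DRB1/DQA1/DQB1)."""

    alleles: tuple[str, ...]

    @property
    def label(self) -> str:
        return "/".join(self.alleles)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class DiplotypeSet:
    """Phasing outcome for one dog."""

    dog_id: str
    status: str  # resolved | unidentified
    haplotypes: Optional[tuple[Haplotype, Haplotype]] = None
    provenance: str = ""
    iteration: Optional[int] = None


@dataclass
class PhasingResult:
    diplotypes: dict[str, DiplotypeSet]
    known_haplotypes: list[Haplotype]  # in discovery order
    n_iterations: int

    def haplotype_pairs(self) -> dict[str, tuple[Haplotype, Haplotype]]:
        return {
            d: r.haplotypes
            for d, r in self.diplotypes.items()
            if r.status == "resolved"
        }


def _ordered_pair(h1: Haplotype, h2: Haplotype) -> tuple[Haplotype, Haplotype]:
    return (h1, h2) if h1 <= h2 else (h2, h1)


def enumerate_phasings(
    calls: Mapping[str, GenotypeCall], loci: tuple[str, ...] = DEFAULT_LOCI
) -> list[tuple[Haplotype, Haplotype]]:
    """All distinct unordered phase decompositions of one dog's genotypes.

    Requires a homozygous or heterozygous call at every locus.  For h
    heterozygous loci there are 2^(h-1) decompositions (one when h <= 1);
    the list order is deterministic.
    """
    pairs = []
    for locus in loci:
        call = calls.get(locus)
        if call is None or not call.is_called:
            status = "absent" if call is None else call.status
            raise IncompleteGenotypeError(
                f"locus {locus} not resolved (status: {status})"
            )
        pairs.append(tuple(sorted(call.alleles)))

    het_idx = [i for i, (a1, a2) in enumerate(pairs) if a1 != a2]
    seen: set[tuple[Haplotype, Haplotype]] = set()
    out: list[tuple[Haplotype, Haplotype]] = []
    # Fix the first heterozygous locus's orientation to halve the search.
    n_free = max(len(het_idx) - 1, 0)
    for bits in product((0, 1), repeat=n_free):
        flips = dict(zip(het_idx[1:], bits))
        h1, h2 = [], []
        for i, (a1, a2) in enumerate(pairs):
            flip = flips.get(i, 0)
            h1.append(a2 if flip else a1)
            h2.append(a1 if flip else a2)
        pair = _ordered_pair(Haplotype(tuple(h1)), Haplotype(tuple(h2)))
        if pair not in seen:
            seen.add(pair)
            out.append(pair)
    return out


def infer_haplotypes(
    cohort_calls: Mapping[str, Mapping[str, GenotypeCall]],
    loci: tuple[str, ...] = DEFAULT_LOCI,
    max_iter: int = 10,
) -> PhasingResult:
    """Phase a cohort with homozygote anchoring (see module docstring).

    ``cohort_calls`` maps dog_id -> locus -> GenotypeCall.  Dogs are visited
    in sorted dog_id order so results do not depend on input ordering; the
    known set is updated as soon as a dog resolves.  Non-convergence simply
    leaves dogs unidentified.
    """
    diplotypes: dict[str, DiplotypeSet] = {}
    known: dict[Haplotype, None] = {}  # insertion-ordered set
    phasings: dict[str, list[tuple[Haplotype, Haplotype]]] = {}

    for dog_id in sorted(cohort_calls):
        calls = cohort_calls[dog_id]
        statuses = {
            locus: (calls[locus].status if locus in calls else "absent")
            for locus in loci
        }
        if all(s in ("homozygous", "heterozygous") for s in statuses.values()):
            phasings[dog_id] = enumerate_phasings(calls, loci)
        else:
            bad = ",".join(f"{l}:{s}" for l, s in statuses.items()
                           if s not in ("homozygous", "heterozygous"))
            diplotypes[dog_id] = DiplotypeSet(
                dog_id, "unidentified", provenance=f"excluded ({bad})"
            )

    # Iteration 0: unique decompositions (all-homozygous dogs, and dogs
    # heterozygous at a single locus) need no anchors at all.  Only fully
    # homozygous dogs seed H; single-het dogs resolve but their haplotypes
    # also enter H, since both are directly observed.
    for dog_id, options in sorted(phasings.items()):
        if len(options) == 1:
            h1, h2 = options[0]
            n_het = sum(
                1 for a, b in zip(h1.alleles, h2.alleles) if a != b
            )
            rule = "all-homozygous" if n_het == 0 else "unique-decomposition"
            diplotypes[dog_id] = DiplotypeSet(
                dog_id, "resolved", (h1, h2), provenance=rule, iteration=0
            )
            known.setdefault(h1)
            known.setdefault(h2)

    n_iter = 0
    for sweep in range(1, max_iter + 1):
        progressed = False
        for dog_id in sorted(phasings):
            if dog_id in diplotypes:
                continue
            options = phasings[dog_id]
            both = [p for p in options if p[0] in known and p[1] in known]
            if len(both) == 1:
                diplotypes[dog_id] = DiplotypeSet(
                    dog_id, "resolved", both[0],
                    provenance="both-known", iteration=sweep,
                )
                progressed = True
                continue
            if both:
                continue  # genuinely ambiguous this sweep; never forced
            one = [
                p for p in options
                if (p[0] in known) != (p[1] in known)
            ]
            if len(one) == 1:
                h1, h2 = one[0]
                new = h2 if h1 in known else h1
                known.setdefault(new)
                diplotypes[dog_id] = DiplotypeSet(
                    dog_id, "resolved", one[0],
                    provenance="one-known-extension", iteration=sweep,
                )
                progressed = True
        n_iter = sweep
        if not progressed:
            break

    for dog_id in sorted(phasings):
        if dog_id not in diplotypes:
            diplotypes[dog_id] = DiplotypeSet(
                dog_id, "unidentified", provenance="no unique phasing"
            )

    return PhasingResult(
        diplotypes={d: diplotypes[d] for d in sorted(diplotypes)},
        known_haplotypes=list(known),
        n_iterations=n_iter,
    )


def phasing_to_frame(result: PhasingResult) -> pd.DataFrame:
    """Phasing result as a DataFrame with the haplotypes.tsv columns."""
    rows = []
    for dog_id, dip in result.diplotypes.items():
        rows.append(
            {
                "dog_id": dog_id,
                "status": dip.status,
                "hap1": dip.haplotypes[0].label if dip.haplotypes else "",
                "hap2": dip.haplotypes[1].label if dip.haplotypes else "",
                "iteration": dip.iteration if dip.iteration is not None else "",
                "provenance": dip.provenance,
            }
        )
    return pd.DataFrame(
        rows, columns=["dog_id", "status", "hap1", "hap2", "iteration", "provenance"]
    )


def frame_to_phasing(frame: pd.DataFrame) -> PhasingResult:
    """Rebuild a PhasingResult from a haplotypes.tsv DataFrame."""
    diplotypes = {}
    known: dict[Haplotype, None] = {}
    for row in frame.itertuples(index=False):
        haps = None
        if isinstance(row.hap1, str) and row.hap1:
            haps = (
                Haplotype(tuple(row.hap1.split("/"))),
                Haplotype(tuple(row.hap2.split("/"))),
            )
            for h in haps:
                known.setdefault(h)
        iteration = None
        if str(row.iteration) not in ("", "nan"):
            iteration = int(float(row.iteration))
        diplotypes[str(row.dog_id)] = DiplotypeSet(
            str(row.dog_id), row.status, haps,
            provenance=str(row.provenance), iteration=iteration,
        )
    return PhasingResult(
        diplotypes={d: diplotypes[d] for d in sorted(diplotypes)},
        known_haplotypes=list(known),
        n_iterations=0,
    )


def count_haplotypes(
    result: PhasingResult, statuses: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cohort haplotype copy counts and frequencies.

    Resolved dogs contribute two copies (their two haplotypes); unidentified
    dogs contribute two copies to the ``Unidentified`` row.  ``statuses``
    maps dog_id -> 'affected' | 'control'.  Copy totals per cohort equal
    2 x number of dogs.
    """
    counters = {"affected": Counter(), "control": Counter()}
    for dog_id, dip in result.diplotypes.items():
        cohort = statuses[dog_id]
        if cohort not in counters:
            raise ValueError(f"unknown status label for {dog_id}: {cohort!r}")
        if dip.status == "resolved":
            for h in dip.haplotypes:
                counters[cohort][h.label] += 1
        else:
            counters[cohort][UNIDENTIFIED] += 2

    n_aff = 2 * sum(1 for d in result.diplotypes if statuses[d] == "affected")
    n_ctl = 2 * sum(1 for d in result.diplotypes if statuses[d] == "control")
    labels = sorted(
        set(counters["affected"]) | set(counters["control"]),
        key=lambda lab: (lab == UNIDENTIFIED, lab),
    )
    rows = []
    for lab in labels:
        a = counters["affected"][lab]
        c = counters["control"][lab]
        rows.append(
            {
                "haplotype": lab,
                "n_affected": a,
                "freq_affected": a / n_aff if n_aff else float("nan"),
                "n_control": c,
                "freq_control": c / n_ctl if n_ctl else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["haplotype", "n_affected", "freq_affected", "n_control", "freq_control"],
    )
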