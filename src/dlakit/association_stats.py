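"""Case-control 2x2 association statistics for alleles and haplotypes.

Each diploid dog contributes two countable copies per locus, so for a study
with n_A affected and n_C control dogs the allele-copy denominators are
2*n_A and 2*n_C.  For every feature (an allele, a haplotype, or
"homozygous at all three loci", whose unit is dogs rather than copies) a
2x2 table is formed:

====================  =========  ========
                      affected   control
====================  =========  ========
carrying the feature  a          c
not carrying it       b          d
====================  =========  ========

and summarised by the classical odds-ratio toolkit:

* OR = ad/bc; if any cell is zero, 0.5 is first added to *every* cell
  (Haldane-Anscombe continuity correction) and the result is flagged.
* Woolf (logit) 95% CI: exp(ln OR +/- z * SE), SE = sqrt(1/a+1/b+1/c+1/d)
  on the possibly corrected cells.
* Two-sided P from the Wald normal statistic z = |ln OR| / SE.

No multiple-testing adjustment is applied in this module; candidate-gene
DLA studies conventionally report unadjusted per-feature P values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .allele_typing import DEFAULT_LOCI, GenotypeCall
from .haplotype_inference import UNIDENTIFIED, PhasingResult

# Conventional two-decimal 95% normal quantile.  Published DLA tables are
# computed with 1.96 (visible in wide zero-cell intervals, where the full
# precision quantile 1.959964 shifts the upper bound by a printable amount).
Z95 = 1.96

AFFECTED, CONTROL = "affected", "control"


class UndefinedTableError(ValueError):
    """A cohort margin of the 2x2 table is zero."""


@dataclass(frozen=True)
class Counts2x2:
    """a/b: affected with/without the feature; c/d: control with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def freq_affected(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def freq_control(self) -> float:
        return self.c / (self.c + self.d)


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    counts: Counts2x2
    freq_affected: float
    freq_control: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool


def _working_cells(t: Counts2x2) -> tuple[tuple[float, float, float, float], bool]:
    if (t.a + t.b) == 0 or (t.c + t.d) == 0:
        raise UndefinedTableError(f"zero cohort margin in table {t.cells}")
    if min(t.cells) == 0:
        return tuple(x + 0.5 for x in t.cells), True
    return tuple(float(x) for x in t.cells), False


def odds_ratio(t: Counts2x2) -> tuple[float, bool]:
    """Odds ratio with Haldane-Anscombe handling of zero cells."""
    (a, b, c, d), corrected = _working_cells(t)
    return (a * d) / (b * c), corrected


def woolf_ci(t: Counts2x2, level: float = 0.95) -> tuple[float, float]:
    """Woolf logit confidence interval on the (possibly corrected) cells.

    At the default 95% level the conventional quantile 1.96 is used (the
    value reporting tools in this field apply); other levels use the exact
    normal quantile.
    """
    (a, b, c, d), _ = _working_cells(t)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z95 if level == 0.95 else norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def wald_p(t: Counts2x2) -> float:
    """Two-sided normal test on ln(OR) using the Woolf standard error."""
    (a, b, c, d), _ = _working_cells(t)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(2 * norm.sf(abs(log_or) / se))


def associate(feature: str, t: Counts2x2) -> AssociationResult:
    """Full OR/CI/P summary for one feature table."""
    or_value, corrected = odds_ratio(t)
    ci_low, ci_high = woolf_ci(t)
    return AssociationResult(
        feature=feature,
        counts=t,
        freq_affected=t.freq_affected,
        freq_control=t.freq_control,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=wald_p(t),
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Tabulation from upstream results
# ---------------------------------------------------------------------------

def _split_cohorts(statuses: Mapping[str, str]) -> tuple[set[str], set[str]]:
    aff = {d for d, s in statuses.items() if s == AFFECTED}
    ctl = {d for d, s in statuses.items() if s == CONTROL}
    unknown = set(statuses) - aff - ctl
    if unknown:
        bad = sorted(statuses[d] for d in unknown)
        raise ValueError(f"unknown status labels: {sorted(set(bad))}")
    if not aff or not ctl:
        raise ValueError("both an affected and a control cohort are required")
    return aff, ctl


def tabulate_alleles(
    calls: Iterable[GenotypeCall], statuses: Mapping[str, str]
) -> list[tuple[str, Counts2x2]]:
    """Allele-copy 2x2 tables per (locus, allele).

    Each dog with a definite call (homozygous or heterozygous) contributes
    two copies at that locus; dogs with ambiguous/novel/missing calls are
    excluded from that locus's denominators.  Feature labels are
    "locus*allele".
    """
    aff, ctl = _split_cohorts(statuses)
    copies = {AFFECTED: Counter(), CONTROL: Counter()}
    totals = {AFFECTED: Counter(), CONTROL: Counter()}
    for call in calls:
        if call.dog_id not in statuses or not call.is_called:
            continue
        cohort = AFFECTED if call.dog_id in aff else CONTROL
        totals[cohort][call.locus] += 2
        for allele in call.alleles:
            copies[cohort][(call.locus, allele)] += 1

    features = sorted({k for c in copies.values() for k in c})
    out = []
    for locus, allele in features:
        a = copies[AFFECTED][(locus, allele)]
        c = copies[CONTROL][(locus, allele)]
        out.append(
            (
                f"{locus}*{allele}",
                Counts2x2(a, totals[AFFECTED][locus] - a, c, totals[CONTROL][locus] - c),
            )
        )
    return out


def tabulate_haplotypes(
    phasing: PhasingResult, statuses: Mapping[str, str], *, include_unidentified: bool = False
) -> list[tuple[str, Counts2x2]]:
    """Haplotype-copy 2x2 tables; unidentified copies optionally included.

    Denominators are 2 x cohort size (all dogs, matching how published DLA
    tables keep the Unidentified copies in the totals).  Association rows
    for the Unidentified class itself are excluded by default since that
    class is a residual, not a haplotype.
    """
    aff, ctl = _split_cohorts(statuses)
    copies = {AFFECTED: Counter(), CONTROL: Counter()}
    totals = {AFFECTED: 0, CONTROL: 0}
    for dog_id, dip in phasing.diplotypes.items():
        if dog_id not in statuses:
            continue
        cohort = AFFECTED if dog_id in aff else CONTROL
        totals[cohort] += 2
        if dip.status == "resolved":
            for h in dip.haplotypes:
                copies[cohort][h.label] += 1
        else:
            copies[cohort][UNIDENTIFIED] += 2

    labels = sorted({k for c in copies.values() for k in c})
    if not include_unidentified:
        labels = [lab for lab in labels if lab != UNIDENTIFIED]
    out = []
    for lab in labels:
        a = copies[AFFECTED][lab]
        c = copies[CONTROL][lab]
        out.append((lab, Counts2x2(a, totals[AFFECTED] - a, c, totals[CONTROL] - c)))
    return out


def tabulate_homozygosity(
    calls: Iterable[GenotypeCall],
    statuses: Mapping[str, str],
    loci: tuple[str, ...] = DEFAULT_LOCI,
) -> tuple[str, Counts2x2]:
    """Dog-unit table for "homozygous at all three loci".

    A dog is a carrier iff it has a homozygous call at every locus; dogs
    with any non-called locus count as non-carriers of complete
    homozygosity but stay in the denominators (the unit is dogs).
    """
    aff, ctl = _split_cohorts(statuses)
    by_dog: dict[str, dict[str, str]] = {}
    for call in calls:
        by_dog.setdefault(call.dog_id, {})[call.locus] = call.status
    n = {AFFECTED: 0, CONTROL: 0}
    homo = {AFFECTED: 0, CONTROL: 0}
    for dog_id in statuses:
        cohort = AFFECTED if dog_id in aff else CONTROL
        n[cohort] += 1
        dog = by_dog.get(dog_id, {})
        if all(dog.get(locus) == "homozygous" for locus in loci):
            homo[cohort] += 1
    t = Counts2x2(
        homo[AFFECTED], n[AFFECTED] - homo[AFFECTED],
        homo[CONTROL], n[CONTROL] - homo[CONTROL],
    )
    return ("homozygous_all_loci", t)


def association_report(
    features: Sequence[tuple[str, Counts2x2]]
) -> pd.DataFrame:
    """OR/CI/P table for a list of (label, counts) features.

    Rows are sorted by descending total copy count, then label, matching
    the most-common-first layout of published prevalence tables.  Values
    are kept at full precision; rounding is a rendering concern.
    """
    results = [associate(lab, t) for lab, t in features]
    results.sort(key=lambda r: (-(r.counts.a + r.counts.c), r.feature))
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "n_affected": [r.counts.a for r in results],
            "freq_affected": [r.freq_affected for r in results],
            "n_control": [r.counts.c for r in results],
            "freq_control": [r.freq_control for r in results],
            "p_value": [r.p_value for r in results],
            "or_value": [r.or_value for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "corrected": [r.corrected for r in results],
        }
    )
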