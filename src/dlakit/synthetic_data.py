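"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-cohort canine case-control study typed at the
three DLA class II loci: a per-locus reference allele library, a pool of
three-locus haplotypes containing one designated risk haplotype, diploid
sampling under Hardy-Weinberg equilibrium, a disease model multiplicative
on the odds per risk-haplotype copy, and rendering of diploid genotypes
into IUPAC consensus strings (the inverse of genotype calling).  An
independent SNP-panel track feeds the GWAS stage.

Defaults mirror the study design this toolkit targets: 34 affected and 66
control dogs typed at DRB1/DQA1/DQB1 (amplicons of 290/312/372 bp), a risk
haplotype at population frequency 0.10 with a per-copy odds ratio of 4, and
a 15-case / 16-control SNP panel.  The default haplotype pool reuses the
allele-sharing structure typical of published Dachshund DLA tables (several
haplotypes share DQA1/DQB1 alleles) while remaining phase-identifiable: no
two pool haplotypes can recombine into another pair of pool haplotypes, so
anchored phasing can always recover the simulated diplotypes.

Everything is a pure function of (config, seed): the same configuration
always yields the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .allele_typing import AlleleLibrary, ConsensusSequence
from .gwas_lite import SnpDataset
from .haplotype_inference import Haplotype, enumerate_phasings
from .iupac import BASES, IUPAC_SYMBOLS, union_sequence

DEFAULT_LOCI: tuple[tuple[str, int], ...] = (
    ("DRB1", 290),
    ("DQA1", 312),
    ("DQB1", 372),
)

#: Haplotype pool loosely patterned on Dachshund DLA class II diversity:
#: a handful of common haplotypes sharing alleles across loci, plus one
#: designated risk haplotype at population frequency 0.10.
DEFAULT_POOL: tuple[tuple[Haplotype, float], ...] = (
    (Haplotype(("U", "00101", "00201")), 0.20),
    (Haplotype(("T", "00101", "C1")), 0.22),
    (Haplotype(("Z", "00901", "00101")), 0.17),
    (Haplotype(("09401", "00101", "C1")), 0.10),
    (Haplotype(("01502", "00601", "02301")), 0.09),
    (Haplotype(("00203", "00901", "00101")), 0.10),
    (Haplotype(("W", "00601", "02301")), 0.07),
    (Haplotype(("04801", "00101", "00802")), 0.05),
)

DEFAULT_RISK = "09401/00101/C1"

# Independent RNG streams per generator so each output is a pure function
# of (config, seed) regardless of which stages are run.
_STREAM_LIBRARY, _STREAM_COHORT, _STREAM_RENDER, _STREAM_SNP = 11, 23, 37, 53


@dataclass(frozen=True)
class SnpConfig:
    """SNP-panel track: sizes follow the genome-scan cohort (15 vs 16)."""

    n_snps: int = 1000
    n_cases: int = 15
    n_controls: int = 16
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    associated_or: Optional[float] = None  # allelic OR of one extra SNP
    associated_maf: float = 0.2            # control-cohort allele frequency

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"MAF range must lie in (0, 0.5]: {self.maf_range}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both cohorts must be non-empty")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for the DLA track; defaults are the target study."""

    seed: int = 0
    loci: tuple[tuple[str, int], ...] = DEFAULT_LOCI
    haplotype_pool: tuple[tuple[Haplotype, float], ...] = DEFAULT_POOL
    risk_haplotype: str = DEFAULT_RISK
    risk_or: float = 4.0
    baseline_odds: float = 0.4
    n_affected: int = 34
    n_control: int = 66
    error_rate: float = 0.0
    snp: SnpConfig = field(default_factory=SnpConfig)

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.haplotype_pool)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if self.n_affected < 1 or self.n_control < 1:
            raise ValueError("both cohorts must be non-empty")
        if self.risk_or <= 0 or self.baseline_odds <= 0:
            raise ValueError("risk_or and baseline_odds must be positive")
        if self.risk_haplotype not in {h.label for h, _ in self.haplotype_pool}:
            raise ValueError(f"risk haplotype {self.risk_haplotype!r} not in pool")
        n_loci = len(self.loci)
        for h, _ in self.haplotype_pool:
            if len(h.alleles) != n_loci:
                raise ValueError(f"haplotype {h.label} does not span {n_loci} loci")


@dataclass(frozen=True)
class DogTruth:
    dog_id: str
    status: str  # affected | control
    haplotypes: tuple[Haplotype, Haplotype]

    def allele_pair(self, locus_index: int) -> tuple[str, str]:
        h1, h2 = self.haplotypes
        return (h1.alleles[locus_index], h2.alleles[locus_index])


@dataclass
class TrueCohort:
    """Ground truth for recovery tests: per-dog status and diplotype."""

    config: SimulationConfig
    dogs: list[DogTruth]

    @property
    def statuses(self) -> dict[str, str]:
        return {d.dog_id: d.status for d in self.dogs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dog_id": [d.dog_id for d in self.dogs],
                "status": [d.status for d in self.dogs],
                "hap1": [d.haplotypes[0].label for d in self.dogs],
                "hap2": [d.haplotypes[1].label for d in self.dogs],
            }
        )


def pool_allele_names(config: SimulationConfig) -> dict[str, list[str]]:
    """Sorted allele names per locus appearing anywhere in the pool."""
    out: dict[str, list[str]] = {}
    for i, (locus, _) in enumerate(config.loci):
        out[locus] = sorted({h.alleles[i] for h, _ in config.haplotype_pool})
    return out


def pool_is_phase_identifiable(
    pool: tuple[tuple[Haplotype, float], ...]
) -> bool:
    """True when no unordered pool pair admits a second all-pool phasing.

    This is the condition under which anchored phasing recovers every
    simulated diplotype exactly (given anchor coverage): any alternative
    decomposition of a dog's genotypes involves at least one haplotype
    outside the pool.
    """
    from .allele_typing import GenotypeCall  # local import to avoid cycle noise

    labels = {h for h, _ in pool}
    haps = [h for h, _ in pool]
    n_loci = len(haps[0].alleles)
    loci = tuple(f"L{i}" for i in range(n_loci))
    for i in range(len(haps)):
        for j in range(i, len(haps)):
            calls = {}
            for k, locus in enumerate(loci):
                a1, a2 = haps[i].alleles[k], haps[j].alleles[k]
                calls[locus] = GenotypeCall(
                    "x", locus,
                    "homozygous" if a1 == a2 else "heterozygous",
                    (a1, a2),
                )
            options = enumerate_phasings(calls, loci)
            in_pool = [p for p in options if p[0] in labels and p[1] in labels]
            if len(in_pool) != 1:
                return False
    return True


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_library(
    config: SimulationConfig, n_polymorphic: Optional[int] = None
) -> AlleleLibrary:
    """Random reference library for every allele named in the pool.

    Alleles at a locus share a random backbone and differ only at a set of
    polymorphic positions (as sequence-based typing amplicons do), with a
    pairwise Hamming distance of at least 2 so that no single-site error
    can turn one allele into another.
    """
    rng = np.random.default_rng([_STREAM_LIBRARY, config.seed])
    names_by_locus = pool_allele_names(config)
    library = AlleleLibrary()
    for locus, length in config.loci:
        names = names_by_locus[locus]
        n_poly = n_polymorphic or max(6, 2 * len(names))
        if n_poly > length:
            raise ValueError(f"locus {locus}: {n_poly} polymorphic sites > {length} bp")
        if 4 ** n_poly < 4 * len(names):
            raise ValueError(
                f"locus {locus}: {len(names)} alleles exceed the sequence space"
            )
        backbone = rng.choice(list(BASES), size=length)
        sites = np.sort(rng.choice(length, size=n_poly, replace=False))
        chosen: list[np.ndarray] = []
        for _ in names:
            for _attempt in range(1000):
                variant = rng.choice(list(BASES), size=n_poly)
                if all(np.sum(variant != prev) >= 2 for prev in chosen):
                    chosen.append(variant)
                    break
            else:
                raise ValueError(
                    f"locus {locus}: could not place alleles at Hamming >= 2"
                )
        for name, variant in zip(names, chosen):
            seq = backbone.copy()
            seq[sites] = variant
            library.add(locus, name, "".join(seq))
    return library


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _affection_probability(config: SimulationConfig, risk_copies: int) -> float:
    odds = config.baseline_odds * config.risk_or ** risk_copies
    return odds / (1 + odds)


def simulate_cohort(
    config: SimulationConfig, *, ensure_anchor_coverage: bool = False,
    max_draws: Optional[int] = None,
) -> TrueCohort:
    """Draw dogs to fixed cohort sizes under HWE and the odds model.

    Each dog receives two haplotypes i.i.d. from the pool; its disease
    odds are baseline_odds * risk_or ** (copies of the risk haplotype), and
    dogs are rejection-sampled until exactly n_affected and n_control have
    been collected (case-control ascertainment, not population prevalence).

    With ``ensure_anchor_coverage`` one dog homozygous for each pool
    haplotype is drawn first (status still from the disease model), which
    guarantees the anchor condition parameter-recovery experiments rely on.
    """
    rng = np.random.default_rng([_STREAM_COHORT, config.seed])
    haps = [h for h, _ in config.haplotype_pool]
    freqs = np.array([f for _, f in config.haplotype_pool])
    freqs = freqs / freqs.sum()
    max_draws = max_draws or 1000 * (config.n_affected + config.n_control)

    need = {"affected": config.n_affected, "control": config.n_control}
    accepted: list[tuple[str, tuple[Haplotype, Haplotype]]] = []

    def classify(pair: tuple[Haplotype, Haplotype]) -> str:
        copies = sum(1 for h in pair if h.label == config.risk_haplotype)
        p = _affection_probability(config, copies)
        return "affected" if rng.random() < p else "control"

    if ensure_anchor_coverage:
        for h in haps:
            status = classify((h, h))
            if need[status] == 0:
                raise ValueError(
                    f"anchor coverage needs more {status} slots than the "
                    f"configured cohort sizes allow"
                )
            need[status] -= 1
            accepted.append((status, (h, h)))

    draws = 0
    while need["affected"] > 0 or need["control"] > 0:
        if draws >= max_draws:
            raise RuntimeError(
                f"cohort sizes unreachable within {max_draws} draws "
                f"(still need {need})"
            )
        draws += 1
        idx = rng.choice(len(haps), size=2, p=freqs)
        pair = (haps[idx[0]], haps[idx[1]])
        status = classify(pair)
        if need[status] > 0:
            need[status] -= 1
            accepted.append((status, pair))

    width = len(str(len(accepted)))
    dogs = [
        DogTruth(f"dog{i + 1:0{width}d}", status, pair)
        for i, (status, pair) in enumerate(accepted)
    ]
    return TrueCohort(config, dogs)


def expected_allele_or(config: SimulationConfig) -> float:
    """Asymptotic case-control allele-copy OR implied by the disease model.

    Enumerates risk-copy genotypes r in {0,1,2} under HWE, weights them by
    P(case|r) and P(control|r), and forms the odds ratio of the resulting
    risk-copy frequencies in cases versus controls.  This is the population
    quantity the Woolf CI should cover; it is slightly below ``risk_or``
    because case-control allele frequencies attenuate a per-copy odds model.
    """
    f = dict(
        (h.label, fr) for h, fr in config.haplotype_pool
    )[config.risk_haplotype]
    hwe = {0: (1 - f) ** 2, 1: 2 * f * (1 - f), 2: f ** 2}
    num_case = num_ctl = den_case = den_ctl = 0.0
    for r, pr in hwe.items():
        p_case = _affection_probability(config, r)
        num_case += (r / 2) * pr * p_case
        den_case += pr * p_case
        num_ctl += (r / 2) * pr * (1 - p_case)
        den_ctl += pr * (1 - p_case)
    fc, f0 = num_case / den_case, num_ctl / den_ctl
    return (fc / (1 - fc)) / (f0 / (1 - f0))


# ---------------------------------------------------------------------------
# Consensus rendering (inverse of genotype calling)
# ---------------------------------------------------------------------------

def render_consensus(
    cohort: TrueCohort, library: AlleleLibrary, error_rate: Optional[float] = None
) -> list[ConsensusSequence]:
    """Render each dog x locus diploid genotype as an IUPAC consensus.

    Each position is the IUPAC union of the two allele bases, so a
    heterozygote shows exactly one ambiguity symbol per differing site.
    With error rate epsilon > 0 every position is independently replaced,
    with probability epsilon, by a uniformly random *different* symbol
    among the 15 IUPAC codes (a pure symbol-substitution error model).
    """
    config = cohort.config
    eps = config.error_rate if error_rate is None else error_rate
    rng = np.random.default_rng([_STREAM_RENDER, config.seed])
    symbols = sorted(IUPAC_SYMBOLS)
    out = []
    for dog in cohort.dogs:
        for i, (locus, _) in enumerate(config.loci):
            a1, a2 = dog.allele_pair(i)
            table = library.alleles(locus)
            seq = union_sequence(table[a1], table[a2])
            if eps > 0:
                chars = list(seq)
                hits = np.nonzero(rng.random(len(chars)) < eps)[0]
                for pos in hits:
                    options = [s for s in symbols if s != chars[pos]]
                    chars[pos] = options[rng.integers(len(options))]
                seq = "".join(chars)
            out.append(ConsensusSequence(dog.dog_id, locus, seq))
    return out


# ---------------------------------------------------------------------------
# SNP-panel simulation
# ---------------------------------------------------------------------------

def simulate_snp_dataset(config: SimulationConfig) -> SnpDataset:
    """Independent SNP panel for the GWAS stage.

    Per-SNP allele frequencies are uniform on the configured MAF range and
    genotypes are Binomial(2, maf) per sample (no structure, no LD).  An
    optionally appended associated SNP has control-cohort allele frequency
    ``associated_maf`` and a case-cohort frequency solving the configured
    allelic odds ratio.  The panel is independent of the DLA track.
    """
    sc = config.snp
    rng = np.random.default_rng([_STREAM_SNP, config.seed])
    n = sc.n_cases + sc.n_controls
    affected = np.zeros(n, dtype=bool)
    affected[: sc.n_cases] = True
    sample_ids = [f"gw{i + 1:04d}" for i in range(n)]

    lo, hi = sc.maf_range
    mafs = rng.uniform(lo, hi, size=sc.n_snps)
    genotypes = rng.binomial(2, mafs[None, :], size=(n, sc.n_snps)).astype(float)

    snp_ids = [f"snp{i + 1:05d}" for i in range(sc.n_snps)]
    if sc.associated_or is not None:
        p0 = sc.associated_maf
        odds_case = sc.associated_or * p0 / (1 - p0)
        p1 = odds_case / (1 + odds_case)
        col = np.where(
            affected, rng.binomial(2, p1, size=n), rng.binomial(2, p0, size=n)
        ).astype(float)
        genotypes = np.column_stack([genotypes, col])
        snp_ids.append("snp_assoc")

    if sc.missing_rate > 0:
        mask = rng.random(genotypes.shape) < sc.missing_rate
        genotypes[mask] = np.nan

    m = len(snp_ids)
    chromosomes = [str(1 + (i % 38)) for i in range(m)]
    positions = [100_000 + 10_000 * (i // 38) for i in range(m)]
    snps = pd.DataFrame(
        {"snp_id": snp_ids, "chromosome": chromosomes, "position_bp": positions}
    )
    return SnpDataset(sample_ids, affected, snps, genotypes)
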