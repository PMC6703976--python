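# Methods

## Genotype calling from diploid consensus sequences

Each dog × locus observation is a single reconciled consensus string over
the 15 IUPAC nucleotide symbols, the information content of a
direct-sequenced diploid amplicon (how forward/reverse chromatogram
conflicts were reconciled upstream is out of scope).  Reference alleles
are equal-length, unambiguous A/C/G/T sequences per locus; indel-bearing
alleles are excluded by construction since the amplicons are fixed-size
products (290/312/372 bp at DRB1/DQA1/DQB1).

A pair of alleles *explains* a consensus iff at every position the IUPAC
union of the two allele bases equals the consensus symbol; in particular
every unambiguous position forces both alleles to match it.  Calling
enumerates all unordered allele pairs:

* no ambiguity symbol and an exact library match → **homozygous**;
* exactly one explaining pair → **heterozygous**;
* two or more explaining pairs → **ambiguous**, with every explaining pair
  reported in lexicographic order.  Ties are never broken by frequency or
  otherwise; downstream stages treat ambiguous as uncallable.
* no explaining pair → **novel**.  For an unambiguous consensus the
  closest known alleles by Hamming distance are reported (all ties) with
  the mismatch positions; "closest" is deliberately operationalised as
  minimum Hamming distance since equal-length alleles make it the natural
  metric.  For an ambiguous consensus compatible with exactly one known
  allele, the complement strand is forced base-by-base and reported —
  this is how a previously unknown allele carried by heterozygous dogs
  becomes visible without cloning.

`N` is treated as a wildcard matching any base pair (strict mode via
`allow_n=False` treats it as the literal 4-base set, which can never equal
a two-allele union).  Because `N` is a wildcard, same-allele pairs are
included in the enumeration: a homozygote can explain a consensus whose
only ambiguity codes are `N`.

## Haplotype inference

Phasing is Clark's parsimony procedure restricted to three loci.  With
*h* heterozygous loci a dog has 2^(h−1) distinct unordered phase
decompositions.  Iteration 0 resolves every dog with a unique
decomposition (h ≤ 1); both of its haplotypes enter the known set H —
fully homozygous dogs are the classical anchors, and single-locus
heterozygotes are equally unambiguous, so their haplotypes are admitted as
seeds too (a deliberate choice; the textbook formulation seeds from both).
Each subsequent sweep visits unresolved dogs in sorted dog-id order,
updating H immediately:

1. **both-known rule** — if exactly one decomposition uses two haplotypes
   already in H, accept it.  If several do, the dog is genuinely ambiguous
   and is left for later (possibly forever) rather than forced.
2. **one-known extension** — otherwise, if exactly one decomposition uses
   exactly one known haplotype, accept it and add the new complement to H.

The both-known rule runs first because it invents nothing.  Sweeps repeat
to fixpoint (default cap 10; convergence is observed within 2–3).
Non-convergence is a valid outcome: unresolved dogs, and dogs with
ambiguous/novel/missing locus calls, are counted as **Unidentified** with
two copies, so per-cohort copy totals are always 2 × dogs.  Provenance
(which rule, which sweep) is recorded per dog so the source of every
Unidentified entry is visible.

The visiting order and immediate H updates make the procedure
deterministic and independent of input file order; results are reproduced
exactly on re-runs.  Like any Clark-style method it has no statistical
model: cohorts without homozygous anchors stay unresolved, which is the
honest answer at candidate-gene scale (statistical phasing is a non-goal).

## Association statistics

Features are allele copies (each called dog contributes two per locus;
dogs without a definite call at a locus leave that locus's denominator),
haplotype copies (Unidentified copies stay in the denominators but get no
association row), and all-three-loci homozygosity with dogs as the unit.

For each 2×2 table: OR = ad/bc; when any cell is zero, 0.5 is added to
every cell (Haldane–Anscombe) before the OR, CI and P are computed, and
the row is flagged `corrected`.  The CI is Woolf's logit interval with the
conventional z = 1.96 at the 95% level — published DLA tables are
computed with the two-decimal quantile, which is visible in wide zero-cell
intervals where the fourth digit of z changes a printable digit; other
levels use the exact normal quantile.  The two-sided P is the Wald normal
test on ln(OR) with the same standard error.  Pearson χ² or Fisher exact
tests are *not* interchangeable here: they give materially different P
values on these tables, and the Wald convention is the one that reproduces
published candidate-gene DLA reports.  No multiple-testing adjustment is
applied at this stage, matching that reporting convention; the report
renderer bolds rows with unadjusted two-sided P < 0.05.

Internally everything is kept at full precision; rounding (OR/CI and
frequencies to 2 decimals, P to 4) happens only in the markdown renderer.

## GWAS stage

QC keeps SNPs with call rate ≥ 0.90 and pooled-cohort minor allele
frequency ≥ 0.05 (boundary inclusive; frequencies folded to the minor
side).  The per-SNP statistic is the 1-df allelic Pearson χ² on the
2×2 allele-count table built from dosages, without continuity correction;
degenerate margins yield (χ² = 0, P = 1).  Missing genotypes are excluded
pairwise per SNP.  Bonferroni multiplies raw P by the number of SNPs
actually tested (capped at 1), so adjusted and raw rankings coincide.
λ = median(χ²)/0.4549364 is reported descriptively and never used to
rescale P.

A small-sample caveat that matters at typing-study scale: with ~30 alleles
per cohort the allelic χ² is a coarse lattice and its null *median* sits
above the asymptotic 0.455, so λ ≈ 1.15 is the expected null value at
15 + 16 samples even without any stratification (verified against direct
binomial sampling with an independent χ² implementation; the same code
gives λ ≈ 1.01 at 200 + 200).  λ from small cohorts should therefore be
read against a simulated null, not against 1.0.

## Synthetic data generator

The generator emulates the target study design, and its defaults are the
study conditions: 34 affected / 66 control typed dogs; three loci with
amplicon lengths 290/312/372 bp; a pool of 8 three-locus haplotypes whose
allele-sharing pattern mimics published Dachshund DLA tables, with one
risk haplotype at population frequency 0.10; per-copy disease odds
multiplicative with OR 4 on a baseline odds of 0.4 (≈ 29% baseline
penetrance, yielding case-control sampling rates that make a 34/66 cohort
readily ascertainable); and an independent SNP panel of 1,000 null SNPs
with MAF ~ U(0.05, 0.5) at the 15-case/16-control genome-scan size.

Dogs draw two haplotypes i.i.d. from the pool (HWE) and are
rejection-sampled to exact cohort sizes — case-control ascertainment, not
population prevalence.  The default pool is *phase-identifiable* (no
unordered pool pair admits a second all-pool decomposition; checked by
`pool_is_phase_identifiable` and asserted in tests), so with anchor
coverage the phasing stage can recover every simulated diplotype exactly.
`ensure_anchor_coverage=True` pre-seeds one homozygous carrier per pool
haplotype (status still drawn from the disease model) for
parameter-recovery experiments; it mildly distorts HWE and is off by
default.  Reference alleles share a random backbone per locus and differ
at a limited set of polymorphic sites with pairwise Hamming distance ≥ 2,
so no single-site error converts one allele into another.

Consensus rendering is the exact inverse of calling at error rate 0; the
optional error process substitutes, per position independently, a
uniformly random different IUPAC symbol.  The model-implied population
allele-copy OR is computed exactly by `expected_allele_or` (≈ 3.81 under
the defaults — case-control allele frequencies attenuate a per-copy odds
model below its per-copy OR), and it is this value, not the nominal 4,
that CI-coverage experiments target.

What the generator does **not** emulate: linkage disequilibrium between
the SNP panel and the DLA haplotypes (the two tracks are independent),
population structure or relatedness, genotyping-array error modes, indels,
and chromatogram-level artifacts.  Passing recovery tests therefore show
algorithmic correctness under the stated model, not robustness to real
Sanger or array data pathologies.

All generators are pure functions of (config, seed); independent RNG
streams per stage keep each output reproducible regardless of which stages
run.

## Numerical and design notes

* Candidate lists, phasing order and report ordering are all sorted
  deterministically; reruns are byte-identical.
* Zero cohort margins raise (`UndefinedTableError`); an all-SNPs-removed
  QC result is an empty dataset, not an error.
* Haplotype count tables place `Unidentified` last; association rows are
  sorted by descending total copy count, then label, mirroring
  most-common-first publication layout.
* Problem sizes used by the validation suite — 50 null panels for λ, 500
  replicates for CI coverage, 1,000 random libraries and 300 random
  cohorts for the brute-force oracle comparisons — were chosen as
  desk-scale defaults that keep sampling error well inside the asserted
  bands.
* The published-table fixtures carry the printed counts and statistics;
  golden tests compare recomputed values at one unit in the last printed
  decimal place, since the source tables themselves round inconsistently
  at half-unit boundaries (two rows with identical counts print CI bounds
  0.06 and 0.07).
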