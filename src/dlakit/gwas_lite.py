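"""Desk-scale genome-wide association scan.

Implements the computation behind a basic PLINK-style case-control scan:
per-SNP quality control (call rate and minor allele frequency), the 1-df
allelic Pearson chi-square test on the 2x2 allele-count table, Bonferroni
adjustment over the number of tested SNPs, the genomic inflation factor
lambda (median observed chi-square over the chi-square_1 median 0.4549364),
and Manhattan / QQ plot data exports.

Genotypes are minor-allele dosages 0/1/2 with NaN for missing; missing
calls are excluded pairwise per SNP, and lambda is reported descriptively
(it is not used to rescale P values).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = 0.4549364

AFFECTED_CODE = 2  # PLINK phenotype convention: 2 = affected, 1 = control


@dataclass
class SnpDataset:
    """Sample x SNP dosage matrix with SNP map metadata.

    ``genotypes`` is an (n_samples, n_snps) float array of minor-allele
    dosages in {0, 1, 2} with NaN for missing; ``affected`` is a boolean
    mask over samples; ``snps`` has columns snp_id, chromosome, position_bp.
    """

    sample_ids: list[str]
    affected: np.ndarray
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.affected = np.asarray(self.affected, dtype=bool)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n_samples, n_snps = self.genotypes.shape
        if len(self.sample_ids) != n_samples or self.affected.shape != (n_samples,):
            raise ValueError("sample dimensions do not match the genotype matrix")
        if len(self.snps) != n_snps:
            raise ValueError("SNP map length does not match the genotype matrix")
        if (self.snps["position_bp"] < 0).any():
            raise ValueError("SNP positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class GwasSummary:
    n_snps_input: int
    n_snps_after_qc: int
    lambda_gc: float


def qc_filter(
    d: SnpDataset, min_call_rate: float = 0.90, min_maf: float = 0.05
) -> SnpDataset:
    """Keep SNPs with call rate >= min_call_rate and MAF >= min_maf.

    MAF is computed over non-missing calls with cohorts pooled, folded to
    the minor side (dosages may count either allele).  A filter that
    removes everything returns an empty dataset rather than raising.
    """
    g = d.genotypes
    called = ~np.isnan(g)
    call_rate = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nansum(g, axis=0) / (2 * called.sum(axis=0))
    af = np.where(np.isnan(af), 0.0, af)
    maf = np.minimum(af, 1 - af)
    keep = (call_rate >= min_call_rate) & (maf >= min_maf)
    return replace(
        d,
        snps=d.snps.loc[keep].reset_index(drop=True),
        genotypes=g[:, keep],
    )


def allelic_test(dosages: np.ndarray, affected: np.ndarray) -> tuple[float, float]:
    """1-df allelic chi-square for one SNP.

    Builds the 2x2 allele-count table (counted x other allele, case x
    control) from dosages of non-missing samples and applies Pearson's
    chi-square without continuity correction.  A degenerate margin (one
    allele absent, or one cohort fully missing) yields (0.0, 1.0).
    """
    dosages = np.asarray(dosages, dtype=float)
    affected = np.asarray(affected, dtype=bool)
    ok = ~np.isnan(dosages)
    a = np.sum(dosages[ok & affected])          # counted allele, cases
    b = 2 * np.sum(ok & affected) - a           # other allele, cases
    c = np.sum(dosages[ok & ~affected])         # counted allele, controls
    d = 2 * np.sum(ok & ~affected) - c
    return _chi2_2x2(a, b, c, d)


def _chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, df=1))


def allelic_scan(d: SnpDataset) -> pd.DataFrame:
    """Vectorised allelic test for every SNP; columns snp_id, chisq, p_raw."""
    g = d.genotypes
    aff = d.affected
    ok = ~np.isnan(g)
    a = np.nansum(np.where(aff[:, None], g, 0.0), axis=0)
    ca = 2 * (ok & aff[:, None]).sum(axis=0)
    c = np.nansum(np.where(~aff[:, None], g, 0.0), axis=0)
    cc = 2 * (ok & ~aff[:, None]).sum(axis=0)
    b, dd = ca - a, cc - c
    n = ca + cc
    r1, r2, c1, c2 = a + b, c + dd, a + c, b + dd
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * dd - b * c) ** 2 / denom, 0.0)
    stat = np.where(n > 0, stat, 0.0)
    p = chi2.sf(stat, df=1)
    p = np.where(denom > 0, p, 1.0)
    return pd.DataFrame(
        {"snp_id": d.snps["snp_id"].to_numpy(), "chisq": stat, "p_raw": p}
    )


def genomic_inflation(chisq: Sequence[float]) -> float:
    """Genomic inflation factor: median chi-square over the null median."""
    arr = np.asarray(chisq, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one statistic is required")
    return float(np.median(arr) / CHI2_1_MEDIAN)


def gwas_run(
    d: SnpDataset, min_call_rate: float = 0.90, min_maf: float = 0.05
) -> tuple[pd.DataFrame, GwasSummary, pd.DataFrame, pd.DataFrame]:
    """QC -> allelic scan -> Bonferroni -> lambda, plus plot exports.

    Returns (results sorted by raw P, summary, manhattan table, qq table).
    Bonferroni multiplies each raw P by the number of SNPs actually tested,
    capped at 1; the ranking by adjusted P therefore equals the raw ranking.
    """
    filtered = qc_filter(d, min_call_rate=min_call_rate, min_maf=min_maf)
    scan = allelic_scan(filtered)
    m = len(scan)
    results = filtered.snps.copy()
    results["chisq"] = scan["chisq"]
    results["p_raw"] = scan["p_raw"]
    results["p_bonferroni"] = np.minimum(1.0, results["p_raw"] * m)
    results = results.sort_values(
        ["p_raw", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)

    lambda_gc = genomic_inflation(scan["chisq"]) if m else float("nan")
    summary = GwasSummary(d.n_snps, m, lambda_gc)

    with np.errstate(divide="ignore"):
        neg_log = -np.log10(results["p_raw"].to_numpy())
    manhattan = pd.DataFrame(
        {
            "snp_id": results["snp_id"],
            "chromosome": results["chromosome"],
            "position_bp": results["position_bp"],
            "neg_log10_p": neg_log,
        }
    )
    observed = np.sort(results["p_raw"].to_numpy())
    expected = (np.arange(1, m + 1) - 0.5) / m if m else np.array([])
    qq = pd.DataFrame(
        {
            "expected_neg_log10_p": -np.log10(expected) if m else [],
            "observed_neg_log10_p": -np.log10(observed) if m else [],
        }
    )
    return results, summary, manhattan, qq


# ---------------------------------------------------------------------------
# Readers: simple TSV dialect and white-space PED/MAP text files
# ---------------------------------------------------------------------------

def read_genotype_tables(geno_path: str | Path, map_path: str | Path) -> SnpDataset:
    """Read the TSV dialect: sample_id, status (1=control, 2=affected), dosages.

    Dosages are 0/1/2 minor-allele copies or NA; the companion map TSV has
    columns snp_id, chromosome, position_bp in matrix column order.
    """
    geno = pd.read_csv(geno_path, sep="\t", dtype={0: str})
    snps = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    sample_ids = geno.iloc[:, 0].tolist()
    status = geno.iloc[:, 1].astype(int).to_numpy()
    dosage = geno.iloc[:, 2:].to_numpy(dtype=float)
    if dosage.shape[1] != len(snps):
        raise ValueError(
            f"{dosage.shape[1]} genotype columns but {len(snps)} SNPs in the map"
        )
    return SnpDataset(sample_ids, status == AFFECTED_CODE, snps, dosage)


def write_genotype_tables(
    d: SnpDataset, geno_path: str | Path, map_path: str | Path
) -> None:
    table = pd.DataFrame(d.genotypes, columns=d.snps["snp_id"])
    table.insert(0, "status", np.where(d.affected, 2, 1))
    table.insert(0, "sample_id", d.sample_ids)
    # Render dosages as integers with NA for missing.
    for col in d.snps["snp_id"]:
        table[col] = table[col].astype("Int64")
    table.to_csv(geno_path, sep="\t", index=False, na_rep="NA")
    d.snps.to_csv(map_path, sep="\t", index=False)


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> SnpDataset:
    """Read white-space separated PED/MAP text files.

    PED columns: family, individual, father, mother, sex, phenotype
    (1=control, 2=affected), then two allele columns per SNP ('0' =
    missing).  Each SNP's two allele columns are collapsed to a dosage of
    the minor allele (pooled cohorts; ties broken to the alphabetically
    first allele).  MAP columns: chromosome, snp_id, genetic distance,
    position_bp.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"], dtype={"chromosome": str},
    )
    snps = map_df[["snp_id", "chromosome", "position_bp"]].copy()
    n_snps = len(snps)

    sample_ids, affected, allele_rows = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"PED row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields) - 6} allele fields, expected {2 * n_snps}"
                )
            sample_ids.append(fields[1])
            affected.append(int(fields[5]) == AFFECTED_CODE)
            allele_rows.append(fields[6:])

    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), n_snps, 2)
    dosage = np.full((len(sample_ids), n_snps), np.nan)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        if observed.size == 0:
            continue
        names, counts = np.unique(observed, return_counts=True)
        # Minor allele: lowest count, ties to alphabetical order.
        minor = names[np.lexsort((names, counts))][0]
        called = (col != "0").all(axis=1)
        dosage[called, j] = (col[called] == minor).sum(axis=1)
    return SnpDataset(sample_ids, np.array(affected), snps, dosage)
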