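"""PLINK 1.x binary I/O, quality control and single-marker association tests.

The genotype matrix is stored samples x SNPs as ``int8`` counts of
``allele1`` (0, 1, 2) with ``-1`` marking a missing call.  Phenotypes are
coded 1 = case, 0 = control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

log = logging.getLogger(__name__)

MISSING: int = -1

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> allele1 count (00 hom A1, 01 missing, 10 het, 11 hom A2)
_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# allele1 count -> 2-bit PLINK code; index 3 is the missing slot (count -1 -> 1)
_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes or unsupported mode)."""


class DatasetConsistencyError(ValueError):
    """bed/bim/fam dimensions (or SNP/sample bookkeeping) disagree."""


class PhenotypeError(ValueError):
    """Phenotype code outside the PLINK 1/2/0/-9 convention."""


class DegenerateDatasetError(ValueError):
    """QC removed every SNP, every sample, or one phenotype group entirely."""


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")


@dataclass
class GenotypeDataset:
    """Case/control genotype matrix plus marker and sample metadata."""

    snps: list[SnpRecord]
    sample_ids: list[str]
    phenotype: np.ndarray  # int8, 1 = case, 0 = control
    genotypes: np.ndarray  # (n_samples, n_snps) int8, -1 = missing

    _snp_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_samples, n_snps = self.genotypes.shape
        if n_snps != len(self.snps) or n_samples != len(self.sample_ids):
            raise DatasetConsistencyError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if self.phenotype.shape != (n_samples,):
            raise DatasetConsistencyError("phenotype length does not match samples")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise PhenotypeError("internal phenotype codes must be 0/1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DegenerateDatasetError("need at least one case and one control")
        ids = [s.snp_id for s in self.snps]
        self._snp_index = {sid: j for j, sid in enumerate(ids)}
        if len(self._snp_index) != len(ids):
            raise DatasetConsistencyError("duplicate SNP identifiers")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP ids; unknown ids raise."""
        try:
            return np.array([self._snp_index[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:
            raise DatasetConsistencyError(f"SNP {exc.args[0]!r} not in dataset") from exc

    def subset_snps(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            snps=[self.snps[j] for j in index],
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype.copy(),
            genotypes=self.genotypes[:, index].copy(),
        )

    def subset_samples(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            snps=list(self.snps),
            sample_ids=[self.sample_ids[i] for i in index],
            phenotype=self.phenotype[index].copy(),
            genotypes=self.genotypes[index, :].copy(),
        )


@dataclass
class QcReport:
    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_by_missingness: int
    removed_by_maf: int
    removed_by_hwe: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AssocResult:
    chi_square: np.ndarray  # per SNP, >= 0
    p_value: np.ndarray  # per SNP, in (0, 1]


# ---------------------------------------------------------------------------
# PLINK binary I/O
# ---------------------------------------------------------------------------

def read_bim(bim_path) -> pd.DataFrame:
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    return bim


def read_plink_dataset(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK 1.x bed/bim/fam triple into a :class:`GenotypeDataset`.

    Only the SNP-major layout (mode byte ``0x01``) is supported.  fam
    phenotypes are mapped 2 -> case, 1 -> control; samples coded 0 or -9
    (missing phenotype) are dropped with a warning; any other code raises
    :class:`PhenotypeError`.
    """
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phe"],
        dtype={"fid": str, "iid": str},
    )
    bim = read_bim(bim_path)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _PLINK_MAGIC[:2]:
        raise PlinkFormatError(f"{bed_path}: not a PLINK bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise PlinkFormatError(f"{bed_path}: only SNP-major bed files are supported")

    n_samples, n_snps = len(fam), len(bim)
    bytes_per_snp = (n_samples + 3) // 4
    if raw.size - 3 != n_snps * bytes_per_snp:
        raise DatasetConsistencyError(
            f"{bed_path}: payload of {raw.size - 3} bytes does not match "
            f"{n_snps} SNPs x {bytes_per_snp} bytes"
        )

    body = raw[3:].reshape(n_snps, bytes_per_snp)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    geno = _DECODE[codes[:, :n_samples]].T  # (n_samples, n_snps)

    phe = fam["phe"].astype(int).to_numpy()
    bad = ~np.isin(phe, [1, 2, 0, -9])
    if bad.any():
        raise PhenotypeError(
            f"{fam_path}: phenotype codes {sorted(set(phe[bad].tolist()))} "
            "outside {1, 2, 0, -9}"
        )
    keep = np.isin(phe, [1, 2])
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d samples with missing phenotype", n_dropped)

    snps = [
        SnpRecord(r.snp_id, r.chrom, int(r.pos), r.allele1, r.allele2)
        for r in bim.itertuples()
    ]
    return GenotypeDataset(
        snps=snps,
        sample_ids=fam.loc[keep, "iid"].tolist(),
        phenotype=(phe[keep] == 2).astype(np.int8),
        genotypes=geno[keep, :],
    )


def write_plink_dataset(ds: GenotypeDataset, prefix) -> None:
    """Write bed/bim/fam files at ``prefix`` (SNP-major, bit-stable)."""
    prefix = str(prefix)
    with open(prefix + ".fam", "w") as fh:
        for sid, phe in zip(ds.sample_ids, ds.phenotype):
            fh.write(f"{sid} {sid} 0 0 0 {2 if phe == 1 else 1}\n")
    with open(prefix + ".bim", "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\t{s.allele1}\t{s.allele2}\n")

    n_samples = ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    code_of = np.zeros(4, dtype=np.uint8)
    for count, code in _ENCODE.items():
        code_of[count] = code  # index -1 wraps to slot 3 on purpose
    codes = code_of[ds.genotypes.T]  # (n_snps, n_samples)
    padded = np.ones((ds.n_snps, bytes_per_snp * 4), dtype=np.uint8) * 0b00
    padded[:, :n_samples] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(genotype_counts) -> float:
    """Exact two-sided Hardy-Weinberg test on (n_AA, n_Aa, n_aa) counts.

    Sums the probability of every heterozygote configuration (with the
    observed allele counts fixed) that is no more probable than the
    observed one.  Returns a p-value in (0, 1].
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in genotype_counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all-zero genotype counts")

    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het = h | n, n_rare) up to a shared constant
    from scipy.special import gammaln, logsumexp

    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Allelic association
# ---------------------------------------------------------------------------

def allele_table_chi2(a_case, alleles_case, a_total, alleles_total):
    """Pearson 1-df chi-square of 2x2 allele tables from margin counts.

    ``a_*`` count allele1; ``alleles_*`` count all non-missing alleles.
    Tables with a zero margin (monomorphic SNP or an empty phenotype
    group) yield 0 by convention.  Fully vectorised.
    """
    a_case = np.asarray(a_case, dtype=np.float64)
    alleles_case = np.asarray(alleles_case, dtype=np.float64)
    a_total = np.asarray(a_total, dtype=np.float64)
    alleles_total = np.asarray(alleles_total, dtype=np.float64)

    b_case = alleles_case - a_case
    a_ctrl = a_total - a_case
    alleles_ctrl = alleles_total - alleles_case
    b_ctrl = alleles_ctrl - a_ctrl

    det = a_case * b_ctrl - b_case * a_ctrl
    denom = alleles_case * alleles_ctrl * a_total * (alleles_total - a_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, alleles_total * det * det / denom, 0.0)
    return chi2


def allelic_association_pvalues(ds: GenotypeDataset) -> AssocResult:
    """Per-SNP allelic chi-square test (2x2 allele table, 1 df, no
    continuity correction) on non-missing genotypes.  Monomorphic SNPs or
    SNPs with an empty phenotype group get chi-square 0 and p = 1."""
    case = ds.case_mask.astype(np.float64)
    nonmiss = ds.genotypes != MISSING
    gz = np.where(nonmiss, ds.genotypes, 0).astype(np.float64)
    alleles = nonmiss.astype(np.float64) * 2.0

    a_case = case @ gz
    alleles_case = case @ alleles
    a_total = gz.sum(axis=0)
    alleles_total = alleles.sum(axis=0)

    empty_group = (alleles_case == 0) | (alleles_case == alleles_total)
    if empty_group.any():
        log.warning(
            "%d SNPs have zero non-missing calls in one phenotype group; p = 1",
            int(empty_group.sum()),
        )
    chi2 = allele_table_chi2(a_case, alleles_case, a_total, alleles_total)
    return AssocResult(chi_square=chi2, p_value=_chi2_dist.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def apply_qc_filters(
    ds: GenotypeDataset,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-3,
):
    """Sequential QC: (1) sample missingness, (2) SNP missingness,
    (3) minor allele frequency, (4) HWE exact test in controls.

    Thresholds follow the strict reading "more than"/"less than": a sample
    or SNP is removed when its missing fraction exceeds ``max_missing``, a
    SNP when its MAF is below ``min_maf`` or its control-group HWE p-value
    is below ``hwe_alpha``.  Returns the surviving dataset plus a
    :class:`QcReport`.
    """
    for name, val in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if not 0.0 <= hwe_alpha <= 1.0:
        raise ValueError("hwe_alpha must be in [0, 1]")

    n_snps_in, n_samples_in = ds.n_snps, ds.n_samples

    # (1) sample missingness
    miss = ds.genotypes == MISSING
    sample_keep = miss.mean(axis=1) <= max_missing
    if not sample_keep.all():
        if sample_keep.sum() == 0:
            raise DegenerateDatasetError("all samples removed by missingness filter")
        try:
            ds = ds.subset_samples(sample_keep)
        except DegenerateDatasetError:
            raise DegenerateDatasetError(
                "sample missingness filter removed every case or every control"
            )

    # (2) SNP missingness
    miss = ds.genotypes == MISSING
    keep = miss.mean(axis=0) <= max_missing
    removed_by_missingness = int((~keep).sum())
    ds = _subset_or_degenerate(ds, keep, "missingness")

    # (3) MAF over all samples
    nonmiss = ds.genotypes != MISSING
    gz = np.where(nonmiss, ds.genotypes, 0)
    with np.errstate(invalid="ignore"):
        freq = gz.sum(axis=0) / (2.0 * nonmiss.sum(axis=0))
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_maf
    removed_by_maf = int((~keep).sum())
    ds = _subset_or_degenerate(ds, keep, "MAF")

    # (4) HWE exact test in controls
    ctrl = ds.genotypes[~ds.case_mask, :]
    keep = np.ones(ds.n_snps, dtype=bool)
    for j in range(ds.n_snps):
        col = ctrl[:, j]
        counts = (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        if sum(counts) == 0:
            continue
        if hwe_exact_test(counts) < hwe_alpha:
            keep[j] = False
    removed_by_hwe = int((~keep).sum())
    ds = _subset_or_degenerate(ds, keep, "HWE")

    report = QcReport(
        n_snps_in=n_snps_in,
        n_snps_out=ds.n_snps,
        n_samples_in=n_samples_in,
        n_samples_out=ds.n_samples,
        removed_by_missingness=removed_by_missingness,
        removed_by_maf=removed_by_maf,
        removed_by_hwe=removed_by_hwe,
    )
    return ds, report


def _subset_or_degenerate(ds, keep, stage):
    if keep.all():
        return ds
    if keep.sum() == 0:
        raise DegenerateDatasetError(f"all SNPs removed by {stage} filter")
    return ds.subset_snps(keep)
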