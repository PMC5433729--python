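"""File formats and quality control.

Readers and writers for PLINK text (.ped/.map) and binary (.bed/.bim/.fam)
genotypes, phased VCF, pedigree TSV, plus SNP quality-control filters (call
rate, MAF, Hardy-Weinberg exact test, Mendelian consistency).

Conventions: coordinates are 1-based inclusive; alleles are biallelic coded
REF="A", ALT="B" on simulated data, and dosages count ALT alleles; missing
dosage is -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import UNKNOWN_PARENT, HaplotypeSet

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK bed, SNP-major, v1.00


@dataclass
class GenotypeSet:
    """Unphased dosages: ``dosage[individual, snp]`` counts ALT alleles, -1 missing."""

    ids: list[str]
    dosage: np.ndarray  # (n, m) int8
    snp_map: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freqs(self) -> np.ndarray:
        d = np.ma.masked_equal(self.dosage, -1)
        return (d.mean(axis=0) / 2.0).filled(np.nan)


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

_SEX_CODE = {"M": "1", "F": "2"}


def write_ped_map(
    haps: HaplotypeSet,
    prefix: str | Path,
    pedigree: pd.DataFrame | None = None,
) -> None:
    """PLINK .ped/.map; haplotype alleles 0/1 are written as 1/2."""
    prefix = Path(prefix)
    smap = haps.snp_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in smap.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    ped_info = None
    if pedigree is not None:
        ped_info = pedigree.set_index("id")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(haps.ids):
            sire = dam = UNKNOWN_PARENT
            sex = "0"
            if ped_info is not None and ind in ped_info.index:
                rec = ped_info.loc[ind]
                sire, dam = rec["sire"], rec["dam"]
                sex = _SEX_CODE.get(rec["sex"], "0")
            cells = [str(x) for pair in zip(haps.alleles[i, 0] + 1, haps.alleles[i, 1] + 1) for x in pair]
            fh.write("\t".join(["0", ind, sire, dam, sex, "-9"] + cells) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeSet:
    """Read PLINK text genotypes; "0 0" allele pairs become missing (-1)."""
    prefix = Path(prefix)
    smap = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        names=["chrom", "snp_id", "cm", "pos"],
    )[["chrom", "pos", "snp_id"]]
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = np.array(parts[6:], dtype=np.int16)
            a1, a2 = alleles[0::2], alleles[1::2]
            dose = (a1 - 1) + (a2 - 1)
            dose[(a1 == 0) | (a2 == 0)] = -1
            rows.append(dose.astype(np.int8))
    return GenotypeSet(ids, np.vstack(rows), smap)


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

# 2-bit genotype codes in a SNP-major v1.00 bed, for ALT dosage with A1=ALT:
# 00 = hom A1 (dosage 2), 01 = missing, 10 = het, 11 = hom A2 (dosage 0)
_DOSE_TO_BED = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_BED_TO_DOSE = np.full(4, -1, dtype=np.int8)
_BED_TO_DOSE[0b00], _BED_TO_DOSE[0b10], _BED_TO_DOSE[0b11] = 2, 1, 0


def write_bed(
    genotypes: GenotypeSet,
    prefix: str | Path,
    pedigree: pd.DataFrame | None = None,
) -> None:
    prefix = Path(prefix)
    smap = genotypes.snp_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in smap.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\tB\tA\n")
    ped_info = pedigree.set_index("id") if pedigree is not None else None
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for ind in genotypes.ids:
            sire = dam = UNKNOWN_PARENT
            sex = "0"
            if ped_info is not None and ind in ped_info.index:
                rec = ped_info.loc[ind]
                sire, dam = rec["sire"], rec["dam"]
                sex = _SEX_CODE.get(rec["sex"], "0")
            fh.write(f"0\t{ind}\t{sire}\t{dam}\t{sex}\t-9\n")
    n = genotypes.n_individuals
    codes = np.empty((genotypes.n_snps, n), dtype=np.uint8)
    for dose, bits in _DOSE_TO_BED.items():
        codes[(genotypes.dosage == dose).T] = bits
    padded = n + (-n) % 4
    block = np.zeros((genotypes.n_snps, padded), dtype=np.uint8)
    block[:, :n] = codes
    shifts = np.tile([0, 2, 4, 6], padded // 4)
    packed = (block << shifts).reshape(genotypes.n_snps, -1, 4).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed(prefix: str | Path) -> GenotypeSet:
    prefix = Path(prefix)
    smap = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )[["chrom", "pos", "snp_id"]]
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        names=["fid", "id", "sire", "dam", "sex", "pheno"],
        dtype=str,
    )
    ids = list(fam["id"])
    n, m = len(ids), len(smap)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK v1.00 bed file (magic mismatch)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != m * bytes_per_snp:
        raise ValueError("truncated bed file")
    body = body.reshape(m, bytes_per_snp)
    twobit = np.stack([(body >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2).reshape(m, -1)[:, :n]
    return GenotypeSet(ids, _BED_TO_DOSE[twobit].T.copy(), smap)


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


def write_vcf(haps: HaplotypeSet, path: str | Path) -> None:
    """Minimal phased VCF (GT only, "|" separated), REF=A ALT=B."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(haps.snp_map["chrom"]):
            length = int(haps.snp_map.loc[haps.snp_map["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(haps.ids) + "\n")
        for s, row in enumerate(haps.snp_map.itertuples(index=False)):
            gts = "\t".join(
                f"{haps.alleles[i, 0, s]}|{haps.alleles[i, 1, s]}" for i in range(haps.n_individuals)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tB\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> HaplotypeSet:
    """Read a phased biallelic VCF (GT with "|") into a HaplotypeSet."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows = []
    map_rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"multi-allelic site {variant.ID} not supported")
        gts = np.array(variant.genotypes)  # (n, 3): a0, a1, phased flag
        if not gts[:, 2].all():
            raise ValueError(f"unphased genotype at {variant.ID}")
        if (gts[:, :2] < 0).any():
            raise ValueError(f"missing genotype at {variant.ID}")
        rows.append(gts[:, :2])
        map_rows.append({"chrom": int(variant.CHROM), "pos": variant.POS, "snp_id": variant.ID})
    alleles = np.stack(rows, axis=2).astype(np.uint8)  # (n, 2, m)
    return HaplotypeSet(ids, alleles, pd.DataFrame(map_rows))


# ---------------------------------------------------------------------------
# Pedigree TSV
# ---------------------------------------------------------------------------


def write_pedigree_tsv(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    required = {"id", "sire", "dam", "sex", "generation"}
    if not required.issubset(ped.columns):
        raise ValueError(f"pedigree TSV must have columns {sorted(required)}")
    return ped


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcParams:
    min_maf: float = 0.05
    min_call_rate: float = 0.90
    hwe_p_threshold: float | None = None  # e.g. 1e-4; None disables the filter
    mendel_check: bool = False
    max_mendel_errors: int = 0  # SNP removed when errors exceed this count

    def __post_init__(self) -> None:
        for v in (self.min_maf, self.min_call_rate):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) no more likely than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def mendel_error_counts(genotypes: GenotypeSet, pedigree: pd.DataFrame) -> np.ndarray:
    """Per-SNP count of opposite-homozygote parent/offspring conflicts."""
    index = {x: i for i, x in enumerate(genotypes.ids)}
    errors = np.zeros(genotypes.n_snps, dtype=int)
    d = genotypes.dosage
    for row in pedigree.itertuples(index=False):
        if row.id not in index:
            continue
        child = d[index[row.id]]
        for parent in (row.sire, row.dam):
            if parent == UNKNOWN_PARENT or parent not in index:
                continue
            par = d[index[parent]]
            conflict = ((par == 0) & (child == 2)) | ((par == 2) & (child == 0))
            errors += conflict & (par >= 0) & (child >= 0)
    return errors


def qc_filter(
    genotypes: GenotypeSet,
    params: QcParams = QcParams(),
    pedigree: pd.DataFrame | None = None,
) -> tuple[GenotypeSet, pd.DataFrame]:
    """Remove SNPs failing call-rate, MAF, HWE or Mendelian screens.

    Returns the filtered set and a per-filter removal log (one row per
    filter with the count of SNPs it removed; a SNP failing several filters
    is attributed to the first in the order call_rate, maf, hwe, mendel).
    """
    d = genotypes.dosage
    n = genotypes.n_individuals
    called = (d >= 0).sum(axis=0)
    call_rate = called / n
    with np.errstate(invalid="ignore"):
        freq = np.where(called > 0, np.where(d < 0, 0, d).sum(axis=0) / (2 * np.maximum(called, 1)), np.nan)
    maf = np.minimum(freq, 1 - freq)

    fail_call = call_rate < params.min_call_rate
    fail_maf = ~fail_call & (maf < params.min_maf)
    fail_hwe = np.zeros_like(fail_call)
    if params.hwe_p_threshold is not None:
        for s in np.flatnonzero(~fail_call & ~fail_maf):
            col = d[:, s]
            p = hwe_exact_p(int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum()))
            fail_hwe[s] = p < params.hwe_p_threshold
    fail_mendel = np.zeros_like(fail_call)
    if params.mendel_check:
        if pedigree is None:
            raise ValueError("mendel_check requires a pedigree")
        errors = mendel_error_counts(genotypes, pedigree)
        fail_mendel = ~fail_call & ~fail_maf & ~fail_hwe & (errors > params.max_mendel_errors)

    keep = ~(fail_call | fail_maf | fail_hwe | fail_mendel)
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    log = pd.DataFrame(
        {
            "filter": ["call_rate", "maf", "hwe", "mendel", "kept"],
            "snps": [
                int(fail_call.sum()),
                int(fail_maf.sum()),
                int(fail_hwe.sum()),
                int(fail_mendel.sum()),
                int(keep.sum()),
            ],
        }
    )
    filtered = GenotypeSet(
        list(genotypes.ids),
        d[:, keep].copy(),
        genotypes.snp_map.loc[keep].reset_index(drop=True),
    )
    return filtered, log
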