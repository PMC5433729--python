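"""Genomic and pedigree relationship matrices.

Three constructions are provided:

* an identity-by-descent (IBD) proportion matrix built from haplotype-hashing
  segment detection (seed-and-extend over fixed SNP slices, in the style of
  GERMLINE with ``-bits`` and ``-err_hom`` parameters);
* the VanRaden method-1 allele-sharing matrix from dosages;
* the pedigree numerator relationship matrix A by the tabular method.

IBD relationships are expressed as the summed length of shared segments over
the total genome length, unioned per individual pair so that a region shared
by several haplotype combinations counts once.  The diagonal is 1 plus the
within-individual sharing (genomic inbreeding), matching the convention of
the exact ancestry-based oracle in :mod:`keycontrib.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MatrixKind = str  # {"ibd", "allele_sharing", "pedigree", "external"}


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    ids: list[str]
    kind: MatrixKind = "external"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        index = {x: i for i, x in enumerate(self.ids)}
        rows = np.array([index[x] for x in ids])
        return RelationshipMatrix(self.values[np.ix_(rows, rows)], list(ids), self.kind)


def write_matrix_tsv(matrix: RelationshipMatrix, path: str | Path) -> None:
    """Square TSV with an id header row and id first column."""
    frame = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    frame.to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path: str | Path, kind: MatrixKind = "external") -> RelationshipMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("matrix TSV row and column ids differ")
    return RelationshipMatrix(frame.to_numpy(dtype=float), [str(x) for x in frame.index], kind)


# ---------------------------------------------------------------------------
# IBD segment detection (haplotype hashing, seed and extend)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IbdParams:
    """Slice-hashing parameters.

    bits
        SNPs per non-overlapping slice (hash word length).
    err_hom
        Number of opposite-homozygote genotype conflicts tolerated in a
        bridged slice during extension.
    min_length_bp
        Minimum reported segment length (3 Mb default).
    """

    bits: int = 9
    err_hom: int = 1
    min_length_bp: int = 3_000_000

    def __post_init__(self) -> None:
        if self.bits < 2:
            raise ValueError("bits must be >= 2")
        if self.err_hom < 0 or self.min_length_bp < 0:
            raise ValueError("err_hom and min_length_bp must be >= 0")


@dataclass(frozen=True)
class IbdSegment:
    individual_i: str
    individual_j: str
    chromosome: int
    start_bp: int
    end_bp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _slice_words(hap_alleles: np.ndarray, bits: int) -> np.ndarray:
    """Pack consecutive ``bits``-SNP windows of each haplotype into integers."""
    n_hap, m = hap_alleles.shape
    n_slices = m // bits
    trimmed = hap_alleles[:, : n_slices * bits].reshape(n_hap, n_slices, bits)
    weights = (1 << np.arange(bits, dtype=np.int64))
    return trimmed.astype(np.int64) @ weights


def _matching_pairs(words: np.ndarray) -> dict[int, set[tuple[int, int]]]:
    """For each slice, the set of haplotype pairs with identical words."""
    n_hap, n_slices = words.shape
    out: dict[int, set[tuple[int, int]]] = {}
    for s in range(n_slices):
        order = np.argsort(words[:, s], kind="stable")
        w = words[order, s]
        pairs: set[tuple[int, int]] = set()
        start = 0
        for t in range(1, n_hap + 1):
            if t == n_hap or w[t] != w[start]:
                if t - start > 1:
                    grp = np.sort(order[start:t])
                    for a in range(len(grp)):
                        for b in range(a + 1, len(grp)):
                            pairs.add((int(grp[a]), int(grp[b])))
                start = t
        out[s] = pairs
    return out


def detect_ibd_segments(
    haps,
    params: IbdParams = IbdParams(),
) -> list[IbdSegment]:
    """Detect pairwise IBD segments from phased haplotypes.

    For every chromosome the SNPs are cut into consecutive slices of
    ``params.bits`` SNPs.  Haplotype pairs with identical slice words (found
    by exact hashing) seed matches; maximal runs of consecutive matching
    slices form candidate segments.  A single non-matching slice flanked by
    matching ones is bridged when the two *individuals* conflict at no more
    than ``err_hom`` opposite-homozygote sites inside it.  Segments from all
    four haplotype combinations of an individual pair are unioned, and
    segments shorter than ``min_length_bp`` are dropped.
    """
    segments: list[IbdSegment] = []
    smap = haps.snp_map
    ids = haps.ids
    n = len(ids)
    for chrom in sorted(smap["chrom"].unique()):
        cols = np.flatnonzero((smap["chrom"] == chrom).to_numpy())
        pos = smap["pos"].to_numpy()[cols]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"SNP positions not strictly increasing on chrom {chrom}")
        alleles = haps.alleles[:, :, cols]
        hap_alleles = alleles.reshape(n * 2, len(cols))
        words = _slice_words(hap_alleles, params.bits)
        n_slices = words.shape[1]
        pairs_by_slice = _matching_pairs(words)

        # slice boundaries in bp (inclusive SNP-position spans)
        starts_bp = pos[np.arange(n_slices) * params.bits]
        ends_bp = pos[np.arange(1, n_slices + 1) * params.bits - 1]

        genotypes = alleles.sum(axis=1)  # (n, mc)

        def hom_conflicts(i: int, j: int, s: int) -> int:
            lo, hi = s * params.bits, (s + 1) * params.bits
            gi = genotypes[i, lo:hi]
            gj = genotypes[j, lo:hi]
            return int(np.sum((gi == 0) & (gj == 2)) + np.sum((gi == 2) & (gj == 0)))

        # run detection per haplotype pair with single-slice bridging
        active: dict[tuple[int, int], int] = {}  # pair -> run start slice
        pending: dict[tuple[int, int], int] = {}  # pair skipped previous slice
        raw: dict[tuple[int, int], list[tuple[int, int]]] = {}

        def close(pair: tuple[int, int], s_start: int, s_end: int) -> None:
            i, j = pair[0] // 2, pair[1] // 2
            if i == j:
                return
            key = (min(i, j), max(i, j))
            raw.setdefault(key, []).append((s_start, s_end))

        for s in range(n_slices):
            pairs = pairs_by_slice[s]
            for pair in pairs:
                if pair in active:
                    continue
                if pair in pending:
                    active[pair] = pending.pop(pair)
                else:
                    active[pair] = s
            for pair, s0 in list(pending.items()):
                if pair not in pairs:
                    close(pair, s0, s - 2)
                    del pending[pair]
            for pair, s0 in list(active.items()):
                if pair not in pairs:
                    i, j = pair[0] // 2, pair[1] // 2
                    if i != j and hom_conflicts(i, j, s) <= params.err_hom:
                        pending[pair] = s0  # may be bridged if next slice matches
                    else:
                        close(pair, s0, s - 1)
                    del active[pair]
        for pair, s0 in pending.items():
            close(pair, s0, n_slices - 2)
        for pair, s0 in active.items():
            close(pair, s0, n_slices - 1)

        for (i, j), runs in raw.items():
            intervals = sorted(
                (int(starts_bp[a]), int(ends_bp[b])) for a, b in runs if b >= a
            )
            merged: list[list[int]] = []
            for lo, hi in intervals:
                if merged and lo <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            for lo, hi in merged:
                if hi - lo + 1 >= params.min_length_bp:
                    segments.append(IbdSegment(ids[i], ids[j], int(chrom), lo, hi))
    return segments


def write_segments_tsv(segments: list[IbdSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tchrom\tstart\tend\tlength_bp\n")
        for s in segments:
            fh.write(
                f"{s.individual_i}\t{s.individual_j}\t{s.chromosome}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.length_bp}\n"
            )


def ibd_relationship_matrix(
    segments: list[IbdSegment],
    ids: list[str],
    genome_length_bp: float,
    self_segments: list[IbdSegment] | None = None,
) -> RelationshipMatrix:
    """IBD-proportion matrix: summed segment length over genome length.

    The diagonal is 1; callers with within-individual sharing information may
    pass ``self_segments`` (segments between the two haplotypes of one
    individual, id repeated) to add genomic inbreeding on the diagonal.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    values = np.zeros((n, n))
    for s in segments:
        if s.individual_i not in index or s.individual_j not in index:
            raise KeyError(f"segment references unknown id {s.individual_i}/{s.individual_j}")
        i, j = index[s.individual_i], index[s.individual_j]
        values[i, j] += s.length_bp
        if i != j:
            values[j, i] += s.length_bp
    values /= genome_length_bp
    np.fill_diagonal(values, 1.0 + np.diag(values))
    if self_segments:
        for s in self_segments:
            i = index[s.individual_i]
            values[i, i] += s.length_bp / genome_length_bp
    off = values[~np.eye(n, dtype=bool)]
    if off.size and off.max() > 1.0 + 1e-9:
        raise ValueError("off-diagonal IBD proportion exceeds 1")
    return RelationshipMatrix(values, list(ids), kind="ibd")


def ibd_grm(haps, params: IbdParams = IbdParams()) -> RelationshipMatrix:
    """Segment detection followed by the proportion matrix, in one call."""
    smap = haps.snp_map
    genome = float(
        smap.groupby("chrom")["pos"].max().sum()
    )
    segments = detect_ibd_segments(haps, params)
    return ibd_relationship_matrix(segments, haps.ids, genome)


# ---------------------------------------------------------------------------
# Allele sharing (VanRaden method 1) and pedigree numerator matrices
# ---------------------------------------------------------------------------


def allele_sharing_grm(
    genotypes: np.ndarray,
    ids: list[str],
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden method-1 GRM: Z Zᵀ / Σ 2p(1-p), Z = dosage − 2p.

    Sample ALT frequencies are used when ``freqs`` is not given; monomorphic
    SNPs are excluded from both Z and the denominator.
    """
    dosage = np.asarray(genotypes, dtype=float)
    if freqs is None:
        freqs = dosage.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    p = freqs[poly]
    z = dosage[:, poly] - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return RelationshipMatrix(z @ z.T / denom, list(ids), kind="allele_sharing")


def pedigree_numerator_matrix(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix A by the tabular method."""
    from .simulate import UNKNOWN_PARENT

    ids = list(pedigree["id"])
    index = {x: i for i, x in enumerate(ids)}
    sires = []
    dams = []
    for row in pedigree.itertuples(index=False):
        for parent, store in ((row.sire, sires), (row.dam, dams)):
            if parent == UNKNOWN_PARENT:
                store.append(-1)
            else:
                if parent not in index:
                    raise KeyError(f"parent {parent!r} missing from pedigree")
                p = index[parent]
                if p >= index[row.id]:
                    raise ValueError("pedigree must list parents before offspring")
                store.append(p)
    n = len(ids)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        a_sd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * a_sd
        val = np.zeros(i)
        if s >= 0:
            val += 0.5 * a[s, :i]
        if d >= 0:
            val += 0.5 * a[d, :i]
        a[i, :i] = val
        a[:i, i] = val
    return RelationshipMatrix(a, ids, kind="pedigree")
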