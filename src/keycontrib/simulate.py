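"""Gene-drop simulation of a discrete-generation livestock breeding design.

The default design mirrors a five-generation random-mating scheme: a base
population of 20 males and 1,000 females; every later generation is produced
by mating each of the 20 sires to 50 dams of the previous generation, each dam
leaving one female offspring except for 20 dams (redrawn every generation)
that leave one male and one female.  The genome is 5 chromosomes of 100 Mb
carrying 2,000 equally spaced SNPs each.

Recombination follows the Haldane model: crossover counts are Poisson with
mean equal to the chromosome length in Morgans (1 Morgan per 100 Mb by
default), crossover positions uniform, no interference.  Every transmitted
chromosome is tracked back to its founder haplotype of origin, which gives an
exact identity-by-descent oracle for the whole pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .relmat import RelationshipMatrix

UNKNOWN_PARENT = "0"


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the breeding design and genome."""

    n_males: int = 20
    n_females: int = 1000
    dams_per_sire: int = 50
    two_offspring_dams: int = 20
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    snps_per_chrom: int = 2000
    bp_per_morgan: float = 100_000_000.0

    def __post_init__(self) -> None:
        if self.n_males * self.dams_per_sire != self.n_females:
            raise ValueError(
                "design requires n_males * dams_per_sire == n_females "
                f"({self.n_males} * {self.dams_per_sire} != {self.n_females})"
            )
        if self.two_offspring_dams > self.n_females:
            raise ValueError("two_offspring_dams exceeds number of dams")

    @property
    def generation_size(self) -> int:
        # one female per dam plus a male+female pair for the selected dams
        return self.n_females + self.two_offspring_dams

    @property
    def genome_length_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp


def snp_map(design: SimDesign = SimDesign()) -> pd.DataFrame:
    """Equally spaced SNP positions (1-based bp) over every chromosome."""
    spacing = design.chrom_length_bp // design.snps_per_chrom
    frames = []
    for c in range(1, design.n_chromosomes + 1):
        pos = spacing * np.arange(1, design.snps_per_chrom + 1, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos": pos,
                    "snp_id": [f"snp{c}_{i + 1}" for i in range(design.snps_per_chrom)],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class HaplotypeSet:
    """Phased biallelic haplotypes: ``alleles[individual, haplotype, snp]``.

    Haplotype 0 is paternal, haplotype 1 maternal.  ``snp_map`` holds one row
    per SNP (chrom, pos, snp_id) in the same column order as ``alleles``.
    """

    ids: list[str]
    alleles: np.ndarray  # (n, 2, m) uint8 in {0, 1}
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValueError("alleles must have shape (n, 2, m)")
        if self.alleles.shape[0] != len(self.ids):
            raise ValueError("ids and alleles disagree on individual count")
        if self.alleles.shape[2] != len(self.snp_map):
            raise ValueError("snp_map and alleles disagree on SNP count")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[2]

    def genotypes(self) -> np.ndarray:
        """ALT-allele dosage matrix (n, m) with values 0/1/2."""
        return self.alleles.sum(axis=1).astype(np.int8)

    def subset(self, ids: list[str]) -> "HaplotypeSet":
        index = {x: i for i, x in enumerate(self.ids)}
        rows = [index[x] for x in ids]
        return HaplotypeSet(list(ids), self.alleles[rows], self.snp_map)


@dataclass
class AncestryTracks:
    """Founder-haplotype origin of every chromosome in the pedigree.

    ``tracks[i][h][c]`` is a pair of arrays ``(ends, labels)``: segment k of
    haplotype ``h`` of individual ``i`` on chromosome index ``c`` covers
    base-pair interval ``[ends[k-1], ends[k])`` (with an implicit 0 start) and
    descends from founder haplotype ``labels[k]``.  Labels are
    ``2 * founder_index + haplotype``.
    """

    ids: list[str]
    chrom_lengths: list[int]
    tracks: list  # [individual][haplotype][chromosome] -> (ends, labels)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def labels_at(self, chrom_index: int, positions: np.ndarray) -> np.ndarray:
        """Founder labels at given bp positions: array (n, 2, len(positions))."""
        positions = np.asarray(positions)
        out = np.empty((len(self.ids), 2, positions.size), dtype=np.int16)
        for i in range(len(self.ids)):
            for h in (0, 1):
                ends, labels = self.tracks[i][h][chrom_index]
                # segment k covers (ends[k-1], ends[k]] in 1-based bp
                out[i, h] = labels[np.searchsorted(ends, positions, side="left")]
        return out

    def grid_labels(self, points_per_chrom: int) -> np.ndarray:
        """Labels on a regular genome-wide grid, concatenated over chromosomes."""
        blocks = []
        for c, length in enumerate(self.chrom_lengths):
            step = length / points_per_chrom
            pos = (step * (np.arange(points_per_chrom) + 0.5)).astype(np.int64)
            blocks.append(self.labels_at(c, pos))
        return np.concatenate(blocks, axis=2)


def simulate_pedigree(
    n_generations: int,
    seed: int | np.random.Generator,
    design: SimDesign = SimDesign(),
) -> pd.DataFrame:
    """Simulate the discrete-generation pedigree.

    Returns a frame with columns id, sire, dam, sex ('M'/'F') and generation;
    unknown parents are coded "0".  Generation 0 holds ``n_males`` males and
    ``n_females`` unrelated females; every later generation is produced by the
    mating rule described in the module docstring, so each one contains
    ``n_females + two_offspring_dams`` individuals.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str, str, int]] = []

    males = [f"F0M{i + 1:04d}" for i in range(design.n_males)]
    females = [f"F0F{i + 1:04d}" for i in range(design.n_females)]
    for m in males:
        records.append((m, UNKNOWN_PARENT, UNKNOWN_PARENT, "M", 0))
    for f in females:
        records.append((f, UNKNOWN_PARENT, UNKNOWN_PARENT, "F", 0))

    for g in range(1, n_generations):
        dams = np.array(females)
        rng.shuffle(dams)
        sire_of_dam = np.repeat(np.array(males), design.dams_per_sire)
        twice = set(rng.choice(len(dams), size=design.two_offspring_dams, replace=False))
        new_males: list[str] = []
        new_females: list[str] = []
        for d in range(len(dams)):
            fid = f"F{g}F{len(new_females) + 1:04d}"
            records.append((fid, sire_of_dam[d], dams[d], "F", g))
            new_females.append(fid)
            if d in twice:
                mid = f"F{g}M{len(new_males) + 1:04d}"
                records.append((mid, sire_of_dam[d], dams[d], "M", g))
                new_males.append(mid)
        males, females = new_males, new_females

    return pd.DataFrame(records, columns=["id", "sire", "dam", "sex", "generation"])


def check_pedigree(pedigree: pd.DataFrame) -> None:
    """Validate parentage: parents precede offspring, no cycles, known sexes."""
    gen = dict(zip(pedigree["id"], pedigree["generation"]))
    for _, row in pedigree.iterrows():
        for parent in (row["sire"], row["dam"]):
            if parent == UNKNOWN_PARENT:
                continue
            if parent not in gen:
                raise ValueError(f"unknown parent {parent!r} of {row['id']!r}")
            if gen[parent] >= row["generation"]:
                raise ValueError(f"parent {parent!r} does not precede {row['id']!r}")


def simulate_founder_haplotypes(
    snp_map: pd.DataFrame,
    n_founders: int,
    seed: int | np.random.Generator,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotype alleles with independent SNPs.

    Allele frequencies are drawn per SNP from Uniform(maf_range); alleles are
    sampled independently for each of the ``2 * n_founders`` haplotypes.
    Returns ``(alleles, freqs)`` where alleles has shape (2*n_founders, m) —
    row ``2*f + h`` is haplotype ``h`` of founder ``f`` — and freqs the drawn
    ALT frequencies.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    m = len(snp_map)
    freqs = rng.uniform(lo, hi, size=m)
    alleles = (rng.random((2 * n_founders, m)) < freqs).astype(np.uint8)
    return alleles, freqs


def _splice(source: list, cuts: np.ndarray, first: int, length: int):
    """Form a gamete track from the two parental tracks of one chromosome.

    ``cuts`` are crossover positions; the gamete copies from parental
    haplotype ``first`` up to the first cut, then alternates.
    """
    bounds = np.concatenate([cuts, [length]])
    out_ends: list[int] = []
    out_labels: list[int] = []
    start = 0
    hap = first
    for b in bounds:
        ends, labels = source[hap]
        k0 = np.searchsorted(ends, start, side="right")
        k1 = np.searchsorted(ends, b, side="left")
        for k in range(k0, k1 + 1):
            seg_end = min(int(ends[k]), int(b))
            if seg_end > start:
                if out_labels and out_labels[-1] == labels[k]:
                    out_ends[-1] = seg_end  # merge contiguous same-origin pieces
                else:
                    out_ends.append(seg_end)
                    out_labels.append(int(labels[k]))
                start = seg_end
            if start >= b:
                break
        hap = 1 - hap
        start = int(b)
    return np.array(out_ends, dtype=np.int64), np.array(out_labels, dtype=np.int32)


def drop_ancestry(
    pedigree: pd.DataFrame,
    seed: int | np.random.Generator,
    design: SimDesign = SimDesign(),
) -> AncestryTracks:
    """Gene-drop founder labels through the pedigree (no alleles needed).

    Founders receive trivial single-segment tracks; every non-founder receives
    one recombinant gamete from each parent (haplotype 0 from the sire,
    haplotype 1 from the dam) under the Haldane model.
    """
    rng = np.random.default_rng(seed)
    ids = list(pedigree["id"])
    index = {x: i for i, x in enumerate(ids)}
    lengths = [design.chrom_length_bp] * design.n_chromosomes
    morgans = [length / design.bp_per_morgan for length in lengths]
    tracks: list = [None] * len(ids)

    n_founders = 0
    for i, row in enumerate(pedigree.itertuples(index=False)):
        if row.sire == UNKNOWN_PARENT and row.dam == UNKNOWN_PARENT:
            tracks[i] = [
                [
                    (np.array([length], dtype=np.int64),
                     np.array([2 * n_founders + h], dtype=np.int32))
                    for length in lengths
                ]
                for h in (0, 1)
            ]
            n_founders += 1
            continue
        if row.sire == UNKNOWN_PARENT or row.dam == UNKNOWN_PARENT:
            raise ValueError(f"individual {row.id!r} has exactly one known parent")
        haps = []
        for parent in (row.sire, row.dam):
            p = index.get(parent)
            if p is None or tracks[p] is None:
                raise ValueError(f"parent {parent!r} not simulated before {row.id!r}")
            gamete = []
            for c, length in enumerate(lengths):
                n_x = rng.poisson(morgans[c])
                cuts = np.sort(rng.integers(1, length, size=n_x))
                first = int(rng.integers(2))
                source = [tracks[p][0][c], tracks[p][1][c]]
                gamete.append(_splice(source, cuts, first, length))
            haps.append(gamete)
        tracks[i] = haps

    return AncestryTracks(ids=ids, chrom_lengths=lengths, tracks=tracks)


def alleles_from_tracks(
    ancestry: AncestryTracks,
    founder_alleles: np.ndarray,
    snp_map: pd.DataFrame,
) -> HaplotypeSet:
    """Materialize SNP alleles for every haplotype from its founder tracks."""
    m = len(snp_map)
    n = ancestry.n_individuals
    alleles = np.empty((n, 2, m), dtype=np.uint8)
    col = 0
    for c, chrom in enumerate(sorted(snp_map["chrom"].unique())):
        pos = snp_map.loc[snp_map["chrom"] == chrom, "pos"].to_numpy()
        labels = ancestry.labels_at(c, pos)  # (n, 2, mc)
        alleles[:, :, col : col + pos.size] = founder_alleles[labels, np.arange(col, col + pos.size)]
        col += pos.size
    return HaplotypeSet(list(ancestry.ids), alleles, snp_map.reset_index(drop=True))


def drop_genes(
    pedigree: pd.DataFrame,
    founder_alleles: np.ndarray,
    snp_map: pd.DataFrame,
    seed: int | np.random.Generator,
    design: SimDesign = SimDesign(),
) -> tuple[HaplotypeSet, AncestryTracks]:
    """Ancestry gene drop followed by allele materialization."""
    ancestry = drop_ancestry(pedigree, seed, design)
    return alleles_from_tracks(ancestry, founder_alleles, snp_map), ancestry


@njit(cache=True)
def _grid_ibd_kernel(lab):  # pragma: no cover - exercised through true_ibd_matrix
    n, _, P = lab.shape
    G = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        a0 = lab[i, 0]
        a1 = lab[i, 1]
        c_self = 0
        for p in range(P):
            if a0[p] == a1[p]:
                c_self += 1
        G[i, i] = 1.0 + c_self / P
        for j in range(i + 1, n):
            b0 = lab[j, 0]
            b1 = lab[j, 1]
            c = 0
            for p in range(P):
                x0 = a0[p]
                x1 = a1[p]
                y0 = b0[p]
                y1 = b1[p]
                if x0 == y0 or x0 == y1 or x1 == y0 or x1 == y1:
                    c += 1
            G[i, j] = c / P
            G[j, i] = G[i, j]
    return G


def _labels_at_one(track, positions: np.ndarray) -> np.ndarray:
    ends, labels = track
    return labels[np.searchsorted(ends, positions, side="left")]


def true_ibd_matrix(
    ancestry: AncestryTracks,
    grid_points_per_chrom: int | None = None,
) -> RelationshipMatrix:
    """Exact ancestry-based IBD-sharing relationship matrix.

    Off-diagonal entry (i, j) is the fraction of the genome over which *any*
    haplotype of i carries the same founder label as *any* haplotype of j
    (union counting — shared regions count once regardless of how many
    haplotype pairs share).  The diagonal is 1 plus the genomic inbreeding of
    the individual (fraction shared between its own two haplotypes).

    With ``grid_points_per_chrom`` the sharing integral is evaluated on a
    regular grid (fast, numba) instead of exactly on segment boundaries.
    """
    n = ancestry.n_individuals
    if grid_points_per_chrom is not None:
        lab = ancestry.grid_labels(grid_points_per_chrom)
        values = _grid_ibd_kernel(np.ascontiguousarray(lab))
        return RelationshipMatrix(values=values, ids=list(ancestry.ids), kind="ibd")

    total = float(sum(ancestry.chrom_lengths))
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            shared = 0.0
            for c, length in enumerate(ancestry.chrom_lengths):
                ti = ancestry.tracks[i]
                tj = ancestry.tracks[j]
                cuts = np.unique(
                    np.concatenate(
                        [ti[0][c][0], ti[1][c][0], tj[0][c][0], tj[1][c][0]]
                    )
                )
                starts = np.concatenate([[0], cuts[:-1]])
                mids = (starts + cuts) / 2.0
                li0 = _labels_at_one(ti[0][c], mids)
                li1 = _labels_at_one(ti[1][c], mids)
                lj0 = _labels_at_one(tj[0][c], mids)
                lj1 = _labels_at_one(tj[1][c], mids)
                if i == j:
                    match = li0 == li1
                else:
                    match = (
                        (li0 == lj0) | (li0 == lj1) | (li1 == lj0) | (li1 == lj1)
                    )
                shared += float(((cuts - starts) * match).sum())
            frac = shared / total
            values[i, j] = values[j, i] = (1.0 + frac) if i == j else frac
    return RelationshipMatrix(values=values, ids=list(ancestry.ids), kind="ibd")


def simulate_population(
    n_generations: int = 5,
    seed: int = 0,
    design: SimDesign = SimDesign(),
    with_alleles: bool = True,
) -> "SimulatedPopulation":
    """Run the full simulation: pedigree, founders, gene drop.

    A single seed governs everything through named substreams, so any prefix
    of the outputs is reproducible independently of which products are
    requested.
    """
    ss = np.random.SeedSequence(seed)
    s_ped, s_founders, s_drop = ss.spawn(3)
    pedigree = simulate_pedigree(n_generations, np.random.default_rng(s_ped), design)
    smap = snp_map(design)
    ancestry = drop_ancestry(pedigree, np.random.default_rng(s_drop), design)
    founder_alleles = freqs = haplotypes = None
    if with_alleles:
        n_founders = int(
            ((pedigree["sire"] == UNKNOWN_PARENT) & (pedigree["dam"] == UNKNOWN_PARENT)).sum()
        )
        founder_alleles, freqs = simulate_founder_haplotypes(
            smap, n_founders, np.random.default_rng(s_founders)
        )
        haplotypes = alleles_from_tracks(ancestry, founder_alleles, smap)
    return SimulatedPopulation(
        design=design,
        pedigree=pedigree,
        snp_map=smap,
        ancestry=ancestry,
        haplotypes=haplotypes,
        founder_alleles=founder_alleles,
        founder_freqs=freqs,
    )


@dataclass
class SimulatedPopulation:
    design: SimDesign
    pedigree: pd.DataFrame
    snp_map: pd.DataFrame
    ancestry: AncestryTracks
    haplotypes: HaplotypeSet | None = None
    founder_alleles: np.ndarray | None = None
    founder_freqs: np.ndarray | None = None

    def ids_of(self, *, generations=None, sexes=None) -> list[str]:
        """Ids filtered by generation and/or sex, in pedigree order."""
        ped = self.pedigree
        mask = np.ones(len(ped), dtype=bool)
        if generations is not None:
            mask &= ped["generation"].isin(list(generations)).to_numpy()
        if sexes is not None:
            mask &= ped["sex"].isin(list(sexes)).to_numpy()
        return list(ped.loc[mask, "id"])

    def analysis_set(self, max_generation: int, full: bool = False) -> list[str]:
        """Founder males plus every individual of generations 1..max_generation.

        This is the nested series of analysis panels used throughout: base
        males with the first progeny generation, then successively adding
        later generations.  ``full=True`` returns the complete population
        (founder females included), the whole-dataset panel.
        """
        if full:
            return list(self.pedigree["id"])
        males = self.ids_of(generations=[0], sexes=["M"])
        rest = self.ids_of(generations=range(1, max_generation + 1))
        return males + rest

    def sires(self, up_to_generation: int) -> list[str]:
        """Males of generations 0..up_to_generation (the breeding sires)."""
        return self.ids_of(generations=range(0, up_to_generation + 1), sexes=["M"])
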