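"""Phasing-accuracy and inbreeding metrics.

The switch-error rate of an inferred haplotype pair against the truth is the
number of phase-orientation changes between consecutive heterozygous sites
divided by (number of heterozygous sites - 1).  Orientation is relative, so
a globally swapped haplotype pair has rate 0.  Switches are counted within
chromosomes only and pooled per individual with one denominator decrement
per chromosome.

Also here: the genome-based method-of-moments inbreeding coefficient
``f = (observed hom - expected hom) / (m - expected hom)`` with expectations
from sample allele frequencies, and two simple reference phasers used to
exercise the selection-strategy comparison: an orientation-flip noiser with
constant error rate (calibration), and one whose per-individual error rate
shrinks with the individual's total relatedness to the population, emulating
the fact that individuals with many close relatives are phased accurately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix
from .simulate import HaplotypeSet


@dataclass
class SwitchErrorReport:
    per_individual: pd.DataFrame  # id, het_sites, switches, rate
    mean_rate: float              # mean of defined per-individual rates
    pooled_rate: float            # total switches / total (h_c - 1)


def _orientation(truth_a: np.ndarray, inferred_a: np.ndarray, het: np.ndarray) -> np.ndarray:
    """+1 where inferred haplotype 0 equals truth haplotype 0 at het sites."""
    return np.where(inferred_a[het] == truth_a[het], 1, -1)


def switch_error_rate(truth: HaplotypeSet, inferred: HaplotypeSet) -> SwitchErrorReport:
    """Per-individual switch-error rates of ``inferred`` phase vs truth.

    Both sets must contain the same individuals, SNPs and (unphased)
    genotypes; a genotype mismatch raises.  Individuals with fewer than two
    heterozygous sites on every chromosome have an undefined rate (NaN) and
    are excluded from the cohort mean.
    """
    if truth.ids != inferred.ids:
        raise ValueError("individual sets differ")
    if truth.alleles.shape != inferred.alleles.shape:
        raise ValueError("SNP sets differ")
    gt = truth.genotypes()
    gi = inferred.genotypes()
    if not np.array_equal(gt, gi):
        raise ValueError("genotypes differ between truth and inferred (not a phase difference)")

    chroms = truth.snp_map["chrom"].to_numpy()
    rows = []
    total_switch = 0
    total_denom = 0
    for i, ind in enumerate(truth.ids):
        het_total = 0
        switches = 0
        denom = 0
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            het = cols[gt[i, cols] == 1]
            if het.size < 2:
                het_total += het.size
                continue
            orient = np.where(inferred.alleles[i, 0, het] == truth.alleles[i, 0, het], 1, -1)
            switches += int(np.sum(orient[1:] != orient[:-1]))
            het_total += het.size
            denom += het.size - 1
        rate = switches / denom if denom > 0 else np.nan
        rows.append({"id": ind, "het_sites": het_total, "switches": switches, "rate": rate})
        total_switch += switches
        total_denom += denom
    frame = pd.DataFrame(rows)
    defined = frame["rate"].dropna()
    return SwitchErrorReport(
        per_individual=frame,
        mean_rate=float(defined.mean()) if len(defined) else np.nan,
        pooled_rate=total_switch / total_denom if total_denom else np.nan,
    )


@dataclass
class InbreedingReport:
    per_individual: pd.DataFrame  # id, observed_hom, expected_hom, f
    freqs: np.ndarray             # allele frequencies used (polymorphic SNPs)


def inbreeding_coefficient(
    genotypes: np.ndarray,
    ids: list[str],
    freqs: np.ndarray | None = None,
) -> InbreedingReport:
    """Method-of-moments genomic inbreeding from ALT dosages.

    ``f_j = (O_j - E) / (m - E)`` with ``O_j`` individual j's homozygous
    site count, ``E = Σ_i (1 - 2 p_i q_i)`` the expected homozygous count
    under Hardy-Weinberg at the (sample) allele frequencies, and ``m`` the
    number of polymorphic SNPs.
    """
    dosage = np.asarray(genotypes)
    if freqs is None:
        freqs = dosage.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    p = freqs[poly]
    m = int(poly.sum())
    expected = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    if m == expected:
        raise ZeroDivisionError("expected homozygosity equals SNP count")
    observed = (dosage[:, poly] != 1).sum(axis=1)
    f = (observed - expected) / (m - expected)
    frame = pd.DataFrame(
        {"id": ids, "observed_hom": observed, "expected_hom": expected, "f": f}
    )
    return InbreedingReport(per_individual=frame, freqs=p)


# ---------------------------------------------------------------------------
# Built-in reference phasers (evaluation harness)
# ---------------------------------------------------------------------------


def _flip_phase(haps: HaplotypeSet, flip_prob: np.ndarray, rng: np.random.Generator) -> HaplotypeSet:
    """Re-phase by random orientation flips.

    At every junction between consecutive heterozygous sites (per individual
    per chromosome) the phase orientation is switched with the individual's
    ``flip_prob``; homozygous sites are unaffected.
    """
    out = haps.alleles.copy()
    chroms = haps.snp_map["chrom"].to_numpy()
    gt = haps.genotypes()
    for i in range(haps.n_individuals):
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            het = cols[gt[i, cols] == 1]
            if het.size < 2:
                continue
            flips = rng.random(het.size - 1) < flip_prob[i]
            orient = np.concatenate([[0], np.cumsum(flips)]) % 2
            swap = het[orient == 1]
            out[i, 0, swap], out[i, 1, swap] = (
                haps.alleles[i, 1, swap],
                haps.alleles[i, 0, swap],
            )
    return HaplotypeSet(list(haps.ids), out, haps.snp_map)


def random_flip_phaser(
    truth: HaplotypeSet,
    epsilon: float,
    seed: int | np.random.Generator,
) -> HaplotypeSet:
    """Noisy phaser with a constant switch rate ``epsilon`` for everyone."""
    rng = np.random.default_rng(seed)
    return _flip_phase(truth, np.full(truth.n_individuals, epsilon), rng)


def relatedness_noise_phaser(
    truth: HaplotypeSet,
    G: RelationshipMatrix,
    epsilon_max: float,
    seed: int | np.random.Generator,
    scale: float = 0.2,
) -> HaplotypeSet:
    """Noisy phaser whose error rate decreases with relatedness support.

    Individual i's flip rate is ``epsilon_max / (1 + scale * c_i)`` where
    ``c_i = Σ_{j≠i} G_ij`` is i's total relationship to the population —
    a stand-in for the empirical behaviour of pedigree/population phasers,
    which phase well-connected individuals (many close relatives carrying
    their haplotypes) far more accurately than isolated ones.
    """
    index = {x: i for i, x in enumerate(G.ids)}
    rows = np.array([index[x] for x in truth.ids])
    # support is relatedness to the *whole* population behind G, not only to
    # the individuals being phased
    connectivity = (G.values.sum(axis=1) - np.diag(G.values))[rows]
    eps = epsilon_max / (1.0 + scale * np.clip(connectivity, 0.0, None))
    rng = np.random.default_rng(seed)
    return _flip_phase(truth, eps, rng)
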