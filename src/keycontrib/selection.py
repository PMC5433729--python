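"""Reference-population selection strategies.

Four ways of choosing an n-individual reference set for sequencing or
phasing, compared throughout the package:

Con
    top key contributors by genetic contribution score ``gc_j``.
Rel
    greedy maximization of the expected relationship variance a set captures
    in the whole population (Goddard-Hayes style): at each step add the
    candidate maximizing ``mean_j G_{j,S} G_{S,S}^{-1} G_{S,j}``.
Ped
    pedigree-based marginal gene contributions (Boichard-style ancestor
    analysis): repeatedly pick the ancestor with the largest expected share
    of the reference genes not already explained by earlier picks, where
    gene flow through an already-selected individual is blocked.
Ran
    uniform random sample without replacement (seeded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrib import ContributionResult
from .relmat import RelationshipMatrix
from .simulate import UNKNOWN_PARENT


@dataclass
class SelectionResult:
    strategy: str               # {"Con", "Rel", "Ped", "Ran"}
    selected: list[str]         # in selection order
    scores: np.ndarray          # per-selected criterion value
    n_requested: int

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate ids in selection")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "rank": np.arange(1, len(self.selected) + 1),
                "id": self.selected,
                "score": self.scores,
            }
        )


def select_con(contribution: ContributionResult, n: int) -> SelectionResult:
    """Top-n individuals by genetic contribution score."""
    if n > len(contribution.ids):
        raise ValueError("n exceeds population size")
    chosen = contribution.ranking[:n]
    gc = dict(zip(contribution.ids, contribution.gc))
    return SelectionResult("Con", chosen, np.array([gc[x] for x in chosen]), n)


def captured_variance(G: RelationshipMatrix, selected: list[str], ridge: float | None = None) -> float:
    """Mean over the population of ``G_{j,S} G_{S,S}^{-1} G_{S,j}``."""
    index = {x: i for i, x in enumerate(G.ids)}
    s = np.array([index[x] for x in selected])
    gss = G.values[np.ix_(s, s)]
    if ridge is None:
        ridge = 1e-8 * np.trace(gss) / max(len(s), 1)
    gss = gss + ridge * np.eye(len(s))
    gps = G.values[:, s]
    sol = np.linalg.solve(gss, gps.T)
    return float(np.mean(np.sum(gps.T * sol, axis=0)))


def select_rel(G: RelationshipMatrix, n: int, candidates: list[str] | None = None) -> SelectionResult:
    """Greedy forward selection maximizing captured relationship variance.

    Equivalent to pivoted-Cholesky-style updates: after selecting set S the
    residual matrix is ``R = G - G_{.,S} G_{S,S}^{-1} G_{S,.}`` and the gain
    of candidate c is ``mean_j R_{j,c}^2 / R_{c,c}``; the residual update
    after picking c is rank one.  A tiny ridge guards the division for
    near-duplicate candidates, which therefore add ~zero gain and are never
    preferred.
    """
    if n > G.n:
        raise ValueError("n exceeds population size")
    index = {x: i for i, x in enumerate(G.ids)}
    pool = np.array([index[x] for x in (candidates or G.ids)])
    r = G.values.copy()
    ridge = 1e-8 * float(np.trace(r)) / G.n
    chosen: list[int] = []
    gains: list[float] = []
    value = 0.0
    for _ in range(n):
        diag = np.clip(r[pool, pool], ridge, None)
        gain = np.mean(r[:, pool] ** 2, axis=0) / diag
        gain[np.isin(pool, chosen)] = -np.inf
        best = pool[int(np.argmax(gain))]
        g = float(np.max(gain))
        col = r[:, best].copy()
        r -= np.outer(col, col) / max(r[best, best], ridge)
        chosen.append(int(best))
        value += g
        gains.append(value)
    return SelectionResult("Rel", [G.ids[i] for i in chosen], np.array(gains), n)


def _gene_contributions(
    pedigree: pd.DataFrame,
    reference_ids: list[str],
    blocked: set[str],
) -> pd.Series:
    """Marginal expected gene contributions to a reference set.

    For each candidate a this is the expected share of reference genes whose
    transmission path reaches a without passing through a ``blocked``
    (already selected) individual, times the fraction of a's own genome not
    descending from blocked ancestors — so contributions already credited to
    earlier selections are not counted again.
    """
    ids = list(pedigree["id"])
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    # contrib[a, i]: share of i's genes reaching i from a along unblocked paths
    contrib = np.zeros((n, n))
    # explained[i]: share of i's genome descending from blocked individuals
    explained = np.zeros(n)
    for i, row in enumerate(pedigree.itertuples(index=False)):
        if row.id in blocked:
            contrib[i, i] = 1.0
            explained[i] = 1.0
            continue
        for parent in (row.sire, row.dam):
            if parent != UNKNOWN_PARENT:
                p = index[parent]
                contrib[:, i] += 0.5 * contrib[:, p]
                explained[i] += 0.5 * explained[p]
        contrib[i, i] = 1.0
    ref = np.array([index[x] for x in reference_ids])
    raw = contrib[:, ref].mean(axis=1)
    return pd.Series(raw * (1.0 - explained), index=ids)


def select_ped(
    pedigree: pd.DataFrame,
    reference_ids: list[str],
    n: int,
) -> SelectionResult:
    """Iterative marginal gene contributions of ancestors to a reference set.

    Round r selects the pedigree member with the largest expected gene
    contribution to the reference individuals computed while blocking gene
    flow through the r-1 previously selected members, so each score is the
    contribution *not yet explained* by earlier selections.
    """
    known = set(pedigree["id"])
    missing = set(reference_ids) - known
    if missing:
        raise KeyError(f"reference ids missing from pedigree: {sorted(missing)[:3]}")
    if n > len(known):
        raise ValueError("n exceeds pedigree size")
    chosen: list[str] = []
    scores: list[float] = []
    for _ in range(n):
        contrib = _gene_contributions(pedigree, reference_ids, set(chosen))
        contrib[chosen] = -np.inf
        best = contrib.idxmax()
        chosen.append(best)
        scores.append(float(contrib[best]))
    return SelectionResult("Ped", chosen, np.array(scores), n)


def select_random(ids: list[str], n: int, seed: int | np.random.Generator) -> SelectionResult:
    """Uniform sample without replacement."""
    if n > len(ids):
        raise ValueError("n exceeds population size")
    rng = np.random.default_rng(seed)
    chosen = [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
    return SelectionResult("Ran", chosen, np.full(n, np.nan), n)


def overlap_report(selections: list[SelectionResult]) -> pd.DataFrame:
    """Counts of every intersection region among 2+ selections (Venn counts).

    Each row is one region, keyed by membership flags per strategy; the
    ``count`` column gives the number of ids exactly in that combination.
    """
    if len(selections) < 2:
        raise ValueError("need at least two selections")
    names = [s.strategy for s in selections]
    if len(set(names)) != len(names):
        names = [f"{s.strategy}{i}" for i, s in enumerate(selections)]
    sets = {name: set(s.selected) for name, s in zip(names, selections)}
    universe = set().union(*sets.values())
    rows = []
    for mask in range(1, 2 ** len(names)):
        inside = [names[b] for b in range(len(names)) if mask >> b & 1]
        outside = [x for x in names if x not in inside]
        region = set.intersection(*(sets[x] for x in inside)) - set().union(
            set(), *(sets[x] for x in outside)
        )
        rows.append({**{x: x in inside for x in names}, "count": len(region)})
    report = pd.DataFrame(rows)
    assert report["count"].sum() == len(universe)
    return report
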