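"""Key-contributor identification from a relationship matrix.

The method has three ingredients:

1. the eigenvalue decomposition ``G = U Λ Uᵀ`` of the (symmetric,
   positive semi-definite) relationship matrix;
2. Horn's parallel analysis to decide how many leading components ``k`` are
   significant: the PCA spectrum of ``G`` — treated as an n-observation ×
   n-variable data matrix, columns standardized, exactly as the classic
   *paran* procedure treats input data — is compared rank by rank against
   the spectrum of structure-free Gaussian data of the same shape, and a
   component is retained when its observed eigenvalue exceeds the
   ``1 - alpha`` Monte-Carlo quantile of the null at that rank;
3. per-individual scores: with standardized eigenvectors
   ``s_i = u_i / sqrt(λ_i)``, the projection ``r_ij = s_iᵀ g_j`` of
   individual *j*'s relationship profile onto component *i* gives the genetic
   contribution score ``gc_j = Σ_{i<=k} r_ij²``.  Individuals ranked in the
   top *k* by ``gc`` are the key contributors.

``gc`` has two useful closed forms used by the tests: ``r_ij = sqrt(λ_i)
u_ij`` so that ``gc_j -> G_jj`` as ``k -> n``, and ``Σ_j gc_j = Σ_{i<=k}
λ_i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import eigsh

from .relmat import RelationshipMatrix

_DENSE_LIMIT = 3000  # full spectra below this size; Lanczos above


@dataclass
class EvdResult:
    """Eigendecomposition of G with eigenvalues in descending order."""

    eigenvalues: np.ndarray
    vectors: np.ndarray  # (n, q) orthonormal columns
    ids: list[str]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def standardized(self, k: int, tol_rel: float = 1e-10) -> np.ndarray:
        """Columns ``s_i = u_i / sqrt(λ_i)`` for the top k components."""
        if k > self.eigenvalues.size:
            raise ValueError(f"k={k} exceeds computed components ({self.eigenvalues.size})")
        lam = self.eigenvalues[:k]
        if lam.size and lam.min() <= tol_rel * max(self.eigenvalues[0], 0.0):
            raise ValueError("eigenvalue below tolerance; standardized vector undefined")
        return self.vectors[:, :k] / np.sqrt(lam)


def eigendecompose(G: RelationshipMatrix, top: int | None = None) -> EvdResult:
    """Full (or leading-``top``) EVD of the relationship matrix."""
    n = G.n
    if top is None or top >= n:
        lam, u = np.linalg.eigh(G.values)
        order = np.argsort(lam)[::-1]
        return EvdResult(lam[order], u[:, order], list(G.ids))
    lam, u = eigsh(G.values, k=top, which="LA")
    order = np.argsort(lam)[::-1]
    return EvdResult(lam[order], u[:, order], list(G.ids))


# ---------------------------------------------------------------------------
# Horn's parallel analysis
# ---------------------------------------------------------------------------


def _standardize_columns(x: np.ndarray, center: bool) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return ((x - x.mean(axis=0)) if center else x) / sd


def pca_spectrum(
    x: np.ndarray,
    top: int | None = None,
    center: bool = False,
) -> tuple[np.ndarray, float]:
    """Leading eigenvalues of the scaled second-moment matrix of ``x``.

    Columns are scaled to unit standard deviation; by default they are *not*
    mean-centered, so that a set of q disjoint group-mean patterns yields q
    structural components rather than the q-1 contrasts survived by centering.
    Returns ``(eigenvalues descending, total)`` where ``total`` is the full
    eigenvalue sum (the matrix trace), available even when only the leading
    ``top`` eigenvalues are computed by Lanczos iteration on the implicit
    ``ZᵀZ/(n-1)``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    z = _standardize_columns(x, center)
    total = float((z * z).sum() / (n - 1))
    # single precision above the dense limit: the spectra involved are O(1)
    # to O(n) in magnitude, far above float32 resolution
    if n > _DENSE_LIMIT:
        z = z.astype(np.float32)
    c = (z.T @ z) / (n - 1)
    lam = np.linalg.eigvalsh(c)[::-1].astype(np.float64)
    if top is not None:
        lam = lam[:top]
    return lam, total


def null_spectrum_quantiles(
    n: int,
    alpha: float = 0.01,
    iterations: int = 100,
    seed: int | np.random.Generator | None = None,
    top: int | None = None,
) -> np.ndarray:
    """Rank-wise ``1 - alpha`` quantiles of null PCA eigenvalues.

    The null replicates are n × n standard-normal data matrices — data with
    the dimensions of the relationship matrix but no structure — whose
    correlation-matrix spectra define, per rank, the eigenvalue magnitude
    expected by chance.
    """
    if iterations < 20:
        warnings.warn("fewer than 20 parallel-analysis iterations; quantiles are unstable")
    rng = np.random.default_rng(seed)
    if top is None and n > _DENSE_LIMIT:
        top = min(400, n - 1)
    draws = []
    for _ in range(iterations):
        x = rng.standard_normal((n, n))
        draws.append(pca_spectrum(x, top=top)[0])
    width = min(len(d) for d in draws)
    stacked = np.stack([d[:width] for d in draws])
    return np.quantile(stacked, 1.0 - alpha, axis=0)


@dataclass
class ParallelAnalysisResult:
    k: int
    alpha: float
    iterations: int
    observed: np.ndarray        # leading PCA eigenvalues of G-as-data
    null_quantiles: np.ndarray  # same ranks
    n: int
    total: float                # full eigenvalue sum (trace), exact
    null: str = "normal"

    def proportion_variance(self, k: int | None = None) -> float:
        """Fraction of relationship-structure variance in the top components.

        The denominator is the exact eigenvalue total (the trace of the
        scaled second-moment matrix), so a partial spectrum suffices.
        """
        k = self.k if k is None else k
        if k > self.observed.size:
            raise ValueError("k exceeds computed spectrum")
        return float(self.observed[:k].sum() / self.total)


def significant_components(
    G: RelationshipMatrix,
    alpha: float = 0.01,
    iterations: int = 100,
    seed: int | np.random.Generator | None = None,
    max_components: int | None = None,
    null_quantiles: np.ndarray | None = None,
    genotypes: np.ndarray | None = None,
    null: str = "normal",
) -> ParallelAnalysisResult:
    """Horn's parallel analysis on the relationship matrix.

    ``null="normal"`` (default) draws structure-free Gaussian data of the
    same dimensions, as in the classic *paran* procedure.  With
    ``null="permutation"`` and a dosage matrix in ``genotypes``, each
    replicate instead permutes every SNP column independently (destroying
    relatedness while preserving allele frequencies), rebuilds a VanRaden
    relationship matrix and takes its PCA spectrum.  Precomputed
    ``null_quantiles`` (which depend only on ``n``, ``alpha`` and the
    iteration count for the normal null) may be passed to amortize the
    Monte-Carlo cost over analyses of equal size.
    """
    n = G.n
    rng = np.random.default_rng(seed)
    top = max_components
    if top is None and n > _DENSE_LIMIT:
        top = min(400, n - 1)

    observed, total = pca_spectrum(G.values, top=top)

    if null_quantiles is None:
        if null == "normal":
            null_quantiles = null_spectrum_quantiles(
                n, alpha=alpha, iterations=iterations, seed=rng, top=top
            )
        elif null == "permutation":
            if genotypes is None:
                raise ValueError("permutation null requires a genotype dosage matrix")
            from .relmat import allele_sharing_grm

            if iterations < 20:
                warnings.warn("fewer than 20 parallel-analysis iterations; quantiles are unstable")
            draws = []
            dosage = np.asarray(genotypes, dtype=np.float64)
            for _ in range(iterations):
                perm = rng.permuted(dosage, axis=0)
                g0 = allele_sharing_grm(perm, list(G.ids))
                draws.append(pca_spectrum(g0.values, top=top)[0])
            width = min(len(d) for d in draws)
            null_quantiles = np.quantile(np.stack([d[:width] for d in draws]), 1.0 - alpha, axis=0)
        else:
            raise ValueError(f"unknown null {null!r}")

    width = min(observed.size, null_quantiles.size)
    exceed = observed[:width] > null_quantiles[:width]
    # contiguous retention: components are kept until the first rank whose
    # eigenvalue is within the null range (deep-tail ranks where a structured
    # spectrum dips below the null are not evidence of structure)
    k = width if exceed.all() else int(np.argmin(exceed))
    if k == width and width < n:
        # spectrum saturated: recompute with a wider window
        return significant_components(
            G,
            alpha=alpha,
            iterations=iterations,
            seed=rng,
            max_components=min(n, 2 * width),
            genotypes=genotypes,
            null=null,
        )
    return ParallelAnalysisResult(
        k=k,
        alpha=alpha,
        iterations=iterations,
        observed=observed[:width],
        null_quantiles=null_quantiles[:width],
        n=n,
        total=total,
        null=null,
    )


# ---------------------------------------------------------------------------
# Contribution scores
# ---------------------------------------------------------------------------


@dataclass
class ContributionResult:
    ids: list[str]
    r: np.ndarray       # (k, n) projections r_ij = s_iᵀ g_j
    gc: np.ndarray      # (n,) genetic contribution scores
    k: int
    ranking: list[str]  # ids by gc descending, ties stable in input order
    key_contributors: list[str]  # top-k of the ranking

    def to_frame(self):
        import pandas as pd

        rank_of = {x: r + 1 for r, x in enumerate(self.ranking)}
        key = set(self.key_contributors)
        return pd.DataFrame(
            {
                "id": self.ids,
                "gc": self.gc,
                "rank": [rank_of[x] for x in self.ids],
                "is_key_contributor": [x in key for x in self.ids],
            }
        )

    def top(self, n: int) -> list[str]:
        return self.ranking[:n]


def standardized_eigenvectors(evd: EvdResult, k: int) -> np.ndarray:
    """Matrix S (n × k) with columns ``u_i / sqrt(λ_i)``; ``sᵢᵀ G sⱼ = δᵢⱼ``."""
    return evd.standardized(k)


def contribution_scores(
    G: RelationshipMatrix,
    k: int,
    evd: EvdResult | None = None,
) -> ContributionResult:
    """Project every individual onto the top-k components and score it.

    ``r_ij = s_iᵀ g_j`` with ``g_j`` the j-th column of G, and
    ``gc_j = Σ_{i<=k} r_ij²``; individuals are ranked by ``gc`` descending
    (ties broken by input order) and the top k flagged as key contributors.
    """
    if evd is None:
        evd = eigendecompose(G, top=None if G.n <= _DENSE_LIMIT else min(G.n - 1, max(2 * k, k + 50)))
    if list(evd.ids) != list(G.ids):
        raise ValueError("EVD and matrix orderings differ")
    s = evd.standardized(k)
    r = s.T @ G.values
    gc = np.sum(r * r, axis=0)
    order = np.argsort(-gc, kind="stable")
    ranking = [G.ids[i] for i in order]
    return ContributionResult(
        ids=list(G.ids),
        r=r,
        gc=gc,
        k=k,
        ranking=ranking,
        key_contributors=ranking[:k],
    )


def key_contributor_analysis(
    G: RelationshipMatrix,
    alpha: float = 0.01,
    iterations: int = 100,
    seed: int | np.random.Generator | None = None,
    null_quantiles: np.ndarray | None = None,
    max_components: int | None = None,
) -> tuple[ParallelAnalysisResult, ContributionResult]:
    """Parallel analysis followed by contribution scoring, in one call.

    Uses a partial eigensolver for the scoring step on large matrices (only
    the retained components are needed).
    """
    pa = significant_components(
        G,
        alpha=alpha,
        iterations=iterations,
        seed=seed,
        null_quantiles=null_quantiles,
        max_components=max_components,
    )
    top = None if G.n <= _DENSE_LIMIT else min(G.n - 1, max(2 * pa.k, pa.k + 50, 130))
    evd = eigendecompose(G, top=top)
    return pa, contribution_scores(G, pa.k, evd)


def proportion_variance(evd: EvdResult, k: int) -> float:
    """Σ_{i<=k} λ_i / Σ_i max(λ_i, 0) for an explicit eigenvalue set."""
    if k > evd.eigenvalues.size:
        raise ValueError("k exceeds number of eigenvalues")
    lam = evd.eigenvalues
    return float(lam[:k].sum() / np.clip(lam, 0.0, None).sum())
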