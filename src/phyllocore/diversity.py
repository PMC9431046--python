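"""Alpha/beta diversity primitives, rarefaction, PERMANOVA and PCoA.

Bray-Curtis dissimilarities computed on an ASV subset keep the ORIGINAL
per-sample totals as denominators, so the mean dissimilarity of a candidate
core set is attributable relative to the whole community; renormalizing
within the subset would inflate the contribution of small early sets.

PERMANOVA is the single-factor distance-based variance decomposition
(among/within sums of squared distances), reported as a pseudo-F, an R² and
a permutation p-value with the +1 correction.  For small two-group designs
an exact mode enumerates every distinct label arrangement instead of
sampling them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .datamodel import AsvTable

__all__ = [
    "PermanovaResult",
    "inverse_simpson",
    "bray_curtis",
    "bray_curtis_matrix",
    "rarefy",
    "mean_pairwise_dissimilarity",
    "permanova",
    "pcoa",
]


class UndefinedDiversityError(ValueError):
    """The requested quantity is undefined for the given input (e.g. an
    all-zero count vector)."""


def inverse_simpson(counts: Sequence[float] | np.ndarray) -> float:
    """Inverse Simpson index 1/Σp²: the effective number of equally
    abundant taxa.  Equals k for a uniform community of k taxa."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise UndefinedDiversityError("inverse Simpson undefined for an empty sample")
    p = arr / total
    return float(1.0 / np.sum(p * p))


def bray_curtis(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 − 2·Σmin(x,y)/(Σx+Σy), in [0, 1]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("count vectors must have equal length")
    denom = xa.sum() + ya.sum()
    if denom <= 0:
        raise UndefinedDiversityError("Bray-Curtis undefined for two empty samples")
    return float(1.0 - 2.0 * np.minimum(xa, ya).sum() / denom)


def bray_curtis_matrix(table: AsvTable, relative: bool = True) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances, by default on relative abundances."""
    data = table.relative_abundances() if relative else table.counts.astype(float)
    arr = data.to_numpy()
    n = arr.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(arr[i], arr[j])
    return DistanceMatrix(out, ids=table.sample_ids)


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples shallower than ``depth`` are dropped, as are ASV columns that end
    up empty.  One draw per sample (no averaging over repeated rarefactions);
    deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    sub = table.counts.loc[keep]
    out = np.empty(sub.shape, dtype=np.int64)
    for i, sid in enumerate(keep):
        out[i] = rng.multivariate_hypergeometric(sub.loc[sid].to_numpy(), depth)
    rarefied = AsvTable(pd.DataFrame(out, index=keep, columns=sub.columns))
    return rarefied.drop_empty_asvs()


def mean_pairwise_dissimilarity(
    table: AsvTable, asv_subset: Sequence[str] | None = None
) -> float:
    """Mean Bray-Curtis over all unordered sample pairs, optionally with
    counts restricted to ``asv_subset``.

    The pair denominator is always the sum of the two samples' FULL totals:
    BC_S(x, y) = Σ_{i∈S} |x_i − y_i| / (Σx + Σy).  Restricting to a subset
    therefore yields that subset's additive share of the pair's
    dissimilarity, growing from 0 (empty subset) to the ordinary
    Bray-Curtis (all taxa); renormalizing within the subset would inflate
    the contribution of small early sets.
    """
    if table.n_samples < 2:
        raise ValueError("mean pairwise dissimilarity needs at least 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if asv_subset is not None:
        cols = [table.counts.columns.get_loc(a) for a in asv_subset]
        sub = counts[:, cols]
    else:
        sub = counts
    vals = []
    for i, j in itertools.combinations(range(counts.shape[0]), 2):
        denom = totals[i] + totals[j]
        if denom <= 0:
            raise UndefinedDiversityError("Bray-Curtis undefined for two empty samples")
        vals.append(np.abs(sub[i] - sub[j]).sum() / denom)
    return float(np.mean(vals))


@dataclass
class PermanovaResult:
    """Single-factor PERMANOVA outcome."""

    factor: str
    r_squared: float
    p_value: float
    n_permutations: int
    pseudo_f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def _permanova_stats(sq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R²) from a squared-distance matrix and integer labels."""
    n = sq.shape[0]
    ss_total = sq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    n_groups = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        n_groups += 1
        if len(idx) > 1:
            block = sq[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    if ss_within <= 0:
        f = np.inf if ss_among > 0 else 0.0
    else:
        f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return float(f), float(r2)


def permanova(
    dist: DistanceMatrix,
    labels: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "factor",
    exact: bool = False,
) -> PermanovaResult:
    """Permutation test for a location effect of a grouping factor.

    p = (1 + #{permuted F ≥ observed F}) / (1 + n_permutations).  With
    ``exact=True`` all distinct label arrangements are enumerated and
    p = #{F ≥ observed F} / #arrangements (the identity arrangement is one
    of them, so p is never 0).
    """
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != dist.shape[0]:
        raise ValueError("labels must match the distance matrix")
    uniq, enc = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(enc)
    if counts.min() < 1:
        raise ValueError("every group must be non-empty")
    sq = np.asarray(dist.data) ** 2
    f_obs, r2 = _permanova_stats(sq, enc)

    if exact:
        n_items = len(enc)
        arrangements = set(itertools.permutations(enc))
        hits = sum(_permanova_stats(sq, np.asarray(a))[0] >= f_obs for a in arrangements)
        return PermanovaResult(
            factor=factor,
            r_squared=r2,
            p_value=hits / len(arrangements),
            n_permutations=len(arrangements),
            pseudo_f=f_obs,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(enc)
        if _permanova_stats(sq, perm)[0] >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        factor=factor, r_squared=r2, p_value=p, n_permutations=n_permutations, pseudo_f=f_obs
    )


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResults:
    """Classical scaling (principal coordinates) of a distance matrix.

    Axes are ordered by descending eigenvalue; negative eigenvalues are
    reported as-is, not corrected.
    """
    res = _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)
    if n_axes is not None:
        res.samples = res.samples.iloc[:, :n_axes]
        res.eigvals = res.eigvals.iloc[:n_axes]
    return res
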