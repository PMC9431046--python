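"""Core-taxon prioritization from occupancy, consistency and beta-diversity
contribution.

Taxa are ranked by an occupancy/consistency index computed over
department × week cells, then prospective core sets are grown rank by rank;
each set's mean Bray-Curtis dissimilarity, divided by that of the full
community, is its cumulative contribution to beta diversity.  Two stopping
rules turn the curve into a core call: the elbow (the split position
maximizing the difference between the mean slopes of the left and right
segments of the curve) and the less stringent "lastcall" (the deepest rank
whose addition still improves explained beta diversity by at least a
threshold ratio, 2% by default).

The ranking index for taxon *i* over non-empty cells *g*:

    index_i = 1/2 * [ mean_g(o_ig) + (1/G) * #{g : o_ig = 1} ]

where o_ig is the fraction of cell g's samples in which *i* is detected
(≥1 read on the rarefied table) and G is the number of non-empty cells.
The first term rewards broad occupancy, the second rewards consistency —
cells in which the taxon is found in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import AsvTable, SampleMetadata, ValidationError
from .diversity import mean_pairwise_dissimilarity, rarefy

__all__ = [
    "OccupancyAbundanceRecord",
    "CoreRanking",
    "occupancy_abundance",
    "rank_by_occupancy",
    "cumulative_contribution",
    "elbow_rank",
    "lastcall_rank",
    "find_core",
]

DEFAULT_LASTCALL_THRESHOLD = 1.02
DEFAULT_RAREFACTION_DEPTH = 500


@dataclass
class OccupancyAbundanceRecord:
    """One ASV's point on the occupancy-abundance cloud."""

    asv_id: str
    occupancy: float
    mean_relative_abundance: float
    log10_mean_abundance: float


@dataclass
class CoreRanking:
    """Ranked taxa with their cumulative beta-diversity contribution and the
    core calls under the elbow and lastcall stopping rules."""

    table: pd.DataFrame  # rank, asv_id, index, contribution, increase
    elbow_rank: int
    lastcall_rank: int
    rarefaction_seed: int | None = None
    rarefaction_depth: int | None = None

    @property
    def core_elbow(self) -> set[str]:
        return set(self.table["asv_id"].iloc[: self.elbow_rank])

    @property
    def core_lastcall(self) -> set[str]:
        return set(self.table["asv_id"].iloc[: self.lastcall_rank])

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["in_core_elbow"] = df["rank"] <= self.elbow_rank
        df["in_core_lastcall"] = df["rank"] <= self.lastcall_rank
        return df


def occupancy_abundance(table: AsvTable) -> list[OccupancyAbundanceRecord]:
    """Occupancy (fraction of samples with ≥1 read) and mean relative
    abundance (zeros included in the mean) for every ASV."""
    if table.n_samples == 0 or table.n_asvs == 0:
        raise ValueError("occupancy-abundance needs a non-empty table")
    occ = (table.counts > 0).mean(axis=0)
    mean_rel = table.relative_abundances().mean(axis=0)
    with np.errstate(divide="ignore"):
        log10 = np.log10(mean_rel.to_numpy())
    return [
        OccupancyAbundanceRecord(
            asv_id=a,
            occupancy=float(occ[a]),
            mean_relative_abundance=float(mean_rel[a]),
            log10_mean_abundance=float(log10[i]),
        )
        for i, a in enumerate(table.asv_ids)
    ]


def rank_by_occupancy(
    table: AsvTable,
    metadata: SampleMetadata,
    time_factor: str = "week",
    replicate_factor: str = "department",
    weights: tuple[float, float] = (0.5, 0.5),
) -> list[tuple[str, float]]:
    """Rank ASVs by the occupancy/consistency index over
    (replicate_factor × time_factor) cells.

    Ties are broken by mean relative abundance (descending), then ASV id.
    """
    metadata.validate_against(table)
    meta = metadata.frame.loc[table.sample_ids]
    for col in (time_factor, replicate_factor):
        holes = meta.index[meta[col].isna()].tolist()
        if holes:
            raise ValidationError(f"samples missing {col}: {holes}")
    cells = meta.groupby([replicate_factor, time_factor], observed=True)
    presence = table.counts > 0
    per_cell_occ = []
    for _, members in cells:
        per_cell_occ.append(presence.loc[members.index].mean(axis=0))
    occ = pd.DataFrame(per_cell_occ)  # cells × ASVs
    w_occ, w_cons = weights
    norm = w_occ + w_cons
    index = (w_occ * occ.mean(axis=0) + w_cons * (occ == 1.0).mean(axis=0)) / norm
    mean_rel = table.relative_abundances().mean(axis=0)
    order = sorted(
        table.asv_ids, key=lambda a: (-index[a], -mean_rel[a], a)
    )
    return [(a, float(index[a])) for a in order]


def cumulative_contribution(
    table: AsvTable, ranked: Sequence[str]
) -> pd.DataFrame:
    """Cumulative contribution of top-k ranked sets to overall beta diversity.

    contribution_k = mean BC dissimilarity over the top-k set (shares kept on
    the full-sample denominator) / mean BC dissimilarity over all ASVs;
    increase_k = contribution_k / contribution_{k-1}, with increase_1 defined
    as contribution_1.
    """
    if set(ranked) != set(table.asv_ids) or len(ranked) != table.n_asvs:
        raise ValueError("ranked list must cover the table's ASVs exactly once")
    if table.n_samples < 2:
        raise ValueError("cumulative contribution needs at least 2 samples")
    full = mean_pairwise_dissimilarity(table)
    if full <= 0:
        raise ValueError("all samples identical; contribution curve undefined")
    contributions = np.empty(len(ranked))
    for k in range(1, len(ranked) + 1):
        contributions[k - 1] = (
            mean_pairwise_dissimilarity(table, ranked[:k]) / full
        )
    increases = np.empty_like(contributions)
    increases[0] = contributions[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = contributions[1:] / contributions[:-1]
    increases[1:] = np.where(np.isfinite(ratio), ratio, 1.0)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "asv_id": list(ranked),
            "contribution": contributions,
            "increase": increases,
        }
    )


def elbow_rank(curve: Sequence[float]) -> int:
    """Elbow of a cumulative contribution curve.

    Returns the split position p (1-based) maximizing
    (C_p − C_1)/p − (C_n − C_p)/(n − p): the mean slope of the left segment
    minus the mean slope of the right segment.  First maximizer on ties.
    """
    c = np.asarray(curve, dtype=float)
    n = len(c)
    if n < 3:
        raise ValueError("elbow needs a curve of length >= 3")
    best_p, best_val = 1, -np.inf
    for p in range(1, n):
        val = (c[p - 1] - c[0]) / p - (c[-1] - c[p - 1]) / (n - p)
        if val > best_val:
            best_p, best_val = p, val
    return best_p


def lastcall_rank(
    curve: Sequence[float],
    threshold: float = DEFAULT_LASTCALL_THRESHOLD,
    increases: Sequence[float] | None = None,
) -> int:
    """Deepest rank whose addition still improves explained beta diversity
    by at least ``threshold`` (a ratio, default 1.02 = 2% gain); falls back
    to the elbow when no rank beyond the first qualifies."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    c = np.asarray(curve, dtype=float)
    if increases is None:
        inc = np.empty_like(c)
        inc[0] = c[0]
        inc[1:] = c[1:] / c[:-1]
    else:
        inc = np.asarray(increases, dtype=float)
    qualifying = np.flatnonzero(inc >= threshold)
    if len(qualifying) == 0:
        return elbow_rank(c)
    return int(qualifying[-1]) + 1


def find_core(
    table: AsvTable,
    metadata: SampleMetadata,
    time_factor: str = "week",
    replicate_factor: str = "department",
    lastcall_threshold: float = DEFAULT_LASTCALL_THRESHOLD,
    rarefaction_depth: int | None = None,
    rarefaction_seed: int | None = None,
) -> CoreRanking:
    """Full prioritization: rank, contribution curve, elbow and lastcall.

    Expects an already-rarefied table; pass ``rarefaction_depth`` (and a
    seed) to rarefy here instead (default depth 500 when requested).
    """
    if rarefaction_depth is not None:
        seed = 0 if rarefaction_seed is None else rarefaction_seed
        table = rarefy(table, rarefaction_depth, seed)
    ranked = rank_by_occupancy(table, metadata, time_factor, replicate_factor)
    order = [a for a, _ in ranked]
    curve = cumulative_contribution(table, order)
    curve.insert(2, "index", [idx for _, idx in ranked])
    contributions = curve["contribution"].to_numpy()
    e_rank = elbow_rank(contributions)
    l_rank = lastcall_rank(
        contributions, lastcall_threshold, curve["increase"].to_numpy()
    )
    return CoreRanking(
        table=curve,
        elbow_rank=e_rank,
        lastcall_rank=l_rank,
        rarefaction_seed=rarefaction_seed,
        rarefaction_depth=rarefaction_depth,
    )
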