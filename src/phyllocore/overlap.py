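"""Arthropod/phyllosphere overlap: associated ASV sets, dispersal and
transfer indices, and shared-ASV (Venn) partitions.

An ASV is *associated* with an arthropod source (bumblebees, predatory
mites) when it reaches at least two reads in at least one sample of that
source.  A plant sample *qualifies* as impacted when it carries at least
two reads of associated ASVs (the default, read-based rule) or at least two
distinct associated ASVs (the alternative rule).  The dispersal index is
the percentage of plant samples qualifying; the transfer index is the mean,
over qualifying samples, of the share of each sample's reads belonging to
associated ASVs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import AsvTable, presence_matrix

__all__ = [
    "OverlapReport",
    "associated_asv_set",
    "dispersal_index",
    "transfer_index",
    "overlap_report",
    "shared_asv_counts",
]

DEFAULT_PRESENCE_MIN_READS = 2
QUALIFICATION_RULES = ("total_reads", "distinct_asvs")


@dataclass
class OverlapReport:
    """Overlap between one arthropod source and a set of plant samples."""

    source_label: str
    associated_asvs: set[str]
    per_sample: pd.DataFrame  # qualifies, associated_reads, total_reads, transfer_share
    dispersal_index: float  # percent of plant samples qualifying
    transfer_index: float | None  # mean percent share over qualifying samples

    @property
    def n_qualifying(self) -> int:
        return int(self.per_sample["qualifies"].sum())

    @property
    def n_plant_samples(self) -> int:
        return len(self.per_sample)


def associated_asv_set(arthropod_table: AsvTable, min_reads: int = DEFAULT_PRESENCE_MIN_READS) -> set[str]:
    """ASVs reaching ``min_reads`` (default 2) in at least one arthropod sample."""
    if arthropod_table.n_samples == 0:
        warnings.warn("no arthropod samples; associated set is empty", stacklevel=2)
        return set()
    present = presence_matrix(arthropod_table, min_reads)
    return set(present.columns[present.any(axis=0)])


def _qualification(
    plant_table: AsvTable,
    associated: set[str],
    rule: str,
    threshold: int,
) -> pd.DataFrame:
    if rule not in QUALIFICATION_RULES:
        raise ValueError(f"rule must be one of {QUALIFICATION_RULES}")
    assoc_cols = [a for a in plant_table.asv_ids if a in associated]
    assoc_counts = plant_table.counts[assoc_cols]
    associated_reads = assoc_counts.sum(axis=1)
    total_reads = plant_table.sample_totals()
    if rule == "total_reads":
        qualifies = associated_reads >= threshold
    else:
        qualifies = (assoc_counts >= 1).sum(axis=1) >= threshold
    share = (associated_reads / total_reads.where(total_reads > 0)).fillna(0.0)
    return pd.DataFrame(
        {
            "qualifies": qualifies,
            "associated_reads": associated_reads,
            "total_reads": total_reads,
            "transfer_share": share,
        }
    )


def dispersal_index(
    plant_table: AsvTable,
    associated: set[str],
    rule: str = "total_reads",
    threshold: int = 2,
) -> tuple[float, pd.DataFrame]:
    """Percentage of plant samples qualifying as impacted, plus the
    per-sample qualification table."""
    per_sample = _qualification(plant_table, associated, rule, threshold)
    if len(per_sample) == 0:
        return 0.0, per_sample
    return 100.0 * per_sample["qualifies"].mean(), per_sample


def transfer_index(
    plant_table: AsvTable,
    associated: set[str],
    qualifying: pd.Series | Sequence[bool],
) -> float | None:
    """Mean percentage of reads belonging to associated ASVs, averaged
    (unweighted) over qualifying samples; ``None`` when no sample qualifies."""
    per_sample = _qualification(plant_table, associated, "total_reads", 0)
    mask = pd.Series(list(qualifying), index=per_sample.index, dtype=bool)
    if mask.sum() == 0:
        return None
    return 100.0 * float(per_sample.loc[mask, "transfer_share"].mean())


def overlap_report(
    plant_table: AsvTable,
    arthropod_tables: Mapping[str, AsvTable],
    source_label: str | None = None,
    min_reads: int = DEFAULT_PRESENCE_MIN_READS,
    rule: str = "total_reads",
    threshold: int = 2,
) -> OverlapReport:
    """Full overlap report for one source, or (default) for the union of
    all sources ('combined')."""
    if source_label is None or source_label == "combined":
        associated: set[str] = set()
        for t in arthropod_tables.values():
            associated |= associated_asv_set(t, min_reads)
        label = "combined"
    else:
        associated = associated_asv_set(arthropod_tables[source_label], min_reads)
        label = source_label
    disp, per_sample = dispersal_index(plant_table, associated, rule, threshold)
    trans = transfer_index(plant_table, associated, per_sample["qualifies"])
    return OverlapReport(
        source_label=label,
        associated_asvs=associated,
        per_sample=per_sample,
        dispersal_index=disp,
        transfer_index=trans,
    )


def shared_asv_counts(
    tables: Mapping[str, AsvTable], min_reads: int = DEFAULT_PRESENCE_MIN_READS
) -> dict[frozenset[str], int]:
    """Venn partition of group-level ASV sets (2 or 3 groups).

    A group's set is the union over its samples of ASVs present at
    ``min_reads`` or more.  Returns counts for every non-empty region of
    the partition, keyed by the frozenset of group labels whose sets the
    region's ASVs belong to (exactly)."""
    labels = list(tables)
    if not 2 <= len(labels) <= 3:
        raise ValueError("shared_asv_counts supports 2 or 3 groups")
    sets = {lab: associated_asv_set(tables[lab], min_reads) for lab in labels}
    universe = set().union(*sets.values())
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = frozenset(combo)
            members = set(universe)
            for lab in labels:
                members &= sets[lab] if lab in inside else universe - sets[lab]
            regions[inside] = len(members)
    return regions
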