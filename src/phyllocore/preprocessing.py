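"""Quality-control rules: organelle read removal and blank-based screening.

Contaminant screening is a threshold rule, run by run: an ASV seen in a
blank indicts itself only within its own sequencing run, and only when its
strongest appearance in a real sample of that run is weak (at most
``max_sample_reads`` reads, 10 by default).  Cross-domain contamination that
blanks cannot catch (e.g. an ASV abundant in unrelated samples multiplexed
on the same run) is handled by explicit overrides, never inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import AsvTable, SampleMetadata, Taxonomy, ValidationError

__all__ = [
    "ContaminantDecision",
    "Override",
    "remove_nonbacterial",
    "identify_contaminants",
    "screen_blank_summary",
    "apply_contaminant_removal",
    "decisions_to_frame",
    "load_blank_screening_example",
]

DEFAULT_MAX_SAMPLE_READS = 10

OVERRIDE_ACTIONS = ("force_contaminant", "force_keep")


@dataclass(frozen=True)
class Override:
    """Manual contaminant call: (asv_id, action, reason)."""

    asv_id: str
    action: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in OVERRIDE_ACTIONS:
            raise ValueError(f"override action must be one of {OVERRIDE_ACTIONS}")


@dataclass
class ContaminantDecision:
    """Outcome of blank screening for one ASV in one run."""

    asv_id: str
    run: str
    max_reads_samples: int
    max_reads_blanks: int
    rule_flagged: bool
    override: str = "none"
    final_removed: bool = False

    def __post_init__(self) -> None:
        if self.rule_flagged and self.max_reads_blanks < 1:
            raise ValidationError(
                f"{self.asv_id}: rule_flagged requires presence in a blank"
            )
        if self.override == "force_contaminant":
            self.final_removed = True
        elif self.override == "force_keep":
            self.final_removed = False
        else:
            self.final_removed = self.rule_flagged


def remove_nonbacterial(
    table: AsvTable, taxonomy: Taxonomy
) -> tuple[AsvTable, pd.Series]:
    """Drop organelle (chloroplast/plastid, mitochondrial) ASVs.

    Returns the bacterial-only table and the per-sample fraction of reads
    removed.  Samples left with zero reads are retained here; the downstream
    minimum-read filter is responsible for dropping them.
    """
    missing = set(table.asv_ids) - set(taxonomy.asv_ids)
    if missing:
        raise ValidationError(f"ASVs missing from taxonomy: {sorted(missing)}")
    nonbact = [a for a in table.asv_ids if a in set(taxonomy.nonbacterial_asvs())]
    totals = table.sample_totals().astype(float)
    removed_reads = table.counts[nonbact].sum(axis=1).astype(float)
    fraction = (removed_reads / totals.where(totals > 0)).fillna(0.0)
    bacterial = [a for a in table.asv_ids if a not in set(nonbact)]
    return table.select_asvs(bacterial), fraction


def identify_contaminants(
    table: AsvTable,
    metadata: SampleMetadata,
    max_sample_reads: int = DEFAULT_MAX_SAMPLE_READS,
    overrides: Sequence[Override] = (),
) -> list[ContaminantDecision]:
    """Screen every ASV observed in a blank, run by run.

    An ASV is rule-flagged when it is present (≥1 read) in at least one
    blank of the run and its maximum count over that run's real (non-blank)
    samples is at most ``max_sample_reads``.  Overrides are applied last and
    win.  Runs with no blanks yield no decisions and a warning.
    """
    metadata.validate_against(table)
    meta = metadata.frame.loc[table.sample_ids]
    decisions: list[ContaminantDecision] = []
    override_map = {o.asv_id: o for o in overrides}
    for run, run_meta in meta.groupby("run", sort=True):
        blanks = run_meta.index[run_meta["sample_type"] == "blank"]
        real = run_meta.index[run_meta["sample_type"] != "blank"]
        if len(blanks) == 0:
            warnings.warn(f"run {run!r} has no blanks; skipped", stacklevel=2)
            continue
        blank_max = table.counts.loc[blanks].max(axis=0)
        sample_max = (
            table.counts.loc[real].max(axis=0)
            if len(real)
            else pd.Series(0, index=table.counts.columns)
        )
        for asv in table.asv_ids:
            if blank_max[asv] < 1:
                continue
            flagged = sample_max[asv] <= max_sample_reads
            override = override_map.get(asv)
            decisions.append(
                ContaminantDecision(
                    asv_id=asv,
                    run=str(run),
                    max_reads_samples=int(sample_max[asv]),
                    max_reads_blanks=int(blank_max[asv]),
                    rule_flagged=bool(flagged),
                    override=override.action if override else "none",
                )
            )
    return decisions


def screen_blank_summary(
    summary: pd.DataFrame,
    max_sample_reads: int = DEFAULT_MAX_SAMPLE_READS,
    overrides: Sequence[Override] = (),
) -> list[ContaminantDecision]:
    """Apply the screening rule to precomputed per-run read maxima.

    ``summary`` needs columns asv_id, run, max_reads_samples,
    max_reads_blanks — the shape in which blank screens are reported.
    """
    override_map = {o.asv_id: o for o in overrides}
    decisions = []
    for row in summary.itertuples(index=False):
        override = override_map.get(str(row.asv_id))
        decisions.append(
            ContaminantDecision(
                asv_id=str(row.asv_id),
                run=str(row.run),
                max_reads_samples=int(row.max_reads_samples),
                max_reads_blanks=int(row.max_reads_blanks),
                rule_flagged=int(row.max_reads_blanks) >= 1
                and int(row.max_reads_samples) <= max_sample_reads,
                override=override.action if override else "none",
            )
        )
    return decisions


def apply_contaminant_removal(
    table: AsvTable, decisions: Iterable[ContaminantDecision]
) -> AsvTable:
    """Drop the columns of removed ASVs table-wide; retained counts untouched."""
    removed = {d.asv_id for d in decisions if d.final_removed}
    keep = [a for a in table.asv_ids if a not in removed]
    return table.select_asvs(keep)


def decisions_to_frame(decisions: Iterable[ContaminantDecision]) -> pd.DataFrame:
    """Tabulate decisions in the layout of a blank-screening report."""
    return pd.DataFrame(
        [
            {
                "asv_id": d.asv_id,
                "run": d.run,
                "max_reads_samples": d.max_reads_samples,
                "max_reads_blanks": d.max_reads_blanks,
                "rule_flagged": d.rule_flagged,
                "override": d.override,
                "final_removed": d.final_removed,
            }
            for d in decisions
        ]
    )


def load_blank_screening_example() -> pd.DataFrame:
    """Packaged worked example: ten blank-screened ASVs from a greenhouse
    phyllosphere survey, with the published removal call for each.

    Columns: asv_id, run, max_reads_samples, max_reads_blanks, removed.
    The Prevotella ASV is the documented cross-domain override case.
    """
    ref = resources.files("phyllocore.data").joinpath("blank_screening_example.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(Path(path), sep="\t")
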