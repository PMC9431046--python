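"""End-to-end pipeline: merge → decontaminate → filter → rarefy → core →
neutral → overlap → diversity report.

Defaults are the analysis constants of the study design this pipeline
serves: samples under 100 reads are discarded, blank-flagged ASVs with at
most 10 reads in real samples are removed, presence calls need 2 reads,
rarefaction depth is 500, the lastcall threshold is a 2% gain, and
PERMANOVA uses 999 permutations.  Running with a default config IS the
reference analysis; every deviation must be explicit in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .core_taxa import find_core
from .datamodel import (
    AsvTable,
    SampleMetadata,
    Taxonomy,
    filter_min_reads,
    merge_runs,
    write_asv_table,
)
from .diversity import bray_curtis_matrix, inverse_simpson, permanova
from .neutral import NeutralCommunityModel
from .overlap import overlap_report, shared_asv_counts
from .preprocessing import (
    Override,
    apply_contaminant_removal,
    decisions_to_frame,
    identify_contaminants,
)

logger = logging.getLogger("phyllocore.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and seeds for one pipeline run."""

    min_sample_reads: int = 100
    contaminant_max_reads: int = 10
    presence_min_reads: int = 2
    rarefaction_depth: int = 500
    lastcall_threshold: float = 1.02
    permanova_permutations: int = 999
    rarefaction_seed: int = 0
    permanova_seed: int = 0
    overrides: tuple[tuple[str, str, str], ...] = ()
    time_factor: str = "week"
    replicate_factor: str = "department"

    def __post_init__(self) -> None:
        for name in (
            "min_sample_reads",
            "contaminant_max_reads",
            "presence_min_reads",
            "rarefaction_depth",
            "permanova_permutations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lastcall_threshold <= 1:
            raise ValueError("lastcall_threshold must exceed 1")

    def override_objects(self) -> list[Override]:
        return [Override(*o) for o in self.overrides]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """In-memory view of the stage outputs of one run."""

    merged: AsvTable
    bacterial: AsvTable
    decontaminated: AsvTable
    filtered: AsvTable
    nonbacterial_fraction: pd.Series
    contaminant_decisions: pd.DataFrame
    core: dict[str, object]  # crop -> CoreRanking
    neutral: dict[str, object]  # crop -> NeutralFitResults
    overlap: dict[tuple[str, str], object]  # (crop, source) -> OverlapReport
    alpha_diversity: pd.Series
    permanova_results: pd.DataFrame
    venn: dict[frozenset, int] | None
    manifest: dict


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_pipeline(
    tables: Mapping[str, AsvTable] | Sequence[AsvTable],
    metadata: SampleMetadata,
    taxonomy: Taxonomy,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on per-run tables; optionally write stage TSVs plus a
    provenance manifest under ``out_dir``.  Deterministic for a fixed config."""
    from .preprocessing import remove_nonbacterial  # local to keep import cheap

    run_tables = list(tables.values()) if isinstance(tables, Mapping) else list(tables)

    stage = "merge"
    try:
        merged = merge_runs(run_tables, metadata, taxonomy)
        logger.info("merge: %d samples, %d ASVs", merged.n_samples, merged.n_asvs)

        stage = "remove_nonbacterial"
        bacterial, nonbact_frac = remove_nonbacterial(merged, taxonomy)
        logger.info(
            "nonbacterial removal: %d ASVs left, mean %%nonbacterial %.1f",
            bacterial.n_asvs,
            100 * nonbact_frac.mean(),
        )

        stage = "contaminants"
        decisions = identify_contaminants(
            bacterial,
            metadata,
            max_sample_reads=config.contaminant_max_reads,
            overrides=config.override_objects(),
        )
        decontaminated = apply_contaminant_removal(bacterial, decisions)
        logger.info(
            "contaminant removal: %d decisions, %d ASVs removed",
            len(decisions),
            sum(d.final_removed for d in decisions),
        )

        stage = "filter_min_reads"
        filtered = filter_min_reads(decontaminated, config.min_sample_reads)
        logger.info(
            "read filter (>=%d): %d samples kept", config.min_sample_reads, filtered.n_samples
        )

        meta = metadata.subset(filtered.sample_ids)
        plants = meta.samples_of_type("plant")
        crops = sorted(
            {str(c) for c in meta.frame.loc[plants, "crop"].dropna().unique()}
        )

        stage = "core"
        if not plants:
            raise PipelineError(
                "core stage: no plant samples remain after filtering; "
                "check min_sample_reads and the upstream filters"
            )
        core: dict[str, object] = {}
        neutral: dict[str, object] = {}
        for crop in crops:
            crop_samples = [
                s for s in plants if str(meta.frame.at[s, "crop"]) == crop
            ]
            crop_table = filtered.select_samples(crop_samples).drop_empty_asvs()
            from .diversity import rarefy

            rarefied = rarefy(
                crop_table, config.rarefaction_depth, config.rarefaction_seed
            )
            if rarefied.n_samples < 2:
                raise PipelineError(
                    f"core stage: fewer than 2 {crop} samples survive rarefaction "
                    f"to {config.rarefaction_depth} reads"
                )
            core[crop] = find_core(
                rarefied,
                metadata,
                time_factor=config.time_factor,
                replicate_factor=config.replicate_factor,
                lastcall_threshold=config.lastcall_threshold,
            )
            core[crop].rarefaction_seed = config.rarefaction_seed
            core[crop].rarefaction_depth = config.rarefaction_depth
            try:
                neutral[crop] = NeutralCommunityModel.from_table(rarefied).fit()
            except ValueError as exc:
                logger.warning("neutral fit skipped for %s: %s", crop, exc)

        stage = "overlap"
        arthropods = meta.samples_of_type("arthropod")
        overlap: dict[tuple[str, str], object] = {}
        if arthropods:
            batches = meta.frame.loc[arthropods, "batch"].astype(str)
            sources = sorted({b.rsplit("_batch", 1)[0] for b in batches})
            source_tables = {
                src: filtered.select_samples(
                    [s for s in arthropods if str(batches[s]).startswith(src)]
                ).drop_empty_asvs()
                for src in sources
            }
            for crop in crops:
                crop_samples = [
                    s for s in plants if str(meta.frame.at[s, "crop"]) == crop
                ]
                crop_table = filtered.select_samples(crop_samples)
                for src in list(sources) + ["combined"]:
                    overlap[(crop, src)] = overlap_report(
                        crop_table,
                        source_tables,
                        source_label=src,
                        min_reads=config.presence_min_reads,
                        threshold=config.presence_min_reads,
                    )

        stage = "diversity"
        alpha = pd.Series(
            {
                s: inverse_simpson(filtered.counts.loc[s].to_numpy())
                for s in plants
                if filtered.counts.loc[s].sum() > 0
            },
            name="inverse_simpson",
        )
        perm_rows = []
        for crop in crops:
            crop_samples = [
                s for s in plants if str(meta.frame.at[s, "crop"]) == crop
            ]
            crop_table = filtered.select_samples(crop_samples).drop_empty_asvs()
            if crop_table.n_samples < 3:
                continue
            dm = bray_curtis_matrix(crop_table)
            for factor in (config.replicate_factor, config.time_factor):
                labels = meta.frame.loc[crop_samples, factor].astype(str)
                if labels.nunique() < 2:
                    continue
                res = permanova(
                    dm,
                    labels.tolist(),
                    n_permutations=config.permanova_permutations,
                    seed=config.permanova_seed,
                    factor=f"{crop}:{factor}",
                )
                perm_rows.append(
                    {
                        "factor": res.factor,
                        "r_squared": res.r_squared,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                    }
                )
        permanova_df = pd.DataFrame(
            perm_rows, columns=["factor", "r_squared", "p_value", "n_permutations"]
        )

        venn = None
        if len(crops) >= 2:
            groups = {
                crop: filtered.select_samples(
                    [s for s in plants if str(meta.frame.at[s, "crop"]) == crop]
                )
                for crop in crops[:3]
            }
            venn = shared_asv_counts(groups, min_reads=config.presence_min_reads)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "phyllocore_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_samples_merged": merged.n_samples,
        "n_samples_final": filtered.n_samples,
        "n_asvs_final": filtered.n_asvs,
    }
    result = PipelineResult(
        merged=merged,
        bacterial=bacterial,
        decontaminated=decontaminated,
        filtered=filtered,
        nonbacterial_fraction=nonbact_frac,
        contaminant_decisions=decisions_to_frame(decisions),
        core=core,
        neutral=neutral,
        overlap=overlap,
        alpha_diversity=alpha,
        permanova_results=permanova_df,
        venn=venn,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_asv_table(result.filtered, out_dir / "filtered_table.tsv")
    result.contaminant_decisions.to_csv(
        out_dir / "contaminant_decisions.tsv", sep="\t", index=False
    )
    result.nonbacterial_fraction.rename("nonbacterial_fraction").to_csv(
        out_dir / "nonbacterial_fraction.tsv", sep="\t"
    )
    for crop, ranking in result.core.items():
        ranking.to_frame().to_csv(
            out_dir / f"core_ranking_{crop}.tsv", sep="\t", index=False
        )
    for crop, fit in result.neutral.items():
        fit.classify().to_csv(out_dir / f"neutral_fit_{crop}.tsv", sep="\t", index=False)
        (out_dir / f"neutral_summary_{crop}.txt").write_text(fit.summary() + "\n")
    for (crop, src), rep in result.overlap.items():
        rep.per_sample.to_csv(
            out_dir / f"overlap_{crop}_{src}.tsv", sep="\t"
        )
    result.alpha_diversity.to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
    result.permanova_results.to_csv(out_dir / "permanova.tsv", sep="\t", index=False)
    if result.venn is not None:
        rows = [
            {"groups": "&".join(sorted(k)), "n_asvs": v} for k, v in result.venn.items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / "venn_regions.tsv", sep="\t", index=False)
    overlap_summary = pd.DataFrame(
        [
            {
                "crop": crop,
                "source": src,
                "dispersal_index_pct": rep.dispersal_index,
                "transfer_index_pct": rep.transfer_index,
                "n_qualifying": rep.n_qualifying,
                "n_plant_samples": rep.n_plant_samples,
            }
            for (crop, src), rep in result.overlap.items()
        ]
    )
    overlap_summary.to_csv(out_dir / "overlap_summary.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
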