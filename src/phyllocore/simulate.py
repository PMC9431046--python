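"""Synthetic greenhouse phyllosphere datasets with complete ground truth.

The generator emulates the statistical structure the analysis assumes, not
sequences: shallow plant libraries (log-uniform 10²–10⁴ bacterial reads),
a department × week sampling design, planted core taxa present in every
design cell and carrying a dominant, varying share of reads, department-
specific bloom taxa, a neutrally assembled background with a known
migration parameter, organelle (host) reads, arthropod sources (bumblebee
and predatory-mite batches with distinct communities) whose ASVs are
injected into a known subset of plant samples, blanks carrying low-count
contaminants, and re-sequenced aliquots split across sequencing runs.

Arthropod-associated, contaminant and organelle ASVs live in reserved id
spaces, so every truth set is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import AsvTable, SampleMetadata, Taxonomy

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "generate_dataset",
    "simulate_neutral_table",
    "simulate_neutral_records",
    "truth_check",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mimic the shape of a two-crop
    greenhouse survey (a handful of departments sampled over several weeks,
    shallow plant libraries, deep arthropod libraries)."""

    seed: int = 0
    # plant design
    n_departments: int = 4
    n_weeks: int = 5
    samples_per_cell: int = 2
    n_plant_asvs: int = 300
    # planted structure
    n_core_asvs: int = 3
    core_effect: float = 0.5  # mean share of a plant sample's reads held by the core block
    bloom_share: float = 0.2  # mean share held by the department's bloom taxon
    neutral_m: float = 0.1
    # depths & host reads
    depth_log10_range: tuple[float, float] = (2.0, 4.0)
    nonbacterial_fraction_range: tuple[float, float] = (0.3, 0.95)
    # arthropods
    arthropod_batches: Mapping[str, int] = field(
        default_factory=lambda: {"bumblebee": 3, "predatory_mite": 2}
    )
    arthropod_asvs_per_batch: int = 30
    arthropod_samples_per_batch: int = 3
    arthropod_depth_log10_range: tuple[float, float] = (3.2, 4.3)
    # transfer of arthropod ASVs onto plants
    transfer_fraction: float = 0.15
    affected_sample_probability: float = 0.8
    # blanks & contaminants
    n_contaminants: int = 5
    blank_reads_range: tuple[int, int] = (1, 15)
    contaminant_sample_max: int = 10
    # runs / replicates
    replicate_fraction: float = 0.25

    def validate(self) -> None:
        probs = {
            "core_effect": self.core_effect,
            "bloom_share": self.bloom_share,
            "transfer_fraction": self.transfer_fraction,
            "affected_sample_probability": self.affected_sample_probability,
            "replicate_fraction": self.replicate_fraction,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.core_effect + self.bloom_share + self.transfer_fraction >= 1.0:
            raise ValueError(
                "core_effect + bloom_share + transfer_fraction must leave room "
                "for the neutral background (< 1)"
            )
        if self.transfer_fraction > 0 and self.arthropod_asvs_per_batch == 0:
            raise ValueError("cannot transfer reads from zero arthropod ASVs")
        if self.neutral_m <= 0:
            raise ValueError("neutral_m must be positive")
        for name in ("n_departments", "n_weeks", "samples_per_cell", "n_plant_asvs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_core_asvs > self.n_plant_asvs:
            raise ValueError("n_core_asvs cannot exceed n_plant_asvs")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream recovery checks."""

    planted_core: set[str]
    arthropod_associated: dict[str, set[str]]
    contaminant_asvs: set[str]
    transfer_share: pd.Series  # realized share of bacterial reads, per plant sample
    affected_samples: set[str]
    true_m: float
    bloom_asvs: dict[str, str]  # department -> bloom ASV


@dataclass
class SimulatedDataset:
    """Per-run count tables plus metadata, taxonomy and ground truth."""

    tables: dict[str, AsvTable]  # run label -> table
    metadata: SampleMetadata
    taxonomy: Taxonomy
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Pure neutral community (used directly by the model-recovery studies)
# ---------------------------------------------------------------------------


def simulate_neutral_table(
    m: float,
    N: int,
    n_taxa: int,
    n_samples: int,
    seed: int,
    source_lognorm_sigma: float = 2.0,
) -> tuple[AsvTable, np.ndarray]:
    """Community assembled purely by the Sloan neutral model.

    Source mean relative abundances are log-normal; each sample's local
    relative abundances are independent Beta(N·m·p, N·m·(1−p)) draws,
    realized as counts by binomial sampling at depth N.  Returns the table
    and the source abundance vector.
    """
    rng = np.random.default_rng(seed)
    p = rng.lognormal(mean=0.0, sigma=source_lognorm_sigma, size=n_taxa)
    p /= p.sum()
    a = N * m * p
    b = N * m * (1.0 - p)
    local = rng.beta(a[None, :], b[None, :], size=(n_samples, n_taxa))
    counts = rng.binomial(N, local)
    table = AsvTable(
        pd.DataFrame(
            counts,
            index=[f"NS{i:03d}" for i in range(n_samples)],
            columns=[f"ASV{j:04d}" for j in range(n_taxa)],
        )
    )
    return table, p


def simulate_neutral_records(
    m: float,
    N: int,
    n_taxa: int,
    n_samples: int,
    seed: int,
    d: float = 1.0,
    source_lognorm_sigma: float = 2.0,
    abundance: str = "source",
):
    """Occupancy-abundance cloud drawn exactly from the Sloan model.

    Local relative abundances are Beta(N·m·p, N·m·(1−p)) draws and a taxon
    counts as detected in a sample when its local abundance reaches the
    detection threshold d/N — the model's own detection rule, so fitting
    these records back recovers m without the bias that discrete read
    sampling introduces.  The abundance axis carries the true source mean
    ``p`` (``abundance="source"``, the model's abscissa) or the empirical
    per-sample mean (``abundance="empirical"``).  Returns a list of
    :class:`~phyllocore.core_taxa.OccupancyAbundanceRecord`.
    """
    from .core_taxa import OccupancyAbundanceRecord

    if abundance not in ("source", "empirical"):
        raise ValueError("abundance must be 'source' or 'empirical'")
    rng = np.random.default_rng(seed)
    p = rng.lognormal(mean=0.0, sigma=source_lognorm_sigma, size=n_taxa)
    p /= p.sum()
    local = rng.beta(
        (N * m * p)[None, :], (N * m * (1.0 - p))[None, :], size=(n_samples, n_taxa)
    )
    detected = local >= d / N
    occ = detected.mean(axis=0)
    mean_rel = p if abundance == "source" else local.mean(axis=0)
    return [
        OccupancyAbundanceRecord(
            asv_id=f"ASV{j:04d}",
            occupancy=float(occ[j]),
            mean_relative_abundance=float(mean_rel[j]),
            log10_mean_abundance=float(np.log10(mean_rel[j])) if mean_rel[j] > 0 else float("-inf"),
        )
        for j in range(n_taxa)
    ]


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def _log_uniform_int(rng: np.random.Generator, lo10: float, hi10: float) -> int:
    return int(round(10.0 ** rng.uniform(lo10, hi10)))


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate per-run ASV tables, metadata, taxonomy and truth.

    Deterministic given ``config.seed``: identical configs yield identical
    outputs down to the byte when written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ---- id spaces -------------------------------------------------------
    plant_asvs = [f"P{j:04d}" for j in range(config.n_plant_asvs)]
    core_asvs = plant_asvs[: config.n_core_asvs]
    departments = [f"D{d+1}" for d in range(config.n_departments)]
    bloom_pool = plant_asvs[config.n_core_asvs : config.n_core_asvs + len(departments)]
    bloom_asvs = dict(zip(departments, bloom_pool))
    arthropod_asvs: dict[str, list[list[str]]] = {}
    for source, n_batches in config.arthropod_batches.items():
        tag = f"A_{source[:2].upper()}"
        arthropod_asvs[source] = [
            [f"{tag}{b}_{j:03d}" for j in range(config.arthropod_asvs_per_batch)]
            for b in range(n_batches)
        ]
    contaminant_asvs = [f"CONT{j:02d}" for j in range(config.n_contaminants)]
    organelle_asvs = ["HOST_chloroplast", "HOST_mitochondria"]

    all_arthropod = [a for per in arthropod_asvs.values() for batch in per for a in batch]
    all_asvs = plant_asvs + all_arthropod + contaminant_asvs + organelle_asvs
    asv_index = {a: i for i, a in enumerate(all_asvs)}
    n_asvs = len(all_asvs)

    # ---- source communities ---------------------------------------------
    background = [a for a in plant_asvs if a not in set(core_asvs) | set(bloom_pool)]
    bg_source = rng.lognormal(0.0, 2.0, size=len(background))
    bg_source /= bg_source.sum()

    batch_communities: dict[str, list[np.ndarray]] = {}
    for source, batches in arthropod_asvs.items():
        batch_communities[source] = []
        for batch in batches:
            w = rng.lognormal(0.0, 1.5, size=len(batch))
            batch_communities[source].append(w / w.sum())
    # combined arthropod community feeding the transfer injection
    transfer_ids = all_arthropod
    transfer_w = rng.lognormal(0.0, 1.5, size=len(transfer_ids))
    transfer_w /= transfer_w.sum()

    # ---- plant samples ---------------------------------------------------
    weeks = list(range(1, config.n_weeks + 1))
    crops = {
        d: ("tomato" if i % 2 == 0 else "strawberry") for i, d in enumerate(departments)
    }
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    transfer_share: dict[str, float] = {}
    affected: set[str] = set()

    plant_runs = ("run1", "run2", "run4")
    counter = 0
    for dep in departments:
        for week in weeks:
            for _ in range(config.samples_per_cell):
                counter += 1
                base_id = f"S{counter:03d}"
                depth = _log_uniform_int(rng, *config.depth_log10_range)

                core_share = float(
                    np.clip(rng.uniform(0.6, 1.4) * config.core_effect, 0.0, 0.9)
                )
                bloom = float(np.clip(rng.uniform(0.5, 1.5) * config.bloom_share, 0.0, 0.9))
                is_affected = bool(rng.random() < config.affected_sample_probability)
                f_transfer = config.transfer_fraction if is_affected else 0.0
                remainder = max(1.0 - core_share - bloom - f_transfer, 1e-9)

                shares = np.zeros(n_asvs)
                if config.n_core_asvs:
                    split = rng.dirichlet(np.ones(config.n_core_asvs))
                    for a, s in zip(core_asvs, split):
                        shares[asv_index[a]] = core_share * s
                shares[asv_index[bloom_asvs[dep]]] = bloom
                # neutral background: beta-distributed local abundances
                a_par = depth * config.neutral_m * bg_source
                b_par = depth * config.neutral_m * (1.0 - bg_source)
                local = rng.beta(a_par, b_par)
                total_local = local.sum()
                if total_local > 0:
                    for a, s in zip(background, local / total_local * remainder):
                        shares[asv_index[a]] += s
                if f_transfer > 0:
                    for a, s in zip(transfer_ids, transfer_w * f_transfer):
                        shares[asv_index[a]] += s
                shares /= shares.sum()
                counts = rng.multinomial(depth, shares)

                realized_transfer = (
                    counts[[asv_index[a] for a in transfer_ids]].sum() / depth
                    if depth
                    else 0.0
                )
                # host (organelle) reads appended on top of the bacterial depth
                h = rng.uniform(*config.nonbacterial_fraction_range)
                n_host = int(round(depth * h / (1.0 - h)))
                counts[asv_index["HOST_chloroplast"]] = int(round(0.8 * n_host))
                counts[asv_index["HOST_mitochondria"]] = n_host - int(round(0.8 * n_host))

                # sparse contaminant appearances (below the screening threshold)
                for c in contaminant_asvs:
                    if rng.random() < 0.3:
                        counts[asv_index[c]] = rng.integers(
                            1, config.contaminant_sample_max + 1
                        )

                aliquots = [(f"{base_id}a", plant_runs[0], counts)]
                if rng.random() < config.replicate_fraction:
                    re_run = plant_runs[1] if rng.random() < 0.5 else plant_runs[2]
                    re_depth = _log_uniform_int(rng, *config.depth_log10_range)
                    re_counts = rng.multinomial(re_depth, shares)
                    h2 = rng.uniform(*config.nonbacterial_fraction_range)
                    n_host2 = int(round(re_depth * h2 / (1.0 - h2)))
                    re_counts[asv_index["HOST_chloroplast"]] = int(round(0.8 * n_host2))
                    re_counts[asv_index["HOST_mitochondria"]] = n_host2 - int(
                        round(0.8 * n_host2)
                    )
                    aliquots.append((f"{base_id}b", re_run, re_counts))

                for aliquot_id, run, cvec in aliquots:
                    sample_ids.append(aliquot_id)
                    rows.append(cvec)
                    meta_rows.append(
                        {
                            "sample_id": aliquot_id,
                            "sample_type": "plant",
                            "crop": crops[dep],
                            "greenhouse": "C" if crops[dep] == "strawberry" else "S",
                            "department": dep,
                            "week": week,
                            "run": run,
                            "batch": pd.NA,
                            "replicate_group": base_id if len(aliquots) > 1 else pd.NA,
                        }
                    )
                if is_affected:
                    affected.add(base_id)
                transfer_share[base_id] = float(realized_transfer)

    # ---- arthropod samples ----------------------------------------------
    arthropod_runs = {"bumblebee": "run3", "predatory_mite": "run5"}
    for source, batches in arthropod_asvs.items():
        run = arthropod_runs.get(source, "run3")
        for b, batch_ids in enumerate(batches):
            community = batch_communities[source][b]
            for k in range(config.arthropod_samples_per_batch):
                depth = _log_uniform_int(rng, *config.arthropod_depth_log10_range)
                counts = np.zeros(n_asvs, dtype=np.int64)
                draw = rng.multinomial(depth, community)
                for a, c in zip(batch_ids, draw):
                    counts[asv_index[a]] = c
                sid = f"{source[:2].upper()}{b+1}_{k+1}"
                sample_ids.append(sid)
                rows.append(counts)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "sample_type": "arthropod",
                        "crop": pd.NA,
                        "greenhouse": pd.NA,
                        "department": pd.NA,
                        "week": pd.NA,
                        "run": run,
                        "batch": f"{source}_batch{b+1}",
                        "replicate_group": pd.NA,
                    }
                )

    # ---- blanks ----------------------------------------------------------
    all_runs = sorted({m["run"] for m in meta_rows})
    lo, hi = config.blank_reads_range
    for run in all_runs:
        for k in range(2):
            counts = np.zeros(n_asvs, dtype=np.int64)
            for c in contaminant_asvs:
                if rng.random() < 0.7:
                    counts[asv_index[c]] = rng.integers(lo, hi + 1)
            sid = f"BL_{run}_{k+1}"
            sample_ids.append(sid)
            rows.append(counts)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "sample_type": "blank",
                    "crop": pd.NA,
                    "greenhouse": pd.NA,
                    "department": pd.NA,
                    "week": pd.NA,
                    "run": run,
                    "batch": pd.NA,
                    "replicate_group": pd.NA,
                }
            )

    # ---- assemble per-run tables ----------------------------------------
    counts_df = pd.DataFrame(
        np.vstack(rows).astype(np.int64), index=sample_ids, columns=all_asvs
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    tables: dict[str, AsvTable] = {}
    for run in all_runs:
        members = [s for s in sample_ids if metadata.frame.at[s, "run"] == run]
        tables[run] = AsvTable(counts_df.loc[members]).drop_empty_asvs()

    taxonomy = _build_taxonomy(all_asvs)
    truth = SyntheticTruth(
        planted_core=set(core_asvs),
        arthropod_associated={
            source: {a for batch in batches for a in batch}
            for source, batches in arthropod_asvs.items()
        },
        contaminant_asvs=set(contaminant_asvs),
        transfer_share=pd.Series(transfer_share, name="transfer_share"),
        affected_samples=affected,
        true_m=config.neutral_m,
        bloom_asvs=bloom_asvs,
    )
    return SimulatedDataset(
        tables=tables, metadata=metadata, taxonomy=taxonomy, truth=truth, config=config
    )


def _build_taxonomy(asv_ids: list[str]) -> Taxonomy:
    rows = []
    for a in asv_ids:
        if a.startswith("HOST_chloroplast"):
            rows.append(
                dict(asv_id=a, domain="Bacteria", phylum="Cyanobacteria",
                     **{"class": "Chloroplast"}, order="", family="", genus="")
            )
        elif a.startswith("HOST_mitochondria"):
            rows.append(
                dict(asv_id=a, domain="Bacteria", phylum="Proteobacteria",
                     **{"class": "Alphaproteobacteria"}, order="Rickettsiales",
                     family="Mitochondria", genus="")
            )
        else:
            rows.append(
                dict(asv_id=a, domain="Bacteria", phylum="", **{"class": ""},
                     order="", family="", genus=f"Genus_{a}")
            )
    return Taxonomy(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------


def truth_check(
    truth: SyntheticTruth,
    core_called: set[str] | None = None,
    contaminant_decisions=None,
    fitted_m: float | None = None,
    dispersal_pct: float | None = None,
    transfer_pct: float | None = None,
    qualifying_threshold: int = 2,
    plant_bacterial_table: AsvTable | None = None,
) -> dict[str, float]:
    """Recovery report: how well pipeline outputs match what was planted.

    Only the pieces supplied are evaluated; truth-derived reference values
    for the dispersal/transfer indices are recomputed from the realized
    per-sample transfer reads when the bacterial plant table is given.
    """
    report: dict[str, float] = {}
    if core_called is not None:
        tp = len(core_called & truth.planted_core)
        report["core_precision"] = tp / len(core_called) if core_called else 0.0
        report["core_recall"] = (
            tp / len(truth.planted_core) if truth.planted_core else 1.0
        )
    if contaminant_decisions is not None:
        correct = sum(
            1
            for d in contaminant_decisions
            if d.final_removed == (d.asv_id in truth.contaminant_asvs)
        )
        report["contaminant_accuracy"] = (
            correct / len(contaminant_decisions) if contaminant_decisions else 1.0
        )
    if fitted_m is not None:
        report["m_relative_error"] = abs(fitted_m - truth.true_m) / truth.true_m
    if plant_bacterial_table is not None:
        assoc = set().union(*truth.arthropod_associated.values())
        cols = [a for a in plant_bacterial_table.asv_ids if a in assoc]
        assoc_reads = plant_bacterial_table.counts[cols].sum(axis=1)
        totals = plant_bacterial_table.sample_totals()
        qual = assoc_reads >= qualifying_threshold
        report["true_dispersal_pct"] = 100.0 * float(qual.mean())
        report["true_transfer_pct"] = (
            100.0 * float((assoc_reads[qual] / totals[qual]).mean())
            if qual.any()
            else float("nan")
        )
        if dispersal_pct is not None:
            report["dispersal_abs_error_pct"] = abs(
                dispersal_pct - report["true_dispersal_pct"]
            )
        if transfer_pct is not None and qual.any():
            report["transfer_abs_error_pct"] = abs(
                transfer_pct - report["true_transfer_pct"]
            )
    return report
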