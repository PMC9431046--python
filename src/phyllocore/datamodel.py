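"""Count-table, metadata and taxonomy containers with TSV/BIOM I/O.

The universal currency of the pipeline is the :class:`AsvTable`: a samples ×
ASVs matrix of non-negative integer read counts, carried as a pandas
DataFrame with sample identifiers on the index and ASV identifiers on the
columns.  Sample metadata and genus-level taxonomy ride alongside it as thin
validated wrappers around DataFrames.

Structural transforms that do not touch the science live here as well:
merging sequencing runs (keeping, per physical sample, the re-sequenced
aliquot with the most reads), dropping shallow samples, and turning counts
into presence/absence calls.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from biom.parse import parse_biom_table
from biom.table import Table as BiomTable

__all__ = [
    "AsvTable",
    "SampleMetadata",
    "Taxonomy",
    "ValidationError",
    "FormatError",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "merge_runs",
    "filter_min_reads",
    "presence_matrix",
]

SAMPLE_TYPES = ("plant", "arthropod", "blank")
METADATA_COLUMNS = (
    "sample_id",
    "sample_type",
    "crop",
    "greenhouse",
    "department",
    "week",
    "run",
    "batch",
    "replicate_group",
)
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

# substrings (lower-cased) marking organellar / host lineages
_NONBACTERIAL_MARKERS = ("chloroplast", "plastid", "mitochond")


class ValidationError(ValueError):
    """An input violated a structural invariant of the data model."""


class FormatError(ValueError):
    """A file did not parse in the declared dialect."""


# ---------------------------------------------------------------------------
# AsvTable
# ---------------------------------------------------------------------------


@dataclass
class AsvTable:
    """Samples × ASVs integer count matrix.

    Parameters
    ----------
    counts
        DataFrame with sample ids on the index, ASV ids on the columns and
        non-negative integer read counts in the cells.
    sequences
        Optional mapping from ASV id to its nucleotide sequence; used to
        harmonize ASV identity across sequencing runs.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dupes}")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative count at sample {df.index[r]!r}, ASV {df.columns[c]!r}"
                )
            if not np.issubdtype(arr.dtype, np.integer):
                rounded = np.rint(arr)
                if not np.array_equal(arr, rounded):
                    r, c = np.argwhere(arr != rounded)[0]
                    raise ValidationError(
                        f"non-integral count {arr[r, c]} at sample "
                        f"{df.index[r]!r}, ASV {df.columns[c]!r}"
                    )
                df = df.astype(np.int64)
        else:
            df = df.astype(np.int64)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self.counts = df
        if self.sequences is not None:
            unknown = set(self.sequences) - set(df.columns)
            if unknown:
                raise ValidationError(f"sequences for unknown ASVs: {sorted(unknown)}")

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        """Total reads (library size) per sample."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> pd.DataFrame:
        """Per-sample proportions; all-zero samples yield all-zero rows."""
        totals = self.sample_totals().to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.to_numpy(dtype=float) / totals[:, None]
        rel[~np.isfinite(rel)] = 0.0
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)

    # -- transforms --------------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)], self._seq_subset(self.asv_ids))

    def select_asvs(self, asv_ids: Sequence[str]) -> "AsvTable":
        keep = list(asv_ids)
        return AsvTable(self.counts[keep], self._seq_subset(keep))

    def drop_empty_asvs(self) -> "AsvTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return self.select_asvs(list(keep))

    def _seq_subset(self, asv_ids: Iterable[str]) -> dict[str, str] | None:
        if self.sequences is None:
            return None
        return {a: self.sequences[a] for a in asv_ids if a in self.sequences}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return self.counts.equals(other.counts) and (self.sequences or {}) == (
            other.sequences or {}
        )


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample factors: type, crop, greenhouse, department, week, run, batch.

    ``replicate_group`` links re-sequenced aliquots of the same physical
    sample across runs; aliquots sharing a group are collapsed by
    :func:`merge_runs`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metadata records: {dupes}")
        for col in METADATA_COLUMNS[1:]:
            if col not in df.columns:
                df[col] = pd.NA
        bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValidationError(f"unknown sample types: {sorted(map(str, bad))}")
        df["week"] = pd.array(
            [int(w) if pd.notna(w) else pd.NA for w in df["week"]], dtype="Int64"
        )
        self.frame = df[list(METADATA_COLUMNS[1:])]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def validate_against(self, table: AsvTable, *, require_factors: bool = False) -> None:
        """Check every table sample has a record, optionally with the factors
        its sample type requires (plant: crop/department/week; arthropod: batch)."""
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        if not require_factors:
            return
        sub = self.frame.loc[table.sample_ids]
        plants = sub[sub["sample_type"] == "plant"]
        for col in ("crop", "department", "week"):
            holes = plants.index[plants[col].isna()].tolist()
            if holes:
                raise ValidationError(f"plant samples missing {col}: {holes}")
        arth = sub[sub["sample_type"] == "arthropod"]
        holes = arth.index[arth["batch"].isna()].tolist()
        if holes:
            raise ValidationError(f"arthropod samples missing batch: {holes}")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def samples_of_type(self, sample_type: str) -> list[str]:
        return list(self.frame.index[self.frame["sample_type"] == sample_type])


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """ASV → ranked lineage (domain..genus) with an organelle flag.

    ``is_nonbacterial`` is true for chloroplast/plastid and mitochondrial
    lineages; when absent from the input it is derived from the lineage
    labels alone.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "asv_id" in df.columns:
            df = df.set_index("asv_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxonomy records: {dupes}")
        for rank in TAXONOMY_RANKS:
            if rank not in df.columns:
                df[rank] = ""
        if "is_nonbacterial" not in df.columns:
            df["is_nonbacterial"] = [
                self._derive_nonbacterial(row)
                for row in df[list(TAXONOMY_RANKS)].itertuples(index=False)
            ]
        df["is_nonbacterial"] = df["is_nonbacterial"].astype(bool)
        self.frame = df[list(TAXONOMY_RANKS) + ["is_nonbacterial"]]

    @staticmethod
    def _derive_nonbacterial(lineage: Iterable[str]) -> bool:
        joined = " ".join(str(v) for v in lineage).lower()
        return any(marker in joined for marker in _NONBACTERIAL_MARKERS)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.frame.index)

    def nonbacterial_asvs(self) -> list[str]:
        return list(self.frame.index[self.frame["is_nonbacterial"]])

    def bacterial_asvs(self) -> list[str]:
        return list(self.frame.index[~self.frame["is_nonbacterial"]])

    def genus(self, asv_id: str) -> str:
        return str(self.frame.at[asv_id, "genus"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BIOM_EPOCH = datetime.datetime(2000, 1, 1)  # fixed so output is byte-stable


def read_asv_table(path: str | Path, format: str = "tsv") -> AsvTable:
    """Read a samples × ASVs count table.

    TSV dialect: first column ``sample_id``, remaining header cells are ASV
    ids, one sample per row.  BIOM: standard observation/sample axes (BIOM
    1.0 JSON); observations become columns.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
        if df.index.name != "sample_id":
            raise FormatError(
                f"{path}: first column must be 'sample_id', got {df.index.name!r}"
            )
        return AsvTable(_coerce_integer(df, path))
    if format == "biom":
        with open(path) as fh:
            try:
                biom_table = parse_biom_table(fh)
            except Exception as exc:
                raise FormatError(f"cannot parse {path} as BIOM: {exc}") from exc
        dense = np.asarray(biom_table.matrix_data.todense()).T  # samples × ASVs
        df = pd.DataFrame(
            dense,
            index=[str(s) for s in biom_table.ids("sample")],
            columns=[str(o) for o in biom_table.ids("observation")],
        )
        return AsvTable(_coerce_integer(df, path))
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def _coerce_integer(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Losslessly coerce cells to int64, naming the first offending cell."""
    out = np.empty(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for (r, c), cell in np.ndenumerate(values):
        try:
            as_float = float(cell)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-numeric count {cell!r} at sample "
                f"{df.index[r]!r}, ASV {df.columns[c]!r}"
            ) from None
        if as_float < 0 or as_float != int(as_float):
            raise ValidationError(
                f"{path}: invalid count {cell!r} at sample "
                f"{df.index[r]!r}, ASV {df.columns[c]!r} (must be a non-negative integer)"
            )
        out[r, c] = int(as_float)
    return pd.DataFrame(out, index=df.index.astype(str), columns=df.columns.astype(str))


def write_asv_table(table: AsvTable, path: str | Path, format: str = "tsv") -> Path:
    """Write a table so that :func:`read_asv_table` reproduces it exactly."""
    path = Path(path)
    if format == "tsv":
        df = table.counts.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", lineterminator="\n")
        return path
    if format == "biom":
        biom_table = BiomTable(
            table.counts.to_numpy().T,
            observation_ids=table.asv_ids,
            sample_ids=table.sample_ids,
        )
        path.write_text(biom_table.to_json("phyllocore", creation_date=_BIOM_EPOCH))
        return path
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "sample_type" not in df.columns:
        raise FormatError(f"{path}: metadata needs sample_id and sample_type columns")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    df = metadata.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")
    return path


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in df.columns:
        raise FormatError(f"{path}: taxonomy needs an asv_id column")
    if "is_nonbacterial" in df.columns:
        df["is_nonbacterial"] = df["is_nonbacterial"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        )
    return Taxonomy(df)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> Path:
    path = Path(path)
    df = taxonomy.frame.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Structural transforms
# ---------------------------------------------------------------------------


def merge_runs(
    tables: Sequence[AsvTable],
    metadata: SampleMetadata,
    taxonomy: Taxonomy | None = None,
) -> AsvTable:
    """Merge per-run tables, keeping one aliquot per physical sample.

    Re-sequenced aliquots share a ``replicate_group``; the aliquot with the
    largest total read count is retained (bacterial reads only when a
    taxonomy is supplied).  Ties go to the latest run label, then the
    lexicographically first sample id.  Samples without a replicate group
    pass through unchanged.

    ASV identity is harmonized by exact sequence match when sequences are
    supplied on every table, else by ASV id.
    """
    tables = [_relabel_by_sequence(t, tables) for t in tables]
    seen: set[str] = set()
    for t in tables:
        for sid in t.sample_ids:
            if sid in seen:
                group = None
                if sid in metadata.frame.index:
                    group = metadata.frame.at[sid, "replicate_group"]
                if group is None or pd.isna(group):
                    raise ValidationError(
                        f"sample {sid!r} appears in multiple runs without a replicate_group"
                    )
                raise ValidationError(
                    f"sample {sid!r} appears in multiple runs; re-sequenced aliquots "
                    "must carry distinct sample ids linked by replicate_group"
                )
            seen.add(sid)

    combined = pd.concat([t.counts for t in tables], axis=0).fillna(0).astype(np.int64)
    order = list(combined.index)

    metadata.validate_against(AsvTable(combined))
    meta = metadata.frame.loc[order]

    if taxonomy is not None:
        bacterial = [a for a in combined.columns if a in set(taxonomy.bacterial_asvs())]
        totals = combined[bacterial].sum(axis=1)
    else:
        totals = combined.sum(axis=1)

    groups = meta["replicate_group"]
    keep = {sid for sid in order if pd.isna(groups[sid])}
    for _, members in meta.groupby("replicate_group"):
        ids = list(members.index)
        runs = members["run"].astype(str)
        best = sorted(ids, key=lambda s: (-int(totals[s]), _run_sort_key(runs[s]), s))[0]
        keep.add(best)
    keep_in_order = [s for s in order if s in keep]
    sequences = None
    if all(t.sequences for t in tables):
        sequences = {}
        for t in tables:
            sequences.update(t.sequences or {})
    merged = AsvTable(combined.loc[keep_in_order], sequences)
    return merged.drop_empty_asvs()


def _run_sort_key(run_label: str) -> tuple:
    """Sort key putting the LATEST run first (descending natural order)."""
    digits = "".join(ch for ch in str(run_label) if ch.isdigit())
    num = int(digits) if digits else -1
    return (-num, tuple(-ord(c) for c in str(run_label)))


def _relabel_by_sequence(table: AsvTable, tables: Sequence[AsvTable]) -> AsvTable:
    """Give ASVs with identical sequences identical ids across runs."""
    if not all(t.sequences for t in tables):
        return table
    canonical: dict[str, str] = {}
    for t in tables:
        for asv, seq in (t.sequences or {}).items():
            canonical.setdefault(seq, asv)
    mapping = {asv: canonical[seq] for asv, seq in (table.sequences or {}).items()}
    renamed = table.counts.rename(columns=mapping)
    renamed = renamed.T.groupby(level=0).sum().T  # collapse duplicates post-rename
    sequences = {canonical[seq]: seq for seq in (table.sequences or {}).values()}
    return AsvTable(renamed, sequences)


def filter_min_reads(table: AsvTable, threshold: int) -> AsvTable:
    """Drop samples with fewer than ``threshold`` total reads, then drop
    all-zero ASV columns."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= threshold]
    return table.select_samples(keep).drop_empty_asvs()


def presence_matrix(table: AsvTable, min_reads: int = 2) -> pd.DataFrame:
    """Boolean samples × ASVs matrix: present iff count ≥ ``min_reads``.

    The default of 2 reads is the presence rule used throughout for shared
    ASV (Venn) sets and arthropod association calls.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return table.counts >= min_reads
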