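"""Tabular input/output for the activity-inference pipeline.

The pipeline starts at mapped-read count tables (genome x sample), not at
alignments.  The native dialect is TSV, UTF-8, no quoting; counts must be
complete non-negative integers ("NA" is forbidden — a feature with no mapped
reads has count 0 by definition of read mapping).  Genome length travels in
column 2 of the count table so that RPKM always has lengths adjacent to
counts; a FASTA file may override lengths.  Sample metadata (zone, assay)
lives in a separate two-column map file because zones and assays are free
text in real studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

ASSAYS = ("DNA", "RNA")

__all__ = [
    "ViractiveError",
    "TableFormatError",
    "TableValidationError",
    "SampleMappingError",
    "CountTable",
    "GeneTable",
    "read_sample_map",
    "read_count_table",
    "read_gene_table",
    "lengths_from_fasta",
    "write_table",
    "read_table",
    "write_count_table",
    "write_results",
]


class ViractiveError(Exception):
    """Base class for all pipeline errors."""


class TableFormatError(ViractiveError):
    """Structural problem with an input file (missing columns, bad header)."""


class TableValidationError(ViractiveError):
    """A cell-level violation; the message carries row/column coordinates."""


class SampleMappingError(ViractiveError):
    """A sample present in one table is missing from the sample map."""


@dataclass
class CountTable:
    """Genome x sample matrix of raw mapped-read counts with genome lengths.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by genome id, one column per sample id.
    lengths
        Genome length in bp, indexed like ``counts``.
    sample_map
        DataFrame indexed by sample id with columns ``zone`` and ``assay``
        (assay in {"DNA", "RNA"}).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    sample_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableValidationError(f"duplicate genome id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise TableValidationError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TableValidationError(
                f"count at genome {self.counts.index[i]!r}, sample "
                f"{self.counts.columns[j]!r} is {arr[i, j]!r}; counts must be "
                "non-negative integers"
            )
        self.counts = self.counts.astype(np.int64)
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            g = self.lengths.index[self.lengths.isna()][0]
            raise TableValidationError(f"genome {g!r} has no length")
        if (self.lengths < 1).any():
            g = self.lengths.index[self.lengths < 1][0]
            raise TableValidationError(
                f"genome {g!r} has length {self.lengths[g]}; lengths must be >= 1"
            )
        self.lengths = self.lengths.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.sample_map.index]
        if missing:
            raise SampleMappingError(
                f"sample {missing[0]!r} in count table is absent from the sample map"
            )
        bad_assay = [
            s for s in self.counts.columns
            if self.sample_map.loc[s, "assay"] not in ASSAYS
        ]
        if bad_assay:
            s = bad_assay[0]
            raise SampleMappingError(
                f"sample {s!r} has assay {self.sample_map.loc[s, 'assay']!r}; "
                f"expected one of {ASSAYS}"
            )

    # -- accessors -----------------------------------------------------
    @property
    def genome_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def zones(self) -> list:
        seen: dict = {}
        for s in self.counts.columns:
            seen.setdefault(self.sample_map.loc[s, "zone"], None)
        return list(seen)

    def samples(self, zone: str | None = None, assay: str | None = None) -> list:
        """Sample ids restricted to a zone and/or assay, in column order."""
        out = []
        for s in self.counts.columns:
            z, a = self.sample_map.loc[s, "zone"], self.sample_map.loc[s, "assay"]
            if zone is not None and z != zone:
                continue
            if assay is not None and a != assay:
                continue
            out.append(s)
        return out

    def subset_samples(self, samples: list) -> "CountTable":
        return CountTable(self.counts[samples].copy(), self.lengths.copy(),
                          self.sample_map.loc[samples].copy())


@dataclass
class GeneTable:
    """Gene-level annotations and per-sample gene counts.

    ``table`` is indexed by gene id with metadata columns ``genome_id``,
    ``gene_length_bp``, ``functional_label``, ``category_label`` and
    ``marker_flags`` (semicolon-joined tags such as ``integrase`` or
    ``AMG:sulfur``), followed by one count column per sample.
    """

    table: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    META_COLS = ("genome_id", "gene_length_bp", "functional_label",
                 "category_label", "marker_flags")

    def __post_init__(self) -> None:
        missing = [c for c in self.META_COLS if c not in self.table.columns]
        if missing:
            raise TableFormatError(f"gene table is missing column {missing[0]!r}")
        if not self.sample_ids:
            self.sample_ids = [c for c in self.table.columns
                               if c not in self.META_COLS]
        arr = self.table[self.sample_ids].to_numpy()
        bad = ~np.isfinite(arr.astype(float)) | (arr < 0) | (arr != np.floor(arr))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TableValidationError(
                f"gene count at gene {self.table.index[i]!r}, sample "
                f"{self.sample_ids[j]!r} is {arr[i, j]!r}; counts must be "
                "non-negative integers"
            )
        if (self.table["gene_length_bp"] < 1).any():
            g = self.table.index[self.table["gene_length_bp"] < 1][0]
            raise TableValidationError(f"gene {g!r} has length < 1")
        self.table["marker_flags"] = self.table["marker_flags"].fillna("")

    def validate_against(self, counts: CountTable) -> None:
        """Every referenced genome must exist in the companion count table."""
        known = set(counts.genome_ids)
        orphans = [g for g in self.table["genome_id"] if g not in known]
        if orphans:
            raise TableValidationError(
                f"gene table references genome {orphans[0]!r} absent from the "
                "count table"
            )

    def flags(self, gene_id) -> set:
        raw = self.table.loc[gene_id, "marker_flags"]
        return set(t for t in str(raw).split(";") if t)

    def genes_with_flag(self, tag: str) -> list:
        col = self.table["marker_flags"].astype(str)
        hit = col.map(lambda v: tag in v.split(";"))
        return list(self.table.index[hit])

    def counts(self) -> pd.DataFrame:
        return self.table[self.sample_ids].astype(np.int64)


# -- readers ----------------------------------------------------------

def read_sample_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "zone", "assay"}
    if not need.issubset(df.columns):
        raise TableFormatError(
            f"sample map {path} must have columns sample_id, zone, assay"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableValidationError(f"duplicate sample id {dup!r} in sample map")
    return df.set_index("sample_id")[["zone", "assay"]]


def read_count_table(path, sample_map_path) -> CountTable:
    """Read a TSV count table (genome_id, length, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "genome_id" or df.columns[1] != "length":
        raise TableFormatError(
            f"count table {path} must start with columns genome_id, length"
        )
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].iloc[0]
        raise TableValidationError(f"duplicate genome id {dup!r} in {path}")
    df = df.set_index("genome_id")
    sample_map = read_sample_map(sample_map_path)
    counts = df.drop(columns=["length"])
    if counts.isna().any().any():
        col = counts.columns[counts.isna().any()][0]
        row = counts.index[counts[col].isna()][0]
        raise TableValidationError(
            f"count at genome {row!r}, sample {col!r} is missing; "
            "'NA' is forbidden in count cells"
        )
    return CountTable(counts, df["length"], sample_map)


def read_gene_table(path) -> GeneTable:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise TableFormatError(f"gene table {path} must have a gene_id column")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise TableValidationError(f"duplicate gene id {dup!r} in {path}")
    df["marker_flags"] = df.get("marker_flags", "").fillna("")
    return GeneTable(df.set_index("gene_id"))


def lengths_from_fasta(path) -> pd.Series:
    """Genome lengths from a FASTA file (non-whitespace sequence characters)."""
    lengths: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise TableValidationError(f"duplicate record id {rec.id!r} in {path}")
        n = len(str(rec.seq).replace(" ", "").replace("\n", ""))
        if n == 0:
            raise TableValidationError(f"record {rec.id!r} in {path} has an empty sequence")
        lengths[rec.id] = n
    return pd.Series(lengths, dtype=np.int64, name="length")


# -- writers ----------------------------------------------------------

FLOAT_FMT = "%.12g"


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    """TSV writer with stable column order and 12-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT,
              index=index_label is not None, index_label=index_label)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_count_table(ct: CountTable, path, sample_map_path=None) -> None:
    out = ct.counts.copy()
    out.insert(0, "length", ct.lengths)
    write_table(out, path, index_label="genome_id")
    if sample_map_path is not None:
        write_table(ct.sample_map, sample_map_path, index_label="sample_id")


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results(tables: dict, out_dir, *, config=None, seed=None,
                  version=None, warnings_seen=()) -> dict:
    """Write output tables plus a machine-readable run summary.

    ``tables`` maps file stem -> DataFrame (written as ``<stem>.tsv`` with the
    index when it is named).  Returns the summary dict, which is also written
    to ``run_summary.json``.  The summary deliberately carries no timestamps
    so that reruns are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row_counts = {}
    for stem, df in tables.items():
        label = df.index.name if df.index.name else None
        write_table(df, out / f"{stem}.tsv", index_label=label)
        row_counts[stem] = int(len(df))
    summary = {
        "tool": "viractive",
        "version": version or _package_version(),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "config": config,
        "row_counts": row_counts,
        "warnings": list(warnings_seen),
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _package_version() -> str:
    from viractive import __version__

    return __version__
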