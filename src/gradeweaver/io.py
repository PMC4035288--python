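"""Domain types and tab-delimited readers/writers.

All on-disk formats are UTF-8, tab-separated, with ``#`` comment lines
ignored.  Genomic coordinates are 0-based half-open (BED convention)
throughout the package; SEG-style inputs expressed in 1-based inclusive
coordinates must be converted before loading (subtract 1 from the start).
Strand is parsed but never used by overlap logic, since copy-number
alteration is strand-agnostic.

Expression values are assumed to be already log2-transformed and
normalised (RMA-style); no background correction is applied anywhere.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "Grade",
    "ExpressionMatrix",
    "SampleTable",
    "GeneModel",
    "SegmentRecord",
    "TargetMap",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_segments",
    "write_segments",
    "read_gene_models",
    "write_gene_models",
    "read_target_map",
    "write_target_map",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


class FeatureKind(str, Enum):
    mRNA = "mRNA"
    miRNA = "miRNA"


class Grade(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


_VALID_GRADES = {g.value for g in Grade}


@dataclass
class ExpressionMatrix:
    """Features x samples log2 expression values of a single feature kind."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_kind: FeatureKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")
        self.feature_kind = FeatureKind(self.feature_kind)

    # -- convenience -------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_kind: FeatureKind) -> "ExpressionMatrix":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            feature_kind=feature_kind,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
            feature_kind=self.feature_kind,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [idx[f] for f in feature_ids]
        return ExpressionMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            feature_kind=self.feature_kind,
        )


@dataclass
class SampleTable:
    """Per-sample clinical covariates: grade, batch and relapse-free survival.

    ``latent_label`` carries the synthetic ground-truth label of G2
    samples (G1 or G3) and is present only for simulated cohorts.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "grade", "batch", "time", "event")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample table missing column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        bad = set(df["grade"]) - _VALID_GRADES
        if bad:
            raise FormatError(f"unknown grade token(s): {sorted(bad)}")
        df["time"] = df["time"].astype(float)
        if (df["time"] < 0).any():
            raise FormatError("negative survival time")
        df["event"] = df["event"].astype(int)
        if not df["event"].isin([0, 1]).all():
            raise FormatError("event must be 0 or 1")
        if "latent_label" in df.columns:
            lab = df["latent_label"].dropna()
            bad = set(lab) - {"G1", "G3"}
            if bad:
                raise FormatError(f"latent label must be G1 or G3, got {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def grades_for(self, sample_ids: Sequence[str]) -> list[str]:
        m = dict(zip(self.df["sample_id"], self.df["grade"]))
        return [m[s] for s in sample_ids]

    def ids_of_grade(self, grade: str) -> list[str]:
        return list(self.df.loc[self.df["grade"] == grade, "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.df[self.df["sample_id"].isin(set(sample_ids))]
        order = {s: i for i, s in enumerate(sample_ids)}
        keep = keep.sort_values("sample_id", key=lambda c: c.map(order))
        return SampleTable(keep.reset_index(drop=True))


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 0-based half-open coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene:
            raise FormatError("blank gene symbol")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"gene {self.gene}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SegmentRecord:
    """One segmented copy-number call for one sample (diploid = 2)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"segment {self.sample_id}/{self.chrom}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.copy_number < 0:
            raise FormatError("negative copy number")


# miRNA id -> set of target gene symbols (miRDB-style, consumed not predicted)
TargetMap = dict


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, feature_kind: FeatureKind) -> ExpressionMatrix:
    """Read a tab-delimited feature x sample matrix.

    First column holds feature ids, header row holds sample ids.
    Duplicate feature ids and non-numeric cells are rejected.
    """
    df = _read_tsv(path, index_col=0, dtype=str)
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: missing header row")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, (fid, row) in enumerate(df.iterrows()):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at feature {fid!r} "
                        f"(row {i + 1}), sample {df.columns[j]!r} (column {j + 1})"
                    ) from None
        raise
    return ExpressionMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
        feature_kind=feature_kind,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def read_sample_table(path) -> SampleTable:
    """Read the per-sample TSV (sample_id, grade, batch, time, event[, latent_label])."""
    df = _read_tsv(path, dtype={"sample_id": str, "batch": str})
    if df.empty:
        raise FormatError(f"{path}: empty sample table")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy-number segments (SEG dialect: sample, chrom, start, end, copy_number)
# ---------------------------------------------------------------------------

def read_segments(path) -> list[SegmentRecord]:
    """Read SEG-like records, sorted by (sample, chrom, start).

    Within one sample and chromosome, segments must not overlap
    (half-open intervals); offenders are reported.
    """
    df = _read_tsv(
        path,
        names=["sample_id", "chrom", "start", "end", "copy_number"],
        header=None,
        dtype={"sample_id": str, "chrom": str},
    )
    if df.empty:
        return []
    # tolerate an optional header line
    if str(df.iloc[0]["start"]).lower() in {"start", "loc.start"}:
        df = df.iloc[1:]
    records = [
        SegmentRecord(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            copy_number=float(r.copy_number),
        )
        for r in df.itertuples(index=False)
    ]
    records.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    _check_segment_overlap(records)
    return records


def _check_segment_overlap(records: Sequence[SegmentRecord]) -> None:
    offenders = []
    for prev, cur in zip(records, records[1:]):
        if (
            prev.sample_id == cur.sample_id
            and prev.chrom == cur.chrom
            and cur.start < prev.end
        ):
            offenders.append((prev, cur))
    if offenders:
        desc = "; ".join(
            f"{a.sample_id}/{a.chrom}:[{a.start},{a.end}) overlaps [{b.start},{b.end})"
            for a, b in offenders[:5]
        )
        raise FormatError(f"overlapping segments: {desc}")


def write_segments(records: Iterable[SegmentRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.copy_number}\n")


# ---------------------------------------------------------------------------
# Gene models (BED4 / BED6)
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Read BED4/BED6 gene models (chrom, start, end, name[, score, strand])."""
    df = _read_tsv(path, header=None, dtype=str)
    if df.empty:
        return []
    if df.shape[1] < 4:
        raise FormatError(f"{path}: BED needs at least 4 columns, got {df.shape[1]}")
    out = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if len(row) >= 6 and not pd.isna(row[5]) else "."
        out.append(
            GeneModel(
                gene=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand,
            )
        )
    return out


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# miRNA -> target map (two-column TSV, one pair per line)
# ---------------------------------------------------------------------------

def read_target_map(path) -> TargetMap:
    """Read miRNA->gene pairs, aggregated into sets (duplicates collapse)."""
    df = _read_tsv(path, header=None, dtype=str)
    targets: TargetMap = {}
    if df.empty:
        return targets
    if df.shape[1] < 2:
        raise FormatError(f"{path}: target map needs two columns")
    for row in df.itertuples(index=False):
        mirna, gene = str(row[0]), str(row[1])
        if not mirna or mirna == "nan":
            raise FormatError("empty miRNA id in target map")
        if not gene or gene == "nan":
            raise FormatError(f"blank gene symbol for miRNA {mirna!r}")
        targets.setdefault(mirna, set()).add(gene)
    return targets


def write_target_map(targets: Mapping[str, set], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")
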