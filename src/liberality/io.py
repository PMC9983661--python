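"""Count-matrix and sample-sheet I/O, validation, and mapping QC.

The package consumes gene-level RNA-seq count matrices (genes x samples)
together with a sample sheet carrying the experimental covariates: strain,
treatment, extract dose (as a decimal dilution fraction, e.g. a 1/100
dilution is 0.01 and untreated controls are 0), and culture time in hours.

Counts may be non-integer so that estimated-count pipelines upstream are
admissible; downstream entropy code treats them as weights.

Supported on-disk formats: TSV/CSV with gene ids in the first column and
sample ids in the header row, and MatrixMarket (``.mtx``) with two sidecar
text files (``<stem>.genes.txt``, ``<stem>.samples.txt``), one id per line.
Text is UTF-8 with "." as the decimal separator; no locale handling.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "QCReport",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "multihit_qc",
    "join_validate",
    "write_table",
    "read_table",
]

#: Columns a sample sheet must provide (extra columns are kept but ignored).
SHEET_COLUMNS = ("sample_id", "strain", "treatment", "dose", "time_h")

#: Significant digits used when writing floats; 17 round-trips IEEE doubles.
FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative gene x sample expression counts.

    Attributes
    ----------
    gene_ids, sample_ids
        Ordered, duplicate-free identifiers for rows and columns.
    counts
        Dense float array of shape ``(len(gene_ids), len(sample_ids))``;
        entries are read counts (or estimated counts) and must be finite
        and non-negative.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        for kind, ids in (("gene", genes), ("sample", samples)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {kind} ids: {sorted(dupes)}")
        bad = ~np.isfinite(counts)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite count at gene {genes[i]!r}, sample {samples[j]!r}"
            )
        neg = counts < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative count {counts[i, j]} at gene {genes[i]!r}, "
                f"sample {samples[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        """Counts for one sample, in gene order."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy(float))


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample covariates: strain, treatment, dose fraction, culture hours."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"sample sheet missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        dupes = _duplicates(df["sample_id"])
        if dupes:
            raise ValidationError(f"duplicate sample ids in sheet: {sorted(dupes)}")
        for col in ("dose", "time_h"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), "sample_id"].iloc[0]
                raise ValidationError(f"non-numeric {col} for sample {bad!r}")
            if (vals < 0).any():
                bad = df.loc[vals < 0, "sample_id"].iloc[0]
                raise ValidationError(f"negative {col} for sample {bad!r}")
            df[col] = vals.astype(float)
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data["sample_id"])


@dataclass(frozen=True)
class QCReport:
    """Multi-hit mapping QC for one sample.

    ``flagged`` is true iff the multi-hit rate strictly exceeds the
    threshold (default 0.30, the reference-acceptance criterion: a
    reference producing over 30% ambiguously mapped reads is rejected).
    """

    sample_id: str
    multihit_rate: float
    library_size: float
    flagged: bool


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ParseError(f"cannot infer count-matrix format from {path.name!r}")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def read_counts(path: str | os.PathLike, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV, CSV, or MatrixMarket with id sidecars.

    Row and column order are preserved from the file. Raises
    :class:`ParseError` for structural problems (empty file, malformed or
    duplicated header) and :class:`ValidationError` for bad values, naming
    the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        return _read_counts_mtx(path)
    if fmt not in ("tsv", "csv"):
        raise ParseError(f"unknown count-matrix format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","

    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ParseError(f"{path}: empty file or blank header (line 1)")
    header = header_line.rstrip("\r\n").split(sep)
    if len(header) < 2:
        raise ParseError(
            f"{path}: header (line 1) has no sample columns; "
            f"expected gene-id column followed by sample ids"
        )
    sample_ids = header[1:]
    if _duplicates(sample_ids):
        raise ParseError(
            f"{path}: duplicate sample ids in header (line 1): "
            f"{sorted(_duplicates(sample_ids))}"
        )

    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows after the header")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        try:
            # str -> float via strtod round-trips %.17g exactly
            # (pd.to_numeric's fast parser can be off by 1 ulp)
            values[:, j] = raw.astype(np.float64)
        except (ValueError, TypeError):
            for gene, cell in zip(df.index, raw):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValidationError(
                        f"{path}: non-numeric count at gene {gene!r}, "
                        f"sample {col!r}"
                    ) from None
            raise
        nan_rows = np.isnan(values[:, j])
        if nan_rows.any():
            gene = df.index[nan_rows][0]
            raise ValidationError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
    return CountMatrix(tuple(df.index.astype(str)), tuple(sample_ids), values)


def _read_counts_mtx(path: Path) -> CountMatrix:
    genes_path, samples_path = _sidecar_paths(path)
    for p in (genes_path, samples_path):
        if not p.exists():
            raise ParseError(f"missing MatrixMarket sidecar file: {p}")
    try:
        mat = scipy.io.mmread(path)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    dense = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    genes = genes_path.read_text(encoding="utf-8").splitlines()
    samples = samples_path.read_text(encoding="utf-8").splitlines()
    return CountMatrix(tuple(genes), tuple(samples), dense)


def write_counts(
    matrix: CountMatrix, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a count matrix in any of the formats :func:`read_counts` reads."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        genes_path, samples_path = _sidecar_paths(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts))
        genes_path.write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
        samples_path.write_text("\n".join(matrix.sample_ids) + "\n", encoding="utf-8")
        return
    sep = "\t" if fmt == "tsv" else ","
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read and validate a CSV sample sheet.

    Required columns: ``sample_id, strain, treatment, dose, time_h``; dose
    is a decimal dilution fraction. Extra columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def multihit_qc(
    sample_id: str,
    unique_counts: float,
    multi_counts: float,
    threshold: float = 0.30,
) -> QCReport:
    """Multi-hit rate QC: rate = multi / (unique + multi), flag if > threshold.

    The rate is invariant under common scaling of both totals. Raises
    :class:`ValidationError` if either total is negative or both are zero
    (the rate is then undefined).
    """
    if unique_counts < 0 or multi_counts < 0:
        raise ValidationError(
            f"negative count totals for sample {sample_id!r}: "
            f"unique={unique_counts}, multi={multi_counts}"
        )
    total = unique_counts + multi_counts
    if total == 0:
        raise ValidationError(
            f"multi-hit rate undefined for sample {sample_id!r}: zero total reads"
        )
    rate = multi_counts / total
    return QCReport(
        sample_id=str(sample_id),
        multihit_rate=rate,
        library_size=total,
        flagged=rate > threshold,
    )


def join_validate(matrix: CountMatrix, sheet: SampleSheet) -> None:
    """Check that matrix and sheet describe the same samples.

    Raises :class:`ValidationError` listing ids present on one side only.
    """
    m = set(matrix.sample_ids)
    s = set(sheet.sample_ids)
    if m != s:
        parts = []
        if m - s:
            parts.append(f"in matrix only: {sorted(m - s)}")
        if s - m:
            parts.append(f"in sheet only: {sorted(s - m)}")
        raise ValidationError("sample id mismatch; " + "; ".join(parts))


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    if rows:
        return pd.DataFrame(rows)
    raise ValidationError(
        "cannot infer a schema from an empty record sequence; "
        "pass a DataFrame with columns instead"
    )


def write_table(records, path: str | os.PathLike) -> None:
    """Write tabular results as TSV with header, stable column order, and
    full float precision (17 significant digits).

    ``records`` may be a DataFrame or a sequence of dataclass instances /
    mappings sharing a schema. An empty DataFrame yields a header-only file.
    """
    frame = _records_to_frame(records)
    if frame.shape[1] == 0:
        raise ValidationError("record set has no columns to write")
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
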