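"""Core data containers and tabular I/O.

The pipeline operates on three inputs: a log-scale expression matrix
(probes x samples), a per-sample clinical table carrying disease-free
survival times/events and tumour grade, and strand-aware gene models with
a probe-to-gene mapping.  All genomic coordinates are stored 0-based
half-open; format-specific conventions are converted at the parser
boundary.  An optional copy-number track lives in :mod:`sagpipe.copynumber`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneRecord",
    "GeneAnnotationSet",
    "read_expression",
    "write_expression",
    "normalize_mean_scale",
    "read_clinical",
    "write_clinical",
    "read_gene_models",
    "write_gene_models_bed",
]

VALID_STRANDS = frozenset({"+", "-"})


class ExpressionMatrix:
    """Log-scale expression intensities, probes x samples.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by probe id, columns by sample id, values finite
        log-scale signal intensities.
    log_base : float, default 2
        Base of the logarithm the values are expressed in.  Affymetrix
        MAS5-style pipelines conventionally use base 2.
    """

    def __init__(self, data: pd.DataFrame, log_base: float = 2.0):
        if log_base <= 0 or log_base == 1:
            raise ValueError(f"invalid log base {log_base!r}")
        data = data.copy()
        dup_p = data.index[data.index.duplicated()].unique().tolist()
        if dup_p:
            raise ValueError(f"duplicated probe id(s): {dup_p}")
        dup_s = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicated sample id(s): {dup_s}")
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression value: {exc}") from exc
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at probe {data.index[i]!r}, "
                f"sample {data.columns[j]!r}"
            )
        self.data = data.astype(float)
        self.log_base = float(log_base)

    # -- basic interface -------------------------------------------------
    @property
    def probe_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, probe_id) -> np.ndarray:
        return self.data.loc[probe_id].to_numpy()

    def subset(self, probes: Sequence) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise KeyError(f"probe id(s) not present: {missing}")
        return ExpressionMatrix(self.data.loc[list(probes)], self.log_base)

    def subset_samples(self, samples: Sequence) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"sample id(s) not present: {missing}")
        return ExpressionMatrix(self.data[list(samples)], self.log_base)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, n = self.shape
        return f"<ExpressionMatrix {p} probes x {n} samples, log{self.log_base:g}>"


@dataclass(frozen=True)
class GeneRecord:
    """One strand-aware gene interval (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    probe_ids: tuple = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start position (5' end, strand-aware)."""
        return self.start if self.strand == "+" else self.end


class GeneAnnotationSet:
    """An ordered collection of :class:`GeneRecord` with id lookup."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            dups = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicated gene id(s): {dups}")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def sorted_by_position(self) -> list[GeneRecord]:
        return sorted(self.records, key=lambda r: (r.chrom, r.start, r.end))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "start": [r.start for r in self.records],
                "end": [r.end for r in self.records],
                "strand": [r.strand for r in self.records],
                "probe_ids": [",".join(r.probe_ids) for r in self.records],
            }
        )


class ClinicalTable:
    """Per-sample disease-free survival outcomes and grade labels.

    ``dfs_time`` is the interval from surgery to first recurrence or last
    follow-up; ``dfs_event`` is 1 for an observed recurrence and 0 for a
    censored record; ``grade`` is a categorical tumour-grade label.
    """

    REQUIRED = ("dfs_time", "dfs_event", "grade")

    def __init__(self, data: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        data = data.copy()
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample id(s): {dups}")
        times = data["dfs_time"].to_numpy(dtype=float)
        if np.any(~np.isfinite(times)) or np.any(times < 0):
            raise ValueError("dfs_time must be finite and non-negative")
        events = data["dfs_event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            bad = sorted(set(events) - {0, 1})
            raise ValueError(f"dfs_event must be 0 or 1, found {bad}")
        data["dfs_time"] = times
        data["dfs_event"] = events.astype(int)
        self.data = data

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def dfs_time(self) -> np.ndarray:
        return self.data["dfs_time"].to_numpy()

    @property
    def dfs_event(self) -> np.ndarray:
        return self.data["dfs_event"].to_numpy()

    @property
    def grade(self) -> pd.Series:
        return self.data["grade"]

    def subset(self, samples: Sequence) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"sample id(s) not present: {missing}")
        return ClinicalTable(self.data.loc[list(samples)])

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# expression I/O and normalization
# ---------------------------------------------------------------------------

def read_expression(path, log_base: float = 2.0) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column holds probe ids, the header row holds sample ids.  Row and
    column order of the file are preserved.  Duplicated ids and non-numeric
    cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.astype(float)
    except ValueError:
        # locate the offending cell for a useful message
        for col in df.columns:
            for probe, cell in df[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at probe {probe!r}, sample {col!r}: "
                        f"{cell!r}"
                    ) from None
        raise
    return ExpressionMatrix(df, log_base=log_base)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV at full float precision."""
    df = expr.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def normalize_mean_scale(
    expr: ExpressionMatrix,
    target: float | None = None,
    already_log: bool = True,
) -> ExpressionMatrix:
    """Shift the matrix so its grand mean equals a target log-signal.

    Mirrors the microarray convention of log-transforming calibrated
    intensities and adjusting the mean signal to log(500).  The adjustment
    is a single additive shift on the log scale (equivalently a common
    multiplicative rescaling of the linear intensities), so it changes no
    correlation, rank or grouping statistic downstream.

    Parameters
    ----------
    expr : ExpressionMatrix
        Input matrix.  If ``already_log`` is False the stored values are
        taken as raw linear intensities (all strictly positive) and are
        log-transformed first.
    target : float, optional
        Target grand mean on the log scale; defaults to
        ``log(500)`` in ``expr.log_base``.
    """
    values = expr.values
    if not already_log:
        if np.any(values <= 0):
            raise ValueError("raw intensities must be positive for log transform")
        values = np.log(values) / math.log(expr.log_base)
    if target is None:
        target = math.log(500.0) / math.log(expr.log_base)
    shifted = values + (target - values.mean())
    out = pd.DataFrame(shifted, index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(out, expr.log_base)


# ---------------------------------------------------------------------------
# clinical I/O
# ---------------------------------------------------------------------------

def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, dfs_time, dfs_event, grade."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    df = clin.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# gene-model I/O
# ---------------------------------------------------------------------------

def _parse_bed6(path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{line_no}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            records.append(
                GeneRecord(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return records


def _gff3_attributes(attr_field: str) -> dict:
    out = {}
    for part in attr_field.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _parse_gff3(path) -> list[GeneRecord]:
    # GFF3 is 1-based closed; convert to 0-based half-open on ingest.
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{line_no}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "transcript", "mRNA"):
                continue
            a = _gff3_attributes(attrs)
            gene_id = a.get("ID") or a.get("gene_id") or a.get("Name")
            if gene_id is None:
                raise ValueError(f"{path}:{line_no}: feature without ID attribute")
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                )
            )
    return records


def read_gene_models(
    path, fmt: str = "auto", probe_map: dict | None = None
) -> GeneAnnotationSet:
    """Read strand-aware gene models from BED6 or GFF3.

    Parameters
    ----------
    fmt : {"bed6", "gff3", "auto"}
        "auto" infers from the file extension.
    probe_map : dict, optional
        Mapping gene_id -> iterable of probe ids to attach.
    """
    fmt = fmt.lower()
    if fmt == "auto":
        suffix = Path(path).suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed6"
    if fmt == "bed6":
        records = _parse_bed6(path)
    elif fmt == "gff3":
        records = _parse_gff3(path)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    if probe_map:
        records = [
            GeneRecord(
                r.gene_id, r.chrom, r.start, r.end, r.strand,
                tuple(probe_map.get(r.gene_id, ())),
            )
            for r in records
        ]
    return GeneAnnotationSet(records)


def write_gene_models_bed(genes: GeneAnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for r in genes:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
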