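"""Readers and writers for the formats the promoterome pipeline touches.

Everything in the package speaks one coordinate convention: 0-based,
half-open, stranded intervals (the BED convention).  Genome-browser style
literals such as ``chr12:50484904..50484950,+`` are 1-based inclusive and
are converted on parsing by :func:`parse_locus`.

Formats
-------
* BED6 for all interval files (peaks, TSS clusters, CpG islands, TATA
  boxes, histone marks, enhancers).
* CTSS files: BED6 rows of width-1 intervals with the tag count in the
  score column.
* Expression tables: strict TSV, header row of sample ids, first column
  row ids, every cell a finite non-negative float.
* TFBS site tables: headerless TSV ``tf  chrom  start  end  posterior
  [strand]``.

Parsing is deliberately strict: non-numeric cells, ragged rows, inverted
coordinates and duplicate identifiers raise :class:`ParseError` with the
offending line, never silently impute.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "STRANDS",
    "UNSTRANDED",
    "ParseError",
    "GenomicInterval",
    "BedFeature",
    "CtssRecord",
    "ExpressionTable",
    "TfbsSiteRecord",
    "parse_locus",
    "read_bed",
    "write_bed",
    "read_ctss",
    "write_ctss",
    "read_expression_table",
    "read_library_totals",
    "write_library_totals",
    "read_promoter_map",
    "write_promoter_map",
    "read_tfbs_sites",
    "write_tfbs_sites",
    "read_background_counts",
    "write_background_counts",
]

UNSTRANDED = "."
STRANDS = ("+", "-", UNSTRANDED)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Integer midpoint floor((start + end - 1) / 2): the reference base."""
        return (self.start + self.end - 1) // 2

    @property
    def midpoint(self) -> float:
        """Geometric midpoint of the covered bases (float)."""
        return (self.start + self.end - 1) / 2.0

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp; 0 when disjoint, on another chrom, or on
        incompatible strands (unstranded matches both)."""
        if self.chrom != other.chrom:
            return 0
        if not strands_compatible(self.strand, other.strand):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def expand(self, pad: int) -> "GenomicInterval":
        if pad < 0:
            raise ValueError("pad must be >= 0")
        return replace(self, start=max(0, self.start - pad), end=self.end + pad)


def strands_compatible(a: str, b: str) -> bool:
    return a == UNSTRANDED or b == UNSTRANDED or a == b


@dataclass(frozen=True)
class BedFeature:
    """One BED record: an interval plus a name and a numeric score."""

    interval: GenomicInterval
    name: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.name}")


@dataclass(frozen=True)
class CtssRecord:
    """A single CAGE TSS: one genomic base with a tag count."""

    interval: GenomicInterval
    count: int

    def __post_init__(self) -> None:
        if self.interval.width != 1:
            raise ValueError("CTSS records must have width 1")
        if self.count < 0:
            raise ValueError("negative tag count")

    @property
    def position(self) -> int:
        return self.interval.start


@dataclass(frozen=True)
class TfbsSiteRecord:
    """A putative TF binding site with its motif-model posterior."""

    tf: str
    interval: GenomicInterval
    posterior: float

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("empty TF name")
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")


_LOCUS_RE = re.compile(r"\s*([\w.]+):(\d+)\.\.(\d+),([+-])\s*$")


def parse_locus(text: str) -> GenomicInterval:
    """Parse a browser-style ``chrN:A..B,strand`` literal (1-based inclusive)
    into the package's 0-based half-open convention."""
    m = _LOCUS_RE.match(text)
    if m is None:
        raise ParseError(f"cannot parse locus literal {text!r}")
    chrom, a, b, strand = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
    if a < 1 or b < a:
        raise ParseError(f"invalid 1-based range in {text!r}")
    return GenomicInterval(chrom, a - 1, b, strand)


def format_locus(iv: GenomicInterval) -> str:
    strand = iv.strand if iv.strand != UNSTRANDED else "+"
    return f"{iv.chrom}:{iv.start + 1}..{iv.end},{strand}"


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_coords(fields: Sequence[str], lineno: int, path: Path) -> GenomicInterval:
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0:
        raise ParseError(f"{path}:{lineno}: negative start {start}")
    if start >= end:
        raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
    strand = UNSTRANDED
    if len(fields) >= 6 and fields[5]:
        if fields[5] not in STRANDS:
            raise ParseError(f"{path}:{lineno}: invalid strand {fields[5]!r}")
        strand = fields[5]
    return GenomicInterval(chrom, start, end, strand)


def read_bed(path: str | Path) -> list[BedFeature]:
    """Read a BED3/BED6 file into an ordered list of features.

    Missing names become ``feat_<line>``; a missing strand is unstranded.
    """
    path = Path(path)
    out: list[BedFeature] = []
    for lineno, fields in _data_lines(path):
        iv = _parse_coords(fields, lineno, path)
        name = fields[3] if len(fields) >= 4 and fields[3] else f"feat_{lineno}"
        score = 0.0
        if len(fields) >= 5 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
        out.append(BedFeature(iv, name, score))
    return out


def write_bed(features: Iterable[BedFeature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in features:
            iv = f.interval
            score = f.score
            score_str = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.name}\t{score_str}\t{iv.strand}\n")


def read_ctss(path: str | Path) -> dict[tuple[str, str], list[CtssRecord]]:
    """Read a CTSS file, grouping records by (chrom, strand).

    Within each group records are sorted by position and duplicate
    positions are merged by summing their counts.
    """
    path = Path(path)
    acc: dict[tuple[str, str], dict[int, int]] = {}
    for lineno, fields in _data_lines(path):
        iv = _parse_coords(fields, lineno, path)
        if iv.width != 1:
            raise ParseError(f"{path}:{lineno}: CTSS interval must have width 1")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: CTSS rows need a count in the score column")
        try:
            count = int(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer tag count {fields[4]!r}") from exc
        if count < 0:
            raise ParseError(f"{path}:{lineno}: negative tag count {count}")
        key = (iv.chrom, iv.strand)
        acc.setdefault(key, {}).setdefault(iv.start, 0)
        acc[key][iv.start] += count
    return {
        key: [
            CtssRecord(GenomicInterval(key[0], pos, pos + 1, key[1]), n)
            for pos, n in sorted(positions.items())
        ]
        for key, positions in acc.items()
    }


def write_ctss(records: Iterable[CtssRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tctss\t{r.count}\t{iv.strand}\n")


class ExpressionTable:
    """A promoters/enhancers x samples expression matrix with sample metadata.

    ``values`` is a pandas DataFrame (rows = features, columns = samples)
    of finite, non-negative floats with unique axis labels.  ``sample_meta``
    is an optional per-sample DataFrame (species, category, stage) indexed
    by sample id.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate row ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if arr.size and (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if sample_meta is not None and not sample_meta.index.equals(values.columns):
            sample_meta = sample_meta.reindex(values.columns)
        self.values = values
        self.sample_meta = sample_meta

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, row_id: str) -> np.ndarray:
        if row_id not in self.values.index:
            raise KeyError(f"unknown row id {row_id!r}")
        return self.values.loc[row_id].to_numpy()

    def subset_rows(self, row_ids: Sequence[str]) -> "ExpressionTable":
        missing = [r for r in row_ids if r not in self.values.index]
        if missing:
            raise KeyError(f"unknown row ids: {missing}")
        return ExpressionTable(self.values.loc[list(row_ids)], self.sample_meta)

    def rename_rows(self, mapping: Mapping[str, str]) -> "ExpressionTable":
        return ExpressionTable(self.values.rename(index=dict(mapping)), self.sample_meta)

    def equals(self, other: "ExpressionTable") -> bool:
        return self.values.equals(other.values)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionTable({self.shape[0]} rows x {self.shape[1]} samples)"


def read_expression_table(
    path: str | Path, sample_meta: pd.DataFrame | None = None
) -> ExpressionTable:
    """Read a strict-TSV expression table (header = sample ids, first
    column = row ids)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [l.rstrip("\n").rstrip("\r") for l in fh]
    lines = [l for l in lines if l]
    if not lines:
        raise ParseError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids in header")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        rid = fields[0]
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate row id {rid!r}")
        seen.add(rid)
        vals = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                ) from exc
        row_ids.append(rid)
        rows.append(vals)
    values = pd.DataFrame(rows, index=row_ids, columns=sample_ids, dtype=float)
    try:
        return ExpressionTable(values, sample_meta)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_library_totals(path: str | Path) -> pd.Series:
    """Two-column TSV (sample id, total mapped tags) -> Series."""
    path = Path(path)
    ids, totals = [], []
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        try:
            total = float(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric total {fields[1]!r}") from exc
        ids.append(fields[0])
        totals.append(total)
    s = pd.Series(totals, index=ids, dtype=float)
    if s.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    return s


def write_library_totals(totals: pd.Series, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, total in totals.items():
            fh.write(f"{sid}\t{total:.10g}\n")


def read_promoter_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (gene, row id) -> gene -> ordered row ids."""
    path = Path(path)
    out: dict[str, list[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (gene, row id)")
        out.setdefault(fields[0], []).append(fields[1])
    return out


def write_promoter_map(mapping: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, rids in mapping.items():
            for rid in rids:
                fh.write(f"{gene}\t{rid}\n")


def read_tfbs_sites(path: str | Path) -> list[TfbsSiteRecord]:
    """Headerless TSV ``tf chrom start end posterior [strand]``."""
    path = Path(path)
    out: list[TfbsSiteRecord] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected >=5 columns")
        tf = fields[0]
        iv = _parse_coords([fields[1], fields[2], fields[3], "", "", *fields[5:6]], lineno, path)
        try:
            posterior = float(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric posterior {fields[4]!r}") from exc
        if not (0.0 <= posterior <= 1.0):
            raise ParseError(f"{path}:{lineno}: posterior {posterior} outside [0, 1]")
        out.append(TfbsSiteRecord(tf, iv, posterior))
    return out


def write_tfbs_sites(sites: Iterable[TfbsSiteRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sites:
            iv = s.interval
            fh.write(
                f"{s.tf}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{s.posterior:.10g}\t{iv.strand}\n"
            )


def read_background_counts(path: str | Path) -> dict[str, np.ndarray]:
    """Per-TF background summed-posterior counts: TSV ``tf promoter count``."""
    path = Path(path)
    acc: dict[str, list[float]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns (tf, promoter, count)")
        try:
            count = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric count {fields[2]!r}") from exc
        if count < 0:
            raise ParseError(f"{path}:{lineno}: negative count {count}")
        acc.setdefault(fields[0], []).append(count)
    return {tf: np.asarray(vals, dtype=float) for tf, vals in acc.items()}


def write_background_counts(backgrounds: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf, vals in backgrounds.items():
            for i, v in enumerate(np.asarray(vals, dtype=float)):
                fh.write(f"{tf}\tbg_{i}\t{v:.10g}\n")
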