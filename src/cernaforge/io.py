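"""Annotation, expression-table and network I/O.

Internal genomic coordinates are 0-based half-open throughout the package;
GTF files (1-based, end-inclusive) are converted at the read/write boundary
and nowhere else. Expression tables are plain UTF-8 TSV with feature IDs in
the first column and sample IDs in the header. Networks are written as a
SIF-compatible three-column file plus a TSV edge-attribute table, in a
deterministic (lexicographic) row order so identical networks produce
byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptRecord",
    "ExpressionMatrix",
    "GTFParseError",
    "read_gtf",
    "write_gtf",
    "read_expression_table",
    "write_expression_table",
    "write_edge_list",
    "DEFAULT_STAGES",
]

#: The study's four growth stages (lamb, pubertal, adult, old); configurable
#: everywhere a stage list is accepted.
DEFAULT_STAGES = ("4m", "1.5y", "3.5y", "6y")

_STRANDS = {"+", "-", "."}


class GTFParseError(ValueError):
    """Raised for malformed GTF content, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True if the intervals share >= 1 bp (optionally requiring same strand)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


def span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open spans; 0 when they touch or overlap."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


@dataclass
class TranscriptRecord:
    """One assembled transcript: exon structure plus coding-potential evidence.

    ``coding_call_a`` / ``coding_call_b`` are the two externally computed
    coding-potential predictions (True means the predictor calls the
    transcript *coding*); ``db_annotated`` is True when the transcript matched
    a protein/ncRNA annotation database and must be excluded from the novel
    set. ``attributes`` keeps unknown GTF attributes verbatim for lossless
    round trips.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    class_code: str = "="
    orf_length: int = 0
    coding_call_a: bool = False
    coding_call_b: bool = False
    coding_score: float = 0.0
    biotype: str = "other_ncRNA"
    db_annotated: bool = False
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"{self.transcript_id}: exons span chromosomes {sorted(chroms)}")
        if len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.orf_length < 0 or self.orf_length > self.length:
            raise ValueError(
                f"{self.transcript_id}: orf_length {self.orf_length} outside [0, {self.length}]"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Transcript (mature) length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'\s*(\S+)\s+"([^"]*)"\s*;?')

# transcript-level fields serialised as GTF attributes so write/read is lossless
_BOOL_FIELDS = ("coding_call_a", "coding_call_b", "db_annotated")
_KNOWN_FIELDS = ("class_code", "orf_length", "coding_score", "biotype") + _BOOL_FIELDS


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    pos = 0
    while pos < len(text.rstrip()):
        m = _ATTR_RE.match(text, pos)
        if m is None:
            raise GTFParseError(f"line {lineno}: malformed attribute column: {text!r}")
        attrs[m.group(1)] = m.group(2)
        pos = m.end()
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Read exon features from a GTF file into transcript records.

    Only ``exon`` features are consumed; each must carry ``transcript_id``
    and ``gene_id`` attributes. 1-based inclusive coordinates are converted
    to 0-based half-open. A missing ``class_code`` defaults to ``"="``
    (matches known annotation).
    """
    by_tid: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"line {lineno}: expected 9 tab-separated columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_col = fields
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_col, lineno)
            try:
                tid = attrs.pop("transcript_id")
                gid = attrs.pop("gene_id")
            except KeyError as exc:
                raise GTFParseError(f"line {lineno}: exon missing {exc} attribute") from None
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: {exc}") from None
            rec = by_tid.setdefault(
                tid, {"transcript_id": tid, "gene_id": gid, "exons": [], "attrs": {}}
            )
            rec["exons"].append(iv)
            rec["attrs"].update(attrs)

    records = []
    for tid, rec in by_tid.items():
        attrs = rec["attrs"]
        kwargs: dict = {
            "transcript_id": tid,
            "gene_id": rec["gene_id"],
            "exons": rec["exons"],
            "class_code": attrs.pop("class_code", "="),
            "orf_length": int(attrs.pop("orf_length", 0)),
            "coding_score": float(attrs.pop("coding_score", 0.0)),
            "biotype": attrs.pop("biotype", "other_ncRNA"),
        }
        for name in _BOOL_FIELDS:
            kwargs[name] = attrs.pop(name, "0") == "1"
        records.append(TranscriptRecord(**kwargs, attributes=attrs))
    return records


def _format_attributes(rec: TranscriptRecord) -> str:
    parts = [f'transcript_id "{rec.transcript_id}"', f'gene_id "{rec.gene_id}"']
    parts.append(f'class_code "{rec.class_code}"')
    parts.append(f'orf_length "{rec.orf_length}"')
    parts.append(f'coding_score "{rec.coding_score!r}"')
    parts.append(f'biotype "{rec.biotype}"')
    for name in _BOOL_FIELDS:
        parts.append(f'{name} "{int(getattr(rec, name))}"')
    for key, value in rec.attributes.items():
        parts.append(f'{key} "{value}"')
    return "; ".join(parts) + ";"


def write_gtf(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """Write one ``exon`` line per exon, converting back to 1-based inclusive.

    Records are written sorted by (chrom, start, transcript_id) so output is
    deterministic; unknown attributes are reproduced verbatim.
    """
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.transcript_id))
    with open(path, "w", encoding="utf-8") as fh:
        for rec in ordered:
            attr_col = _format_attributes(rec)
            for exon in rec.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "cernaforge",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attr_col,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Feature-by-sample abundance table with stage/replicate metadata.

    ``values`` is features x samples (FPKM or counts, all >= 0); ``design``
    is indexed by sample ID with columns ``stage`` and ``replicate``.
    """

    values: pd.DataFrame
    layer: str = "mRNA"
    design: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dupes}")
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                f"NA value at feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.design is None:
            self.design = _design_from_sample_ids(self.values.columns)
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            stage = self.design.loc[s, "stage"]
            if stage not in seen:
                seen.append(stage)
        return seen

    def samples_in_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.design.loc[s, "stage"] == stage]

    def unexpressed(self) -> list[str]:
        """Features with all-zero rows (flagged, not dropped)."""
        zero = (self.values == 0).all(axis=1)
        return list(self.values.index[zero])

    def log2p(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.values + pseudocount)


def _design_from_sample_ids(sample_ids: Iterable[str]) -> pd.DataFrame:
    """Fallback design: parse ``<stage>_<replicate>`` sample IDs."""
    rows = []
    for sid in sample_ids:
        stage, _, rep = sid.rpartition("_")
        if not stage:
            stage, rep = sid, "1"
        rows.append({"sample": sid, "stage": stage, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample")


def read_expression_table(
    path: str | Path,
    layer: str = "mRNA",
    design_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TSV matrix (first column feature IDs, header sample IDs).

    Stage/replicate metadata comes from a sidecar design TSV (columns
    ``sample``, ``stage``, ``replicate``) when given, else from the
    ``<stage>_<replicate>`` sample-ID pattern.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    design = None
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t").set_index("sample")
        design.index = design.index.astype(str)
    return ExpressionMatrix(values=values, layer=layer, design=design)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, design_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(path, sep="\t")
    if design_path is not None:
        matrix.design.to_csv(design_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Network edge lists
# ---------------------------------------------------------------------------


def write_edge_list(edges: Iterable, sif_path: str | Path, attrs_path: str | Path) -> None:
    """Write typed network edges as SIF plus a TSV attribute table.

    Each edge must expose ``node_a``, ``node_b``, ``kind``, ``statistic`` and
    ``p_value``. Rows are sorted lexicographically by (source, target), so
    the same network always yields byte-identical files (ready for Cytoscape
    or igraph import).
    """
    rows = sorted(
        (
            (e.node_a, e.kind, e.node_b, e.statistic, e.p_value)
            for e in edges
        ),
        key=lambda r: (r[0], r[2], r[1]),
    )
    with open(sif_path, "w", encoding="utf-8") as fh:
        for source, kind, target, _stat, _p in rows:
            fh.write(f"{source}\t{kind}\t{target}\n")
    with open(attrs_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tkind\tstatistic\tp_value\n")
        for source, kind, target, stat, p in rows:
            stat_s = "NA" if stat is None else repr(float(stat))
            p_s = "NA" if p is None else repr(float(p))
            fh.write(f"{source}\t{target}\t{kind}\t{stat_s}\t{p_s}\n")
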