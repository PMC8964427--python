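"""Novel-lncRNA identification cascade and positional classification.

The cascade mirrors the standard assembly-based workflow: candidate novelty
by assembler class code; structural plausibility (length > 200 bp, exon
count); removal of transcripts overlapping protein-coding exons; exclusion
of transcripts matching annotation databases; and the intersection of two
independent coding-potential predictors (both must call noncoding).

Every rule is evaluated independently for every candidate, so the surviving
set is identical regardless of the order the rules are applied in, and a
failing transcript reports *all* rules it violates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .io import GenomicInterval, TranscriptRecord, span_gap

__all__ = [
    "NOVEL_CLASS_CODES",
    "FilterReport",
    "PositionalClass",
    "select_novel_candidates",
    "apply_structural_filters",
    "remove_coding_overlap",
    "call_noncoding",
    "filter_cascade",
    "classify_position",
]

#: Assembler class codes treated as novel-transcript candidates.
NOVEL_CLASS_CODES = frozenset("ijxuceo")

#: All class codes with a defined meaning in this pipeline.
_KNOWN_CLASS_CODES = NOVEL_CLASS_CODES | frozenset("=kmnpsry.")

RULE_CLASS_CODE = "class_code"
RULE_LENGTH = "length"
RULE_EXON_COUNT = "exon_count"
RULE_CODING_OVERLAP = "coding_overlap"
RULE_KNOWN_ANNOTATION = "known_annotation"
RULE_CODING_POTENTIAL = "coding_potential"


@dataclass
class FilterReport:
    """Per-transcript outcome of the identification cascade."""

    transcript_id: str
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


class PositionalClass(str, Enum):
    """Five-way positional class of a lncRNA relative to coding genes."""

    INTERGENIC = "intergenic"
    BIDIRECTIONAL = "bidirectional"
    INTRONIC = "intronic"
    ANTISENSE = "antisense"
    SENSE_OVERLAPPING = "sense_overlapping"


def select_novel_candidates(
    transcripts: Sequence[TranscriptRecord],
) -> list[TranscriptRecord]:
    """Keep transcripts whose class code marks them novel (i/j/x/u/c/e/o).

    Unknown class codes trigger a warning and are excluded.
    """
    kept = []
    for t in transcripts:
        if t.class_code in NOVEL_CLASS_CODES:
            kept.append(t)
        elif t.class_code not in _KNOWN_CLASS_CODES:
            warnings.warn(
                f"{t.transcript_id}: unknown class code {t.class_code!r}, excluded",
                stacklevel=2,
            )
    return kept


def apply_structural_filters(
    candidates: Sequence[TranscriptRecord],
    min_length: int = 200,
    min_exons: int = 2,
) -> list[FilterReport]:
    """Length / exon-count screen.

    A transcript fails the length rule iff its mature length is <= ``min_length``
    (the 200-bp rule is "longer than 200 bp", so 201 passes), and fails the
    exon rule iff it has fewer than ``min_exons`` exons. Pass ``min_exons=3``
    for the strict "more than 2 exons" reading.
    """
    reports = []
    for t in candidates:
        failed = []
        if t.length <= min_length:
            failed.append(RULE_LENGTH)
        if t.exon_count < min_exons:
            failed.append(RULE_EXON_COUNT)
        reports.append(FilterReport(t.transcript_id, failed))
    return reports


def _exonic_overlap(t: TranscriptRecord, mrnas: Sequence[TranscriptRecord], stranded: bool) -> bool:
    for m in mrnas:
        if t.chrom != m.chrom:
            continue
        if span_gap(t.start, t.end, m.start, m.end) > 0:
            continue
        for e in t.exons:
            for me in m.exons:
                if e.overlaps(me, stranded=stranded):
                    return True
    return False


def remove_coding_overlap(
    candidates: Sequence[TranscriptRecord],
    mrnas: Sequence[TranscriptRecord],
    stranded: bool = True,
) -> list[FilterReport]:
    """Fail candidates whose exons share >= 1 bp with any mRNA exon.

    ``stranded=True`` (default) requires the overlap to be on the same strand;
    ``stranded=False`` removes overlap on either strand.
    """
    return [
        FilterReport(
            t.transcript_id,
            [RULE_CODING_OVERLAP] if _exonic_overlap(t, mrnas, stranded) else [],
        )
        for t in candidates
    ]


def call_noncoding(candidates: Sequence[TranscriptRecord]) -> list[FilterReport]:
    """Intersection rule: pass iff BOTH coding-potential predictors call noncoding."""
    reports = []
    for t in candidates:
        if t.coding_call_a is None or t.coding_call_b is None:
            raise ValueError(f"{t.transcript_id}: missing coding-potential call")
        failed = [] if (not t.coding_call_a and not t.coding_call_b) else [RULE_CODING_POTENTIAL]
        reports.append(FilterReport(t.transcript_id, failed))
    return reports


def filter_cascade(
    transcripts: Sequence[TranscriptRecord],
    mrnas: Sequence[TranscriptRecord],
    min_length: int = 200,
    min_exons: int = 2,
    stranded_overlap: bool = True,
) -> list[FilterReport]:
    """Run the full identification cascade, one report per input transcript.

    All six rules are evaluated for every transcript (no short-circuiting),
    so ``failed_rules`` is complete and the pass set is order-independent.
    """
    reports = []
    for t in transcripts:
        failed = []
        if t.class_code not in NOVEL_CLASS_CODES:
            failed.append(RULE_CLASS_CODE)
        if t.length <= min_length:
            failed.append(RULE_LENGTH)
        if t.exon_count < min_exons:
            failed.append(RULE_EXON_COUNT)
        if _exonic_overlap(t, mrnas, stranded_overlap):
            failed.append(RULE_CODING_OVERLAP)
        if t.db_annotated:
            failed.append(RULE_KNOWN_ANNOTATION)
        if t.coding_call_a or t.coding_call_b:
            failed.append(RULE_CODING_POTENTIAL)
        reports.append(FilterReport(t.transcript_id, failed))
    return reports


def _five_prime(t: TranscriptRecord) -> int:
    return t.start if t.strand != "-" else t.end


def _contained_in_intron(lnc: TranscriptRecord, gene: TranscriptRecord) -> bool:
    if lnc.chrom != gene.chrom:
        return False
    for left, right in zip(gene.exons, gene.exons[1:]):
        if left.end <= lnc.start and lnc.end <= right.start:
            return True
    return False


def classify_position(
    lnc: TranscriptRecord,
    coding_genes: Sequence[TranscriptRecord],
    bidi_window: int = 1000,
) -> PositionalClass:
    """Assign one of the five positional classes.

    Precedence: sense-overlapping (exonic overlap, same strand) > antisense
    (any overlap, opposite strand) > intronic (fully inside an intron) >
    bidirectional (no overlap, 5' end within ``bidi_window`` bp of an
    opposite-strand gene's 5' end) > intergenic.
    """
    for g in coding_genes:
        if g.chrom != lnc.chrom:
            continue
        same_strand = g.strand == lnc.strand
        if same_strand and _exonic_overlap(lnc, [g], stranded=True):
            return PositionalClass.SENSE_OVERLAPPING
    for g in coding_genes:
        if g.chrom != lnc.chrom or g.strand == lnc.strand:
            continue
        if span_gap(lnc.start, lnc.end, g.start, g.end) == 0:
            return PositionalClass.ANTISENSE
    for g in coding_genes:
        if _contained_in_intron(lnc, g):
            return PositionalClass.INTRONIC
    for g in coding_genes:
        if g.chrom != lnc.chrom or g.strand == lnc.strand:
            continue
        if span_gap(lnc.start, lnc.end, g.start, g.end) == 0:
            continue
        if abs(_five_prime(lnc) - _five_prime(g)) <= bidi_window:
            return PositionalClass.BIDIRECTIONAL
    return PositionalClass.INTERGENIC
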