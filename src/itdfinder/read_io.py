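"""Candidate-read extraction from SAM/BAM alignment files.

Candidates are (a) reads with the unmapped flag set and (b) primary mapped
reads whose CIGAR starts or ends with a soft clip of at least ``min_clip``
bases.  All internal coordinates are 0-based half-open; conversion to/from
SAM's 1-based convention happens only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

MIN_READ_LENGTH = 20


@dataclass(frozen=True)
class CandidateRead:
    """A read selected for duplication analysis.

    For ``origin == "softclip"`` the ``clip_segment`` is the unaligned head
    or tail of the read and is by construction a prefix or suffix of
    ``sequence``.
    """

    read_id: str
    sequence: str
    origin: str  # "unmapped" | "softclip"
    clip_segment: str | None = None
    clip_side: str | None = None  # "head" | "tail"
    source_locus: tuple[str, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.origin not in ("unmapped", "softclip"):
            raise ValueError(f"bad origin {self.origin!r}")
        if len(self.sequence) < MIN_READ_LENGTH:
            raise ValueError("candidate sequence shorter than 20 bp")
        if self.origin == "softclip":
            if self.clip_segment is None or len(self.clip_segment) < 4:
                raise ValueError("soft-clip segment must be >= 4 bp")
            ok = (
                self.sequence.startswith(self.clip_segment)
                if self.clip_side == "head"
                else self.sequence.endswith(self.clip_segment)
            )
            if not ok:
                raise ValueError("clip_segment is not a prefix/suffix of sequence")


def _iter_records(alignment):
    if isinstance(alignment, (str, bytes)):
        with pysam.AlignmentFile(str(alignment), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from alignment


def extract_candidates(alignment, min_clip: int = 4) -> set[CandidateRead]:
    """Collect unmapped reads and soft-clipped reads with clips >= min_clip.

    Secondary, supplementary and duplicate-marked records are skipped.  A
    read clipped at both ends yields one candidate per qualifying side.
    """
    if min_clip < 1:
        raise ValueError("min_clip must be >= 1")
    out: set[CandidateRead] = set()
    for rec in _iter_records(alignment):
        try:
            if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            seq = rec.query_sequence
            if seq is None or len(seq) < MIN_READ_LENGTH:
                if rec.is_unmapped:
                    logger.warning("skipping unmapped read %s without usable sequence",
                                   rec.query_name)
                continue
            if rec.is_unmapped:
                out.add(CandidateRead(rec.query_name, seq, "unmapped"))
                continue
            cig = rec.cigartuples
            if not cig:
                continue
            locus = (rec.reference_name, rec.reference_start)
            if cig[0][0] == 4 and cig[0][1] >= min_clip:
                n = cig[0][1]
                out.add(CandidateRead(f"{rec.query_name}/clipH", seq, "softclip",
                                      seq[:n], "head", locus))
            if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
                n = cig[-1][1]
                out.add(CandidateRead(f"{rec.query_name}/clipT", seq, "softclip",
                                      seq[-n:], "tail", locus))
        except (ValueError, TypeError) as exc:  # malformed record
            logger.warning("skipping malformed record %s: %s",
                           getattr(rec, "query_name", "?"), exc)
    return out


def hard_filtered_depth(alignment, locus: tuple[str, int]) -> int:
    """Number of primary alignments overlapping the 1-bp ``locus``.

    Used as the allele-fraction denominator.  ``locus`` is (ref_name,
    0-based position) and must lie within the reference bounds declared in
    the header.
    """
    return _depth(alignment, locus, flank=0)


def spanning_depth(alignment, locus: tuple[str, int], flank: int = 5) -> int:
    """Primary alignments fully spanning ``locus`` +/- ``flank`` bases.

    Window edges are clamped to the reference bounds.  Used by the pipeline
    so the allele-fraction denominator counts reads under the same
    junction-spanning rule as the numerator.
    """
    return _depth(alignment, locus, flank=flank)


def _depth(alignment, locus: tuple[str, int], flank: int) -> int:
    ref_name, pos = locus
    if isinstance(alignment, (str, bytes)):
        fh = pysam.AlignmentFile(str(alignment), "r", check_sq=False)
        close = True
    else:
        fh = alignment
        close = False
    try:
        lengths = dict(zip(fh.references, fh.lengths))
        if ref_name not in lengths or not 0 <= pos < lengths[ref_name]:
            raise ValueError(f"locus {ref_name}:{pos} outside reference bounds")
        lo = max(0, pos - flank)
        hi = min(lengths[ref_name], pos + flank + 1)
        depth = 0
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary \
                    or rec.is_duplicate:
                continue
            if rec.reference_name != ref_name:
                continue
            if rec.reference_start <= lo and rec.reference_end >= hi:
                depth += 1
        return depth
    finally:
        if close:
            fh.close()
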