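"""Contig annotation: duplicated-kmer collapse, reference alignment,
classification, allele fraction and optional RNA validation.

A contig confirming a tandem duplication carries the same kmer twice at the
duplication distance.  One copy is collapsed out and the remainder is
aligned to the reference with a local affine-gap aligner; only alignments
with high identity, high query coverage and a clear specificity margin over
the second-best locus are annotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from itdfinder.assemble import Contig
from itdfinder.util import kmer_positions, revcomp

logger = logging.getLogger(__name__)

CODING_ITD = "coding_ITD"
INTRONIC = "intronic"
NON_INSERTION = "non_insertion"
OFF_TARGET = "off_target"

#: a junction-supporting read must reach this far past the junction
JUNCTION_FLANK = 5

#: contiguous reference alignment tolerates at most this gap
MAX_REFERENCE_GAP = 2


class UndefinedAlleleFraction(ValueError):
    """Raised when the depth denominator is zero."""


@dataclass(frozen=True)
class ITDCall:
    ref_name: str
    start: int  # 0-based half-open locus of the duplicated reference segment
    end: int
    dup_length: int
    classification: str
    gene: str | None
    support_reads: int
    depth: int
    allele_fraction: float  # NaN when depth is unavailable
    contig_id: str
    junction_offset: int  # contig coordinate of the start of the second copy


@dataclass(frozen=True)
class AlignmentHit:
    ref_name: str
    strand: str  # "+"/"-" of the collapsed query
    score: float
    identity: float
    query_cover: float
    margin: float
    ref_start: int
    ref_end: int
    max_ref_gap: int
    query_length: int
    # aligned blocks in (target, query-as-aligned) coordinates
    target_blocks: tuple = field(compare=False, default=())
    query_blocks: tuple = field(compare=False, default=())

    def map_query_interval(self, qstart: int, qend: int) -> tuple[int, int]:
        """Project a query interval (query-as-aligned coords) onto the reference."""

        def project(q: int) -> int:
            for (ts, te), (qs, qe) in zip(self.target_blocks, self.query_blocks):
                if qs <= q < qe:
                    return int(ts + (q - qs))
                if q < qs:
                    return int(ts)
            # beyond the last aligned block: extrapolate off its end
            (ts, te), (qs, qe) = self.target_blocks[-1], self.query_blocks[-1]
            return int(te + (q - qe))

        lo, hi = project(qstart), project(qend - 1) + 1
        return (lo, hi) if lo <= hi else (hi, lo)


def make_aligner() -> Align.PairwiseAligner:
    """Local aligner: match 1, mismatch -2, gap open -3, extend -1."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def find_duplicated_kmer(contig: str, d_kmer: int, r_min: int, r_max: int):
    """Leftmost pair (p1, p2) of equal d_kmer-mers with r_min <= p2-p1 <= r_max."""
    if len(contig) < d_kmer:
        raise ValueError("contig shorter than d_kmer")
    positions = kmer_positions(contig, d_kmer)
    best = None
    for hits in positions.values():
        if len(hits) < 2:
            continue
        for i, p1 in enumerate(hits):
            for p2 in hits[i + 1:]:
                if r_min <= p2 - p1 <= r_max:
                    if best is None or (p1, p2) < best:
                        best = (p1, p2)
                    break
    return best


def candidate_kmer_pairs(contig: str, d_kmer: int, r_min: int, r_max: int,
                         limit: int = 5):
    """Duplicated-kmer pairs in leftmost order (fallbacks for collapse)."""
    pairs = set()
    for hits in kmer_positions(contig, d_kmer).values():
        for i, p1 in enumerate(hits):
            for p2 in hits[i + 1:]:
                if r_min <= p2 - p1 <= r_max:
                    pairs.add((p1, p2))
    return sorted(pairs)[:limit]


def collapse_duplication(contig: str, p1: int, p2: int) -> str:
    """Delete the segment [p1, p2) — the extra duplicated copy — from contig."""
    if not 0 <= p1 < p2 <= len(contig):
        raise ValueError("collapse positions out of range")
    return contig[:p1] + contig[p2:]


def _as_dict(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return {k: str(v) for k, v in reference.items()}
    # pyfaidx.Fasta or SeqIO dict-like
    return {name: str(reference[name][:]) for name in reference.keys()}


def _alignment_stats(alignment, query: str, target: str):
    tb = tuple(tuple(b) for b in alignment.aligned[0])
    qb = tuple(tuple(b) for b in alignment.aligned[1])
    matches = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        matches += sum(1 for i in range(te - ts) if target[ts + i] == query[qs + i])
    q_span = qb[-1][1] - qb[0][0]
    identity = matches / q_span if q_span else 0.0
    cover = q_span / len(query)
    max_gap = 0
    for prev, nxt in zip(tb, tb[1:]):
        max_gap = max(max_gap, nxt[0] - prev[1])
    return tb, qb, identity, cover, max_gap


def align_collapsed(collapsed: str, reference, min_identity: float = 0.95,
                    min_cover: float = 0.9, min_margin: float = 10.0):
    """Best specific local alignment of the collapsed contig, or None.

    Acceptance requires identity >= min_identity over >= min_cover of the
    query AND a score margin of >= min_margin over the second-best locus
    (other contigs, the opposite strand, and the best contig with the
    winning window excised).
    """
    refs = _as_dict(reference)
    if not refs:
        raise OSError("reference is empty or unreadable")
    aligner = make_aligner()
    scored = []
    for name in sorted(refs):
        target = refs[name]
        for strand, query in (("+", collapsed), ("-", revcomp(collapsed))):
            try:
                score = aligner.score(target, query)
            except ValueError:
                score = 0.0
            scored.append((score, name, strand, query))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_score, name, strand, query = scored[0]
    if best_score <= 0:
        return None
    target = refs[name]
    alignment = aligner.align(target, query)[0]
    tb, qb, identity, cover, max_gap = _alignment_stats(alignment, query, target)
    ref_start, ref_end = tb[0][0], tb[-1][1]

    rivals = [s for s, n, st, _ in scored[1:]]
    pad = len(query)
    for fragment in (target[: max(0, ref_start - pad)], target[ref_end + pad:]):
        if len(fragment) >= 10:
            try:
                rivals.append(aligner.score(fragment, query))
            except ValueError:
                pass
    margin = best_score - max(rivals) if rivals else best_score

    if identity < min_identity or cover < min_cover or margin < min_margin:
        return None
    return AlignmentHit(
        ref_name=name, strand=strand, score=best_score, identity=identity,
        query_cover=cover, margin=margin, ref_start=ref_start, ref_end=ref_end,
        max_ref_gap=max_gap, query_length=len(query),
        target_blocks=tb, query_blocks=qb,
    )


def classify_call(hit: AlignmentHit, p1: int, dup_length: int,
                  targets=None) -> tuple[str, int, int, str | None]:
    """Classification plus the duplicated reference segment for one event.

    ``p1`` is the start of the retained duplication copy in collapsed-contig
    coordinates.  Returns (classification, start, end, gene).
    """
    if hit.strand == "+":
        qs, qe = p1, p1 + dup_length
    else:
        qs = hit.query_length - (p1 + dup_length)
        qe = hit.query_length - p1
    rs, _ = hit.map_query_interval(qs, qe)
    start, end = rs, rs + dup_length

    if hit.max_ref_gap > MAX_REFERENCE_GAP:
        return NON_INSERTION, start, end, None
    if targets:
        for chrom, t_start, t_end, gene in targets:
            if chrom == hit.ref_name and t_start < end and start < t_end:
                return CODING_ITD, start, end, gene
        return OFF_TARGET, start, end, None
    return INTRONIC, start, end, None


def refine_duplication_locus(ref_seq: str, contig_seq: str, start: int,
                             dup_length: int) -> int:
    """Pin the duplicated segment by consistency with the contig evidence.

    When a contig begins or ends inside the duplication's periodic region,
    the kmer-pair position alone cannot place the segment boundary.  Each
    candidate start near the provisional one is tested by building the
    implied duplication allele and asking whether the contig (either strand)
    is an exact substring of it; the leftmost consistent start wins.  If no
    candidate validates (e.g. consensus errors), the provisional start is
    kept.
    """
    d = dup_length
    lo = max(0, start - d)
    hi = min(len(ref_seq) - d, start + d)
    rc = revcomp(contig_seq)
    valid = []
    for s in range(lo, hi + 1):
        end = s + d
        w_lo = max(0, s - len(contig_seq))
        w_hi = min(len(ref_seq), end + len(contig_seq))
        allele = ref_seq[w_lo:end] + ref_seq[s:w_hi]
        if contig_seq in allele or rc in allele:
            valid.append(s)
    if not valid:
        return start
    canonical = {left_align(ref_seq, s, s + d)[0] for s in valid}
    return min(canonical)


def left_align(ref_seq: str, start: int, end: int) -> tuple[int, int]:
    """Canonical (leftmost) representation of a tandem-duplicated segment.

    [start, end) and [start-1, end-1) describe the same duplication event
    whenever the base entering the window equals the base leaving it, so
    coordinates are shifted left until that no longer holds.
    """
    while start > 0 and ref_seq[start - 1] == ref_seq[end - 1]:
        start -= 1
        end -= 1
    return start, end


def allele_fraction(support_reads: int, depth: int) -> float:
    """support / depth with domain checks."""
    if support_reads < 0:
        raise ValueError("support_reads must be >= 0")
    if depth < 1:
        raise UndefinedAlleleFraction("depth must be >= 1")
    if support_reads > depth:
        raise ValueError("support_reads cannot exceed depth")
    return support_reads / depth


def count_junction_support(contig: Contig, junction_offset: int,
                           read_lengths: dict[str, int]) -> int:
    """Constituent reads whose placement spans the junction +/- JUNCTION_FLANK."""
    lo = junction_offset - JUNCTION_FLANK
    hi = junction_offset + JUNCTION_FLANK + 1
    n = 0
    for rid, (off, _strand) in contig.layout.items():
        if off <= lo and off + read_lengths.get(rid, 0) >= hi:
            n += 1
    return n


def rna_validate(contig, junction_offset: int, rna_reads,
                 min_identity: float = 0.97, min_reads: int = 10):
    """Count junction-crossing RNA reads on a contig.

    ``rna_reads`` is an iterable of sequences (or (id, seq) pairs).  A read
    counts as aligned when its best local alignment to the contig exceeds
    ``min_identity`` (matches / read length); it supports the junction when
    the alignment spans junction_offset +/- JUNCTION_FLANK.  The event is
    validated iff at least one junction read exists among transcripts with
    >= min_reads aligned reads in total.
    """
    sequence = contig.sequence if isinstance(contig, Contig) else str(contig)
    if not 0 <= junction_offset <= len(sequence):
        raise ValueError("junction_offset outside the contig")
    aligner = make_aligner()
    aligned = 0
    junction = 0
    for item in rna_reads:
        seq = item[1] if isinstance(item, tuple) else str(item)
        best = None
        for query in (seq, revcomp(seq)):
            try:
                score = aligner.score(sequence, query)
            except ValueError:
                continue
            if best is None or score > best[0]:
                best = (score, query)
        if best is None or best[0] <= 0:
            continue
        alignment = aligner.align(sequence, best[1])[0]
        tb, qb, _, _, _ = _alignment_stats(alignment, best[1], sequence)
        matches = 0
        for (ts, te), (qs, qe) in zip(tb, qb):
            matches += sum(
                1 for i in range(te - ts) if sequence[ts + i] == best[1][qs + i]
            )
        if matches / len(seq) <= min_identity:
            continue
        aligned += 1
        t_lo, t_hi = tb[0][0], tb[-1][1]
        if t_lo <= junction_offset - JUNCTION_FLANK and \
                t_hi >= junction_offset + JUNCTION_FLANK + 1:
            junction += 1
    validated = aligned >= min_reads and junction >= 1
    return junction, validated


def merge_calls(calls) -> list[ITDCall]:
    """Merge identical (ref_name, start, dup_length) events, keep max support."""
    grouped: dict[tuple, ITDCall] = {}
    for call in calls:
        key = (call.ref_name, call.start, call.dup_length)
        cur = grouped.get(key)
        if cur is None or (call.support_reads, call.contig_id) > \
                (cur.support_reads, cur.contig_id):
            grouped[key] = call
    return sorted(
        grouped.values(),
        key=lambda c: (c.ref_name, c.start, c.end, c.dup_length),
    )


# ---------------------------------------------------------------------------
# BED I/O

BED_HEADER_PREFIX = "#"


def write_calls_bed(path: str, calls, params_echo: dict | None = None) -> None:
    """BED6+4: chrom start end gene|dup_length support strand af class contig junction."""
    with open(path, "w") as fh:
        if params_echo:
            for key in sorted(params_echo):
                fh.write(f"#param {key}={params_echo[key]}\n")
        for c in calls:
            gene = c.gene if c.gene else "."
            af = "NA" if c.allele_fraction != c.allele_fraction else \
                format(c.allele_fraction, ".17g")
            fh.write(
                f"{c.ref_name}\t{c.start}\t{c.end}\t{gene}|{c.dup_length}\t"
                f"{c.support_reads}\t.\t{af}\t{c.classification}\t"
                f"{c.contig_id}\t{c.junction_offset}\n"
            )


def read_calls_bed(path: str) -> list[ITDCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(BED_HEADER_PREFIX) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gene, dup_length = f[3].rsplit("|", 1)
            af = float("nan") if f[6] == "NA" else float(f[6])
            support = int(f[4])
            depth = 0 if af != af or af == 0 else int(round(support / af))
            calls.append(ITDCall(
                ref_name=f[0], start=int(f[1]), end=int(f[2]),
                dup_length=int(dup_length),
                classification=f[7],
                gene=None if gene == "." else gene,
                support_reads=support, depth=depth, allele_fraction=af,
                contig_id=f[8], junction_offset=int(f[9]),
            ))
    return calls


def read_targets_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Capture targets: (chrom, start, end, name) per 4+ column BED line."""
    targets = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            targets.append((f[0], int(f[1]), int(f[2]), name))
    return targets
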