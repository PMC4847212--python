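"""Greedy overlap-layout-consensus assembly of a bin's candidate reads.

Replaces an external OLC assembler with an internal greedy one: the
highest-scoring pairwise overlap (score = span x identity) is merged first,
layouts are tracked explicitly, and the consensus is a per-column majority
vote.  Quality values play no role.  All tie-breaking is total so that a
fixed input yields byte-identical contigs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from itdfinder.util import encode, revcomp

SAME = "same"
RC = "reverse-complement"


@dataclass(frozen=True)
class Overlap:
    read_a: str
    read_b: str
    orientation: str  # "same" | "reverse-complement"
    overhang: int  # offset of b's start on a
    length: int  # overlap span in bases
    identity: float


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    read_ids: frozenset
    bin_length: int
    # read_id -> (offset of the read on the contig, strand "+"/"-")
    layout: dict = field(default_factory=dict, compare=False)


def _match_counts(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    """Match counts between a and b at every shift.

    Returned index ``i`` corresponds to placing b's start at position
    ``s = i - (len(b) - 1)`` on a (verified against direct comparison in the
    test suite).  N bases (code 4) never match.
    """
    out = np.zeros(ea.size + eb.size - 1)
    for base in range(4):
        out += np.correlate(
            (ea == base).astype(np.float32),
            (eb == base).astype(np.float32),
            "full",
        )
    return out


def _span(m: int, n: int, s: int) -> int:
    return min(m, s + n) - max(0, s)


def _best_shift(ea, eb, min_overlap, min_identity, dovetail_only=False):
    """Best qualifying placement of b on a.

    Returns (score, span, shift, identity) or None.  With ``dovetail_only``
    the placement is restricted to suffix(a)/prefix(b) overlaps (b starts
    inside a and extends to or past a's end).
    """
    m, n = ea.size, eb.size
    counts = _match_counts(ea, eb)
    best = None
    for i in range(counts.size):
        s = i - (n - 1)
        span = _span(m, n, s)
        if span < min_overlap:
            continue
        if dovetail_only and not (0 <= s and s + n >= m):
            continue
        ident = counts[i] / span
        if ident < min_identity:
            continue
        key = (span * ident, span, -abs(s))
        if best is None or key > best[0]:
            best = (key, span, s, ident)
    if best is None:
        return None
    return (best[0][0], best[1], best[2], best[3])


def find_overlaps(reads, min_overlap: int = 15, min_identity: float = 0.95):
    """All maximal suffix-prefix overlaps between read pairs, both strands.

    ``reads`` maps read_id -> sequence.  For every qualifying overlap the
    mirrored entry (read_b, read_a) is also emitted.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0.8 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0.8, 1.0]")
    ids = sorted(reads)
    enc = {rid: encode(reads[rid]) for rid in ids}
    enc_rc = {rid: encode(revcomp(reads[rid])) for rid in ids}
    out: list[Overlap] = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            m, n = enc[a].size, enc[b].size
            for orient, eb in ((SAME, enc[b]), (RC, enc_rc[b])):
                hit = _best_shift(enc[a], eb, min_overlap, min_identity,
                                  dovetail_only=True)
                if hit is not None:
                    _, span, s, ident = hit
                    out.append(Overlap(a, b, orient, s, span, ident))
                    if orient == SAME:
                        out.append(Overlap(b, a, orient, -s, span, ident))
                    else:
                        out.append(Overlap(b, a, orient, n - span, span, ident))
                # suffix(b)/prefix(a) in same orientation is a distinct overlap
                if orient == SAME:
                    hit = _best_shift(eb, enc[a], min_overlap, min_identity,
                                      dovetail_only=True)
                    if hit is not None:
                        _, span, s, ident = hit
                        out.append(Overlap(b, a, SAME, s, span, ident))
                        out.append(Overlap(a, b, SAME, -s, span, ident))
    return out


def run_external_assembler(command: str, reads, bin_length: int = 0,
                           id_prefix: str = "contig"):
    """Adapter for an external OLC assembler.

    ``command`` is run with one argument (a FASTA of the reads) and must
    print assembled contigs as FASTA on stdout.  Constituent-read tracking
    is not available through this interface, so every contig is attributed
    to the full read set and has an empty layout.
    """
    import shlex
    import subprocess
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for rid in sorted(reads):
            fh.write(f">{rid}\n{reads[rid]}\n")
        fasta = fh.name
    try:
        proc = subprocess.run(
            shlex.split(command) + [fasta],
            check=True, capture_output=True, text=True,
        )
    finally:
        import os
        os.unlink(fasta)
    contigs = []
    name, chunks = None, []
    lines = proc.stdout.splitlines() + [">"]
    for line in lines:
        if line.startswith(">"):
            if name is not None and chunks:
                contigs.append(Contig(
                    contig_id=f"{id_prefix}{len(contigs)}",
                    sequence="".join(chunks),
                    read_ids=frozenset(reads),
                    bin_length=bin_length,
                ))
            name, chunks = line[1:], []
        else:
            chunks.append(line.strip())
    return contigs


class _Layout:
    """Mutable contig under construction: placed reads plus consensus."""

    __slots__ = ("reads", "consensus", "enc", "enc_rc")

    def __init__(self, reads):
        self.reads = reads  # list of (read_id, oriented_seq, offset)
        self._rebuild()

    def _rebuild(self):
        lo = min(off for _, _, off in self.reads)
        if lo:
            self.reads = [(rid, seq, off - lo) for rid, seq, off in self.reads]
        length = max(off + len(seq) for _, seq, off in self.reads)
        counts = np.zeros((length, 4), dtype=np.int32)
        for _, seq, off in self.reads:
            codes = encode(seq)
            valid = codes < 4
            idx = np.flatnonzero(valid)
            counts[off + idx, codes[idx]] += 1
        best = counts.max(axis=1)
        argbest = counts.argmax(axis=1)
        cons = np.full(length, 4, dtype=np.uint8)
        covered = best > 0
        cons[covered] = argbest[covered]
        # tie columns: take the base of the lexicographically smallest read
        ties = covered & ((counts == best[:, None]).sum(axis=1) > 1)
        if ties.any():
            order = sorted(self.reads, key=lambda t: t[0])
            tie_cols = set(np.flatnonzero(ties).tolist())
            for col in sorted(tie_cols):
                tied = set(np.flatnonzero(counts[col] == best[col]).tolist())
                for rid, seq, off in order:
                    if off <= col < off + len(seq):
                        code = int(encode(seq[col - off])[0])
                        if code in tied:
                            cons[col] = code
                            break
        self.consensus = "".join("ACGTN"[c] for c in cons)
        self.enc = encode(self.consensus)
        self.enc_rc = encode(revcomp(self.consensus))

    @property
    def min_read_id(self):
        return min(rid for rid, _, _ in self.reads)


def _merge(a: _Layout, b: _Layout, shift: int, orientation: str) -> _Layout:
    placed = list(a.reads)
    blen = len(b.consensus)
    for rid, seq, off in b.reads:
        if orientation == RC:
            placed.append((rid, revcomp(seq), shift + blen - (off + len(seq))))
        else:
            placed.append((rid, seq, shift + off))
    return _Layout(placed)


def greedy_assemble(reads, min_overlap: int = 15, min_identity: float = 0.95,
                    bin_length: int = 0, id_prefix: str = "contig"):
    """Assemble ``reads`` (mapping read_id -> sequence) into contigs.

    Highest score = span x identity merges first; ties resolve by longer
    span, then by smallest participating read ids.  Every read ends up in
    exactly one contig; reads with no qualifying overlap become singletons.
    """
    if not reads:
        return []
    # identical sequences collapse into one seed layout (weighted consensus)
    by_seq: dict[str, list[str]] = {}
    for rid in sorted(reads):
        by_seq.setdefault(reads[rid], []).append(rid)
    layouts: dict[int, _Layout] = {}
    version: dict[int, int] = {}
    for i, (seq, ids) in enumerate(
        sorted(by_seq.items(), key=lambda kv: kv[1][0])
    ):
        layouts[i] = _Layout([(rid, seq, 0) for rid in ids])
        version[i] = 0
    next_id = len(layouts)

    def candidate(u: int, v: int):
        """Best merge of layouts u and v as a heap entry, or None."""
        a, b = layouts[u], layouts[v]
        best = None
        for orient, eb in ((SAME, b.enc), (RC, b.enc_rc)):
            hit = _best_shift(a.enc, eb, min_overlap, min_identity)
            if hit is not None:
                score, span, s, _ = hit
                key = (-score, -span, a.min_read_id, b.min_read_id,
                       0 if orient == SAME else 1)
                entry = (key, u, v, s, orient, version[u], version[v])
                if best is None or key < best[0]:
                    best = entry
        return best

    heap = []
    live = sorted(layouts)
    for i in range(len(live)):
        for j in range(i + 1, len(live)):
            entry = candidate(live[i], live[j])
            if entry is not None:
                heapq.heappush(heap, entry)

    while heap:
        key, u, v, s, orient, vu, vv = heapq.heappop(heap)
        if u not in layouts or v not in layouts:
            continue
        if version[u] != vu or version[v] != vv:
            continue
        merged = _merge(layouts[u], layouts[v], s, orient)
        del layouts[u], layouts[v]
        w = next_id
        next_id += 1
        layouts[w] = merged
        version[w] = 0
        for other in sorted(layouts):
            if other == w:
                continue
            entry = candidate(w, other)
            if entry is not None:
                heapq.heappush(heap, entry)

    contigs = []
    ordered = sorted(layouts.values(), key=lambda la: la.min_read_id)
    for idx, layout in enumerate(ordered):
        layout_map = {}
        for rid, seq, off in layout.reads:
            strand = "+"
            # a read stored reverse-complemented relative to its input
            if reads[rid] != seq and revcomp(reads[rid]) == seq:
                strand = "-"
            layout_map[rid] = (off, strand)
        contigs.append(
            Contig(
                contig_id=f"{id_prefix}{idx}",
                sequence=layout.consensus,
                read_ids=frozenset(rid for rid, _, _ in layout.reads),
                bin_length=bin_length,
                layout=layout_map,
            )
        )
    return contigs
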