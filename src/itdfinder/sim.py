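"""Synthetic references, implanted tandem-duplication alleles and read sets.

The simulator is a deterministic surrogate for an exome-like experiment: it
samples fixed-length single-end reads from a mixture of the reference allele
and one or more duplication-carrying alleles, applies substitution errors,
and emits each read as mapped, soft-clipped or unmapped depending on how far
it reaches past a duplication junction.  This reproduces the aligner failure
mode that the downstream pipeline mines for, without invoking an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from itdfinder.util import max_homopolymer_run, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: a read reaching at least this many bases past a junction is unmapped;
#: shorter overhangs are emitted as soft clips
CROSS_MARGIN = 4


@dataclass(frozen=True)
class TruthITD:
    """Ground-truth record for one implanted tandem duplication."""

    ref_name: str
    start: int  # 0-based offset of the first duplicated base
    dup_length: int
    allele_fraction: float

    def validate(self, ref_length: int) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.dup_length < 1:
            raise ValueError("dup_length must be >= 1")
        if self.start + self.dup_length > ref_length:
            raise ValueError("duplication extends past the reference end")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    ref_length: int
    read_length: int
    coverage: float
    error_rate: float
    seed: int
    itds: tuple[TruthITD, ...] = ()
    ref_name: str = "chrS"

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")
        object.__setattr__(self, "itds", tuple(self.itds))
        if sum(t.allele_fraction for t in self.itds) > 1.0 + 1e-9:
            raise ValueError("allele fractions sum to more than 1")


@dataclass(frozen=True)
class SimRead:
    """One simulated read plus its provenance (for truth-based tests)."""

    read_id: str
    sequence: str  # as sequenced (reverse-complemented for '-' unmapped reads)
    status: str  # mapped | softclip | unmapped
    ref_name: str
    ref_start: int | None  # 0-based leftmost mapped base, None when unmapped
    cigar: str | None
    allele: int  # -1 = reference allele, otherwise index into cfg.itds
    allele_start: int  # 0-based start on the source allele
    strand: str


def make_reference(length: int, seed: int) -> str:
    """Random reference sequence with no homopolymer run of 15 or more.

    Runs of >= 15 are resampled so that fixture reads can never be lost to
    the homopolymer filter by accident.  Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    arr = rng.choice(_BASES, size=length)
    seq = arr.tobytes().decode("ascii")
    while max_homopolymer_run(seq) >= 15:
        # break every offending run by resampling its interior
        out = list(seq)
        i = 0
        while i < length:
            j = i
            while j < length and out[j] == out[i]:
                j += 1
            if j - i >= 15:
                for p in range(i + 1, j, 2):
                    choices = [b for b in "ACGT" if b != out[i]]
                    out[p] = choices[int(rng.integers(3))]
            i = j
        seq = "".join(out)
    return seq


def implant_itd(reference: str, start: int, dup_length: int) -> str:
    """Duplicate ``reference[start:start+dup_length]`` in tandem after itself."""
    if start < 0 or dup_length < 0 or start + dup_length > len(reference):
        raise ValueError("duplication coordinates out of range")
    end = start + dup_length
    return reference[:end] + reference[start:end] + reference[end:]


def _classify_span(p: int, read_len: int, junctions: tuple[int, ...]):
    """Decide mapped/softclip/unmapped for a read at [p, p+read_len).

    Returns (status, junction, overhang_side, overhang) where junction is the
    allele coordinate of the touched junction for soft clips.
    """
    touch = None
    for j in junctions:
        if p < j < p + read_len:
            over = min(j - p, p + read_len - j)
            if over >= CROSS_MARGIN:
                return ("unmapped", None, None, 0)
            if touch is None:
                side = "tail" if (p + read_len - j) <= (j - p) else "head"
                touch = (j, side, over)
    if touch is not None:
        return ("softclip", touch[0], touch[1], touch[2])
    return ("mapped", None, None, 0)


def simulate_reads(cfg: SimConfig) -> tuple[list[SimRead], list[TruthITD]]:
    """Sample reads from the allele mixture; deterministic for a fixed seed."""
    reference = make_reference(cfg.ref_length, cfg.seed)
    for t in cfg.itds:
        t.validate(cfg.ref_length)
    alleles: list[str] = [reference]
    for t in cfg.itds:
        alleles.append(implant_itd(reference, t.start, t.dup_length))
    weights = [max(0.0, 1.0 - sum(t.allele_fraction for t in cfg.itds))]
    weights += [t.allele_fraction for t in cfg.itds]

    rng = np.random.default_rng(cfg.seed)
    n_reads = int(round(cfg.coverage * cfg.ref_length / cfg.read_length))
    reads: list[SimRead] = []
    cum = np.cumsum(weights)
    for idx in range(n_reads):
        u = rng.random()
        allele_idx = int(np.searchsorted(cum, u, side="right"))
        allele_idx = min(allele_idx, len(alleles) - 1)
        allele = alleles[allele_idx]
        p = int(rng.integers(0, len(allele) - cfg.read_length + 1))
        frag = allele[p : p + cfg.read_length]
        if cfg.error_rate > 0:
            frag = _mutate(frag, cfg.error_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"

        if allele_idx == 0:
            status, junction, side, over = "mapped", None, None, 0
        else:
            t = cfg.itds[allele_idx - 1]
            j_a = t.start + t.dup_length
            j_b = t.start + 2 * t.dup_length
            status, junction, side, over = _classify_span(
                p, cfg.read_length, (j_a, j_b)
            )
            dup = t.dup_length

        rid = f"sim{idx:06d}"
        if status == "mapped":
            if allele_idx == 0:
                ref_start = p
            else:
                ref_start = p if p + cfg.read_length <= j_a else p - dup
            reads.append(
                SimRead(rid, frag, "mapped", cfg.ref_name, ref_start,
                        f"{cfg.read_length}M", allele_idx - 1, p, strand)
            )
        elif status == "softclip":
            m = cfg.read_length - over
            if side == "tail":
                cigar = f"{m}M{over}S"
                ref_start = p if p + m <= j_a else p - dup
            else:
                cigar = f"{over}S{m}M"
                ref_start = junction if junction <= j_a else junction - dup
            reads.append(
                SimRead(rid, frag, "softclip", cfg.ref_name, ref_start,
                        cigar, allele_idx - 1, p, strand)
            )
        else:
            seq = frag if strand == "+" else revcomp(frag)
            reads.append(
                SimRead(rid, seq, "unmapped", cfg.ref_name, None, None,
                        allele_idx - 1, p, strand)
            )
    return reads, list(cfg.itds)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for h in hits:
        alts = [b for b in b"ACGT" if b != arr[h]]
        arr[h] = alts[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# writers

def write_fasta(path: str, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, reads: list[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_sam(path: str, reads: list[SimRead], ref_name: str, ref_length: int) -> None:
    """Coordinate-sorted SAM with unmapped records (flag 0x4) at the end."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_length}],
    }
    mapped = sorted(
        (r for r in reads if r.status != "unmapped"),
        key=lambda r: (r.ref_start, r.read_id),
    )
    unmapped = [r for r in reads if r.status == "unmapped"]
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in mapped:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 0  # SEQ is stored as the forward-strand projection
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            out.write(a)
        for r in unmapped:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 4
            a.reference_id = -1
            a.reference_start = -1
            a.mapping_quality = 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            out.write(a)


def write_truth_bed(path: str, itds: list[TruthITD]) -> None:
    """Truth intervals: chrom, start, end, name, score=dup_length, allele_fraction."""
    with open(path, "w") as fh:
        for t in itds:
            fh.write(
                f"{t.ref_name}\t{t.start}\t{t.start + t.dup_length}\tITD\t"
                f"{t.dup_length}\t{t.allele_fraction}\n"
            )
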