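"""Read-level filters, kmer repeat-distance annotation and binning.

A read carries a duplication signature when some kmer occurs at two
positions a fixed distance apart; the distance equals the duplication
length, so reads sharing a distance are clustered into the same bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from itdfinder.read_io import CandidateRead
from itdfinder.util import kmer_positions, max_homopolymer_run


@dataclass
class Params:
    """Pipeline parameters.

    ``d_kmer`` (De Bruijn kmer size) defaults to ``p_kmer`` and may not be
    smaller.  ``r_min``/``r_max`` bound the duplication lengths for which
    bins are created; detection is impossible outside [r_min, r_max] and
    above read_length - p_kmer.
    """

    p_kmer: int = 10
    d_kmer: int | None = None
    r_min: int = 15
    r_max: int = 61
    cov_cutoff_min: int = 2
    cov_cutoff_max: int = 500
    max_n: int = 50
    max_homopolymer: int = 14
    light_mode: bool = False

    def __post_init__(self) -> None:
        if self.d_kmer is None:
            self.d_kmer = self.p_kmer
        self.validate()

    def validate(self) -> None:
        if self.p_kmer < 1:
            raise ValueError("p_kmer must be >= 1")
        if self.d_kmer < self.p_kmer:
            raise ValueError("d_kmer cannot be less than p_kmer")
        if self.r_min < self.p_kmer:
            raise ValueError("r_min must be >= p_kmer")
        if self.r_max < self.r_min:
            raise ValueError("r_max must be >= r_min")
        if self.cov_cutoff_min > self.cov_cutoff_max:
            raise ValueError("cov_cutoff_min must be <= cov_cutoff_max")

    @classmethod
    def flt3_preset(cls) -> "Params":
        """Parameter set used for targeted FLT3-style reruns."""
        return cls(p_kmer=15, d_kmer=15, r_min=15, r_max=85,
                   cov_cutoff_min=30, cov_cutoff_max=200)


@dataclass(frozen=True)
class RepeatSignature:
    read_id: str
    distances: frozenset[int]


@dataclass
class Bin:
    length: int
    reads: set = field(default_factory=set)


def count_base(seq: str, base: str) -> int:
    """Occurrence count of ``base`` in ``seq``."""
    return seq.count(base)


def filter_n(reads, max_n: int = 50):
    """Keep reads with at most ``max_n`` ambiguous 'N' bases."""
    return {r for r in reads if count_base(r.sequence, "N") <= max_n}


def filter_homopolymer(reads, max_run: int = 14):
    """Keep reads whose longest single-base run is at most ``max_run``."""
    return {r for r in reads if max_homopolymer_run(r.sequence) <= max_run}


def repeat_distances(seq: str, k: int) -> set[int]:
    """Distances between consecutive occurrences of repeated k-mers.

    Empty iff all kmers of ``seq`` are distinct, i.e. the kmer spectrum has
    the maximal size |S| - k + 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    out: set[int] = set()
    for positions in kmer_positions(seq, k).values():
        for a, b in zip(positions, positions[1:]):
            out.add(b - a)
    return out


def _occurrences(seq: str, pattern: str) -> list[int]:
    """All (possibly overlapping) occurrence positions of pattern in seq."""
    hits = []
    i = seq.find(pattern)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + 1)
    return hits


def read_signature(read: CandidateRead, params: Params) -> RepeatSignature:
    """Repeat-distance set for one candidate.

    Unmapped reads use the full kmer spectrum at ``p_kmer``; soft-clipped
    reads search for further occurrences of the clipped segment only, i.e.
    the effective kmer length is the clip length.
    """
    if read.origin == "softclip":
        positions = _occurrences(read.sequence, read.clip_segment)
        dists = {b - a for a, b in zip(positions, positions[1:])}
    else:
        dists = repeat_distances(read.sequence, params.p_kmer)
    return RepeatSignature(read.read_id, frozenset(dists))


def bin_reads(reads, params: Params) -> dict[int, Bin]:
    """Cluster reads into bins keyed by repeat distance.

    A read with several distances in [r_min, r_max] joins every matching
    bin; reads with no in-range distance are dropped from the pipeline.
    """
    params.validate()
    bins: dict[int, Bin] = {}
    for read in sorted(reads, key=lambda r: r.read_id):
        sig = read_signature(read, params)
        for d in sig.distances:
            if params.r_min <= d <= params.r_max:
                bins.setdefault(d, Bin(d)).reads.add(read)
    return bins
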