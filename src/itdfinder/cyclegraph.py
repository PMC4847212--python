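"""Per-bin De Bruijn graphs and closed-walk detection via boolean matrix powers.

A tandem duplication of length ``i`` induces a cycle of length ``i`` in the
bin's De Bruijn graph.  Vertices with a closed walk of length exactly ``i``
through them are read off the diagonal of the i-th boolean power of the
adjacency matrix, computed by exponentiation-by-squaring (O(log i) products).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from itdfinder.signature import Bin, Params


@dataclass
class DeBruijnGraph:
    k: int
    vertices: dict[str, int]  # kmer -> vertex index
    coverage: np.ndarray  # per-vertex occurrence count across the bin
    adjacency: np.ndarray  # boolean matrix; (u, v) iff u->v observed in a read

    @property
    def n(self) -> int:
        return len(self.vertices)


def build_graph(bin_: Bin, params: Params) -> DeBruijnGraph:
    """De Bruijn graph of a bin at kmer size d_kmer with coverage cutoffs.

    Vertex coverage is the total occurrence count of the kmer across all
    reads (a kmer occurring twice in one read counts twice).  Only vertices
    with coverage in [cov_cutoff_min, cov_cutoff_max] are kept; edges join
    surviving vertices observed consecutively in a read.  Kmers containing
    'N' are excluded.
    """
    k = params.d_kmer
    counts: dict[str, int] = {}
    seqs = sorted(r.sequence for r in bin_.reads)
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" not in km:
                counts[km] = counts.get(km, 0) + 1
    kept = sorted(
        km for km, c in counts.items()
        if params.cov_cutoff_min <= c <= params.cov_cutoff_max
    )
    vertices = {km: i for i, km in enumerate(kept)}
    coverage = np.array([counts[km] for km in kept], dtype=np.int64)
    n = len(kept)
    adj = np.zeros((n, n), dtype=bool)
    for seq in seqs:
        prev = None
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            cur = vertices.get(km)
            if prev is not None and cur is not None:
                adj[prev, cur] = True
            prev = cur
    return DeBruijnGraph(k, vertices, coverage, adj)


def _bool_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a.astype(np.uint8) @ b.astype(np.uint8)) > 0


def boolean_matrix_power(adj: np.ndarray, i: int) -> np.ndarray:
    """i-th power of a boolean adjacency matrix over the boolean semiring."""
    if i < 1:
        raise ValueError("power must be >= 1")
    result: np.ndarray | None = None
    base = adj.copy()
    e = i
    while e:
        if e & 1:
            result = base.copy() if result is None else _bool_matmul(result, base)
        e >>= 1
        if e:
            base = _bool_matmul(base, base)
    return result


def closed_walk_vertices(graph: DeBruijnGraph, i: int) -> set[str]:
    """Kmers lying on a closed walk of length exactly ``i``."""
    if i < 1:
        raise ValueError("walk length must be >= 1")
    if graph.n == 0:
        return set()
    power = boolean_matrix_power(graph.adjacency, i)
    diag = np.diagonal(power)
    inv = {idx: km for km, idx in graph.vertices.items()}
    return {inv[int(v)] for v in np.flatnonzero(diag)}


def filter_reads_by_cycle(bin_: Bin, cycle_kmers: set[str], k: int | None = None):
    """Keep reads containing at least one kmer participating in an i-cycle."""
    if not cycle_kmers:
        return set()
    if k is None:
        k = len(next(iter(cycle_kmers)))
    kept = set()
    for read in bin_.reads:
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in cycle_kmers:
                kept.add(read)
                break
    return kept
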