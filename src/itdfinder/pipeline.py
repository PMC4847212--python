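"""End-to-end orchestration: extract -> filter/bin -> cycle-filter ->
assemble -> annotate, with per-stage accounting and optional per-bin
parallelism.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

from itdfinder import annotate as ann
from itdfinder import cyclegraph, read_io, signature
from itdfinder.assemble import Contig, greedy_assemble
from itdfinder.signature import Bin, Params


@dataclass(frozen=True)
class _ReadLite:
    """Picklable stand-in for a candidate read inside bin workers."""

    read_id: str
    sequence: str


@dataclass
class RunReport:
    extracted: int = 0
    after_n: int = 0
    after_homopolymer: int = 0
    binned_reads: int = 0
    n_bins: int = 0
    per_bin: dict = field(default_factory=dict)
    n_contigs: int = 0
    n_calls: int = 0
    params: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def check_serial_reduction(self) -> bool:
        return (self.extracted >= self.after_n >= self.after_homopolymer
                >= self.binned_reads)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_reference(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return {k: str(v).upper() for k, v in reference.items()}
    refs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(reference) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    refs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        refs[name] = "".join(chunks).upper()
    return refs


def _process_bin(payload):
    """Cycle-filter and assemble one bin.  Top level for multiprocessing."""
    bin_length, read_tuples, params, min_overlap, min_identity, assembler = payload
    reads = {rid: seq for rid, seq in read_tuples}
    stats = {"reads": len(reads), "after_cycle": len(reads), "contigs": 0}
    if not params.light_mode:
        bin_ = Bin(bin_length, {_ReadLite(r, s) for r, s in read_tuples})
        graph = cyclegraph.build_graph(bin_, params)
        cycle_kmers = cyclegraph.closed_walk_vertices(graph, bin_length)
        kept = cyclegraph.filter_reads_by_cycle(bin_, cycle_kmers, params.d_kmer)
        reads = {r.read_id: r.sequence for r in kept}
        stats["after_cycle"] = len(reads)
        if not reads:
            return bin_length, [], stats
    if assembler.startswith("external:"):
        from itdfinder.assemble import run_external_assembler

        contigs = run_external_assembler(
            assembler.split(":", 1)[1], reads, bin_length=bin_length,
            id_prefix=f"bin{bin_length}c",
        )
    else:
        contigs = greedy_assemble(
            reads, min_overlap=min_overlap, min_identity=min_identity,
            bin_length=bin_length, id_prefix=f"bin{bin_length}c",
        )
    stats["contigs"] = len(contigs)
    return bin_length, contigs, stats


def run_bins_parallel(payloads, workers: int = 1):
    """Process bins, optionally across worker processes; order-stable."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if workers == 1 or len(payloads) <= 1:
        return [_process_bin(p) for p in payloads]
    import multiprocessing

    with multiprocessing.Pool(workers) as pool:
        return pool.map(_process_bin, payloads)


def _calls_from_contig(contig: Contig, refs, params: Params, targets,
                       read_lengths, max_rounds: int = 3):
    calls = []
    seq = contig.sequence
    removed: list[tuple[int, int]] = []  # (collapse position, removed length)
    for _ in range(max_rounds):
        pairs = ann.candidate_kmer_pairs(seq, params.d_kmer,
                                         params.r_min, params.r_max)
        found = None
        for p1, p2 in pairs:
            collapsed = ann.collapse_duplication(seq, p1, p2)
            hit = ann.align_collapsed(collapsed, refs)
            if hit is not None:
                found = (p1, p2, collapsed, hit)
                break
        if found is None:
            break
        p1, p2, collapsed, hit = found
        dup = p2 - p1
        cls, start, end, gene = ann.classify_call(hit, p1, dup, targets)
        ref_seq = refs.get(hit.ref_name)
        if ref_seq and 0 <= start < end <= len(ref_seq):
            start = ann.refine_duplication_locus(ref_seq, seq, start, dup)
            start, end = ann.left_align(ref_seq, start, start + dup)
        junction = p2
        for pos, rem in reversed(removed):
            if junction >= pos:
                junction += rem
        support = ann.count_junction_support(contig, junction, read_lengths)
        calls.append({
            "ref_name": hit.ref_name, "start": start, "end": end,
            "dup_length": dup, "classification": cls, "gene": gene,
            "support": support, "contig_id": contig.contig_id,
            "junction_offset": junction,
        })
        removed.append((p1, p2 - p1))
        seq = collapsed
    return calls


def run(alignment, reference, targets=None, params: Params | None = None,
        min_overlap: int = 15, min_identity: float = 0.95,
        workers: int = 1, min_clip: int = 4, assembler: str = "internal",
        dump_contigs: str | None = None):
    """Execute the full pipeline.

    Returns (list of ITDCall, RunReport).  ``alignment`` is a SAM/BAM path,
    ``reference`` a FASTA path or dict, ``targets`` a capture BED path or a
    list of (chrom, start, end, name) tuples (None disables target
    classification).  Deterministic for fixed inputs and parameters.
    """
    params = params or Params()
    params.validate()
    refs = _load_reference(reference)
    if isinstance(targets, (str, bytes)):
        targets = ann.read_targets_bed(targets)
    report = RunReport(params=dataclasses.asdict(params))
    t0 = time.perf_counter()

    candidates = read_io.extract_candidates(alignment, min_clip=min_clip)
    report.extracted = len(candidates)
    report.timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    kept = signature.filter_n(candidates, params.max_n)
    report.after_n = len(kept)
    kept = signature.filter_homopolymer(kept, params.max_homopolymer)
    report.after_homopolymer = len(kept)

    # the repeat distance cannot exceed read_length - p_kmer
    eff = params
    if kept:
        max_len = max(len(r.sequence) for r in kept)
        r_max_eff = min(params.r_max, max_len - params.p_kmer)
        if r_max_eff < params.r_max:
            eff = dataclasses.replace(params, r_max=max(params.r_min, r_max_eff))
    bins = signature.bin_reads(kept, eff)
    binned_ids = {r.read_id for b in bins.values() for r in b.reads}
    report.binned_reads = len(binned_ids)
    report.n_bins = len(bins)
    report.timings["filter_bin"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    payloads = [
        (length, sorted((r.read_id, r.sequence) for r in bins[length].reads),
         eff, min_overlap, min_identity, assembler)
        for length in sorted(bins)
    ]
    results = run_bins_parallel(payloads, workers=workers)
    report.timings["assemble"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    read_lengths = {r.read_id: len(r.sequence) for r in candidates}
    origin = {r.read_id: r.origin for r in candidates}
    all_contigs: list[Contig] = []
    raw_calls = []
    for bin_length, contigs, stats in results:
        report.per_bin[bin_length] = stats
        all_contigs.extend(contigs)
        for contig in contigs:
            raw_calls.extend(
                _calls_from_contig(contig, refs, eff, targets, read_lengths)
            )
    report.n_contigs = len(all_contigs)
    if dump_contigs:
        import os

        os.makedirs(dump_contigs, exist_ok=True)
        by_bin: dict[int, list[Contig]] = {}
        for c in all_contigs:
            by_bin.setdefault(c.bin_length, []).append(c)
        for length, cs in sorted(by_bin.items()):
            with open(os.path.join(dump_contigs, f"bin{length}.fa"), "w") as fh:
                for c in cs:
                    fh.write(f">{c.contig_id}\n{c.sequence}\n")

    contig_by_id = {c.contig_id: c for c in all_contigs}
    calls = []
    for raw in raw_calls:
        if raw["classification"] == ann.OFF_TARGET:
            continue
        support = raw["support"]
        contig = contig_by_id[raw["contig_id"]]
        unmapped_support = sum(
            1 for rid in contig.layout
            if origin.get(rid) == "unmapped"
            and contig.layout[rid][0] <= raw["junction_offset"] - ann.JUNCTION_FLANK
            and contig.layout[rid][0] + read_lengths.get(rid, 0)
            >= raw["junction_offset"] + ann.JUNCTION_FLANK + 1
        )
        ref_len = len(refs.get(raw["ref_name"], ""))
        locus = min(max(raw["end"], 0), max(ref_len - 1, 0))
        try:
            mapped_depth = read_io.spanning_depth(
                alignment, (raw["ref_name"], locus), flank=ann.JUNCTION_FLANK)
        except ValueError:
            mapped_depth = 0
        depth = max(mapped_depth + unmapped_support, support)
        try:
            af = ann.allele_fraction(support, depth)
        except ann.UndefinedAlleleFraction:
            af = float("nan")
        calls.append(ann.ITDCall(
            ref_name=raw["ref_name"], start=raw["start"], end=raw["end"],
            dup_length=raw["dup_length"],
            classification=raw["classification"], gene=raw["gene"],
            support_reads=support, depth=depth, allele_fraction=af,
            contig_id=raw["contig_id"],
            junction_offset=raw["junction_offset"],
        ))
    calls = ann.merge_calls(calls)
    report.n_calls = len(calls)
    report.timings["annotate"] = time.perf_counter() - t0
    return calls, report
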