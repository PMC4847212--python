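"""Shared fixtures: hand-built SAM files and simulated pipeline inputs."""

from __future__ import annotations

import pysam
import pytest

from itdfinder import sim
from itdfinder.annotate import left_align
from itdfinder.signature import Params
from itdfinder import pipeline

REF_NAME = "chrS"


def build_sam(path, records, ref_name=REF_NAME, ref_length=2000):
    """Write a SAM file from dicts: name, seq, flag, pos (0-based), cigar."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": ref_name, "LN": ref_length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["name"]
            a.query_sequence = rec["seq"]
            a.flag = rec.get("flag", 0)
            if a.flag & 0x4:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = 0
                a.reference_start = rec["pos"]
                a.cigarstring = rec.get("cigar", f"{len(rec['seq'])}M")
                a.mapping_quality = rec.get("mapq", 60)
            out.write(a)
    return str(path)


@pytest.fixture
def sam_builder(tmp_path):
    def _build(records, name="test.sam", **kw):
        return build_sam(tmp_path / name, records, **kw)

    return _build


def simulate_to_files(tmp_path, *, ref_length=1500, read_length=75,
                      coverage=100.0, error_rate=0.0, seed=11, itds=()):
    """Run the simulator and write reference FASTA + SAM; returns paths etc."""
    cfg = sim.SimConfig(ref_length=ref_length, read_length=read_length,
                        coverage=coverage, error_rate=error_rate, seed=seed,
                        itds=tuple(itds), ref_name=REF_NAME)
    reads, truth = sim.simulate_reads(cfg)
    reference = sim.make_reference(ref_length, seed)
    fa = tmp_path / f"ref{seed}.fa"
    samf = tmp_path / f"reads{seed}.sam"
    sim.write_fasta(str(fa), REF_NAME, reference)
    sim.write_sam(str(samf), reads, REF_NAME, ref_length)
    return {"cfg": cfg, "reads": reads, "truth": truth,
            "reference": reference, "fasta": str(fa), "sam": str(samf)}


def run_itd_sim(tmp_path, *, dup_start=700, dup_length=30, allele_fraction=1.0,
                seed=11, read_length=75, coverage=100.0, error_rate=0.0,
                ref_length=1500, params=None, **run_kw):
    """Simulate one implanted duplication and run the pipeline on it.

    Returns (calls, report, truth_locus) with the truth locus left-aligned
    the same way the pipeline normalizes its calls.
    """
    itd = sim.TruthITD(REF_NAME, dup_start, dup_length, allele_fraction)
    data = simulate_to_files(
        tmp_path, ref_length=ref_length, read_length=read_length,
        coverage=coverage, error_rate=error_rate, seed=seed, itds=(itd,),
    )
    targets = [(REF_NAME, max(0, dup_start - 150),
                min(ref_length, dup_start + dup_length + 150), "GENE1")]
    calls, report = pipeline.run(
        data["sam"], data["fasta"], targets=targets,
        params=params or Params(), **run_kw,
    )
    ts, te = left_align(data["reference"], dup_start, dup_start + dup_length)
    return calls, report, (ts, te, dup_length), data
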