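# itdfinder

Detection of internal tandem duplications (ITDs) from short-read sequencing
data. Reads that span a tandem-duplication junction typically fail to align
(unmapped) or align only partially (soft-clipped); `itdfinder` mines exactly
those reads:

1. **extract** — collect unmapped reads and soft-clipped reads with clips
   ≥ 4 bp from a SAM/BAM file (`read_io`);
2. **filter & bin** — discard reads with > 50 ambiguous bases or
   homopolymer runs ≥ 15; annotate the remainder with repeat distances
   between duplicated kmers (kmer size `p_kmer`) and cluster them into one
   bin per distance (`signature`);
3. **cycle filter** — per bin, build a De Bruijn graph (kmer size `d_kmer`,
   vertex-coverage cutoffs) and keep only reads containing kmers that lie
   on a closed walk whose length equals the bin's repeat distance, detected
   from the diagonal of the boolean i-th power of the adjacency matrix
   (`cyclegraph`); `--light` skips this stage entirely;
4. **assemble** — greedy overlap-layout-consensus assembly of each bin's
   surviving reads, quality-agnostic, with majority-vote consensus
   (`assemble`);
5. **annotate** — find the duplicated kmer pair in each contig, collapse one
   copy, align the collapsed contig to the reference with a local
   affine-gap aligner, require high identity/coverage and a specificity
   margin over the second-best locus, classify against capture targets,
   and report junction support and allele fraction (`annotate`).

A duplication of length L is detectable when
`r_min ≤ L ≤ min(r_max, read_length − p_kmer)`.

The package also ships a deterministic read simulator (`sim`) that implants
tandem duplications into synthetic references and emulates the aligner
failure mode (junction-crossing reads emitted unmapped, near-junction reads
soft-clipped), writing FASTA/FASTQ/SAM plus a BED truth file.

## CLI

Simulate a data set, then call ITDs on it:

```sh
cat > sim.json <<'EOF'
{"ref_length": 5000, "read_length": 75, "coverage": 100, "error_rate": 0.01,
 "seed": 7, "itds": [{"start": 2500, "dup_length": 30, "allele_fraction": 0.5}]}
EOF
itd simulate --config sim.json --out simdata

printf 'chrS\t2300\t2700\tGENE1\n' > targets.bed
itd run --bam simdata.sam --ref simdata.fa --targets targets.bed --out calls
```

`itd run` writes `calls.bed` (BED6+4: chrom, start, end, gene|dup_length,
support, strand, allele_fraction, classification, contig_id,
junction_offset) and `calls.report.json` (per-stage read counts, parameter
echo, timings). Key options: `--p-kmer` (10), `--d-kmer` (= p-kmer),
`--r-min`/`--r-max` (15/61), `--cov-min`/`--cov-max` (2/500), `--min-clip`
(4), `--light`, `--workers N`, `--preset flt3`
(p_kmer = d_kmer = 15, cov 30–200, r 15–85), `--assembler external:<cmd>`,
`--dump-contigs DIR`.

RNA-based validation of calls (≥ 10 aligned reads per contig, identity
> 97 %, junction-crossing):

```sh
itd run --bam simdata.sam --ref simdata.fa --targets targets.bed \
        --out calls --dump-contigs contigs
cat contigs/*.fa > contigs.fa
itd validate-rna --calls calls.bed --contigs contigs.fa --rna rna.fastq
```

## Library use

```python
from itdfinder import Params, run

calls, report = run("sample.bam", "ref.fa", targets="targets.bed",
                    params=Params(p_kmer=10, r_min=15, r_max=61))
for call in calls:
    print(call.ref_name, call.start, call.end, call.dup_length,
          call.allele_fraction)
```
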