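# aavjunct

Detection of adeno-associated virus (AAV) vector integration junctions in a
host genome, from long-read and short-read sequencing, with a built-in
simulator of planted integrations.

AAV vectors mostly persist as episomes, but a minority integrate into host
chromosomes through cellular DNA-repair pathways — an important safety
consideration for gene therapy. An integration junction is visible in
sequencing data as a *chimeric* read: one that aligns partly to the vector
genome and partly to a host chromosome. `aavjunct` implements both of the
complementary calling strategies used for this problem:

- **Long-read mode** (kilobase reads, e.g. Cas9-enriched nanopore
  libraries): split alignments of each read are turned into breakend
  adjacencies; adjacencies joining the vector to a host chromosome are
  clustered by single linkage per `(chrom, side)` (default tolerance 25 nt),
  each cluster becoming an integration event with its distinct supporting
  read names. The event with the most supporting reads is the clone's
  *baseline integration site*. Reads with several vector segments also
  yield a per-read reconstruction of the integrated vector structure
  (internal deletions, head-to-tail concatemers, inversions, junction
  indels).
- **Short-read mode** (~250 bp fragments, e.g. hybridization-capture
  Illumina libraries): per read, adjacent (host, vector) alignment-block
  pairs are extracted; each block carries a match score
  `matches / aligned_span`, and a pair is kept only when *both* segments
  have strictly more than 35 matched nt and a score ≥ 0.9, and the two
  blocks abut on the read within a 20 nt window. The junction coordinate is
  the host block's reference boundary adjacent to the vector segment
  (orientation-dependent, reported 1-based), and supporting reads are
  aggregated per unique `(chrom, pos, side)`.

Alignment blocks come from three sources: an internal desk-scale
seed-and-extend split aligner (exact k-mer seeds, diagonal chaining,
edit-style extension), SAM/BAM records (via pysam), or BLAT PSL files. A
hybrid reference — host assembly plus vector sequence in one FASTA — makes
chimeras visible to a single aligner pass. The `simulate` module generates
hosts, ITR-flanked vectors, clones with planted (possibly rearranged)
integrations, and reads with per-read truth, so every stage is testable at
desk scale.

## Worked example

```bash
# simulate a clone: 200 kb host, full-length 2928 nt vector planted at chr1:100000,
# and a capture-style short-read library over it
aavjunct simulate --mode short --seed 5 --n-reads 2000 \
    --host-lengths 120000,80000 --insert-pos 100000 --sub-rate 0 \
    --out-prefix sim

# call junctions from the R1/R2 FASTQ against the hybrid reference
aavjunct call-short --r1 sim.R1.fastq --r2 sim.R2.fastq \
    --host sim.host.fasta --vector sim.vector.fasta --out-prefix called
```

which prints

```
2000 read pairs -> sim.R1/R2.fastq
2 junction coordinates -> called.summary.tsv
```

and `called.summary.tsv` contains (provenance comment lines omitted):

```
chrom   pos1    side    support read_ids
chr1    100001  left    99      frag_00015/1;frag_00021/2;...
chr1    100000  right   94      frag_00048/2;frag_00051/2;...
```

The two rows are the entry and exit junctions of the single planted
insertion, each with its distinct supporting-read count. With this seed
both junctions carry one base of incidental microhomology (the first
inserted base equals the next host base, and symmetrically at the exit), so
the `left` junction is reported one base to the right of the raw insertion
point — a junction coordinate is only defined up to its homology tract, and
the caller uses the host-maximal convention. `sim.truth.tsv` records both
the raw planted coordinates and these homology-adjusted observable ones,
and
`aavjunct evaluate --calls called.summary.tsv --truth sim.truth.tsv --out eval.tsv`
scores the callset (here: precision 1.000, recall 1.000).

The long-read mode works the same way from a single FASTQ
(`aavjunct call-long`), and `aavjunct compare` matches the two callsets per
chromosome into `both` / `long_only` / `short_only` rows.

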