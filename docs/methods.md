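# Methods

## Problem and model

An AAV vector that integrates into a host chromosome creates two
host–vector junctions (entry and exit). Sequencing reads that cross a
junction align in two pieces — one to the vector, one to a host chromosome
— when mapped against a *hybrid reference* (host assembly concatenated with
the vector sequence). `aavjunct` turns such split alignments into junction
calls two ways, mirroring the two library designs the tool targets:

- **Long-read caller.** Each consecutive pair of alignment blocks on a read
  defines a breakend adjacency: the reference boundary the read leaves one
  block through, joined to the boundary it enters the next block through
  (boundaries are strand-corrected to forward reference orientation). Only
  adjacencies joining the vector to a host chromosome, with at most
  `window_long` (default 50) unaligned read bases between the blocks, are
  junction evidence. Host breakends on the same chromosome and side are
  clustered by single linkage at `cluster_tol` (default 25 nt); the event
  position is the member median (lower middle for even counts — robust to
  long-read end jitter, unlike the mode), support is the distinct
  supporting-read count, and the highest-support event is flagged as the
  clone's baseline integration site (ties: smaller member spread, then
  lexicographic chrom/position). Entry and exit junctions are deliberately
  kept as separate left-/right-side events; breakpoint-level reporting is
  what downstream validation (junction PCR) consumes.
- **Short-read caller.** Per read, adjacent (host, vector) block pairs are
  candidates. A pair passes only if both blocks exceed `min_match_nt`
  matched bases (strictly: 35 matches reject, 36 accept) and reach
  `min_score` = 0.9 match score (`matches / aligned_span`), and the blocks
  abut on the read within `window_short` = 20 nt (`|gap| <= window`;
  negative gaps — overlaps — count by absolute value and typically reflect
  junction microhomology). "Consistent orientation" is enforced as
  intra-reference collinearity: blocks of one read on the same reference
  must share strand and follow read order; the host–vector strand relation
  itself is data (`vector_strand`), since integrations join either strand.
  The junction coordinate is the host block's reference boundary adjacent
  to the vector segment, converted to forward-strand coordinates and
  reported 1-based; `side` records the direction of the retained host
  flank. Calls aggregate into a summary keyed by unique
  `(chrom, pos1, side)` with distinct-read support.

Coordinates are 0-based half-open internally and 1-based in every report
(BED output is 0-based half-open, per the format).

## Alignment blocks

All callers consume `AlignmentBlock` records — read interval (always on the
forward-oriented read, so junction adjacency logic is strand-free), ref
interval, strand, and an exact matched-base count — from three sources:

- **Internal seed-and-extend aligner.** Exact k-mer seeds on both strands
  (k = 15 for kilobase reads, 11 for ~150-nt reads), chained per reference
  by diagonal band (60 nt drift allowance) and read-coordinate gaps, then
  extended. Extension is exact while bases match; an imperfect chain
  segment up to 600 read bases is refined by bounded local DP
  (Bio.Align.PairwiseAligner), longer segments by banded global alignment
  (edlib) plus chunked end extension cut at the running-score peak.
  Scoring is match +1, mismatch/gap −2 throughout. The stronger-than-unit
  penalty is deliberate: with unit costs a block end drifts past the true
  junction through any net-positive mismatch run, destabilising junction
  coordinates; −2 requires three chance matches per mismatch to extend,
  anchoring ends at the last exact-match run. Blocks must both span and
  match at least `min_block` = 30 read bases — below the 35-nt caller
  threshold, so filtering stays the caller's decision, and the match
  requirement keeps palindromic ITR flanks from padding sub-threshold
  overhangs into nominally long blocks.
- **SAM/BAM import** (pysam): one block per primary or supplementary
  record; secondary and unmapped records are skipped, hard clips count
  like soft clips for read-coordinate arithmetic. Matched bases use the MD
  tag when present (exact), else NM corrected for indel bases (NM counts
  inserted/deleted bases as edits), else the aligned span (logged as
  approximate).
- **PSL import**: 21-column BLAT output, headers tolerated;
  `matches + repMatches` as the match count; PSL query coordinates are
  already forward-oriented 0-based half-open.

Blocks of one read overlapping more than 50% (of the shorter) on the read
are reduced to the best block (more matches, then longer reference span,
then lexicographic reference name, ref start, strand) before junction
analysis — ITR palindromes make duplicate vector hits routine. When a read
segment lies entirely within an ITR, the two vector ends are genuinely
indistinguishable; the reduction resolves the tie deterministically toward
the lower vector coordinate, so vector-side breakpoints inside an ITR are
reported up to that ambiguity (host-side coordinates are unaffected).

## Vector structure reconstruction

For reads with vector blocks, the blocks in read order give the integrated
structure: adjacent same-orientation vector segments with a reference gap
above 30 nt are internal deletions, reference overlaps above 30 nt are
duplications (a head-to-tail concatemer re-entering the vector start shows
as a full-length duplication), orientation flips count as rearrangements,
and read gaps at host–vector transitions are junction indels. The 30-nt
slack absorbs block-end jitter without hiding kilobase-scale alterations.

## Simulator

The generator emulates the two library designs end to end and is the test
bed for every caller claim:

- **Host**: random multi-chromosome sequence at 41% GC (human-like);
  defaults two chromosomes of 120 kb and 80 kb. N bases are accepted in
  real references but never generated.
- **Vector**: 2928 nt with 145-nt terminal repeats (the canonical AAV2 ITR
  length), built as GC-rich imperfect palindromes (~3% divergence from a
  perfect palindrome, ≥80% self-reverse-complement identity) identical at
  both ends, and an interior partitioned into promoter/transgene/WPRE
  analog features (20/50/30%).
- **Integration**: the clone chromosome replaces `host_deletion` bases at
  the insertion point with a concatenation of oriented vector segments
  (full-length, partial deletion, concatemer, inversion are all
  expressible), with signed junction indels. Length conservation holds by
  construction and is property-tested.
- **Reads**: long reads default to 8 kb ± 1.5 kb fragments (a ~10 kb shear
  scale) with substitution/insertion/deletion rates 0.02/0.015/0.02
  (nanopore-like chemistry; configurable); short mode draws 250 ± 25 bp
  fragments read as inward-facing 150-nt pairs with 0.001 substitutions
  per base. Quality strings are constant Q20: no caller is quality-aware.
  Enrichment is fragment-level: with probability `on_target_fraction` a
  fragment is drawn from those overlapping the cassette (0.9 in the
  long-read scenarios, emulating Cas9-guided enrichment; 0.95 in the
  short-read scenarios, emulating probe capture). Optional cut positions
  snap a fragment end to a contained cut site, a simplified stand-in for
  Cas9 cleavage ends.
- **Truth**: per-read fragment provenance plus, per planted junction, both
  the raw planted coordinate and the homology-adjusted *observable*
  coordinate. A junction position is only defined up to its microhomology
  tract: if inserted bases happen to continue the host sequence, any
  aligner extends the host block through them. The observable coordinate
  applies the callers' own extension rule (match +1, mismatch −2 score
  peak, host-maximal) to the planted sequence context. Microhomology is
  incidental, not modelled or controlled.

What the simulator does *not* emulate — PCR duplicates, coverage bias along
probes, basecalling artifacts, chimera formation in library prep,
repetitive host sequence — bounds what passing tests show: recovery results
demonstrate the callers' logic is correct on clean planted truth, not that
real-sample specificity matches these numbers.

## Reference utilities

`build_validation_reference` produces a single-sequence genome of host
flank (default ±5 kb, clipped at chromosome ends) around the cassette at a
candidate junction, for local re-alignment and inspection of supporting
reads; insertion without host deletion is the default, with an optional
deletion span. `design_capture_probes` tiles a target with fixed-length
probes at a fixed step (`floor((L − probe_len)/step) + 1` probes); the
120-nt/40-nt-step defaults reproduce a 71-probe panel over a 2928-bp
cassette — the step is an inference from that count, since commercial
designers do not publish their tiling, and is configurable.

## Numerical and design choices

- Proximity windows: 20 nt (short mode) and 50 nt (long mode) between
  paired blocks on the read; the scale difference reflects long-read indel
  noise at junctions.
- Cluster tolerance 25 nt and minimum reported support 1 suit the
  single-cell-clone regime; mixed populations should raise `min_support`.
- Both mates are processed independently by default (mates are counted as
  distinct supporting observations); `--r1-only` restricts to R1 for
  workflows that extract chimeric sequence from the first mate only.
- A read spanning a short insertion entirely yields both junction calls;
  both are retained. When one host block has vector neighbours on both
  sides, the smaller-|gap| pair wins (then higher vector matches).
- Concordance matching (`compare_callsets`, default tolerance 10 nt) is
  greedy nearest-pair per chromosome and symmetric up to status labels;
  evaluation against truth matches each truth site to at most one call.
- Degenerate inputs: empty FASTQ, host-only reads, and empty callsets all
  produce empty outputs with exit code 0; name collisions between vector
  and host sequences, out-of-range coordinates, and malformed config are
  explicit errors (CLI exit codes 2/3).

## Desk-scale validation scenarios

The shared scenarios (`aavjunct.scenarios`) fix the study conditions used
by the test suite and the acceptance script: a two-chromosome 200 kb host,
one planted single-copy full-length integration mid-chr1, 200 error-free
(or 120 nanopore-error) long reads, 5000 short fragments (error-free and
1% substitutions), structure clones with a planted 1300-nt internal
deletion and a head-to-tail concatemer, vector-free negative controls, and
200 random planted-locus instances on which the internal aligner is
checked coordinate-for-coordinate against an independent full
Smith-Waterman oracle (`tests/oracle_sw.py`). These sizes exercise every
stage — enrichment, chimera extraction, filtering, clustering, ranking,
reconstruction — while a full run completes in minutes on one CPU.

## Known limitations

- The internal aligner is desk-scale: a Python k-mer index over megabase
  references, not a production mapper; production data should enter via
  SAM/BAM or PSL import.
- Vector-side breakpoints inside an ITR are reported up to the two-end
  ambiguity inherent to identical terminal repeats.
- No UMI/duplicate handling, no gene annotation of sites, no methylation
  analysis, and no inversion-aware host-side structural variant calling
  beyond vector-touching junctions.
- Support counts treat each mate and each junction crossing as one
  observation; fragment-level deduplication is out of scope.
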