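"""Synthetic hosts, vectors, clones with planted integrations, and reads.

The generator emulates the two library designs the callers target: kilobase
fragments (~8-10 kb shear) enriched for vector-containing molecules and read
on a long-read instrument with nanopore-like error rates, and ~250 bp
fragments enriched by probe capture and read as 150-nt inward-facing pairs.
Every planted integration emits truth records, so recovery can be measured
at desk scale.

A planted junction position is only defined up to its microhomology tract:
if the first inserted base happens to equal the next host base, an aligner
(any aligner) will extend the host block through it, and the observable
junction shifts by the homology length.  Truth records therefore carry both
the planted coordinate and the homology-adjusted *observable* coordinate
(host-maximal convention, matching the callers); microhomology itself is
incidental, not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .refmodel import Genome, VectorModel

#: flank required on each side of a breakpoint for the "spans junction" flag;
#: an error-free spanning read then contains the exact 2k-mer junction string
JUNCTION_KMER = 20


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class LongReadParams:
    """Kilobase-fragment library: ~10 kb shear read with nanopore-like errors."""

    mean_len: int = 8000
    sd_len: float = 1500.0
    sub_rate: float = 0.02
    ins_rate: float = 0.015
    del_rate: float = 0.02


@dataclass
class ShortReadParams:
    """~250 bp fragment library read as inward-facing 150-nt pairs."""

    fragment_mean: int = 250
    fragment_sd: float = 25.0
    read_len: int = 150
    sub_rate: float = 0.001


@dataclass
class EnrichmentParams:
    """Fragment-level target enrichment.

    With probability ``on_target_fraction`` a fragment is drawn from those
    overlapping a target region (the planted cassette), emulating Cas9-guided
    enrichment for the long library and probe capture for the short one.
    ``cut_positions`` optionally snaps a fragment end to the nearest
    contained cut site, emulating Cas9 cleavage ends.
    """

    on_target_fraction: float = 0.0
    cut_positions: tuple[int, ...] = ()


@dataclass
class SimConfig:
    seed: int = 0
    long_read: LongReadParams = field(default_factory=LongReadParams)
    short_read: ShortReadParams = field(default_factory=ShortReadParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    n_long: int = 200
    n_short: int = 5000

    def __post_init__(self) -> None:
        lr, sr = self.long_read, self.short_read
        for rate in (lr.sub_rate, lr.ins_rate, lr.del_rate, sr.sub_rate):
            if not 0 <= rate < 1:
                raise ValueError("error rates must lie in [0, 1)")
        if not 0 <= self.enrichment.on_target_fraction <= 1:
            raise ValueError("on_target_fraction must lie in [0, 1]")
        if min(lr.mean_len, sr.fragment_mean, sr.read_len) <= 0:
            raise ValueError("lengths must be positive")


# ---------------------------------------------------------------------------
# genome & vector generators
# ---------------------------------------------------------------------------


def simulate_host_genome(
    n_chrom: int, lengths: Sequence[int], gc: float = 0.41, seed: int = 0
) -> Genome:
    """Random multi-chromosome host with the requested GC content."""
    if n_chrom != len(lengths):
        raise ValueError("n_chrom must equal len(lengths)")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng([seed, 101])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seqs = {
        f"chr{i + 1}": "".join(rng.choice(bases, size=length, p=p))
        for i, length in enumerate(lengths)
    }
    return Genome(seqs, source_label=f"simulated host (gc={gc}, seed={seed})")


def _mutate_positions(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in positions:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def simulate_vector(
    length: int = 2928,
    itr_len: int = 145,
    seed: int = 0,
    name: str = "AAV",
) -> VectorModel:
    """ITR-flanked vector with labelled interior features.

    The terminal ``itr_len`` segments are GC-rich imperfect palindromes (the
    same sequence at both ends, as in a real vector genome); the interior is
    partitioned into promoter / transgene / WPRE analog intervals.  145 nt is
    the canonical AAV2 ITR length.
    """
    if itr_len < 0 or 2 * itr_len >= length:
        raise ValueError("need 2*itr_len < length and itr_len >= 0")
    rng = np.random.default_rng([seed, 202])
    bases = np.array(list("ACGT"))
    if itr_len:
        half = itr_len // 2
        gc_rich = np.array([0.1, 0.4, 0.4, 0.1])
        left = "".join(rng.choice(bases, size=half, p=gc_rich))
        mid = "" if itr_len % 2 == 0 else str(rng.choice(bases))
        palindrome = left + mid + revcomp(left)
        n_mut = max(1, int(round(0.03 * itr_len)))
        pos = rng.choice(itr_len, size=n_mut, replace=False)
        itr = _mutate_positions(palindrome, pos, rng)
    else:
        itr = ""
    interior_len = length - 2 * itr_len
    interior = "".join(rng.choice(bases, size=interior_len))
    sequence = itr + interior + itr
    i0 = itr_len
    i1 = length - itr_len
    a = i0 + int(round(0.2 * interior_len))
    b = i0 + int(round(0.7 * interior_len))
    features = [
        ("promoter", (i0, a)),
        ("transgene", (a, b)),
        ("WPRE", (b, i1)),
    ]
    itrs = ((0, itr_len), (length - itr_len, length)) if itr_len else ()
    return VectorModel(name=name, sequence=sequence, itr_intervals=itrs, features=features)


# ---------------------------------------------------------------------------
# planting integrations
# ---------------------------------------------------------------------------


@dataclass
class IntegrationTruth:
    """Description of one planted integration.

    ``pos1`` is the 1-based host coordinate after which the insert is placed
    (the last retained host base of the left flank); the next
    ``host_deletion`` host bases are replaced by the concatenation of
    ``segments`` (vector intervals with orientation), with signed
    ``junction_indels`` applied at the two host-vector junctions (positive =
    random inserted bases, negative = bases trimmed from the insert end).
    """

    clone_id: str
    chrom: str
    pos1: int
    host_deletion: int = 0
    segments: tuple[tuple[tuple[int, int], str], ...] = ()
    junction_indels: tuple[int, int] = (0, 0)
    label: str = ""


@dataclass
class PlantedJunction:
    """One observable host-vector junction of a planted integration."""

    clone_id: str
    chrom: str
    side: str  # direction of the retained host flank
    pos1: int  # homology-adjusted observable host coordinate, 1-based
    planted_pos1: int  # raw planted coordinate, 1-based
    vector_pos1: int
    clone_pos: int  # 0-based boundary position in clone coordinates
    homology: int


def _homology_extension(a: str, b: str) -> int:
    """Length of the score-positive common extension of two strings.

    Mirrors the callers' block-end extension rule (match +1, mismatch -2,
    no indels): the observable junction boundary sits at the score peak of
    comparing the inserted sequence against the continuing host reference.
    For a plain homology tract this equals the common-prefix length.
    """
    score = best = best_pos = 0
    for i, (x, y) in enumerate(zip(a, b)):
        score += 1 if x == y else -2
        if score > best:
            best, best_pos = score, i + 1
    return best_pos


def plant_integration(
    host: Genome,
    vector: VectorModel,
    truth: IntegrationTruth,
    seed: int = 0,
) -> tuple[Genome, list[PlantedJunction]]:
    """Clone genome with the described integration, plus its junction records.

    Length conservation holds by construction: the clone chromosome is the
    host chromosome minus ``host_deletion`` bases plus the summed (oriented)
    segment lengths plus the signed junction indels.
    """
    if truth.chrom not in host.sequences:
        raise ValueError(f"chromosome {truth.chrom!r} not in host")
    if not truth.segments:
        raise ValueError("truth.segments must be non-empty")
    chrom_seq = host.sequences[truth.chrom]
    p = truth.pos1
    if not (1 <= p <= len(chrom_seq)):
        raise ValueError(f"pos1={p} out of range for {truth.chrom}")
    d = truth.host_deletion
    if d < 0 or p + d > len(chrom_seq):
        raise ValueError("host_deletion runs past the chromosome end")
    vec = vector.sequence
    parts = []
    for (s, e), orient in truth.segments:
        if not (0 <= s < e <= len(vec)):
            raise ValueError(f"segment [{s},{e}) out of vector bounds")
        seg = vec[s:e]
        parts.append(seg if orient == "+" else revcomp(seg))
    insert = "".join(parts)
    li, ri = truth.junction_indels
    rng = np.random.default_rng([seed, 303])
    bases = np.array(list("ACGT"))
    if li < 0:
        insert = insert[-li:]
    elif li > 0:
        insert = "".join(rng.choice(bases, size=li)) + insert
    if ri < 0:
        insert = insert[: len(insert) + ri] if ri != 0 else insert
    elif ri > 0:
        insert = insert + "".join(rng.choice(bases, size=ri))
    if not insert:
        raise ValueError("junction indels removed the entire insert")

    clone_seqs = dict(host.sequences)
    clone_seqs[truth.chrom] = chrom_seq[:p] + insert + chrom_seq[p + d :]
    clone = Genome(clone_seqs, source_label=f"clone {truth.clone_id}")

    # observable coordinates under the host-maximal convention: the host
    # block of a spanning read extends through any incidental homology
    h_left = _homology_extension(insert, chrom_seq[p:])
    h_right = _homology_extension(insert[::-1], chrom_seq[:p + d][::-1])
    (s0, e0), o0 = truth.segments[0]
    (sl, el), ol = truth.segments[-1]
    vec_left = (s0 + 1) if o0 == "+" else e0
    vec_right = el if ol == "+" else (sl + 1)
    junctions = [
        PlantedJunction(
            clone_id=truth.clone_id,
            chrom=truth.chrom,
            side="left",
            pos1=p + h_left,
            planted_pos1=p,
            vector_pos1=vec_left,
            clone_pos=p,
            homology=h_left,
        ),
        PlantedJunction(
            clone_id=truth.clone_id,
            chrom=truth.chrom,
            side="right",
            pos1=p + d + 1 - h_right,
            planted_pos1=p + d + 1,
            vector_pos1=vec_right,
            clone_pos=p + len(insert),
            homology=h_right,
        ),
    ]
    return clone, junctions


def cassette_interval(truth: IntegrationTruth, junctions: Sequence[PlantedJunction]) -> tuple[str, int, int]:
    """Clone-coordinate interval occupied by the planted insert."""
    left = next(j for j in junctions if j.side == "left")
    right = next(j for j in junctions if j.side == "right")
    return truth.chrom, left.clone_pos, right.clone_pos


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    read_id: str
    seq: str
    qual: str


@dataclass
class ReadTruth:
    """Fragment provenance of one simulated read (or read pair)."""

    read_id: str
    chrom: str
    start: int  # 0-based fragment interval in the source genome
    end: int
    strand: str
    spans_junction: bool
    junction_flanks: tuple[tuple[int, int, int], ...] = ()
    # (clone_pos, left_flank, right_flank) for each planted junction covered


def _apply_errors(
    seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator
) -> str:
    if sub == 0 and ins == 0 and dele == 0:
        return seq
    bases = "ACGT"
    out: list[str] = []
    n = len(seq)
    r = rng.random(n)
    which = rng.random(n)  # reused uniform draws for op selection
    p_any = sub + ins + dele
    for i, ch in enumerate(seq):
        if r[i] >= p_any:
            out.append(ch)
            continue
        u = which[i] * p_any
        if u < dele:
            continue
        if u < dele + sub:
            out.append(bases[(bases.index(ch) + 1 + int(u * 9973) % 3) % 4])
        else:
            out.append(bases[int(u * 7919) % 4])
            out.append(ch)
    return "".join(out)


def _sample_fragment(
    genome: Genome,
    length: int,
    rng: np.random.Generator,
    targets: Sequence[tuple[str, int, int]] | None,
    on_target_fraction: float,
    chrom_names: list[str],
    chrom_weights: np.ndarray,
) -> tuple[str, int, int]:
    if targets and rng.random() < on_target_fraction:
        chrom, t0, t1 = targets[rng.integers(len(targets))]
        chrom_len = len(genome.sequences[chrom])
        lo = max(0, t0 - length + 1)
        hi = min(chrom_len - 1, t1 - 1)
        start = int(rng.integers(lo, hi + 1))
    else:
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
        chrom_len = len(genome.sequences[chrom])
        start = int(rng.integers(0, max(1, chrom_len)))
    end = min(start + length, len(genome.sequences[chrom]))
    return chrom, start, end


def _junction_coverage(
    start: int, end: int, junction_positions: Sequence[int]
) -> tuple[bool, tuple[tuple[int, int, int], ...]]:
    flanks = []
    spans = False
    for j in junction_positions:
        if start < j < end:
            lf, rf = j - start, end - j
            flanks.append((j, lf, rf))
            if lf >= JUNCTION_KMER and rf >= JUNCTION_KMER:
                spans = True
    return spans, tuple(flanks)


def simulate_long_reads(
    genome: Genome,
    n: int,
    cfg: SimConfig,
    targets: Sequence[tuple[str, int, int]] | None = None,
    junction_positions: Sequence[int] | None = None,
    junction_chrom: str | None = None,
    read_prefix: str = "long",
) -> tuple[list[SimRead], list[ReadTruth]]:
    """Single-end kilobase reads with per-base errors and known provenance.

    ``targets`` are clone-coordinate intervals (the planted cassette) used
    for fragment-level enrichment; ``junction_positions`` are the clone
    coordinates of planted breakpoints on ``junction_chrom``, recorded per
    read as spanning flags and flank lengths.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([cfg.seed, 404])
    lr = cfg.long_read
    chrom_names = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chrom_names], dtype=float)
    weights = lens / lens.sum()
    cuts = sorted(cfg.enrichment.cut_positions)
    reads: list[SimRead] = []
    truths: list[ReadTruth] = []
    for i in range(n):
        length = max(100, int(round(rng.normal(lr.mean_len, lr.sd_len))))
        chrom, start, end = _sample_fragment(
            genome, length, rng, targets, cfg.enrichment.on_target_fraction,
            chrom_names, weights,
        )
        if cuts:
            inside = [c for c in cuts if start < c < end]
            if inside:
                # Cas9 cleavage: fragment end snaps to the nearest contained cut
                c = min(inside, key=lambda c: min(c - start, end - c))
                if c - start < end - c:
                    start = c
                else:
                    end = c
        frag = genome.sequences[chrom][start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        seq = _apply_errors(frag, lr.sub_rate, lr.ins_rate, lr.del_rate, rng)
        if not seq:
            continue
        read_id = f"{read_prefix}_{i:05d}"
        reads.append(SimRead(read_id, seq, "5" * len(seq)))
        if junction_positions is not None and chrom == junction_chrom:
            spans, flanks = _junction_coverage(start, end, junction_positions)
        else:
            spans, flanks = False, ()
        truths.append(ReadTruth(read_id, chrom, start, end, strand, spans, flanks))
    return reads, truths


def simulate_short_pairs(
    genome: Genome,
    n: int,
    cfg: SimConfig,
    targets: Sequence[tuple[str, int, int]] | None = None,
    junction_positions: Sequence[int] | None = None,
    junction_chrom: str | None = None,
    read_prefix: str = "frag",
) -> tuple[list[SimRead], list[SimRead], list[ReadTruth]]:
    """Inward-facing R1/R2 pairs from ~250 bp fragments.

    R1 reads the fragment's 5' end on a random strand; R2 reads the opposite
    end on the opposite strand.  Reads are truncated to the fragment length
    when the fragment is shorter than the read length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([cfg.seed, 505])
    sr = cfg.short_read
    chrom_names = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chrom_names], dtype=float)
    weights = lens / lens.sum()
    r1s: list[SimRead] = []
    r2s: list[SimRead] = []
    truths: list[ReadTruth] = []
    for i in range(n):
        length = max(30, int(round(rng.normal(sr.fragment_mean, sr.fragment_sd))))
        chrom, start, end = _sample_fragment(
            genome, length, rng, targets, cfg.enrichment.on_target_fraction,
            chrom_names, weights,
        )
        frag = genome.sequences[chrom][start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = frag if strand == "+" else revcomp(frag)
        r1 = oriented[: sr.read_len]
        r2 = revcomp(oriented)[: sr.read_len]
        r1 = _apply_errors(r1, sr.sub_rate, 0.0, 0.0, rng)
        r2 = _apply_errors(r2, sr.sub_rate, 0.0, 0.0, rng)
        read_id = f"{read_prefix}_{i:05d}"
        r1s.append(SimRead(f"{read_id}/1", r1, "5" * len(r1)))
        r2s.append(SimRead(f"{read_id}/2", r2, "5" * len(r2)))
        if junction_positions is not None and chrom == junction_chrom:
            spans, flanks = _junction_coverage(start, end, junction_positions)
        else:
            spans, flanks = False, ()
        truths.append(ReadTruth(read_id, chrom, start, end, strand, spans, flanks))
    return r1s, r2s, truths


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_fastq(reads: Sequence[SimRead], path: str) -> None:
    from ._util import open_text

    with open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_truth_frame(truths: Sequence[ReadTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [t.read_id, t.chrom, t.start, t.end, t.strand, t.spans_junction,
             ";".join(f"{j}:{lf}:{rf}" for j, lf, rf in t.junction_flanks)]
            for t in truths
        ],
        columns=["read_id", "chrom", "start", "end", "strand",
                 "spans_junction", "junction_flanks"],
    )


def junctions_to_frame(junctions: Sequence[PlantedJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [j.clone_id, j.chrom, j.pos1, j.planted_pos1, j.side,
             j.vector_pos1, j.clone_pos, j.homology]
            for j in junctions
        ],
        columns=["clone_id", "chrom", "pos1", "planted_pos1", "side",
                 "vector_pos1", "clone_pos", "homology"],
    )


def junctions_to_bed(junctions: Sequence[PlantedJunction], path: str) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.pos1 - 1}\t{j.pos1}\t"
                f"{j.clone_id}:{j.side}:{j.vector_pos1}\n"
            )
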