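"""Alignment blocks from three sources: an internal split aligner, SAM/BAM, PSL.

Everything downstream (both junction callers) consumes ``AlignmentBlock``
records: one gapped local alignment segment of a read against one reference
sequence, with an exact matched-base count.  Read coordinates are always
stored on the *forward-oriented* read, so junction adjacency logic is
strand-free.

The internal aligner is a desk-scale stand-in for a production long/short
read mapper: exact k-mer seeds on both strands, chained by diagonal, extended
with edit-distance-style alignment (match +1, mismatch/gap -2).  The -2
penalty anchors block ends at the last exact-match run, which keeps junction
coordinates stable instead of letting blocks drift through net-positive
mismatch runs past the true breakpoint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib
import pandas as pd
import pysam
from Bio import Align

from ._util import revcomp
from .refmodel import Genome, HybridReference

logger = logging.getLogger(__name__)

MATCH_SCORE = 1
MISMATCH_PENALTY = -2
GAP_PENALTY = -2

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentBlock:
    """One local alignment segment of a read against one reference sequence.

    ``read_start``/``read_end`` are 0-based half-open on the forward-oriented
    read; ``ref_start``/``ref_end`` are 0-based half-open on the reference.
    ``matches`` counts identical aligned bases; ``aligned_span`` is the number
    of read bases the block consumes (== read_end - read_start).
    """

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    ref_name: str
    ref_start: int
    ref_end: int
    matches: int
    source: str = "internal"
    is_vector: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise ValueError(
                f"bad read interval [{self.read_start},{self.read_end}) "
                f"for read of length {self.read_len}"
            )
        if not (self.ref_start < self.ref_end):
            raise ValueError("empty reference interval")
        if not (0 < self.matches <= self.aligned_span):
            raise ValueError(
                f"matches={self.matches} outside (0, {self.aligned_span}]"
            )

    @property
    def aligned_span(self) -> int:
        return self.read_end - self.read_start


def match_score(block: AlignmentBlock) -> float:
    """Proportion of matched bases relative to the aligned span, in (0, 1]."""
    return block.matches / block.aligned_span


# ---------------------------------------------------------------------------
# internal seed-and-extend aligner
# ---------------------------------------------------------------------------


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _ops_matches(ops: list[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op == "=")


class SeedExtendAligner:
    """Exact k-mer seeding, diagonal chaining, and edit-style extension.

    Parameters
    ----------
    ref : HybridReference or Genome
        The alignment target.  When a hybrid reference is given, emitted
        blocks carry ``is_vector`` flags.
    k : int
        Seed length.  15 suits kilobase reads, 11 suits ~150-nt reads.
    min_block : int
        Blocks spanning fewer read bases than this are dropped.
    """

    #: max diagonal drift tolerated inside one chain (covers indel wander)
    DIAG_BAND = 60
    #: max read-coordinate gap between consecutive seeds of one chain
    MAX_SEED_GAP = 500
    #: DP refinement is used for chain segments up to this many read bases;
    #: longer segments use banded edlib alignment with peak-trimmed extension
    DP_LIMIT = 600
    #: chunk size for the peak-trimmed extension past the seeded region
    EXTEND_CHUNK = 400

    def __init__(self, ref: HybridReference | Genome, k: int = 15, min_block: int = 30):
        if isinstance(ref, HybridReference):
            self.sequences = ref.genome.sequences
            self.vector_names = set(ref.vector_names)
        else:
            self.sequences = ref.sequences
            self.vector_names = set()
        self.k = k
        self.min_block = min_block
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((name, pos))
        self._dp = Align.PairwiseAligner(
            mode="local",
            match_score=MATCH_SCORE,
            mismatch_score=MISMATCH_PENALTY,
            open_gap_score=GAP_PENALTY,
            extend_gap_score=GAP_PENALTY,
        )

    # -- seeding / chaining -------------------------------------------------

    def _seed_hits(self, oriented: str) -> dict[str, list[tuple[int, int]]]:
        """Map ref name -> [(read_pos, ref_pos)] of exact k-mer hits."""
        k = self.k
        hits: dict[str, list[tuple[int, int]]] = {}
        idx = self._index
        for rpos in range(len(oriented) - k + 1):
            entry = idx.get(oriented[rpos : rpos + k])
            if entry is None:
                continue
            for name, tpos in entry:
                hits.setdefault(name, []).append((rpos, tpos))
        return hits

    def _chains(self, hits: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
        """Cluster seed hits into chains by diagonal band, then read gaps."""
        by_diag = sorted(hits, key=lambda h: (h[1] - h[0], h[0]))
        bands: list[list[tuple[int, int]]] = []
        for h in by_diag:
            d = h[1] - h[0]
            if bands and d - (bands[-1][-1][1] - bands[-1][-1][0]) <= self.DIAG_BAND:
                bands[-1].append(h)
            else:
                bands.append([h])
        chains: list[list[tuple[int, int]]] = []
        for band in bands:
            band.sort()
            cur = [band[0]]
            for h in band[1:]:
                if h[0] - cur[-1][0] <= self.MAX_SEED_GAP:
                    cur.append(h)
                else:
                    chains.append(cur)
                    cur = [h]
            chains.append(cur)
        return chains

    # -- extension ----------------------------------------------------------

    @staticmethod
    def _exact_extend(
        read: str, ref: str, rs: int, re_: int, ts: int, te: int
    ) -> tuple[int, int, int, int]:
        while rs > 0 and ts > 0 and read[rs - 1] == ref[ts - 1]:
            rs -= 1
            ts -= 1
        n, m = len(read), len(ref)
        while re_ < n and te < m and read[re_] == ref[te]:
            re_ += 1
            te += 1
        return rs, re_, ts, te

    def _peak_extend(
        self, read: str, ref: str, rpos: int, tpos: int, direction: int
    ) -> tuple[int, int, int]:
        """Extend from (rpos, tpos) while the running score keeps a peak.

        ``direction`` +1 extends rightwards, -1 leftwards.  Returns the number
        of read bases and ref bases consumed and the matches gained.  The
        extension aligns successive read chunks with edlib and cuts the path
        at the score maximum (match +1, mismatch/indel -2), the local-
        alignment analog of an X-drop extension.
        """
        total_r = total_t = total_m = 0
        while True:
            if direction > 0:
                tail = read[rpos : rpos + self.EXTEND_CHUNK]
                window = ref[tpos : tpos + self.EXTEND_CHUNK + 60]
            else:
                tail = read[max(0, rpos - self.EXTEND_CHUNK) : rpos][::-1]
                window = ref[max(0, tpos - self.EXTEND_CHUNK - 60) : tpos][::-1]
            if not tail or not window:
                break
            res = edlib.align(tail, window, mode="SHW", task="path")
            ops = _cigar_ops(res["cigar"])
            best = (0, 0, 0, 0)  # score, read adv, ref adv, matches
            score = radv = tadv = mats = 0
            for n, op in ops:
                if op == "=":
                    score += n * MATCH_SCORE
                    radv += n
                    tadv += n
                    mats += n
                elif op in "XM":
                    score += n * MISMATCH_PENALTY
                    radv += n
                    tadv += n
                elif op == "I":  # read base not in ref
                    score += n * GAP_PENALTY
                    radv += n
                elif op == "D":
                    score += n * GAP_PENALTY
                    tadv += n
                if score > best[0]:
                    best = (score, radv, tadv, mats)
            if best[0] <= 0:
                break
            _, radv, tadv, mats = best
            total_r += radv
            total_t += tadv
            total_m += mats
            rpos += direction * radv
            tpos += direction * tadv
            if radv < len(tail):  # the peak fell inside the chunk: done
                break
        return total_r, total_t, total_m

    # -- per-chain block construction --------------------------------------

    def _block_from_chain(
        self,
        chain: list[tuple[int, int]],
        oriented: str,
        ref_name: str,
        strand: str,
        read_id: str,
        read_len: int,
    ) -> AlignmentBlock | None:
        ref = self.sequences[ref_name]
        k = self.k
        rs = chain[0][0]
        re_ = chain[-1][0] + k
        ts = min(t for _, t in chain)
        te = max(t for _, t in chain) + k
        rs, re_, ts, te = self._exact_extend(oriented, ref, rs, re_, ts, te)

        if oriented[rs:re_] == ref[ts:te]:
            matches = re_ - rs
            dr, dt, dm = self._peak_extend(oriented, ref, re_, te, +1)
            re_ += dr
            te += dt
            matches += dm
            dr, dt, dm = self._peak_extend(oriented, ref, rs, ts, -1)
            rs -= dr
            ts -= dt
            matches += dm
        elif re_ - rs <= self.DP_LIMIT:
            block = self._dp_refine(oriented, ref, rs, re_, ts, te)
            if block is None:
                return None
            rs, re_, ts, te, matches = block
        else:
            res = edlib.align(oriented[rs:re_], ref[ts:te], mode="NW", task="path")
            matches = _ops_matches(_cigar_ops(res["cigar"]))
            dr, dt, dm = self._peak_extend(oriented, ref, re_, te, +1)
            re_ += dr
            te += dt
            matches += dm
            dr, dt, dm = self._peak_extend(oriented, ref, rs, ts, -1)
            rs -= dr
            ts -= dt
            matches += dm

        # a block must both span and *match* at least min_block read bases;
        # palindromic ITR flanks otherwise pad sub-threshold overhangs into
        # nominally long enough blocks
        if re_ - rs < self.min_block or matches < self.min_block:
            return None
        if strand == "+":
            f_start, f_end = rs, re_
        else:
            f_start, f_end = read_len - re_, read_len - rs
        return AlignmentBlock(
            read_id=read_id,
            read_len=read_len,
            read_start=f_start,
            read_end=f_end,
            strand=strand,
            ref_name=ref_name,
            ref_start=ts,
            ref_end=te,
            matches=matches,
            source="internal",
            is_vector=ref_name in self.vector_names,
        )

    def _dp_refine(
        self, oriented: str, ref: str, rs: int, re_: int, ts: int, te: int
    ) -> tuple[int, int, int, int, int] | None:
        """Bounded local DP around the chain to recover exact block bounds."""
        pad_r = 40
        pad_t = pad_r + (re_ - rs) // 4 + 20
        qs = max(0, rs - pad_r)
        qe = min(len(oriented), re_ + pad_r)
        ws = max(0, ts - pad_t)
        we = min(len(ref), te + pad_t)
        query = oriented[qs:qe]
        window = ref[ws:we]
        if self._dp.score(window, query) <= 0:
            return None
        aln = next(iter(self._dp.align(window, query)))
        t_segs, q_segs = aln.aligned
        matches = 0
        for (t0, t1), (q0, q1) in zip(t_segs, q_segs):
            matches += sum(
                1 for a, b in zip(window[t0:t1], query[q0:q1]) if a == b
            )
        rs2 = qs + q_segs[0][0]
        re2 = qs + q_segs[-1][1]
        ts2 = ws + t_segs[0][0]
        te2 = ws + t_segs[-1][1]
        if matches <= 0:
            return None
        return rs2, re2, ts2, te2, matches

    # -- public API ---------------------------------------------------------

    def align(self, read_id: str, seq: str) -> list[AlignmentBlock]:
        """All alignment blocks of one read against the reference, both strands."""
        seq = seq.upper()
        read_len = len(seq)
        if read_len < self.k:
            return []
        blocks: list[AlignmentBlock] = []
        seen: set[tuple] = set()
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for ref_name, hits in self._seed_hits(oriented).items():
                for chain in self._chains(hits):
                    blk = self._block_from_chain(
                        chain, oriented, ref_name, strand, read_id, read_len
                    )
                    if blk is None:
                        continue
                    key = (
                        blk.ref_name,
                        blk.strand,
                        blk.read_start,
                        blk.read_end,
                        blk.ref_start,
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    blocks.append(blk)
        blocks.sort(key=lambda b: (b.read_start, b.read_end))
        return blocks


def seed_and_extend_align(
    read: str,
    ref: HybridReference | Genome,
    k: int = 15,
    min_block: int = 30,
    read_id: str = "read",
) -> list[AlignmentBlock]:
    """One-shot convenience wrapper around :class:`SeedExtendAligner`.

    Building the aligner indexes the reference; reuse a ``SeedExtendAligner``
    instance when aligning many reads against the same reference.
    """
    return SeedExtendAligner(ref, k=k, min_block=min_block).align(read_id, read)


# ---------------------------------------------------------------------------
# overlap reduction
# ---------------------------------------------------------------------------


def reduce_overlaps(blocks: Sequence[AlignmentBlock]) -> list[AlignmentBlock]:
    """Collapse blocks of one read that overlap >50% mutually on the read.

    ITR palindromes routinely produce duplicate vector hits for the same read
    segment; before junction analysis only the best block per read segment is
    kept.  Preference: more matches, then longer reference span, then
    lexicographic reference name, then smaller ref_start, then '+' strand.
    """
    ordered = sorted(
        blocks,
        key=lambda b: (
            -b.matches,
            -(b.ref_end - b.ref_start),
            b.ref_name,
            b.ref_start,
            b.strand,
        ),
    )
    kept: list[AlignmentBlock] = []
    for blk in ordered:
        redundant = False
        for other in kept:
            ov = min(blk.read_end, other.read_end) - max(
                blk.read_start, other.read_start
            )
            if ov <= 0:
                continue
            if ov > 0.5 * min(blk.aligned_span, other.aligned_span):
                redundant = True
                break
        if not redundant:
            kept.append(blk)
    kept.sort(key=lambda b: (b.read_start, b.read_end))
    return kept


def group_by_read(blocks: Iterable[AlignmentBlock]) -> dict[str, list[AlignmentBlock]]:
    out: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        out.setdefault(b.read_id, []).append(b)
    for lst in out.values():
        lst.sort(key=lambda b: (b.read_start, b.read_end))
    return out


# ---------------------------------------------------------------------------
# SAM / BAM import
# ---------------------------------------------------------------------------

_READ_CONSUMING = {0, 1, 7, 8}  # M, I, =, X
_ALIGNED = {0, 7, 8}  # M, =, X
_CLIP = {4, 5}  # S, H


def parse_sam_blocks(
    source: str | pysam.AlignmentFile,
    ref: HybridReference | None = None,
) -> list[AlignmentBlock]:
    """Alignment blocks from primary and supplementary SAM/BAM records.

    Unmapped and secondary records are skipped; records without a CIGAR are
    rejected (counted in the log).  Matched-base counts use, in order of
    preference: the MD tag (exact), NM corrected for indel bases, or the
    aligned span (flagged approximate in the log).  Hard clips are treated
    like soft clips for read-coordinate arithmetic, and read coordinates are
    reported on the forward-oriented read.
    """
    own = False
    if isinstance(source, (str, bytes)):
        source = pysam.AlignmentFile(str(source), check_sq=False)
        own = True
    vector_names = set(ref.vector_names) if ref is not None else set()
    blocks: list[AlignmentBlock] = []
    n_unmapped = n_secondary = n_nocigar = n_approx = 0
    try:
        for rec in source.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary:
                n_secondary += 1
                continue
            cig = rec.cigartuples
            if not cig:
                n_nocigar += 1
                continue
            left = 0
            for op, ln in cig:
                if op in _CLIP:
                    left += ln
                else:
                    break
            right = 0
            for op, ln in reversed(cig):
                if op in _CLIP:
                    right += ln
                else:
                    break
            consumed = sum(ln for op, ln in cig if op in _READ_CONSUMING)
            aligned_bases = sum(ln for op, ln in cig if op in _ALIGNED)
            read_len = left + consumed + right
            if rec.is_reverse:
                f_start = read_len - (left + consumed)
                f_end = read_len - left
            else:
                f_start = left
                f_end = left + consumed
            matches = None
            if rec.has_tag("MD"):
                pairs = rec.get_aligned_pairs(with_seq=True)
                matches = sum(
                    1
                    for q, t, s in pairs
                    if q is not None and t is not None and s is not None and s.isupper()
                )
            elif rec.has_tag("NM"):
                nm = rec.get_tag("NM")
                ins = sum(ln for op, ln in cig if op == 1)
                dels = sum(ln for op, ln in cig if op == 2)
                mismatches = max(0, nm - ins - dels)
                matches = max(0, aligned_bases - mismatches)
            else:
                matches = aligned_bases
                n_approx += 1
            if matches <= 0:
                continue
            blocks.append(
                AlignmentBlock(
                    read_id=rec.query_name,
                    read_len=read_len,
                    read_start=f_start,
                    read_end=f_end,
                    strand="-" if rec.is_reverse else "+",
                    ref_name=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    matches=matches,
                    source="sam",
                    is_vector=rec.reference_name in vector_names,
                )
            )
    finally:
        if own:
            source.close()
    if n_unmapped or n_secondary or n_nocigar or n_approx:
        logger.info(
            "SAM import: %d blocks, skipped %d unmapped / %d secondary, "
            "rejected %d without CIGAR, %d with approximate match counts",
            len(blocks), n_unmapped, n_secondary, n_nocigar, n_approx,
        )
    return blocks


# ---------------------------------------------------------------------------
# PSL import
# ---------------------------------------------------------------------------


def parse_psl_blocks(
    source: str | Iterable[str],
    ref: HybridReference | None = None,
) -> list[AlignmentBlock]:
    """Alignment blocks from 21-column PSL (BLAT output), header tolerated.

    PSL query coordinates are already 0-based half-open on the forward-
    oriented query, matching the block convention directly.  ``matches`` is
    PSL matches + repMatches.  Malformed lines are rejected and logged with
    their line number.
    """
    if isinstance(source, (str, bytes)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    vector_names = set(ref.vector_names) if ref is not None else set()
    blocks: list[AlignmentBlock] = []
    bad: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        s = line.rstrip("\n")
        if not s.strip():
            continue
        stripped = s.strip()
        if (
            stripped.startswith("psLayout")
            or stripped.startswith("-")
            or stripped.startswith("match")
            or stripped.startswith("\t")
            or stripped[0].isalpha() and stripped.split()[0] in ("match", "Q", "T")
        ):
            # header block of BLAT's default output
            continue
        fields = s.split("\t")
        if len(fields) < 21:
            fields = s.split()
        if len(fields) < 21:
            bad.append(lineno)
            continue
        try:
            matches = int(fields[0]) + int(fields[2])  # matches + repMatches
            strand = fields[8][0]
            q_name = fields[9]
            q_size = int(fields[10])
            q_start = int(fields[11])
            q_end = int(fields[12])
            t_name = fields[13]
            t_start = int(fields[15])
            t_end = int(fields[16])
            block = AlignmentBlock(
                read_id=q_name,
                read_len=q_size,
                read_start=q_start,
                read_end=q_end,
                strand=strand,
                ref_name=t_name,
                ref_start=t_start,
                ref_end=t_end,
                matches=min(matches, q_end - q_start),
                source="psl",
                is_vector=t_name in vector_names,
            )
        except (ValueError, IndexError):
            bad.append(lineno)
            continue
        blocks.append(block)
    if bad:
        logger.warning("PSL import: rejected malformed lines %s", bad)
    return blocks


# ---------------------------------------------------------------------------
# block TSV round-trip
# ---------------------------------------------------------------------------

BLOCK_COLUMNS = [
    "read_id", "read_len", "read_start", "read_end", "strand",
    "ref_name", "ref_start", "ref_end", "matches", "source", "is_vector",
]


def blocks_to_frame(blocks: Iterable[AlignmentBlock]) -> pd.DataFrame:
    rows = [[getattr(b, c) for c in BLOCK_COLUMNS] for b in blocks]
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


def write_blocks_tsv(
    blocks: Iterable[AlignmentBlock], path: str, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        blocks_to_frame(blocks).to_csv(fh, sep="\t", index=False)


def read_blocks_tsv(path: str) -> list[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AlignmentBlock(
            read_id=str(r.read_id),
            read_len=int(r.read_len),
            read_start=int(r.read_start),
            read_end=int(r.read_end),
            strand=str(r.strand),
            ref_name=str(r.ref_name),
            ref_start=int(r.ref_start),
            ref_end=int(r.ref_end),
            matches=int(r.matches),
            source=str(r.source),
            is_vector=bool(r.is_vector),
        )
        for r in df.itertuples()
    ]


def flag_vector_blocks(
    blocks: Iterable[AlignmentBlock], ref: HybridReference
) -> list[AlignmentBlock]:
    """Return blocks with ``is_vector`` set from a hybrid reference."""
    return [replace(b, is_vector=ref.is_vector(b.ref_name)) for b in blocks]
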