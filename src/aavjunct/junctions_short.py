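"""Short-read junction caller: chimeric block pairs -> junction coordinates.

A read aligned partly to the vector and partly to a host chromosome is
evidence of an integration junction.  The caller extracts adjacent
(host, vector) block pairs per read, applies the matched-base and match-score
thresholds (strict > 35 matched nt on *both* segments by default), requires
the two blocks to be contiguous on the read within a small window, derives
the host junction coordinate from the host block boundary adjacent to the
vector segment (orientation-dependent), and aggregates supporting reads per
unique (chrom, position, side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentBlock, group_by_read, match_score, reduce_overlaps

logger = logging.getLogger(__name__)

DEFAULT_MIN_MATCH_NT = 35
DEFAULT_MIN_SCORE = 0.9
DEFAULT_WINDOW = 20


@dataclass
class PairCandidate:
    """A host block and a vector block adjacent on one read.

    ``gap`` is downstream.read_start - upstream.read_end on the forward-
    oriented read (negative = the blocks overlap, e.g. junction
    microhomology).  ``vector_first`` records which side of the read the
    vector segment occupies.  ``read_blocks`` keeps the read's full reduced
    block list for the intra-reference consistency check.
    """

    host: AlignmentBlock
    vector: AlignmentBlock
    gap: int
    vector_first: bool
    read_blocks: tuple[AlignmentBlock, ...] = ()


@dataclass
class JunctionCall:
    read_id: str
    chrom: str
    pos1: int
    side: str  # 'left'/'right': direction of the retained host flank
    vector_pos1: int
    vector_strand: str  # vector orientation relative to the host forward strand
    human_score: float
    vector_score: float
    gap: int


def extract_chimeric_candidates(
    blocks: Iterable[AlignmentBlock] | dict[str, list[AlignmentBlock]],
    reduce: bool = True,
) -> list[PairCandidate]:
    """Adjacent (host, vector) block pairs for every chimeric read.

    Reads mapping to only one reference class emit nothing.  A read whose
    blocks run host|vector|host yields two candidates (both junctions of a
    fully spanned insertion).  When one host block has vector neighbours on
    both sides, the pair with the smaller |gap| (then more vector matches)
    is kept: ITR duplication makes vector-side multimapping routine.
    """
    grouped = blocks if isinstance(blocks, dict) else group_by_read(blocks)
    candidates: list[PairCandidate] = []
    for read_id, blks in grouped.items():
        if reduce:
            blks = reduce_overlaps(blks)
        if not any(b.is_vector for b in blks) or all(b.is_vector for b in blks):
            continue
        per_host: dict[int, list[PairCandidate]] = {}
        for i in range(len(blks) - 1):
            up, down = blks[i], blks[i + 1]
            if up.is_vector == down.is_vector:
                continue
            gap = down.read_start - up.read_end
            if up.is_vector:
                cand = PairCandidate(down, up, gap, True, tuple(blks))
                per_host.setdefault(i + 1, []).append(cand)
            else:
                cand = PairCandidate(up, down, gap, False, tuple(blks))
                per_host.setdefault(i, []).append(cand)
        for cands in per_host.values():
            cands.sort(key=lambda c: (abs(c.gap), -c.vector.matches))
            candidates.append(cands[0])
    return candidates


def filter_pair(
    pair: PairCandidate,
    min_match_nt: int = DEFAULT_MIN_MATCH_NT,
    min_score: float = DEFAULT_MIN_SCORE,
) -> tuple[bool, str]:
    """Matched-base and identity thresholds on both segments.

    The matched-base threshold is a strict inequality: exactly
    ``min_match_nt`` matches rejects, ``min_match_nt + 1`` accepts.
    """
    if not pair.host.matches > min_match_nt:
        return False, "host_matches"
    if not pair.vector.matches > min_match_nt:
        return False, "vector_matches"
    if match_score(pair.host) < min_score:
        return False, "host_score"
    if match_score(pair.vector) < min_score:
        return False, "vector_score"
    return True, "ok"


def check_consistency(
    pair: PairCandidate, window: int = DEFAULT_WINDOW
) -> tuple[bool, str]:
    """Contiguity on the read and intra-reference collinearity.

    The vector and host blocks must abut within ``window`` nt on the read
    (|gap| <= window; overlaps count by absolute value).  When the read has
    several blocks on the *same* reference they must share strand and be
    collinear with the read order; inconsistency there indicates a mapping
    artifact rather than a junction.
    """
    if abs(pair.gap) > window:
        return False, "gap"
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in pair.read_blocks:
        by_ref.setdefault(b.ref_name, []).append(b)
    for blks in by_ref.values():
        if len(blks) < 2:
            continue
        strands = {b.strand for b in blks}
        if len(strands) > 1:
            return False, "strand_inconsistent"
        ordered = sorted(blks, key=lambda b: b.read_start)
        starts = [b.ref_start for b in ordered]
        if strands == {"+"}:
            ok = all(a <= b for a, b in zip(starts, starts[1:]))
        else:
            ok = all(a >= b for a, b in zip(starts, starts[1:]))
        if not ok:
            return False, "not_collinear"
    return True, "ok"


def derive_junction(pair: PairCandidate) -> JunctionCall:
    """Orientation-dependent junction coordinate from the host block.

    If the vector segment precedes the host segment on the read, the junction
    is the host block's read-upstream reference boundary; if it follows, the
    read-downstream boundary.  The boundary is converted to host forward-
    strand coordinates via the host block strand and reported 1-based.
    ``side`` is the direction in which the retained host flank extends.
    """
    h, v = pair.host, pair.vector
    if pair.vector_first:
        host_boundary_is_start = h.strand == "+"
    else:
        host_boundary_is_start = h.strand == "-"
    if host_boundary_is_start:
        pos1 = h.ref_start + 1
        side = "right"
    else:
        pos1 = h.ref_end
        side = "left"
    # vector boundary adjacent to the junction, mirrored logic
    if pair.vector_first:
        vec_boundary_is_end = v.strand == "+"
    else:
        vec_boundary_is_end = v.strand == "-"
    vector_pos1 = v.ref_end if vec_boundary_is_end else v.ref_start + 1
    return JunctionCall(
        read_id=h.read_id,
        chrom=h.ref_name,
        pos1=pos1,
        side=side,
        vector_pos1=vector_pos1,
        vector_strand="+" if v.strand == h.strand else "-",
        human_score=match_score(h),
        vector_score=match_score(v),
        gap=pair.gap,
    )


@dataclass
class StageCounts:
    """Per-stage survivor counts with rejection-reason histograms."""

    reads: int = 0
    candidates: int = 0
    filtered: int = 0
    consistent: int = 0
    reject_reasons: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.reject_reasons[reason] = self.reject_reasons.get(reason, 0) + 1


def call_junctions(
    blocks: Iterable[AlignmentBlock] | dict[str, list[AlignmentBlock]],
    min_match_nt: int = DEFAULT_MIN_MATCH_NT,
    min_score: float = DEFAULT_MIN_SCORE,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[JunctionCall], StageCounts]:
    """Candidate extraction, filtering, consistency check, and derivation."""
    grouped = blocks if isinstance(blocks, dict) else group_by_read(blocks)
    counts = StageCounts(reads=len(grouped))
    candidates = extract_chimeric_candidates(grouped)
    counts.candidates = len(candidates)
    calls: list[JunctionCall] = []
    for pair in candidates:
        ok, reason = filter_pair(pair, min_match_nt=min_match_nt, min_score=min_score)
        if not ok:
            counts.reject(reason)
            continue
        counts.filtered += 1
        ok, reason = check_consistency(pair, window=window)
        if not ok:
            counts.reject(reason)
            continue
        counts.consistent += 1
        calls.append(derive_junction(pair))
    logger.info(
        "short-read caller: %d reads, %d candidates, %d after thresholds, "
        "%d consistent; rejections %s",
        counts.reads, counts.candidates, counts.filtered,
        counts.consistent, counts.reject_reasons,
    )
    return calls, counts


ANNOTATION_COLUMNS = [
    "read_id", "chrom", "pos1", "side", "vector_pos1", "vector_strand",
    "human_score", "vector_score", "gap",
]


def aggregate(calls: Sequence[JunctionCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(summary, annotation) tables.

    The annotation table keeps every call with its read-level statistics.
    The summary groups calls by unique (chrom, pos1, side) and reports the
    distinct supporting-read count, sorted by support descending then
    coordinate.
    """
    annotation = pd.DataFrame(
        [[getattr(c, col) for col in ANNOTATION_COLUMNS] for c in calls],
        columns=ANNOTATION_COLUMNS,
    )
    if annotation.empty:
        summary = pd.DataFrame(
            columns=["chrom", "pos1", "side", "support", "read_ids"]
        )
        return summary, annotation
    grouped = (
        annotation.groupby(["chrom", "pos1", "side"])["read_id"]
        .agg(lambda s: sorted(set(s)))
        .reset_index()
    )
    grouped["support"] = grouped["read_id"].map(len)
    grouped["read_ids"] = grouped["read_id"].map(";".join)
    summary = grouped.drop(columns="read_id").sort_values(
        ["support", "chrom", "pos1", "side"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )[["chrom", "pos1", "side", "support", "read_ids"]].reset_index(drop=True)
    return summary, annotation
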