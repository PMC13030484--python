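"""End-to-end pipelines, cross-method concordance, and truth-based evaluation."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import junctions_long, junctions_short
from ._util import open_text
from .align import AlignmentBlock, SeedExtendAligner, group_by_read, reduce_overlaps
from .refmodel import HybridReference
from .simulate import PlantedJunction, SimRead

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of both callers; CLI flags map onto these fields."""

    k_long: int = 15
    k_short: int = 11
    min_block: int = 30
    min_match_nt: int = 35
    min_score: float = 0.9
    window_short: int = 20
    window_long: int = 50
    cluster_tol: int = 25
    min_support: int = 1
    r1_only: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    """Accept FASTQ path, SimRead sequence, or (id, seq) tuples."""
    if isinstance(reads, (str, bytes)):
        with open_text(str(reads)) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq)
        return
    for r in reads:
        if isinstance(r, SimRead):
            yield r.read_id, r.seq
        else:
            yield r[0], r[1]


@dataclass
class LongResult:
    events: list[junctions_long.IntegrationEvent]
    structures: list[junctions_long.VectorStructure]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def events_frame(self) -> pd.DataFrame:
        return junctions_long.events_to_frame(self.events)


def run_long_pipeline(
    reads,
    ref: HybridReference,
    config: PipelineConfig | None = None,
    aligner: SeedExtendAligner | None = None,
) -> LongResult:
    """Align -> adjacencies -> vector-host selection -> cluster -> rank.

    ``reads`` may be a FASTQ(.gz) path, SimRead records, or (id, seq) pairs.
    A prebuilt aligner for the same reference may be passed to avoid
    re-indexing.  Deterministic for fixed inputs.
    """
    cfg = config or PipelineConfig()
    if aligner is None:
        aligner = SeedExtendAligner(ref, k=cfg.k_long, min_block=cfg.min_block)
    n_reads = n_split = 0
    pairs: list[junctions_long.BreakendPair] = []
    structures: list[junctions_long.VectorStructure] = []
    for read_id, seq in _iter_reads(reads):
        n_reads += 1
        blocks = reduce_overlaps(aligner.align(read_id, seq))
        if len(blocks) >= 2:
            n_split += 1
            pairs.extend(junctions_long.derive_adjacencies(blocks))
        if sum(b.is_vector for b in blocks) >= 1:
            st = junctions_long.reconstruct_vector_structure(blocks)
            if st is not None and len(blocks) >= 2:
                structures.append(st)
    if n_reads == 0:
        logger.warning("long pipeline: empty input, no events")
    selected = junctions_long.select_vector_host(pairs, window=cfg.window_long)
    events = junctions_long.cluster_events(selected, tol=cfg.cluster_tol)
    events = [e for e in events if e.support >= cfg.min_support]
    junctions_long.rank_baseline(events)
    counts = {
        "reads": n_reads,
        "split_reads": n_split,
        "adjacencies": len(pairs),
        "vector_host_pairs": len(selected),
        "events": len(events),
    }
    logger.info("long pipeline stage counts: %s", counts)
    return LongResult(events=events, structures=structures, stage_counts=counts)


@dataclass
class ShortResult:
    summary: pd.DataFrame
    annotation: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_short_pipeline(
    r1,
    r2=None,
    ref: HybridReference | None = None,
    config: PipelineConfig | None = None,
    aligner: SeedExtendAligner | None = None,
) -> ShortResult:
    """Short-read caller over R1 (and optionally R2) reads.

    Both mates are processed independently by default; ``config.r1_only``
    restricts the analysis to R1, reproducing a workflow that extracts
    chimeric sequences from the first mate only.
    """
    cfg = config or PipelineConfig()
    if aligner is None:
        if ref is None:
            raise ValueError("either ref or a prebuilt aligner is required")
        aligner = SeedExtendAligner(ref, k=cfg.k_short, min_block=cfg.min_block)
    blocks: dict[str, list[AlignmentBlock]] = {}
    n_reads = 0
    sources = [r1] if (cfg.r1_only or r2 is None) else [r1, r2]
    for source in sources:
        for read_id, seq in _iter_reads(source):
            n_reads += 1
            got = aligner.align(read_id, seq)
            if got:
                blocks.setdefault(read_id, []).extend(got)
    if n_reads == 0:
        logger.warning("short pipeline: empty input, no junctions")
    grouped = group_by_read([b for lst in blocks.values() for b in lst])
    calls, counts = junctions_short.call_junctions(
        grouped,
        min_match_nt=cfg.min_match_nt,
        min_score=cfg.min_score,
        window=cfg.window_short,
    )
    summary, annotation = junctions_short.aggregate(calls)
    stage = {
        "reads": n_reads,
        "aligned_reads": len(grouped),
        "candidates": counts.candidates,
        "filtered": counts.filtered,
        "consistent": counts.consistent,
        "junctions": len(summary),
    }
    logger.info("short pipeline stage counts: %s", stage)
    return ShortResult(summary=summary, annotation=annotation, stage_counts=stage)


# ---------------------------------------------------------------------------
# cross-method concordance
# ---------------------------------------------------------------------------

CONCORDANCE_COLUMNS = ["chrom", "pos1_long", "pos1_short", "distance", "status"]


def compare_callsets(
    long_events, short_summary, tol: int = 10
) -> pd.DataFrame:
    """Greedy nearest matching of long- and short-mode sites per chromosome.

    Inputs are DataFrames (or objects exposing ``events_frame``/``summary``)
    with ``chrom`` and ``pos1`` columns.  Within each chromosome, the closest
    cross-method pair within ``tol`` is matched first, repeatedly; leftovers
    are labelled ``long_only`` / ``short_only``.  Matching is symmetric in
    the two callsets up to the status labels.
    """
    if isinstance(long_events, LongResult):
        long_events = long_events.events_frame
    if isinstance(short_summary, ShortResult):
        short_summary = short_summary.summary
    long_sites = (
        sorted(set(zip(long_events["chrom"], long_events["pos1"])))
        if len(long_events)
        else []
    )
    short_sites = (
        sorted(set(zip(short_summary["chrom"], short_summary["pos1"])))
        if len(short_summary)
        else []
    )
    rows = []
    chroms = sorted({c for c, _ in long_sites} | {c for c, _ in short_sites})
    for chrom in chroms:
        lp = sorted(p for c, p in long_sites if c == chrom)
        sp = sorted(p for c, p in short_sites if c == chrom)
        while lp and sp:
            best = min(
                ((abs(a - b), a, b) for a in lp for b in sp),
                key=lambda t: (t[0], t[1], t[2]),
            )
            dist, a, b = best
            if dist > tol:
                break
            rows.append([chrom, a, b, dist, "both"])
            lp.remove(a)
            sp.remove(b)
        rows.extend([chrom, a, None, None, "long_only"] for a in lp)
        rows.extend([chrom, None, b, None, "short_only"] for b in sp)
    return pd.DataFrame(rows, columns=CONCORDANCE_COLUMNS)


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    rows: pd.DataFrame  # per truth site: detected flag and coordinate error
    precision: float
    recall: float
    n_calls: int
    n_truth: int


def evaluate_against_truth(
    calls, truth: Sequence[PlantedJunction] | pd.DataFrame, tol: int = 10
) -> EvalReport:
    """Precision/recall of a callset against planted junctions.

    Each truth site greedily claims the nearest unmatched call on its
    chromosome within ``tol``; a call matches at most one truth site.
    Precision = matched calls / calls, recall = detected truths / truths.
    """
    if isinstance(calls, LongResult):
        calls = calls.events_frame
    elif isinstance(calls, ShortResult):
        calls = calls.summary
    call_sites = (
        [(c, int(p)) for c, p in zip(calls["chrom"], calls["pos1"])]
        if len(calls)
        else []
    )
    if isinstance(truth, pd.DataFrame):
        truth_sites = [
            (str(r.chrom), int(r.pos1), str(getattr(r, "side", "")))
            for r in truth.itertuples()
        ]
    else:
        truth_sites = [(t.chrom, t.pos1, t.side) for t in truth]
    unmatched = list(call_sites)
    rows = []
    matched_calls = 0
    for chrom, pos1, side in truth_sites:
        cands = [(abs(p - pos1), (c, p)) for c, p in unmatched if c == chrom]
        cands.sort()
        if cands and cands[0][0] <= tol:
            err, site = cands[0]
            unmatched.remove(site)
            matched_calls += 1
            rows.append([chrom, pos1, side, True, err])
        else:
            rows.append([chrom, pos1, side, False, None])
    n_calls = len(call_sites)
    n_truth = len(truth_sites)
    precision = matched_calls / n_calls if n_calls else 0.0
    recall = matched_calls / n_truth if n_truth else 0.0
    report = pd.DataFrame(
        rows, columns=["chrom", "pos1", "side", "detected", "error_nt"]
    )
    return EvalReport(
        rows=report,
        precision=precision,
        recall=recall,
        n_calls=n_calls,
        n_truth=n_truth,
    )
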