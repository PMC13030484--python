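"""Desk-scale validation scenarios emulating the study's library designs.

Each scenario builds a synthetic host, plants an integration, simulates a
library, runs the matching caller, and measures recovery against the planted
truth.  The same scenarios back the test suite and the acceptance script.

Problem sizes are deliberately desk-scale: a two-chromosome 200 kb host with
one planted single-copy integration, a couple hundred kilobase reads or a
few thousand short fragments.  These exercise every pipeline stage while a
full run stays in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import junctions_long
from .align import SeedExtendAligner, reduce_overlaps
from .pipeline import (
    LongResult,
    PipelineConfig,
    ShortResult,
    run_long_pipeline,
    run_short_pipeline,
)
from .refmodel import Genome, HybridReference, VectorModel, build_hybrid_reference
from .simulate import (
    EnrichmentParams,
    IntegrationTruth,
    LongReadParams,
    PlantedJunction,
    ShortReadParams,
    SimConfig,
    cassette_interval,
    plant_integration,
    simulate_host_genome,
    simulate_long_reads,
    simulate_short_pairs,
    simulate_vector,
)

HOST_LENGTHS = (120_000, 80_000)
HOST_GC = 0.41
VECTOR_LENGTH = 2928
ITR_LENGTH = 145
INSERT_CHROM = "chr1"
INSERT_POS1 = 60_000


@dataclass
class Scenario:
    """A planted clone plus everything needed to call and score it."""

    host: Genome
    vector: VectorModel
    clone: Genome
    truth: IntegrationTruth
    junctions: list[PlantedJunction]
    hybrid: HybridReference
    targets: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def junction_clone_positions(self) -> list[int]:
        return [j.clone_pos for j in self.junctions]

    def truth_for_side(self, side: str) -> PlantedJunction:
        return next(j for j in self.junctions if j.side == side)


def build_clone_scenario(
    seed: int = 1,
    segments: tuple[tuple[tuple[int, int], str], ...] | None = None,
    host_deletion: int = 0,
) -> Scenario:
    """Two-chromosome 200 kb host with one planted integration.

    By default a single full-length vector copy is inserted mid-chr1 without
    host deletion; ``segments`` overrides the integrated structure (partial
    deletions, concatemers, inversions).
    """
    host = simulate_host_genome(2, list(HOST_LENGTHS), gc=HOST_GC, seed=seed)
    vector = simulate_vector(VECTOR_LENGTH, ITR_LENGTH, seed=seed)
    if segments is None:
        segments = (((0, len(vector)), "+"),)
    truth = IntegrationTruth(
        clone_id=f"clone_s{seed}",
        chrom=INSERT_CHROM,
        pos1=INSERT_POS1,
        host_deletion=host_deletion,
        segments=segments,
    )
    clone, junctions = plant_integration(host, vector, truth, seed=seed)
    hybrid = build_hybrid_reference(host, vector)
    targets = [cassette_interval(truth, junctions)]
    return Scenario(
        host=host, vector=vector, clone=clone, truth=truth,
        junctions=junctions, hybrid=hybrid, targets=targets,
    )


# ---------------------------------------------------------------------------
# long-read round trip
# ---------------------------------------------------------------------------


@dataclass
class LongRoundTrip:
    scenario: Scenario
    result: LongResult
    baseline: junctions_long.IntegrationEvent | None
    baseline_truth: PlantedJunction | None
    coord_error: int | None
    expected_support: int | None


def _callable_spanning_reads(
    scenario: Scenario, truths, junction: PlantedJunction, min_block: int
) -> set[str]:
    """Reads whose fragment covers the junction with >= min_block on each side.

    The host-side flank is the fragment overhang beyond the junction away
    from the insert; the vector-side flank is capped at the insert extent.
    """
    j = junction.clone_pos
    positions = sorted(set(t.clone_pos for t in scenario.junctions))
    lo, hi = positions[0], positions[-1]
    wanted = set()
    for t in truths:
        if t.chrom != scenario.truth.chrom or not (t.start < j < t.end):
            continue
        if junction.side == "left":
            host_flank = j - t.start
            vec_flank = min(t.end, hi) - j
        else:
            host_flank = t.end - j
            vec_flank = j - max(t.start, lo)
        if host_flank >= min_block and vec_flank >= min_block:
            wanted.add(t.read_id)
    return wanted


def long_roundtrip(
    seed: int = 1,
    n_reads: int = 200,
    error_free: bool = True,
    on_target: float = 0.9,
    config: PipelineConfig | None = None,
) -> LongRoundTrip:
    """Simulate a long-read library over the planted clone and call it.

    With ``error_free=True`` reads are exact clone substrings; recovery of
    the baseline coordinate is then expected to be exact and its support to
    equal the number of callable junction-spanning reads.
    """
    scenario = build_clone_scenario(seed=seed)
    lr = (
        LongReadParams(sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        if error_free
        else LongReadParams()
    )
    cfg = SimConfig(
        seed=seed,
        long_read=lr,
        enrichment=EnrichmentParams(on_target_fraction=on_target),
    )
    reads, truths = simulate_long_reads(
        scenario.clone, n_reads, cfg,
        targets=scenario.targets,
        junction_positions=scenario.junction_clone_positions,
        junction_chrom=scenario.truth.chrom,
    )
    pcfg = config or PipelineConfig()
    result = run_long_pipeline(reads, scenario.hybrid, pcfg)
    baseline = next((e for e in result.events if e.is_baseline), None)
    if baseline is None:
        return LongRoundTrip(scenario, result, None, None, None, None)
    bt = scenario.truth_for_side(baseline.side)
    expected = _callable_spanning_reads(scenario, truths, bt, pcfg.min_block)
    return LongRoundTrip(
        scenario=scenario,
        result=result,
        baseline=baseline,
        baseline_truth=bt,
        coord_error=abs(baseline.pos1 - bt.pos1),
        expected_support=len(expected),
    )


# ---------------------------------------------------------------------------
# short-read round trip
# ---------------------------------------------------------------------------


@dataclass
class ShortRoundTrip:
    scenario: Scenario
    result: ShortResult
    top_coord_error: int | None


def short_roundtrip(
    seed: int = 1,
    n_fragments: int = 5000,
    sub_rate: float = 0.0,
    on_target: float = 0.95,
    config: PipelineConfig | None = None,
) -> ShortRoundTrip:
    """Simulate a capture-style short-read library and call junctions.

    Returns the distance between the top summary row and the planted truth
    coordinate for the corresponding junction side.
    """
    scenario = build_clone_scenario(seed=seed)
    cfg = SimConfig(
        seed=seed,
        short_read=ShortReadParams(sub_rate=sub_rate),
        enrichment=EnrichmentParams(on_target_fraction=on_target),
    )
    r1, r2, _ = simulate_short_pairs(
        scenario.clone, n_fragments, cfg,
        targets=scenario.targets,
        junction_positions=scenario.junction_clone_positions,
        junction_chrom=scenario.truth.chrom,
    )
    result = run_short_pipeline(r1, r2, scenario.hybrid, config or PipelineConfig())
    if result.summary.empty:
        return ShortRoundTrip(scenario, result, None)
    top = result.summary.iloc[0]
    bt = scenario.truth_for_side(str(top["side"]))
    err = abs(int(top["pos1"]) - bt.pos1) if str(top["chrom"]) == bt.chrom else None
    return ShortRoundTrip(scenario=scenario, result=result, top_coord_error=err)


# ---------------------------------------------------------------------------
# negative control
# ---------------------------------------------------------------------------


def negative_control(seed: int = 1, n_long: int = 60, n_fragments: int = 400):
    """Reads from the untransduced host through both pipelines.

    Mirrors an untransduced negative-control sample: no vector sequence is
    present, so both callers must return zero junctions.
    """
    host = simulate_host_genome(2, [60_000, 40_000], gc=HOST_GC, seed=seed)
    vector = simulate_vector(VECTOR_LENGTH, ITR_LENGTH, seed=seed)
    hybrid = build_hybrid_reference(host, vector)
    cfg = SimConfig(seed=seed, long_read=LongReadParams(mean_len=6000))
    reads, _ = simulate_long_reads(host, n_long, cfg)
    long_result = run_long_pipeline(reads, hybrid)
    r1, r2, _ = simulate_short_pairs(host, n_fragments, cfg)
    short_result = run_short_pipeline(r1, r2, hybrid)
    return long_result, short_result


# ---------------------------------------------------------------------------
# structure reconstruction
# ---------------------------------------------------------------------------


def structure_examples(seed: int = 1, flank: int = 600) -> dict[str, junctions_long.VectorStructure]:
    """Error-free reads over a partial-deletion clone and a concatemer clone.

    Returns reconstructed structures keyed 'deletion' and 'concatemer'.
    The deletion clone integrates vector [0,1200)+[2500,2928) (an internal
    deletion of 1300 nt); the concatemer clone integrates two head-to-tail
    full-length copies.
    """
    out: dict[str, junctions_long.VectorStructure] = {}
    cases = {
        "deletion": (((0, 1200), "+"), ((2500, VECTOR_LENGTH), "+")),
        "concatemer": (((0, VECTOR_LENGTH), "+"), ((0, VECTOR_LENGTH), "+")),
    }
    for label, segments in cases.items():
        sc = build_clone_scenario(seed=seed, segments=segments)
        lo = min(sc.junction_clone_positions) - flank
        hi = max(sc.junction_clone_positions) + flank
        read = sc.clone.sequences[sc.truth.chrom][lo:hi]
        aligner = SeedExtendAligner(sc.hybrid, k=15, min_block=30)
        blocks = reduce_overlaps(aligner.align(f"{label}_read", read))
        st = junctions_long.reconstruct_vector_structure(blocks)
        if st is not None:
            out[label] = st
    return out


# ---------------------------------------------------------------------------
# internal aligner vs exhaustive oracle
# ---------------------------------------------------------------------------


def oracle_instances(n: int = 200, seed: int = 1):
    """Random (read, reference) pairs with one planted locus.

    The read is a copy of a reference interval with a few interior
    substitutions (never within 6 nt of either end, so the optimal local
    alignment is the unique full-read placement), aligned on either strand.
    """
    from ._util import revcomp

    rng = np.random.default_rng([seed, 606])
    bases = np.array(list("ACGT"))
    for i in range(n):
        ref_len = int(rng.integers(400, 2001))
        read_len = int(rng.integers(80, 201))
        ref = "".join(rng.choice(bases, size=ref_len))
        start = int(rng.integers(0, ref_len - read_len + 1))
        read = ref[start : start + read_len]
        n_sub = int(rng.integers(0, 4))
        if n_sub:
            pos = rng.choice(np.arange(6, read_len - 6), size=n_sub, replace=False)
            chars = list(read)
            for p in pos:
                alts = [b for b in "ACGT" if b != chars[p]]
                chars[p] = alts[int(rng.integers(3))]
            read = "".join(chars)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            read = revcomp(read)
        yield i, read, ref, start, start + read_len, strand
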