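import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aavjunct._util import revcomp
from aavjunct.simulate import (
    EnrichmentParams,
    IntegrationTruth,
    LongReadParams,
    ShortReadParams,
    SimConfig,
    JUNCTION_KMER,
    cassette_interval,
    plant_integration,
    simulate_host_genome,
    simulate_long_reads,
    simulate_short_pairs,
    simulate_vector,
)

ERROR_FREE = SimConfig(
    seed=3,
    long_read=LongReadParams(mean_len=2000, sd_len=300, sub_rate=0, ins_rate=0, del_rate=0),
    short_read=ShortReadParams(sub_rate=0),
)


class TestHostGenome:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_host_genome(2, [5000, 4000], gc=0.41, seed=7)
        b = simulate_host_genome(2, [5000, 4000], gc=0.41, seed=7)
        assert a.sequences == b.sequences

    def test_degenerate_gc_one(self):
        g = simulate_host_genome(1, [2000], gc=1.0, seed=1)
        assert set(g.sequences["chr1"]) <= {"G", "C"}

    def test_gc_concentrates_around_request(self):
        g = simulate_host_genome(1, [100_000], gc=0.5, seed=5)
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52


class TestVector:
    def test_itr_intervals_and_length(self):
        v = simulate_vector(2928, 145, seed=1)
        assert len(v) == 2928
        assert v.itr_intervals == ((0, 145), (2783, 2928))
        assert v.sequence[:145] == v.sequence[2783:]  # identical terminal repeats

    def test_itrs_are_imperfect_palindromes(self):
        v = simulate_vector(2928, 145, seed=2)
        for s, e in v.itr_intervals:
            itr = v.sequence[s:e]
            ident = sum(a == b for a, b in zip(itr, revcomp(itr))) / len(itr)
            assert ident >= 0.8

    def test_features_partition_interior(self):
        v = simulate_vector(2928, 145, seed=3)
        intervals = [iv for _, iv in v.features]
        assert intervals[0][0] == 145 and intervals[-1][1] == 2783
        for (_, e0), (s1, _) in zip(intervals, intervals[1:]):
            assert e0 == s1

    def test_zero_itr_still_valid(self):
        v = simulate_vector(1000, 0, seed=1)
        assert v.itr_intervals == () and len(v) == 1000

    def test_deterministic(self):
        assert simulate_vector(2928, 145, seed=9).sequence == simulate_vector(
            2928, 145, seed=9
        ).sequence


class TestPlantIntegration:
    def test_full_length_insertion_conserves_length(self, host_small, vector, planted):
        truth, clone, _ = planted
        assert len(clone.sequences["chr1"]) == len(host_small.sequences["chr1"]) + len(vector)
        assert clone.sequences["chr2"] == host_small.sequences["chr2"]

    def test_concatemer_and_partial_structures(self, host_small, vector):
        L = len(vector)
        concat = IntegrationTruth(
            "c", "chr1", 3000, segments=(((0, L), "+"), ((0, L), "+"))
        )
        clone, _ = plant_integration(host_small, vector, concat)
        assert len(clone.sequences["chr1"]) == 6000 + 2 * L
        partial = IntegrationTruth(
            "p", "chr1", 3000, segments=(((0, 1200), "+"), ((2500, L), "+"))
        )
        clone, _ = plant_integration(host_small, vector, partial)
        assert len(clone.sequences["chr1"]) == 6000 + 1200 + (L - 2500)

    @given(
        deletion=st.integers(0, 40),
        li=st.integers(-30, 30),
        ri=st.integers(-30, 30),
        minus=st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_length_conservation_property(self, host_small, vector, deletion, li, ri, minus):
        seg = ((100, 900), "-" if minus else "+")
        truth = IntegrationTruth(
            "x", "chr1", 2500, host_deletion=deletion,
            segments=(seg,), junction_indels=(li, ri),
        )
        clone, junctions = plant_integration(host_small, vector, truth, seed=5)
        expected = 6000 - deletion + 800 + li + ri
        assert len(clone.sequences["chr1"]) == expected
        left = next(j for j in junctions if j.side == "left")
        right = next(j for j in junctions if j.side == "right")
        assert right.clone_pos - left.clone_pos == 800 + li + ri

    def test_out_of_bounds_rejected(self, host_small, vector):
        with pytest.raises(ValueError):
            plant_integration(
                host_small, vector,
                IntegrationTruth("x", "chr1", 10**7, segments=(((0, 100), "+"),)),
            )
        with pytest.raises(ValueError):
            plant_integration(
                host_small, vector,
                IntegrationTruth("x", "chr1", 100, segments=(((0, 10**6), "+"),)),
            )

    def test_junction_string_round_trip(self, planted):
        """Error-free junction-spanning reads contain the exact 2k junction k-mer."""
        truth, clone, junctions = planted
        k = JUNCTION_KMER
        seq = clone.sequences[truth.chrom]
        cfg = SimConfig(
            seed=4,
            long_read=LongReadParams(mean_len=1500, sd_len=200, sub_rate=0, ins_rate=0, del_rate=0),
            enrichment=EnrichmentParams(on_target_fraction=1.0),
        )
        reads, read_truths = simulate_long_reads(
            clone, 50, cfg,
            targets=[cassette_interval(truth, junctions)],
            junction_positions=[j.clone_pos for j in junctions],
            junction_chrom=truth.chrom,
        )
        by_id = {r.read_id: r for r in reads}
        n_span = 0
        for rt in read_truths:
            if not rt.spans_junction:
                continue
            n_span += 1
            for j, lf, rf in rt.junction_flanks:
                if lf < k or rf < k:
                    continue
                junction_kmer = seq[j - k : j + k]
                read = by_id[rt.read_id]
                assert junction_kmer in read.seq or revcomp(junction_kmer) in read.seq
        assert n_span > 0


class TestLongReads:
    def test_error_free_reads_are_genome_substrings(self, planted):
        truth, clone, _ = planted
        reads, read_truths = simulate_long_reads(clone, 20, ERROR_FREE)
        for r, t in zip(reads, read_truths):
            frag = clone.sequences[t.chrom][t.start : t.end]
            assert r.seq == (frag if t.strand == "+" else revcomp(frag))

    def test_enrichment_limit_every_fragment_on_target(self, planted):
        truth, clone, junctions = planted
        cfg = SimConfig(
            seed=8,
            long_read=LongReadParams(mean_len=1000, sd_len=100, sub_rate=0, ins_rate=0, del_rate=0),
            enrichment=EnrichmentParams(on_target_fraction=1.0),
        )
        target = cassette_interval(truth, junctions)
        _, read_truths = simulate_long_reads(clone, 50, cfg, targets=[target])
        _, t0, t1 = target
        for t in read_truths:
            assert t.chrom == truth.chrom
            assert t.start < t1 and t.end > t0

    def test_deterministic_for_fixed_seed(self, planted):
        _, clone, _ = planted
        a, _ = simulate_long_reads(clone, 10, ERROR_FREE)
        b, _ = simulate_long_reads(clone, 10, ERROR_FREE)
        assert [(r.read_id, r.seq) for r in a] == [(r.read_id, r.seq) for r in b]

    def test_spanning_count_matches_coverage_oracle(self, host_small, vector):
        """Junction-spanning read count agrees with the coverage integral."""
        from aavjunct.refmodel import build_validation_reference

        ref = build_validation_reference(host_small, vector, "chr1", 3000, flank=1500)
        (name, seq), = ref.sequences.items()
        L = len(seq)
        j = 1500  # left junction position inside the validation reference
        n = 500
        cfg = SimConfig(
            seed=13,
            long_read=LongReadParams(mean_len=2500, sd_len=400, sub_rate=0, ins_rate=0, del_rate=0),
        )
        _, truths = simulate_long_reads(
            ref, n, cfg, junction_positions=[j], junction_chrom=name
        )
        observed = sum(t.spans_junction for t in truths)
        # oracle: P(start <= j-k and min(start+len, L) >= j+k), start ~ U{0..L-1},
        # len ~ round(Normal) truncated at 100, marginalised over the length pmf
        k = JUNCTION_KMER
        lengths = np.arange(100, int(cfg.long_read.mean_len + 6 * cfg.long_read.sd_len))
        from scipy.stats import norm

        pmf = norm.pdf(lengths, cfg.long_read.mean_len, cfg.long_read.sd_len)
        pmf[0] += norm.cdf(100, cfg.long_read.mean_len, cfg.long_read.sd_len)
        pmf /= pmf.sum()
        lo = np.maximum(0, j + k - lengths)  # smallest start covering j+k
        hi = j - k  # largest start covering j-k
        counts = np.clip(hi - lo + 1, 0, None)
        p = float((pmf * counts).sum() / L)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) <= 3 * sd


class TestShortPairs:
    def test_pair_geometry_exact_substrings(self, planted):
        _, clone, _ = planted
        cfg = SimConfig(
            seed=6,
            short_read=ShortReadParams(fragment_mean=250, fragment_sd=0, read_len=150, sub_rate=0),
        )
        r1s, r2s, truths = simulate_short_pairs(clone, 10, cfg)
        for r1, r2, t in zip(r1s, r2s, truths):
            frag = clone.sequences[t.chrom][t.start : t.end]
            oriented = frag if t.strand == "+" else revcomp(frag)
            assert r1.seq == oriented[:150]
            assert r2.seq == revcomp(oriented)[:150]
            if t.end - t.start == 250:
                # 150 + 150 - 250 = 50 nt overlap in the fragment middle
                assert r1.seq[100:150] == revcomp(r2.seq)[:50]

    def test_reads_truncated_to_short_fragments(self, planted):
        _, clone, _ = planted
        cfg = SimConfig(
            seed=6,
            short_read=ShortReadParams(fragment_mean=80, fragment_sd=0, read_len=150, sub_rate=0),
        )
        r1s, r2s, truths = simulate_short_pairs(clone, 5, cfg)
        for r1, r2, t in zip(r1s, r2s, truths):
            assert len(r1.seq) == t.end - t.start <= 150
            assert revcomp(r2.seq) == r1.seq

    def test_deterministic_fastq_bytes(self, planted, tmp_path):
        from aavjunct.simulate import write_fastq

        _, clone, _ = planted
        cfg = SimConfig(seed=2)
        paths = []
        for run in (1, 2):
            r1s, _, _ = simulate_short_pairs(clone, 20, cfg)
            p = tmp_path / f"run{run}.fastq"
            write_fastq(r1s, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestConfigValidation:
    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(long_read=LongReadParams(sub_rate=1.5))
        with pytest.raises(ValueError):
            SimConfig(enrichment=EnrichmentParams(on_target_fraction=2.0))
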