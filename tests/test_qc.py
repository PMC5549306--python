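import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import grid_map
from cnvfam import qc
from cnvfam.types import BlacklistRegion, CallSource, CnvCall, CnvState


def call_from_probes(probe_lo, probe_hi, state=CnvState.DELETION, sample="S1",
                     chrom="chr1", start=1000, spacing=1000, source=CallSource.CALLER_A):
    """Call spanning probes [probe_lo, probe_hi] of a grid_map."""
    return CnvCall(
        sample_id=sample,
        chrom=chrom,
        start_bp=start + probe_lo * spacing,
        end_bp=start + probe_hi * spacing,
        state=state,
        num_snps=probe_hi - probe_lo + 1,
        source=source,
    )


def layout_calls(lengths_and_gaps):
    """Alternating (call_length, following_gap) probe layout -> calls."""
    calls, probe = [], 0
    for length, gap in lengths_and_gaps:
        calls.append(call_from_probes(probe, probe + length - 1))
        probe += length + gap
    return calls, probe


def merge_oracle(calls, positions, gap_fraction=0.2):
    """Independent fixed-point merger: re-scan every adjacent pair until no
    change, merging when the probe gap is < gap_fraction of both neighbours'
    probe counts."""
    def probes_in(lo, hi):
        return sum(1 for p in positions if lo <= p <= hi)

    spans = sorted((c.start_bp, c.end_bp) for c in calls)
    changed = True
    while changed:
        changed = False
        for i in range(len(spans) - 1):
            (s1, e1), (s2, e2) = spans[i], spans[i + 1]
            gap = sum(1 for p in positions if e1 < p < s2)
            if gap < gap_fraction * probes_in(s1, e1) and gap < gap_fraction * probes_in(s2, e2):
                spans[i : i + 2] = [(s1, e2)]
                changed = True
                break
    return spans


class TestMergeAdjacent:
    def test_small_gap_merges(self):
        calls, n = layout_calls([(50, 5), (40, 0)])
        snp_map = grid_map(n)
        (merged,) = qc.merge_adjacent_calls(calls, snp_map)
        assert merged.num_snps == 95  # 50 + 40 + the 5 gap probes
        assert (merged.start_bp, merged.end_bp) == (calls[0].start_bp, calls[1].end_bp)

    def test_wide_gap_does_not_merge(self):
        calls, n = layout_calls([(50, 9), (40, 0)])  # 9 >= 0.2 * 40
        assert len(qc.merge_adjacent_calls(calls, grid_map(n))) == 2

    def test_chain_merges_to_fixed_point(self):
        # the middle pair only becomes mergeable after the first pair fuses
        calls, n = layout_calls([(10, 1), (30, 7), (40, 0)])
        snp_map = grid_map(n)
        assert len(qc.merge_adjacent_calls(calls[1:], snp_map)) == 2  # B,C alone: no merge
        (merged,) = qc.merge_adjacent_calls(calls, snp_map)
        assert merged.num_snps == 10 + 1 + 30 + 7 + 40

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 30), st.integers(1, 12)), min_size=1, max_size=8
        )
    )
    def test_matches_rescan_oracle_and_idempotent(self, layout):
        calls, n = layout_calls(layout)
        snp_map = grid_map(n + 1)
        positions = [l.position_bp for l in snp_map]
        merged = qc.merge_adjacent_calls(calls, snp_map)
        assert [(c.start_bp, c.end_bp) for c in merged] == merge_oracle(calls, positions)
        assert qc.merge_adjacent_calls(merged, snp_map) == merged
        # probe conservation: merged calls cover all original probes
        assert sum(c.num_snps for c in merged) >= sum(c.num_snps for c in calls)

    def test_either_rule_is_more_permissive(self):
        # gap 7 < 0.2*40 but >= 0.2*30: merges only under the 'either' reading
        calls, n = layout_calls([(30, 7), (40, 0)])
        snp_map = grid_map(n)
        assert len(qc.merge_adjacent_calls(calls, snp_map)) == 2
        cfg = qc.QcConfig(gap_rule="either")
        assert len(qc.merge_adjacent_calls(calls, snp_map, cfg)) == 1

    def test_probe_free_call_rejected(self):
        snp_map = grid_map(5)
        orphan = CnvCall("S1", "chr1", 100, 900, CnvState.DELETION, 3)
        with pytest.raises(ValueError, match="no probe"):
            qc.merge_adjacent_calls([orphan], snp_map)


class TestSmallCallFilter:
    @pytest.mark.parametrize(
        "num_snps,length,kept",
        [
            (9, 50_000, False),   # too few probes
            (12, 9_999, False),   # too short
            (10, 10_000, True),   # both thresholds inclusive
            (9, 9_999, False),
        ],
    )
    def test_boundaries(self, num_snps, length, kept):
        call = CnvCall("S1", "chr1", 1000, 1000 + length - 1, CnvState.DELETION, num_snps)
        assert (qc.filter_small_calls([call]) == [call]) is kept


class TestBlacklist:
    REGION = BlacklistRegion("chr1", 200, 300, "telomere")

    def test_one_bp_overlap_removes(self):
        call = CnvCall("S1", "chr1", 100, 200, CnvState.DELETION, 10)
        assert qc.filter_blacklist([call], [self.REGION]) == []

    def test_adjacent_but_disjoint_kept(self):
        call = CnvCall("S1", "chr1", 100, 199, CnvState.DELETION, 10)
        assert qc.filter_blacklist([call], [self.REGION]) == [call]

    def test_empty_blacklist_identity(self):
        calls = [CnvCall("S1", "chr1", 100, 199, CnvState.DELETION, 10)]
        assert qc.filter_blacklist(calls, []) == calls


class TestSampleQc:
    def metrics(self, lrr=0.20, a=50, b=50, sid="S1"):
        return qc.SampleQcMetrics(
            sample_id=sid,
            lrr_sd=lrr,
            n_calls_by_source={CallSource.CALLER_A: a, CallSource.CALLER_B: b},
        )

    @pytest.mark.parametrize(
        "lrr,a,b,passes",
        [
            (0.36, 50, 50, False),   # noisy intensity
            (0.35, 200, 100, True),  # equality passes everywhere
            (0.20, 50, 101, False),  # too many PennCNV-like calls
            (0.20, 201, 50, False),  # too many Birdseye-like calls
        ],
    )
    def test_thresholds(self, lrr, a, b, passes):
        passing = qc.sample_qc([self.metrics(lrr, a, b)])
        assert ("S1" in passing) is passes


class TestConsensus:
    def test_overlap_intersected(self):
        snp_map = grid_map(300, start=1)  # probes at 1, 1001, ...
        a = CnvCall("S1", "chr1", 100, 100250, CnvState.DELETION, 100, source=CallSource.CALLER_A)
        b = CnvCall("S1", "chr1", 50150, 200300, CnvState.DELETION, 150, source=CallSource.CALLER_B)
        (cons,) = qc.consensus_intersect([a], [b], snp_map)
        assert (cons.start_bp, cons.end_bp) == (50150, 100250)
        assert cons.source is CallSource.CONSENSUS
        # probes recomputed from the map over the intersected span
        assert cons.num_snps == sum(1 for l in snp_map if 50150 <= l.position_bp <= 100250)

    def test_state_mismatch_never_intersects(self):
        snp_map = grid_map(300)
        a = CnvCall("S1", "chr1", 1000, 250000, CnvState.DELETION, 100)
        b = CnvCall("S1", "chr1", 150000, 280000, CnvState.DUPLICATION, 100, 3)
        assert qc.consensus_intersect([a], [b], snp_map) == []

    def test_self_consensus_is_identity(self, rng):
        snp_map = grid_map(500)
        calls = []
        probe = 0
        for _ in range(6):
            length = int(rng.integers(5, 40))
            calls.append(call_from_probes(probe, probe + length - 1))
            probe += length + int(rng.integers(2, 10))
        cons = qc.consensus_intersect(calls, calls, snp_map)
        assert [(c.start_bp, c.end_bp, c.num_snps) for c in cons] == [
            (c.start_bp, c.end_bp, c.num_snps) for c in calls
        ]

    def test_per_base_subset_oracle(self, rng):
        """Every consensus base is covered by a same-state call in both
        inputs, and together they cover exactly the per-base intersection
        (brute-force over instances confined to 10 kb)."""
        snp_map = grid_map(100, start=1, spacing=100)  # 10 kb, dense probes
        for _ in range(20):
            def random_calls(source):
                calls, pos = [], 1
                while pos < 9000:
                    length = int(rng.integers(200, 3000))
                    if rng.random() < 0.5:
                        calls.append(
                            CnvCall("S1", "chr1", pos, min(pos + length, 10000),
                                    CnvState.DELETION, 1, source=source)
                        )
                    pos += length + int(rng.integers(100, 2000))
                return calls

            a, b = random_calls(CallSource.CALLER_A), random_calls(CallSource.CALLER_B)
            cons = qc.consensus_intersect(a, b, snp_map)
            base_a = {p for c in a for p in range(c.start_bp, c.end_bp + 1)}
            base_b = {p for c in b for p in range(c.start_bp, c.end_bp + 1)}
            base_c = {p for c in cons for p in range(c.start_bp, c.end_bp + 1)}
            assert base_c <= (base_a & base_b)
            # bases lost from the exact intersection carry no probe
            probe_positions = {l.position_bp for l in snp_map}
            assert ((base_a & base_b) - base_c) & probe_positions == set()


class TestStage2Pipeline:
    def test_conservation_of_counts(self, tiny_cohort):
        c = tiny_cohort
        consensus, passing, report = qc.stage2_qc(
            c.calls_caller_a, c.calls_caller_b, c.snp_map, [], c.lrr_sd
        )
        for caller in ("callerA", "callerB"):
            assert report.n_input[caller] == (
                report.n_merged_away[caller]
                + report.n_small_removed[caller]
                + report.n_blacklist_removed[caller]
                + report.n_sample_removed[caller]
                + report.n_surviving[caller]
            )
        assert report.n_consensus == len(consensus)
        assert all(c_.sample_id in passing for c_ in consensus)

    def test_sample_without_metrics_fails_qc(self, tiny_cohort):
        c = tiny_cohort
        lrr = dict(c.lrr_sd)
        victim = c.sample_ids[0]
        del lrr[victim]
        _, passing, _ = qc.stage2_qc(c.calls_caller_a, c.calls_caller_b, c.snp_map, [], lrr)
        assert victim not in passing


def test_qc_config_validation():
    with pytest.raises(ValueError):
        qc.QcConfig(gap_fraction=1.5)
    with pytest.raises(ValueError):
        qc.QcConfig(min_snps=0)
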