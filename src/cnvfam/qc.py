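"""Stage-2 quality control on CNV calls and consensus construction.

Per caller, and per sample/chromosome/state: adjacent same-state calls are
merged when the probe gap between them is small relative to both neighbours,
calls with too few probes or too little span are dropped, calls touching
blacklist regions are dropped, and noisy samples (high intensity-ratio SD or
excessive call counts) are removed. Consensus calls are then the base-pair
intersections of same-state calls from the two callers.

Gap and CNV lengths in the merge rule are measured in probe counts, not base
pairs. The small-call thresholds keep calls at the boundary (>=10 probes,
>=10 kb) because the removal rules are strict inequalities ("less than 10
SNPs", "smaller than 10 kb"); the sample filters likewise pass equality
(0.35 SD, 100/200 calls) and fail only strictly above.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import BlacklistRegion, CallSource, CnvCall, CnvState, SnpLocus

log = logging.getLogger(__name__)


@dataclass
class QcConfig:
    """Thresholds for stage-2 QC.

    gap_fraction
        Merge two adjacent same-state calls when the probe gap between them
        is below this fraction of the probe length of the neighbouring calls
        (of both neighbours by default, see ``gap_rule``).
    min_snps / min_length_bp
        Keep a call only with at least this many probes and this many base
        pairs (inclusive thresholds).
    lrr_sd_max
        Maximum per-sample standard deviation of the log intensity ratio.
    max_calls_caller_a / max_calls_caller_b
        Per-sample call-count caps (the Birdseye-like caller produces many
        more calls than the PennCNV-like caller, hence 200 vs 100).
    gap_rule
        "both": gap must be < gap_fraction x probes of each neighbour
        (conservative reading); "either": of at least one neighbour.
    blacklist_min_overlap_bp
        A call is removed when it overlaps a blacklist region by at least
        this many base pairs (default 1: any overlap).
    """

    gap_fraction: float = 0.20
    min_snps: int = 10
    min_length_bp: int = 10_000
    lrr_sd_max: float = 0.35
    max_calls_caller_a: int = 200
    max_calls_caller_b: int = 100
    gap_rule: str = "both"
    blacklist_min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must be in (0, 1)")
        for name in ("min_snps", "min_length_bp", "lrr_sd_max", "max_calls_caller_a",
                     "max_calls_caller_b", "blacklist_min_overlap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gap_rule not in ("both", "either"):
            raise ValueError("gap_rule must be 'both' or 'either'")


@dataclass
class SampleQcMetrics:
    """Per-sample QC metrics: intensity-ratio SD and call counts by source."""

    sample_id: str
    lrr_sd: float
    n_calls_by_source: dict[CallSource, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lrr_sd < 0:
            raise ValueError("lrr_sd must be >= 0")
        if any(v < 0 for v in self.n_calls_by_source.values()):
            raise ValueError("call counts must be >= 0")


@dataclass
class QcReport:
    """Per-step removal counts (conservation: in = out + removed)."""

    n_input: dict[str, int] = field(default_factory=dict)
    n_merged_away: dict[str, int] = field(default_factory=dict)
    n_small_removed: dict[str, int] = field(default_factory=dict)
    n_blacklist_removed: dict[str, int] = field(default_factory=dict)
    n_sample_removed: dict[str, int] = field(default_factory=dict)
    n_surviving: dict[str, int] = field(default_factory=dict)
    failed_samples: dict[str, set[str]] = field(default_factory=dict)
    n_consensus: int = 0


class ProbeIndex:
    """Probe positions per chromosome with O(log n) interval counts."""

    def __init__(self, snp_map: Sequence[SnpLocus]):
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for locus in snp_map:
            by_chrom[locus.chrom].append(locus.position_bp)
        self.positions = {c: np.array(sorted(p), dtype=np.int64) for c, p in by_chrom.items()}

    def count_in(self, chrom: str, start_bp: int, end_bp: int) -> int:
        """Probes within [start_bp, end_bp], closed interval."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end_bp, "right") - np.searchsorted(pos, start_bp, "left"))

    def count_between(self, chrom: str, left_end: int, right_start: int) -> int:
        """Probes strictly between two calls: in (left_end, right_start)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, right_start, "left") - np.searchsorted(pos, left_end, "right"))


def _probe_len(call: CnvCall, index: ProbeIndex) -> int:
    n = index.count_in(call.chrom, call.start_bp, call.end_bp)
    if n == 0:
        raise ValueError(
            f"call {call.sample_id} {call.chrom}:{call.start_bp}-{call.end_bp} "
            "covers no probe in the SNP map"
        )
    return n


def merge_adjacent_calls(
    calls: Sequence[CnvCall],
    snp_map: Sequence[SnpLocus] | ProbeIndex,
    cfg: Optional[QcConfig] = None,
) -> list[CnvCall]:
    """Merge adjacent same-state calls of one sample/chromosome separated by
    small probe gaps, iterating to a fixed point.

    Two neighbouring calls merge when the number of map probes strictly
    between them is below ``gap_fraction`` times the probe length of both
    neighbours (or of either one under ``gap_rule="either"``). The merged
    call spans both originals, and its probe count is recomputed from the
    map (probes of both calls plus the gap probes).
    """
    cfg = cfg or QcConfig()
    if not calls:
        return []
    index = snp_map if isinstance(snp_map, ProbeIndex) else ProbeIndex(snp_map)
    sample, chrom, state = calls[0].sample_id, calls[0].chrom, calls[0].state
    for c in calls:
        if (c.sample_id, c.chrom, c.state) != (sample, chrom, state):
            raise ValueError("merge_adjacent_calls expects calls of one sample, chromosome and state")
    current = sorted(calls, key=lambda c: c.start_bp)
    for a, b in zip(current, current[1:]):
        if b.start_bp <= a.end_bp:
            raise ValueError("merge_adjacent_calls expects non-overlapping calls")
    for c in current:
        _probe_len(c, index)  # map/call mismatch surfaces before merging

    changed = True
    while changed:
        changed = False
        merged: list[CnvCall] = [current[0]]
        for nxt in current[1:]:
            prev = merged[-1]
            gap = index.count_between(chrom, prev.end_bp, nxt.start_bp)
            len_prev = _probe_len(prev, index)
            len_next = _probe_len(nxt, index)
            lo, hi = sorted((len_prev, len_next))
            limit = lo if cfg.gap_rule == "both" else hi
            if gap < cfg.gap_fraction * limit:
                cn = prev.copy_number if prev.copy_number == nxt.copy_number else None
                merged[-1] = CnvCall(
                    sample_id=sample,
                    chrom=chrom,
                    start_bp=prev.start_bp,
                    end_bp=nxt.end_bp,
                    state=state,
                    num_snps=index.count_in(chrom, prev.start_bp, nxt.end_bp),
                    copy_number=cn,
                    source=prev.source,
                )
                changed = True
            else:
                merged.append(nxt)
        current = merged
    return current


def filter_small_calls(calls: Iterable[CnvCall], cfg: Optional[QcConfig] = None) -> list[CnvCall]:
    """Keep calls with >= ``min_snps`` probes and >= ``min_length_bp`` span."""
    cfg = cfg or QcConfig()
    return [
        c for c in calls
        if c.num_snps >= cfg.min_snps and c.length_bp >= cfg.min_length_bp
    ]


def filter_blacklist(
    calls: Iterable[CnvCall],
    regions: Sequence[BlacklistRegion],
    cfg: Optional[QcConfig] = None,
) -> list[CnvCall]:
    """Remove calls overlapping any blacklist region by at least
    ``blacklist_min_overlap_bp`` base pairs (default: any overlap)."""
    cfg = cfg or QcConfig()
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append((r.start_bp, r.end_bp))
    starts_ends = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts_ends[chrom] = ([s for s, _ in ivs], [e for _, e in ivs])

    def hits(call: CnvCall) -> bool:
        if call.chrom not in starts_ends:
            return False
        starts, ends = starts_ends[call.chrom]
        # regions with start <= call.end could overlap; check their ends
        hi = bisect_right(starts, call.end_bp)
        for i in range(hi):
            overlap = min(call.end_bp, ends[i]) - max(call.start_bp, starts[i]) + 1
            if overlap >= cfg.blacklist_min_overlap_bp:
                return True
        return False

    return [c for c in calls if not hits(c)]


def sample_qc(
    metrics: Iterable[SampleQcMetrics], cfg: Optional[QcConfig] = None
) -> set[str]:
    """Return the sample ids passing the noise and call-count filters.

    A sample passes iff lrr_sd <= ``lrr_sd_max``, its PennCNV-like call count
    is <= ``max_calls_caller_b`` and its Birdseye-like count is
    <= ``max_calls_caller_a`` (equality passes; the removal rules are
    "larger than" / "more than").
    """
    cfg = cfg or QcConfig()
    passing: set[str] = set()
    for m in metrics:
        if m.lrr_sd > cfg.lrr_sd_max:
            log.info("sample %s fails QC: lrr_sd %.3f > %.2f", m.sample_id, m.lrr_sd, cfg.lrr_sd_max)
            continue
        if m.n_calls_by_source.get(CallSource.CALLER_B, 0) > cfg.max_calls_caller_b:
            log.info("sample %s fails QC: too many callerB calls", m.sample_id)
            continue
        if m.n_calls_by_source.get(CallSource.CALLER_A, 0) > cfg.max_calls_caller_a:
            log.info("sample %s fails QC: too many callerA calls", m.sample_id)
            continue
        passing.add(m.sample_id)
    return passing


def _group_key(c: CnvCall) -> tuple[str, str, CnvState]:
    return (c.sample_id, c.chrom, c.state)


def consensus_intersect(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    snp_map: Sequence[SnpLocus] | ProbeIndex,
) -> list[CnvCall]:
    """Base-pair intersection of same-state calls from the two callers.

    For each sample, chromosome and state, every overlapping pair of calls
    (one per caller) yields a consensus call covering their intersection;
    differing states never intersect. Probe counts are recomputed from the
    map over the intersected span; intersections covering no probe are
    discarded (a consensus call must retain probe support).
    """
    index = snp_map if isinstance(snp_map, ProbeIndex) else ProbeIndex(snp_map)
    grouped_a: dict[tuple, list[CnvCall]] = defaultdict(list)
    grouped_b: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls_a:
        grouped_a[_group_key(c)].append(c)
    for c in calls_b:
        grouped_b[_group_key(c)].append(c)

    out: list[CnvCall] = []
    for key in grouped_a.keys() & grouped_b.keys():
        sample, chrom, state = key
        a_list = sorted(grouped_a[key], key=lambda c: c.start_bp)
        b_list = sorted(grouped_b[key], key=lambda c: c.start_bp)
        i = j = 0
        while i < len(a_list) and j < len(b_list):
            a, b = a_list[i], b_list[j]
            start = max(a.start_bp, b.start_bp)
            end = min(a.end_bp, b.end_bp)
            if start <= end:
                n = index.count_in(chrom, start, end)
                if n >= 1:
                    cn = a.copy_number if a.copy_number == b.copy_number else None
                    out.append(
                        CnvCall(
                            sample_id=sample,
                            chrom=chrom,
                            start_bp=start,
                            end_bp=end,
                            state=state,
                            num_snps=n,
                            copy_number=cn,
                            source=CallSource.CONSENSUS,
                        )
                    )
            if a.end_bp <= b.end_bp:
                i += 1
            else:
                j += 1
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start_bp))
    return out


def _per_caller_qc(
    calls: Sequence[CnvCall],
    index: ProbeIndex,
    blacklist: Sequence[BlacklistRegion],
    cfg: QcConfig,
    label: str,
    report: QcReport,
) -> tuple[list[CnvCall], dict[str, int]]:
    """merge -> small-call filter -> blacklist filter for one caller."""
    report.n_input[label] = len(calls)
    grouped: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls:
        grouped[_group_key(c)].append(c)
    merged: list[CnvCall] = []
    for group in grouped.values():
        merged.extend(merge_adjacent_calls(group, index, cfg))
    report.n_merged_away[label] = len(calls) - len(merged)

    # post-merge per-sample call counts feed the sample-QC caps
    counts: dict[str, int] = defaultdict(int)
    for c in merged:
        counts[c.sample_id] += 1

    kept = filter_small_calls(merged, cfg)
    report.n_small_removed[label] = len(merged) - len(kept)
    survived = filter_blacklist(kept, blacklist, cfg)
    report.n_blacklist_removed[label] = len(kept) - len(survived)
    return survived, counts


def stage2_qc(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    snp_map: Sequence[SnpLocus],
    blacklist: Sequence[BlacklistRegion] = (),
    lrr_sd: Optional[dict[str, float]] = None,
    cfg: Optional[QcConfig] = None,
) -> tuple[list[CnvCall], set[str], QcReport]:
    """Run the full stage-2 pipeline and build consensus calls.

    Order per caller: merge -> small-call filter -> blacklist filter; then
    sample QC (intensity SD from ``lrr_sd`` plus post-merge call counts);
    consensus is computed last from surviving calls of surviving samples.
    Returns (consensus calls, passing sample ids, removal report). Samples
    missing an ``lrr_sd`` entry fail QC with a logged reason.
    """
    cfg = cfg or QcConfig()
    index = ProbeIndex(snp_map)
    report = QcReport()
    out_a, counts_a = _per_caller_qc(calls_a, index, blacklist, cfg, "callerA", report)
    out_b, counts_b = _per_caller_qc(calls_b, index, blacklist, cfg, "callerB", report)

    all_samples = sorted(
        {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b} | set(lrr_sd or {})
    )
    metrics = []
    failed_missing: set[str] = set()
    for sid in all_samples:
        if lrr_sd is not None and sid not in lrr_sd:
            log.warning("sample %s has no QC metrics; failing sample QC", sid)
            failed_missing.add(sid)
            continue
        metrics.append(
            SampleQcMetrics(
                sample_id=sid,
                lrr_sd=(lrr_sd or {}).get(sid, 0.0),
                n_calls_by_source={
                    CallSource.CALLER_A: counts_a.get(sid, 0),
                    CallSource.CALLER_B: counts_b.get(sid, 0),
                },
            )
        )
    passing = sample_qc(metrics, cfg)
    report.failed_samples["all"] = (set(all_samples) - passing) | failed_missing

    surv_a = [c for c in out_a if c.sample_id in passing]
    surv_b = [c for c in out_b if c.sample_id in passing]
    report.n_sample_removed["callerA"] = len(out_a) - len(surv_a)
    report.n_sample_removed["callerB"] = len(out_b) - len(surv_b)
    report.n_surviving["callerA"] = len(surv_a)
    report.n_surviving["callerB"] = len(surv_b)

    consensus = consensus_intersect(surv_a, surv_b, index)
    report.n_consensus = len(consensus)
    return consensus, passing, report
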