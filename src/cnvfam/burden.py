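"""Genome-wide rare-CNV burden analysis.

A CNV call is *rare* when the proportion of samples carrying at least one
same-state call overlapping its span is below 5%. Each individual's burden
is the count of their rare calls (deletions and duplications separately),
and the association between the adjusted trait and the count is tested with
a GEE regression using an exchangeable within-family correlation and a
robust two-sided Wald p-value.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence

from .io import sample_family_index
from .types import AdjustedPhenotype, CnvCall, CnvState, Family

RARE_FREQ_MAX = 0.05


@dataclass
class BurdenProfile:
    """Per-sample counts of rare consensus CNVs."""

    sample_id: str
    n_rare_deletions: int = 0
    n_rare_duplications: int = 0

    def __post_init__(self) -> None:
        if self.n_rare_deletions < 0 or self.n_rare_duplications < 0:
            raise ValueError("burden counts must be >= 0")


@dataclass
class BurdenTestResult:
    coefficient: float
    p_value: float
    std_error: float
    n_samples: int
    n_clusters: int


def _overlap_components(calls: Sequence[CnvCall]):
    """Group same-chromosome calls into connected overlap components."""
    ordered = sorted(calls, key=lambda c: (c.start_bp, c.end_bp))
    comp: list[CnvCall] = []
    max_end = -1
    for c in ordered:
        if comp and c.start_bp > max_end:
            yield comp
            comp = []
            max_end = -1
        comp.append(c)
        max_end = max(max_end, c.end_bp)
    if comp:
        yield comp


def _call_frequencies(
    calls: Sequence[CnvCall], n_samples: int
) -> dict[int, float]:
    """Frequency for every call (by list position): the fraction of samples
    owning a same-state call that overlaps it by >= 1 bp."""
    by_group: dict[tuple[str, CnvState], list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        by_group[(c.chrom, c.state)].append(i)
    freq: dict[int, float] = {}
    for idxs in by_group.values():
        group = [calls[i] for i in idxs]
        pos_of = {id(c): i for c, i in zip(group, idxs)}
        for comp in _overlap_components(group):
            for c in comp:
                samples = {
                    o.sample_id
                    for o in comp
                    if o.start_bp <= c.end_bp and o.end_bp >= c.start_bp
                }
                freq[pos_of[id(c)]] = len(samples) / n_samples
    return freq


def call_frequency(calls: Sequence[CnvCall], target: CnvCall, n_samples: Optional[int] = None) -> float:
    """Frequency of ``target`` among ``calls``: the proportion of samples
    with >= 1 call of the same state overlapping the target span by >= 1 bp
    (the any-overlap region-frequency rule). ``n_samples`` defaults to the
    number of distinct samples in ``calls``."""
    n = n_samples or len({c.sample_id for c in calls})
    carriers = {
        c.sample_id
        for c in calls
        if c.state is target.state
        and c.chrom == target.chrom
        and c.start_bp <= target.end_bp
        and c.end_bp >= target.start_bp
    }
    return len(carriers) / n


def rare_counts(
    calls: Sequence[CnvCall],
    freq_max: float = RARE_FREQ_MAX,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[BurdenProfile]:
    """Per-sample counts of calls with frequency strictly below ``freq_max``,
    split by state. ``sample_ids`` fixes the sample universe (samples with
    no calls get zero counts and enter the frequency denominator)."""
    if sample_ids is None:
        sample_ids = sorted({c.sample_id for c in calls})
    n = len(sample_ids)
    freqs = _call_frequencies(calls, n)
    counts = {sid: [0, 0] for sid in sample_ids}
    for i, c in enumerate(calls):
        if c.sample_id not in counts:
            continue
        if freqs[i] < freq_max:
            counts[c.sample_id][0 if c.state is CnvState.DELETION else 1] += 1
    return [
        BurdenProfile(sample_id=sid, n_rare_deletions=d, n_rare_duplications=u)
        for sid, (d, u) in counts.items()
    ]


def burden_gee_test(
    profiles: Sequence[BurdenProfile],
    adjusted: Sequence[AdjustedPhenotype],
    families: Iterable[Family],
    state: CnvState | str = CnvState.DELETION,
) -> BurdenTestResult:
    """GEE regression of the adjusted trait on the rare-CNV count.

    Exchangeable within-family working correlation (independence when every
    cluster is a singleton, where the estimate coincides with OLS), robust
    sandwich standard error, two-sided normal Wald p-value for the slope.
    """
    state = CnvState(state)
    count_of = {
        p.sample_id: (p.n_rare_deletions if state is CnvState.DELETION else p.n_rare_duplications)
        for p in profiles
    }
    pairs = [(a.sample_id, a.residual, count_of[a.sample_id]) for a in adjusted if a.sample_id in count_of]
    if not pairs:
        raise ValueError("no samples with both residuals and burden profiles")
    ids = [p[0] for p in pairs]
    y = np.array([p[1] for p in pairs])
    counts = np.array([p[2] for p in pairs], dtype=float)
    if np.var(counts) == 0:
        raise ValueError("zero variance in CNV counts: burden test undefined")

    fam_of = sample_family_index(families)
    labels = [fam_of.get(sid, f"__singleton__{sid}") for sid in ids]
    _, codes = np.unique(labels, return_inverse=True)
    n_clusters = len(np.unique(codes))
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    X = np.column_stack([np.ones_like(counts), counts])
    singleton_only = n_clusters == len(ids)
    cov_struct = Independence() if singleton_only else Exchangeable()
    result = sm.GEE(y, X, groups=codes, family=sm.families.Gaussian(), cov_struct=cov_struct).fit(
        maxiter=100
    )
    return BurdenTestResult(
        coefficient=float(result.params[1]),
        p_value=float(result.pvalues[1]),
        std_error=float(result.bse[1]),
        n_samples=len(ids),
        n_clusters=n_clusters,
    )
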