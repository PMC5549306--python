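"""Per-SNP CNV state association testing.

The CNV state of a SNP for an individual is the state of the consensus call
covering the SNP's position (normal when no call covers it). For one tested
state (deletion or duplication) the statistic is

    T = mean(residual | tested state) - mean(residual | normal state),

evaluated on covariate-adjusted residuals; samples carrying the *other*
abnormal state at that locus are excluded from both groups. Significance
comes from randomly permuting residuals among the siblings of each family
(the state labels stay fixed), with the two-sided p-value the proportion of
permuted statistics at least as extreme as the observed one; ties count
toward p and the denominator is the number of permutations B (no add-one
correction, optionally available).

For the genome-wide scan one family shuffle per permutation replicate is
reused across all loci, so the permuted-statistic matrix preserves the
correlation between loci that share a CNV region; single-step maxT adjusted
p-values and an empirical FDR are computed from that matrix. A
population-based variant permutes residuals across all samples at once
(used for unrelated replication cohorts).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._permute import within_family_permutation_indices
from .io import sample_family_index
from .types import (
    STATE_DELETION,
    STATE_DUPLICATION,
    STATE_NORMAL,
    AdjustedPhenotype,
    CnvCall,
    CnvState,
    Family,
    SnpLocus,
    chrom_sort_key,
    state_code,
)

log = logging.getLogger(__name__)


class StateIntegrityError(ValueError):
    """A locus is covered by calls of different states for one sample."""


@dataclass
class PermutationPlan:
    """How to permute: number of replicates B, seed, and the shuffling scheme
    (within sibships, or across the whole sample for population cohorts)."""

    n_permutations: int = 5000
    seed: int = 0
    scheme: str = "within_family"  # or "across_all"
    add_one: bool = False  # p = (r+1)/(B+1) instead of r/B

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.scheme not in ("within_family", "across_all"):
            raise ValueError("scheme must be 'within_family' or 'across_all'")


@dataclass
class StateMatrix:
    """Samples x SNP-loci grid of CNV state codes (0 normal / 1 del / 2 dup)."""

    sample_ids: list[str]
    loci: list[SnpLocus]
    codes: np.ndarray  # (n_samples, n_loci) int8

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("state matrix shape mismatch")

    def locus_index(self, snp_id: str) -> int:
        for i, locus in enumerate(self.loci):
            if locus.snp_id == snp_id:
                return i
        raise KeyError(snp_id)

    def states_at(self, locus: "int | str") -> np.ndarray:
        j = locus if isinstance(locus, int) else self.locus_index(locus)
        return self.codes[:, j]


@dataclass
class AssocResult:
    """Association output for one SNP and one tested state."""

    snp_id: str
    chrom: str
    position_bp: int
    state_tested: CnvState
    frequency: float
    statistic: float
    p_value: float
    n_carriers: int
    n_normal: int
    p_adjusted: Optional[float] = None
    fdr: Optional[float] = None


@dataclass
class PermutationTestResult:
    """Single-locus test output, optionally carrying the permuted statistics."""

    statistic: float
    p_value: float
    n_carriers: int
    n_normal: int
    frequency: float
    perm_statistics: Optional[np.ndarray] = field(default=None, repr=False)


def build_state_matrix(
    consensus_calls: Iterable[CnvCall],
    snp_map: Sequence[SnpLocus],
    sample_ids: Sequence[str],
) -> StateMatrix:
    """Project consensus calls onto SNP positions.

    A sample's state at a locus is the state of the consensus call covering
    the locus position (closed interval, so a call's end position is still
    covered); loci under no call are normal. A locus covered by calls of two
    different states for the same sample raises
    :class:`StateIntegrityError`.
    """
    loci = sorted(snp_map, key=lambda s: (chrom_sort_key(s.chrom), s.position_bp))
    sample_pos = {sid: i for i, sid in enumerate(sample_ids)}
    if len(sample_pos) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    positions: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    for j, locus in enumerate(loci):
        if locus.chrom not in offsets:
            offsets[locus.chrom] = j
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for locus in loci:
        by_chrom[locus.chrom].append(locus.position_bp)
    for chrom, pos in by_chrom.items():
        positions[chrom] = np.asarray(pos, dtype=np.int64)

    codes = np.zeros((len(sample_ids), len(loci)), dtype=np.int8)
    for call in consensus_calls:
        if call.sample_id not in sample_pos:
            continue
        pos = positions.get(call.chrom)
        if pos is None:
            continue
        lo = int(np.searchsorted(pos, call.start_bp, "left"))
        hi = int(np.searchsorted(pos, call.end_bp, "right"))
        if lo == hi:
            continue
        i = sample_pos[call.sample_id]
        j0 = offsets[call.chrom]
        code = state_code(call.state)
        segment = codes[i, j0 + lo : j0 + hi]
        clash = (segment != 0) & (segment != code)
        if clash.any():
            k = j0 + lo + int(np.flatnonzero(clash)[0])
            raise StateIntegrityError(
                f"sample {call.sample_id}: locus {loci[k].snp_id} covered by "
                "calls of different states"
            )
        segment[:] = code
    return StateMatrix(sample_ids=list(sample_ids), loci=loci, codes=codes)


def state_frequency(matrix: StateMatrix, locus: "int | str", state) -> float:
    """Proportion of samples with the given state at a locus."""
    col = matrix.states_at(locus)
    return float(np.mean(col == state_code(state)))


def _pvalue(n_extreme: int, B: int, add_one: bool) -> float:
    return (n_extreme + 1) / (B + 1) if add_one else n_extreme / B


def _count_extreme(t_star: np.ndarray, T: float) -> int:
    """#{b : |T*_b| >= |T|}. Ties count toward the p-value; a guard of one
    part in 10^12 absorbs floating-point noise between the (differently
    summed) observed and permuted statistics so that genuine ties — e.g.
    the identity permutation, or constant residuals — are never lost."""
    tol = 1e-12 * max(1.0, abs(T), float(np.max(np.abs(t_star), initial=0.0)))
    return int(np.count_nonzero(np.abs(t_star) >= abs(T) - tol))


def _align(
    states: "Mapping[str, object] | Sequence",
    adjusted: Sequence[AdjustedPhenotype],
    families: Optional[Iterable[Family]],
):
    """Assemble aligned residual/state/family-code arrays over the samples
    that have residuals. ``states`` is a mapping sample->state, or a
    sequence aligned with ``adjusted``. With ``families=None`` all samples
    form one exchangeable pool (the population scheme)."""
    ids = [a.sample_id for a in adjusted]
    res = np.array([a.residual for a in adjusted], dtype=float)
    if isinstance(states, Mapping):
        codes = np.array([state_code(states[sid]) for sid in ids], dtype=np.int8)
    else:
        if len(states) != len(adjusted):
            raise ValueError("states and adjusted must align")
        codes = np.array([state_code(s) for s in states], dtype=np.int8)
    if families is None:
        fam = np.zeros(len(ids), dtype=np.int64)
        return ids, res, codes, fam, 0
    fam_of = sample_family_index(families)
    keep = np.array([sid in fam_of for sid in ids])
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%d samples with residuals are absent from the pedigree; excluded", n_dropped)
    ids = [sid for sid, k in zip(ids, keep) if k]
    res, codes = res[keep], codes[keep]
    _, fam = np.unique([fam_of[sid] for sid in ids], return_inverse=True)
    return ids, res, codes, fam, n_dropped


def _mean_diff_test(
    res: np.ndarray,
    codes: np.ndarray,
    tested: int,
    fam: np.ndarray,
    plan: PermutationPlan,
    rng: Optional[np.random.Generator] = None,
    return_perm: bool = False,
) -> PermutationTestResult:
    carriers = codes == tested
    normals = codes == STATE_NORMAL
    k, nn = int(carriers.sum()), int(normals.sum())
    if k == 0:
        raise ValueError("no carriers of the tested state: test undefined")
    if nn == 0:
        raise ValueError("no normal-state samples: test undefined")
    w = np.zeros(res.shape[0])
    w[carriers] = 1.0 / k
    w[normals] = -1.0 / nn
    T = float(res[carriers].mean() - res[normals].mean())
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    B = plan.n_permutations
    P = within_family_permutation_indices(fam, B, rng)
    t_star = res[P] @ w
    n_extreme = _count_extreme(t_star, T)
    return PermutationTestResult(
        statistic=T,
        p_value=_pvalue(n_extreme, B, plan.add_one),
        n_carriers=k,
        n_normal=nn,
        frequency=k / res.shape[0],
        perm_statistics=t_star if return_perm else None,
    )


def family_permutation_test(
    states: "Mapping[str, object] | Sequence",
    state_tested,
    adjusted: Sequence[AdjustedPhenotype],
    families: Iterable[Family],
    plan: Optional[PermutationPlan] = None,
    return_perm: bool = False,
) -> PermutationTestResult:
    """Family-based permutation test of one locus.

    Residuals are shuffled independently among the members of each family
    in every replicate; state labels stay attached to sample positions, so
    samples excluded from the statistic (other abnormal state) still
    contribute their residuals to the shuffle.
    """
    plan = plan or PermutationPlan()
    ids, res, codes, fam, _ = _align(states, adjusted, families)
    return _mean_diff_test(res, codes, state_code(state_tested), fam, plan, return_perm=return_perm)


def population_permutation_test(
    states: "Mapping[str, object] | Sequence",
    state_tested,
    adjusted: Sequence[AdjustedPhenotype],
    plan: Optional[PermutationPlan] = None,
    return_perm: bool = False,
) -> PermutationTestResult:
    """Population-based variant: residuals are permuted across all samples
    (equivalent to the family test with every sample in a single family)."""
    plan = plan or PermutationPlan()
    ids, res, codes, fam, _ = _align(states, adjusted, None)
    return _mean_diff_test(res, codes, state_code(state_tested), fam, plan, return_perm=return_perm)


def adjust_maxT_fdr(t_obs: np.ndarray, t_perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-step maxT adjusted p-values and empirical FDR.

    ``t_perm`` must come from a scan whose permutation replicates shared one
    family shuffle across loci, so inter-locus correlation is preserved.

    For locus j with observed statistic T_j:

    * ``p_adjusted[j]`` = proportion of replicates whose genome-wide maximum
      |T*| reaches |T_j|;
    * ``fdr[j]`` = (mean over replicates of the number of permuted |T*|
      reaching |T_j|) / max(1, number of observed |T| reaching |T_j|).
    """
    t_obs = np.asarray(t_obs, dtype=float)
    t_perm = np.asarray(t_perm, dtype=float)
    if t_perm.ndim != 2 or t_perm.shape[1] != t_obs.shape[0]:
        raise ValueError("t_perm must be (B, n_loci) matching t_obs")
    B = t_perm.shape[0]
    abs_obs = np.abs(t_obs)
    max_per_rep = np.abs(t_perm).max(axis=1)
    p_adj = np.array([np.count_nonzero(max_per_rep >= t) / B for t in abs_obs])
    flat = np.sort(np.abs(t_perm).ravel())
    sorted_obs = np.sort(abs_obs)
    fdr = np.empty_like(abs_obs)
    for j, t in enumerate(abs_obs):
        expected = (flat.size - np.searchsorted(flat, t, "left")) / B
        observed = abs_obs.size - np.searchsorted(sorted_obs, t, "left")
        fdr[j] = expected / max(1, observed)
    return np.clip(p_adj, 0.0, 1.0), np.maximum(fdr, 0.0)


@dataclass
class ScanResult:
    """Genome-wide scan output for one tested state."""

    results: list[AssocResult]
    t_perm: np.ndarray  # (B, n_tested_loci)
    tested_locus_indices: np.ndarray
    n_below_frequency: int


def genomewide_scan(
    matrix: StateMatrix,
    state_tested,
    adjusted: Sequence[AdjustedPhenotype],
    families: Optional[Iterable[Family]],
    plan: Optional[PermutationPlan] = None,
    freq_min: float = 0.05,
) -> ScanResult:
    """Test every locus where the tested state reaches frequency ``freq_min``.

    One within-family shuffle per replicate is applied to all loci (required
    for the maxT/FDR adjustment); loci below the frequency threshold are
    skipped and counted. ``families=None`` selects the population scheme.
    """
    plan = plan or PermutationPlan()
    tested = state_code(state_tested)
    adj_index = {a.sample_id: a.residual for a in adjusted}
    have_res = np.array([sid in adj_index for sid in matrix.sample_ids])
    ids = [sid for sid, k in zip(matrix.sample_ids, have_res) if k]
    res = np.array([adj_index[sid] for sid in ids])
    codes_all = matrix.codes[have_res]

    if families is None or plan.scheme == "across_all":
        fam = np.zeros(len(ids), dtype=np.int64)
    else:
        fam_of = sample_family_index(families)
        keep = np.array([sid in fam_of for sid in ids])
        if not keep.all():
            log.warning("%d samples dropped from scan: absent from pedigree", int((~keep).sum()))
            ids = [sid for sid, k in zip(ids, keep) if k]
            res = res[keep]
            codes_all = codes_all[keep]
        _, fam = np.unique([fam_of[sid] for sid in ids], return_inverse=True)

    n = len(ids)
    carrier_mask = codes_all == tested
    normal_mask = codes_all == STATE_NORMAL
    n_carr = carrier_mask.sum(axis=0)
    n_norm = normal_mask.sum(axis=0)
    freq = n_carr / max(n, 1)
    eligible = (freq >= freq_min) & (n_carr >= 1) & (n_norm >= 1)
    idx = np.flatnonzero(eligible)
    n_skipped = int(np.count_nonzero((freq < freq_min) & (n_carr > 0)))

    B = plan.n_permutations
    rng = np.random.default_rng(plan.seed)
    if idx.size == 0:
        return ScanResult([], np.empty((B, 0)), idx, n_skipped)

    W = np.zeros((n, idx.size))
    cm = carrier_mask[:, idx]
    nm = normal_mask[:, idx]
    W[cm] = np.broadcast_to(1.0 / n_carr[idx], (n, idx.size))[cm]
    W[nm] = np.broadcast_to(-1.0 / n_norm[idx], (n, idx.size))[nm]

    t_obs = res @ W
    P = within_family_permutation_indices(fam, B, rng)
    t_perm = res[P] @ W
    pvals = np.array(
        [_pvalue(_count_extreme(t_perm[:, c], float(t_obs[c])), B, plan.add_one)
         for c in range(idx.size)]
    )
    p_adj, fdr = adjust_maxT_fdr(t_obs, t_perm)

    results = []
    for col, j in enumerate(idx):
        locus = matrix.loci[j]
        results.append(
            AssocResult(
                snp_id=locus.snp_id,
                chrom=locus.chrom,
                position_bp=locus.position_bp,
                state_tested=CnvState.DELETION if tested == STATE_DELETION else CnvState.DUPLICATION,
                frequency=float(freq[j]),
                statistic=float(t_obs[col]),
                p_value=float(pvals[col]),
                n_carriers=int(n_carr[j]),
                n_normal=int(n_norm[j]),
                p_adjusted=float(p_adj[col]),
                fdr=float(fdr[col]),
            )
        )
    return ScanResult(results, t_perm, idx, n_skipped)


def expected_amplicon_size(flank_bp: int, deletion_bp: int) -> int:
    """Expected PCR amplicon size when a primer pair spanning ``flank_bp``
    amplifies across a deletion of ``deletion_bp`` (e.g. a 17.4 kb flank
    over an 11 kb deletion yields a 6.4 kb product)."""
    if deletion_bp <= 0:
        raise ValueError("deletion_bp must be > 0")
    if deletion_bp >= flank_bp:
        raise ValueError("deletion must be smaller than the flanking span")
    return flank_bp - deletion_bp
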