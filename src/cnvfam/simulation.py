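"""Operating characteristics of the family-based CNV test.

Type-I error: deletions are repeatedly assigned at random (i.i.d. Bernoulli
per individual at the study carrier frequency) while the observed adjusted
trait values stay fixed; each replicate is tested with the within-family
permutation test, and the rejection rate at each significance level is
reported with a Wald binomial confidence interval. Because the permutation
test is exact conditional on the within-family trait arrangements, the rate
should match the nominal level for any residual distribution.

Power: families are bootstrapped (resampled whole, carrying their states
and residuals) and the proportion of bootstrap p-values strictly below the
significance level estimates the power at the observed effect. Type-I error
counts rejections as p <= alpha; power counts p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._permute import within_family_permutation_indices
from .assoc import _count_extreme
from .io import sample_family_index
from .types import (
    STATE_DELETION,
    STATE_NORMAL,
    AdjustedPhenotype,
    Family,
    state_code,
)

log = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    """Parameters of the type-I-error and power studies.

    n_permutations is the inner permutation count B of each single test
    (1000 keeps Monte-Carlo noise below the smallest default alpha's
    resolution, 20/alpha at alpha=0.01); n_replicates R is the number of
    null carrier re-assignments; n_bootstraps the number of family
    bootstrap draws.
    """

    n_replicates: int = 5000
    n_bootstraps: int = 1000
    carrier_frequency: float = 0.052
    alphas: tuple[float, ...] = (0.05, 0.01)
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_frequency < 1.0):
            raise ValueError("carrier_frequency must be in (0, 1)")
        if self.n_replicates < 1 or self.n_permutations < 1 or self.n_bootstraps < 1:
            raise ValueError("n_replicates, n_permutations, n_bootstraps must be >= 1")
        if any(not (0.0 < a < 1.0) for a in self.alphas) and tuple(self.alphas) != (1.0,):
            if any(not (0.0 < a <= 1.0) for a in self.alphas):
                raise ValueError("alphas must be in (0, 1]")


def simulate_null_states(
    sample_ids: Sequence[str], f: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign a deletion independently to each sample with probability ``f``
    (state codes: 1 deletion, 0 normal)."""
    if not (0.0 < f < 1.0):
        raise ValueError("carrier frequency must be in (0, 1)")
    return (rng.random(len(sample_ids)) < f).astype(np.int8)


@dataclass
class Type1Result:
    rates: dict[float, tuple[float, tuple[float, float]]]
    n_replicates: int
    n_redrawn: int
    p_values: np.ndarray = field(repr=False)


def _family_arrays(
    families: Iterable[Family], adjusted: Sequence[AdjustedPhenotype]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    fam_of = sample_family_index(families)
    ids, res, labels = [], [], []
    for a in adjusted:
        fid = fam_of.get(a.sample_id)
        if fid is None:
            continue
        ids.append(a.sample_id)
        res.append(a.residual)
        labels.append(fid)
    if not ids:
        raise ValueError("no samples shared between pedigree and residuals")
    _, codes = np.unique(labels, return_inverse=True)
    return ids, np.asarray(res, dtype=float), codes


def type1_error(
    families: Iterable[Family],
    adjusted: Sequence[AdjustedPhenotype],
    spec: Optional[SimulationSpec] = None,
) -> Type1Result:
    """Empirical size of the family-based test under random carrier labels.

    For each of R replicates, deletion carriers are drawn i.i.d.
    Bernoulli(f) over the samples (replicates with zero carriers or zero
    normals are redrawn and counted) and the two-sided permutation p-value
    is computed with B fresh within-family shuffles. The rate at level
    alpha is #{p <= alpha}/R with a Wald 95% CI.
    """
    spec = spec or SimulationSpec()
    ids, res, fam = _family_arrays(families, adjusted)
    n = len(ids)
    rng = np.random.default_rng(spec.seed)
    B = spec.n_permutations
    pvals = np.empty(spec.n_replicates)
    n_redrawn = 0
    for r in range(spec.n_replicates):
        while True:
            carrier = rng.random(n) < spec.carrier_frequency
            k = int(carrier.sum())
            if 0 < k < n:
                break
            n_redrawn += 1
            log.info("replicate %d redrawn: degenerate carrier draw", r)
        w = np.where(carrier, 1.0 / k, -1.0 / (n - k))
        T = res @ w
        P = within_family_permutation_indices(fam, B, rng)
        t_star = res[P] @ w
        pvals[r] = _count_extreme(t_star, float(T)) / B
    rates = {}
    R = spec.n_replicates
    for alpha in spec.alphas:
        rate = float(np.count_nonzero(pvals <= alpha) / R)
        half = 1.959963984540054 * np.sqrt(rate * (1.0 - rate) / R)
        rates[alpha] = (rate, (rate - half, rate + half))
    return Type1Result(rates=rates, n_replicates=R, n_redrawn=n_redrawn, p_values=pvals)


@dataclass
class PowerResult:
    power: float
    n_bootstraps: int
    n_redrawn: int
    p_values: np.ndarray = field(repr=False)


def bootstrap_power(
    families: Iterable[Family],
    states: Mapping[str, object],
    adjusted: Sequence[AdjustedPhenotype],
    spec: Optional[SimulationSpec] = None,
    alpha: float = 0.05,
    state_tested: int = STATE_DELETION,
) -> PowerResult:
    """Bootstrap power of the family-based test at the observed effect.

    Each bootstrap draws as many families as observed, with replacement;
    a family's members travel together with their states and residuals and
    each draw receives a fresh family identity. Power is the proportion of
    bootstrap p-values strictly below ``alpha``; draws without both a
    carrier and a normal sample are redrawn and counted.
    """
    spec = spec or SimulationSpec()
    fam_list = [f for f in families]
    fam_of = sample_family_index(fam_list)
    res_of = {a.sample_id: a.residual for a in adjusted}
    members: dict[str, list[str]] = {}
    for f in fam_list:
        kept = [sid for sid in f.member_ids if sid in res_of and sid in states]
        if kept:
            members[f.family_id] = kept
    fids = sorted(members)
    if not fids:
        raise ValueError("no families with residuals and states")
    fam_res = [np.array([res_of[s] for s in members[fid]]) for fid in fids]
    fam_car = [
        np.array([state_code(states[s]) == state_tested for s in members[fid]]) for fid in fids
    ]
    tested = state_code(state_tested)
    other = np.array(
        [[state_code(states[s]) not in (tested, STATE_NORMAL) for s in members[fid]] for fid in fids],
        dtype=object,
    )

    rng = np.random.default_rng(spec.seed)
    B = spec.n_permutations
    nf = len(fids)
    pvals = np.empty(spec.n_bootstraps)
    n_redrawn = 0
    b = 0
    while b < spec.n_bootstraps:
        draw = rng.integers(0, nf, size=nf)
        res = np.concatenate([fam_res[i] for i in draw])
        carrier = np.concatenate([fam_car[i] for i in draw])
        excl = np.concatenate([np.asarray(other[i], dtype=bool) for i in draw])
        fam = np.repeat(np.arange(nf), [len(fam_res[i]) for i in draw])
        k = int(carrier.sum())
        nn = int((~carrier & ~excl).sum())
        if k == 0 or nn == 0:
            n_redrawn += 1
            log.info("bootstrap redrawn: no carriers or no normals")
            continue
        w = np.zeros(len(res))
        w[carrier] = 1.0 / k
        w[~carrier & ~excl] = -1.0 / nn
        T = res @ w
        P = within_family_permutation_indices(fam, B, rng)
        t_star = res[P] @ w
        pvals[b] = _count_extreme(t_star, float(T)) / B
        b += 1
    power = float(np.count_nonzero(pvals < alpha) / spec.n_bootstraps)
    return PowerResult(power=power, n_bootstraps=spec.n_bootstraps, n_redrawn=n_redrawn, p_values=pvals)
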