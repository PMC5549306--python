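"""Within-family permutation machinery.

The family-based test shuffles adjusted trait values among the members of
each sibship while every CNV-state label stays attached to its position.
All tests in :mod:`cnvfam.assoc` and :mod:`cnvfam.simulation` draw their
permutations from :func:`within_family_permutation_indices`, so one seed
yields one reproducible stream everywhere.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# Families up to this size use a precomputed table of all m! permutations
# indexed by a single random integer; larger sibships fall back to argsort
# of random keys (equivalent in distribution, slower).
_TABLE_MAX = 7

_perm_tables: dict[int, np.ndarray] = {}


def _table(m: int) -> np.ndarray:
    tab = _perm_tables.get(m)
    if tab is None:
        tab = np.array(list(itertools.permutations(range(m))), dtype=np.int64)
        _perm_tables[m] = tab
    return tab


def within_family_permutation_indices(
    family_codes: np.ndarray, n_perms: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate independent within-family permutations of ``0..n-1``.

    Parameters
    ----------
    family_codes
        Integer array of length n; equal values mark members of the same
        family. Codes need not be contiguous or sorted.
    n_perms
        Number of permutation replicates B.
    rng
        Source of randomness.

    Returns
    -------
    (n_perms, n) integer array ``P`` where row b is a permutation of
    ``0..n-1`` and ``P[b, i]`` lies in the same family as ``i``; permuted
    values are ``x[P]``.
    """
    family_codes = np.asarray(family_codes)
    n = family_codes.shape[0]
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    order = np.argsort(family_codes, kind="stable")
    sorted_codes = family_codes[order]
    block_starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
    block_ends = np.r_[block_starts[1:], n]
    sizes = block_ends - block_starts

    out = np.empty((n_perms, n), dtype=np.int64)
    for m in np.unique(sizes):
        starts = block_starts[sizes == m]  # (F,)
        positions = order[starts[:, None] + np.arange(m)[None, :]]  # (F, m)
        if m == 1:
            out[:, positions[:, 0]] = positions[:, 0][None, :]
            continue
        if m <= _TABLE_MAX:
            tab = _table(int(m))
            codes = rng.integers(0, math.factorial(int(m)), size=(n_perms, len(starts)))
            sel = tab[codes]  # (B, F, m)
        else:
            keys = rng.random((n_perms, len(starts), m))
            sel = np.argsort(keys, axis=2)
        src = order[starts[None, :, None] + sel]  # (B, F, m)
        out[:, positions.ravel()] = src.reshape(n_perms, -1)
    return out


def exhaustive_within_family_permutations(family_codes: np.ndarray) -> np.ndarray:
    """Enumerate every distinct within-family arrangement (small cohorts only).

    Returns an (N, n) index array covering the full permutation group, the
    cartesian product of each family's symmetric group. Raises if the group
    has more than 2**20 elements.
    """
    family_codes = np.asarray(family_codes)
    n = family_codes.shape[0]
    blocks = [np.flatnonzero(family_codes == c) for c in np.unique(family_codes)]
    total = 1
    for b in blocks:
        total *= math.factorial(len(b))
        if total > 2**20:
            raise ValueError("permutation group too large to enumerate")
    out = np.tile(np.arange(n, dtype=np.int64), (total, 1))
    rows = np.arange(total)
    rep = 1
    for b in blocks:
        m = len(b)
        tab = np.array(list(itertools.permutations(b)), dtype=np.int64)  # (m!, m)
        codes = (rows // rep) % math.factorial(m)
        out[:, b] = tab[codes]
        rep *= math.factorial(m)
    return out
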