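import itertools

import numpy as np
import pytest

from conftest import grid_map
from cnvfam import assoc
from cnvfam.types import (
    AdjustedPhenotype,
    CallSource,
    CnvCall,
    CnvState,
    Family,
    SnpLocus,
)


def adjusted(values, prefix="S"):
    return [AdjustedPhenotype(f"{prefix}{i}", float(v)) for i, v in enumerate(values)]


def pair_families(n_pairs, prefix="S", fam_prefix="F"):
    fams, ids = [], []
    for i in range(n_pairs):
        members = [f"{prefix}{2 * i}", f"{prefix}{2 * i + 1}"]
        fams.append(Family(f"{fam_prefix}{i}", members, {m: 1 for m in members}))
        ids.extend(members)
    return fams, ids


def exhaustive_p(residuals, carrier, families_of):
    """Independent oracle: enumerate the full within-family permutation group
    with itertools and count |T*| >= |T|."""
    residuals = np.asarray(residuals, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    k, nn = carrier.sum(), (~carrier).sum()

    def stat(values):
        return values[carrier].mean() - values[~carrier].mean()

    T = stat(residuals)
    blocks = [np.flatnonzero(np.asarray(families_of) == f) for f in sorted(set(families_of))]
    count = total = 0
    for perms in itertools.product(*(itertools.permutations(b) for b in blocks)):
        arranged = residuals.copy()
        for block, perm in zip(blocks, perms):
            arranged[block] = residuals[np.array(perm)]
        total += 1
        if abs(stat(arranged)) >= abs(T):
            count += 1
    return T, count / total


class TestStateMatrix:
    MAP = [
        SnpLocus("a", "chr1", 100),
        SnpLocus("b", "chr1", 200),
        SnpLocus("c", "chr1", 201),
    ]

    def test_closed_interval_coverage(self):
        call = CnvCall("S1", "chr1", 100, 200, CnvState.DELETION, 2, source=CallSource.CONSENSUS)
        m = assoc.build_state_matrix([call], self.MAP, ["S1"])
        assert m.states_at("a")[0] == 1
        assert m.states_at("b")[0] == 1  # end position included
        assert m.states_at("c")[0] == 0  # one past the end

    def test_no_calls_all_normal(self):
        m = assoc.build_state_matrix([], self.MAP, ["S1", "S2"])
        assert not m.codes.any()

    def test_conflicting_states_rejected(self):
        calls = [
            CnvCall("S1", "chr1", 100, 200, CnvState.DELETION, 2),
            CnvCall("S1", "chr1", 150, 250, CnvState.DUPLICATION, 2, 3),
        ]
        with pytest.raises(assoc.StateIntegrityError):
            assoc.build_state_matrix(calls, self.MAP, ["S1"])

    def test_frequency(self):
        n = 444
        ids = [f"S{i}" for i in range(n)]
        calls = [
            CnvCall(ids[i], "chr1", 100, 200, CnvState.DELETION, 2) for i in range(23)
        ]
        m = assoc.build_state_matrix(calls, self.MAP, ids)
        f = assoc.state_frequency(m, "a", "deletion")
        assert f == pytest.approx(23 / 444)
        assert round(100 * f, 1) == 5.2
        assert assoc.state_frequency(m, "c", "deletion") == 0.0
        assert assoc.state_frequency(m, "c", "normal") == 1.0


class TestFamilyPermutationTest:
    def test_constant_residuals_give_null_result(self):
        fams, ids = pair_families(4)
        res = adjusted(np.ones(8))
        states = {sid: "normal" for sid in ids}
        states[ids[0]] = "deletion"
        out = assoc.family_permutation_test(states, "deletion", res, fams,
                                            assoc.PermutationPlan(n_permutations=100, seed=1))
        assert out.statistic == 0.0
        assert out.p_value == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        """Monte-Carlo p agrees with the exact permutation p on a cohort
        small enough to enumerate (4 sib pairs -> 2^4 arrangements)."""
        fams, ids = pair_families(4)
        values = rng.normal(0, 1, 8)
        carrier = np.zeros(8, bool)
        carrier[0] = True
        famof = np.repeat(np.arange(4), 2)
        T, p_exact = exhaustive_p(values, carrier, famof)
        states = {sid: ("deletion" if carrier[i] else "normal") for i, sid in enumerate(ids)}
        B = 10_000
        out = assoc.family_permutation_test(states, "deletion", adjusted(values), fams,
                                            assoc.PermutationPlan(n_permutations=B, seed=5))
        assert out.statistic == pytest.approx(T)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(out.p_value - p_exact) <= 3 * se

    def test_singleton_carriers_match_oracle(self, rng):
        """Carriers confined to singleton families keep their residuals
        fixed; permuted statistics vary only through the sibs' shuffles."""
        fams = [Family("F0", ["S0"], {"S0": 1})]
        f2, _ = pair_families(3, prefix="T", fam_prefix="G")
        fams += f2
        ids = ["S0"] + [m for f in f2 for m in f.member_ids]
        values = rng.normal(0, 1, 7)
        carrier = np.array([True] + [False] * 6)
        famof = [0, 1, 1, 2, 2, 3, 3]
        T, p_exact = exhaustive_p(values, carrier, famof)
        states = {sid: ("deletion" if carrier[i] else "normal") for i, sid in enumerate(ids)}
        B = 20_000
        out = assoc.family_permutation_test(
            states, "deletion",
            [AdjustedPhenotype(sid, float(v)) for sid, v in zip(ids, values)],
            fams, assoc.PermutationPlan(n_permutations=B, seed=6))
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / B)
        assert abs(out.p_value - p_exact) <= 3 * se

    def test_no_carriers_is_undefined(self):
        fams, ids = pair_families(2)
        states = {sid: "normal" for sid in ids}
        with pytest.raises(ValueError, match="carrier"):
            assoc.family_permutation_test(states, "deletion", adjusted(np.arange(4)), fams)

    def test_shift_invariance_and_label_swap(self, rng):
        fams, ids = pair_families(6)
        values = rng.normal(0, 2, 12)
        carrier = rng.random(12) < 0.4
        carrier[0], carrier[1] = True, False
        states = {sid: ("deletion" if carrier[i] else "normal") for i, sid in enumerate(ids)}
        plan = assoc.PermutationPlan(n_permutations=2000, seed=9)
        out = assoc.family_permutation_test(states, "deletion", adjusted(values), fams, plan)
        shifted = assoc.family_permutation_test(states, "deletion", adjusted(values + 57.0), fams, plan)
        assert shifted.statistic == pytest.approx(out.statistic)
        assert shifted.p_value == out.p_value
        flipped = {sid: ("normal" if s == "deletion" else "deletion") for sid, s in states.items()}
        swap = assoc.family_permutation_test(flipped, "deletion", adjusted(values), fams, plan)
        assert swap.statistic == pytest.approx(-out.statistic)
        assert swap.p_value == out.p_value

    def test_other_state_excluded_from_statistic(self):
        fams, ids = pair_families(3)
        values = np.array([10.0, 0.0, 0.0, 0.0, 99.0, 0.0])
        states = dict(zip(ids, ["deletion", "normal", "normal", "normal", "duplication", "normal"]))
        out = assoc.family_permutation_test(states, "deletion", adjusted(values), fams,
                                            assoc.PermutationPlan(n_permutations=10, seed=2))
        assert out.n_carriers == 1
        assert out.n_normal == 4  # the duplication carrier is in neither group
        assert out.statistic == pytest.approx(10.0 - 0.0)


class TestPopulationTest:
    def test_equivalent_to_single_family_test(self, rng):
        values = rng.normal(0, 1, 30)
        ids = [f"S{i}" for i in range(30)]
        carrier = rng.random(30) < 0.2
        carrier[0] = True
        states = {sid: ("deletion" if carrier[i] else "normal") for i, sid in enumerate(ids)}
        res = adjusted(values)
        plan = assoc.PermutationPlan(n_permutations=3000, seed=3)
        pop = assoc.population_permutation_test(states, "deletion", res, plan)
        one_family = [Family("ALL", ids, {i: 1 for i in ids})]
        fam = assoc.family_permutation_test(states, "deletion", res, one_family, plan)
        assert pop.statistic == pytest.approx(fam.statistic)
        assert pop.p_value == fam.p_value

    def test_constant_residuals(self):
        ids = [f"S{i}" for i in range(10)]
        states = {sid: "normal" for sid in ids}
        states["S0"] = "deletion"
        out = assoc.population_permutation_test(states, "deletion", adjusted(np.zeros(10)),
                                                assoc.PermutationPlan(n_permutations=50, seed=1))
        assert out.p_value == 1.0


def maxt_fdr_oracle(t_obs, t_perm):
    """Brute-force spreadsheet-style computation with explicit loops."""
    B, L = t_perm.shape
    p_adj, fdr = [], []
    for j in range(L):
        t = abs(t_obs[j])
        hits = sum(1 for b in range(B) if max(abs(t_perm[b, k]) for k in range(L)) >= t)
        p_adj.append(hits / B)
        exceed = sum(1 for b in range(B) for k in range(L) if abs(t_perm[b, k]) >= t)
        observed = sum(1 for k in range(L) if abs(t_obs[k]) >= t)
        fdr.append((exceed / B) / max(1, observed))
    return np.array(p_adj), np.array(fdr)


class TestMaxTFdr:
    def test_matches_brute_force_exactly(self, rng):
        t_obs = rng.normal(0, 1, 5)
        t_perm = rng.normal(0, 1, (20, 5))
        p_adj, fdr = assoc.adjust_maxT_fdr(t_obs, t_perm)
        p_oracle, fdr_oracle = maxt_fdr_oracle(t_obs, t_perm)
        np.testing.assert_array_equal(p_adj, p_oracle)
        np.testing.assert_allclose(fdr, fdr_oracle, rtol=1e-12)

    def test_monotone_in_statistic(self, rng):
        t_obs = rng.normal(0, 2, 12)
        t_perm = rng.normal(0, 1, (200, 12))
        p_adj, fdr = assoc.adjust_maxT_fdr(t_obs, t_perm)
        order = np.argsort(-np.abs(t_obs))
        assert (np.diff(p_adj[order]) >= 0).all()
        assert p_adj[order[0]] == p_adj.min()
        # the empirical-FDR *numerator and denominator* are monotone in |T|
        # even though their ratio need not be
        expected = np.array([np.mean(np.abs(t_perm) >= t) for t in np.abs(t_obs)])
        assert (np.diff(expected[order]) >= 0).all()

    def test_single_locus_adjusted_equals_raw(self, rng):
        t_obs = np.array([1.3])
        t_perm = rng.normal(0, 1, (50, 1))
        p_adj, fdr = assoc.adjust_maxT_fdr(t_obs, t_perm)
        raw = np.mean(np.abs(t_perm[:, 0]) >= abs(t_obs[0]))
        assert p_adj[0] == raw
        assert fdr[0] >= raw

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assoc.adjust_maxT_fdr(np.zeros(3), np.zeros((10, 4)))


class TestScan:
    def _setup(self, rng):
        snp_map = grid_map(30, start=1000)
        n = 60
        ids = [f"S{i}" for i in range(n)]
        fams, fids = pair_families(30)
        id_map = dict(zip(fids, ids))
        fams = [Family(f.family_id, [id_map[m] for m in f.member_ids],
                       {id_map[m]: 1 for m in f.member_ids}) for f in fams]
        carrier = rng.random(n) < 0.15
        carrier[:2] = True
        calls = [
            CnvCall(ids[i], "chr1", 5000, 12000, CnvState.DELETION, 8, source=CallSource.CONSENSUS)
            for i in range(n) if carrier[i]
        ]
        matrix = assoc.build_state_matrix(calls, snp_map, ids)
        res = adjusted(rng.normal(0, 1, n))
        return matrix, res, fams

    def test_single_locus_scan_equals_single_test(self, rng):
        matrix, res, fams = self._setup(rng)
        plan = assoc.PermutationPlan(n_permutations=500, seed=4)
        scan = assoc.genomewide_scan(matrix, "deletion", res, fams, plan, freq_min=0.05)
        covered = [r for r in scan.results]
        assert covered  # the shared deletion region is eligible
        first = covered[0]
        states = {sid: ("deletion" if s else "normal")
                  for sid, s in zip(matrix.sample_ids, matrix.states_at(first.snp_id) == 1)}
        single = assoc.family_permutation_test(states, "deletion", res, fams, plan)
        assert first.statistic == pytest.approx(single.statistic)
        assert first.p_value == single.p_value

    def test_identical_loci_get_identical_results(self, rng):
        matrix, res, fams = self._setup(rng)
        plan = assoc.PermutationPlan(n_permutations=400, seed=8)
        scan = assoc.genomewide_scan(matrix, "deletion", res, fams, plan)
        covered = scan.results
        assert len(covered) >= 2  # loci inside one CNV region share carriers
        for r in covered[1:]:
            assert r.statistic == pytest.approx(covered[0].statistic)
            assert r.p_value == covered[0].p_value
            assert r.p_adjusted == covered[0].p_adjusted
            assert r.fdr == covered[0].fdr

    def test_adjusted_p_dominates_raw_p(self, rng):
        matrix, res, fams = self._setup(rng)
        scan = assoc.genomewide_scan(matrix, "deletion", res, fams,
                                     assoc.PermutationPlan(n_permutations=300, seed=2))
        for r in scan.results:
            assert r.p_adjusted >= r.p_value

    def test_reproducible_with_same_seed(self, rng):
        matrix, res, fams = self._setup(rng)
        plan = assoc.PermutationPlan(n_permutations=300, seed=11)
        s1 = assoc.genomewide_scan(matrix, "deletion", res, fams, plan)
        s2 = assoc.genomewide_scan(matrix, "deletion", res, fams, plan)
        assert [(r.snp_id, r.statistic, r.p_value, r.p_adjusted, r.fdr) for r in s1.results] == [
            (r.snp_id, r.statistic, r.p_value, r.p_adjusted, r.fdr) for r in s2.results
        ]


class TestAmpliconSize:
    def test_worked_example(self):
        assert assoc.expected_amplicon_size(17_400, 11_000) == 6_400

    @pytest.mark.parametrize("flank,deletion", [(100, 100), (100, 150), (100, 0), (100, -5)])
    def test_degenerate_inputs_rejected(self, flank, deletion):
        with pytest.raises(ValueError):
            assoc.expected_amplicon_size(flank, deletion)
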