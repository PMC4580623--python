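import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coupledmoves.metrics import (
    AA_ORDER,
    PositionProfile,
    build_profiles,
    design_diagnostics,
    enrichment_analysis,
    entropy_tertiles,
    fisher_correctness_pvalue,
    paired_similarity_pvalue,
    profile_similarity,
    rmsd_report,
    sequence_entropy,
    uniform_null_similarity,
)
from coupledmoves.sampler import DesignTrace, MoveRecord


def point_mass(aa):
    p = np.zeros(20)
    p[AA_ORDER.index(aa)] = 1.0
    return PositionProfile(aa, p)


def profile(vec):
    return PositionProfile("x", np.asarray(vec) / np.sum(vec))


class TestEnrichment:
    def test_pe_from_definition(self):
        native = ["L"] * 8 + ["A"] * 2       # A in 20% of native
        nonnative = ["A"] * 8 + ["L"] * 2    # A in 80% of non-native
        rows = enrichment_analysis(native, nonnative, "wt2mut", reference_seq="L")
        a_row = next(r for r in rows if r.to_aa == "A")
        assert a_row.PE == pytest.approx(60.0)
        assert a_row.correct

    def test_identical_sets_nothing_correct(self):
        seqs = ["L", "A", "S"]
        rows = enrichment_analysis(seqs, list(seqs), "wt2mut", reference_seq="L")
        assert all(r.PE == 0 for r in rows)
        assert not any(r.correct for r in rows)

    def test_top_mutation_rank_one_percentile_100(self):
        native = ["LL"] * 10
        nonnative = ["SL"] * 8 + ["LV"] * 2
        rows = enrichment_analysis(native, nonnative, "wt2mut", reference_seq="LL")
        top = rows[0]
        assert (top.to_aa, top.rank, top.percentile) == ("S", 1, 100.0)

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(0)
        native = ["".join(rng.choice(list("LASV"), 3)) for _ in range(30)]
        nonnative = ["".join(rng.choice(list("LASV"), 3)) for _ in range(30)]
        fwd = enrichment_analysis(native, nonnative, "wt2mut", reference_seq="LLL")
        rev = enrichment_analysis(native, nonnative, "mut2wt", reference_seq="LLL")
        fwd_map = {(r.position, r.to_aa): r.PE for r in fwd}
        for r in rev:
            assert fwd_map[(r.position, r.to_aa)] == -r.PE

    def test_ranks_are_a_permutation_and_percentile_decreasing(self):
        native = ["LA", "LS", "AA", "LA"]
        nonnative = ["SA", "SS", "LV", "SA"]
        rows = enrichment_analysis(native, nonnative, "wt2mut", reference_seq="LA")
        assert sorted(r.rank for r in rows) == list(range(1, len(rows) + 1))
        by_rank = sorted(rows, key=lambda r: r.rank)
        assert all(a.percentile > b.percentile for a, b in zip(by_rank, by_rank[1:]))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_analysis([], ["L"], "wt2mut")


class TestProfiles:
    def test_identical_sequences_point_mass(self):
        profs = build_profiles(["LAS"] * 10)
        for p, aa in zip(profs, "LAS"):
            assert p.p[AA_ORDER.index(aa)] == 1.0

    def test_half_half_column(self):
        profs = build_profiles(["A", "A", "V", "V", "A", "V"])
        assert profs[0].p[AA_ORDER.index("A")] == pytest.approx(0.5)
        assert profs[0].p[AA_ORDER.index("V")] == pytest.approx(0.5)

    def test_pseudocount_formula(self):
        profs = build_profiles(["A"], pseudocount=1.0)
        assert profs[0].p[AA_ORDER.index("A")] == pytest.approx(2 / 21)
        assert profs[0].p[AA_ORDER.index("V")] == pytest.approx(1 / 21)

    def test_gap_columns_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            profs = build_profiles(["A-S", "A-S"])
        assert [p.position for p in profs] == [0, 2]


class TestSimilarityEntropy:
    def test_identical_profiles_similarity_one(self):
        p = profile([1, 2, 3] + [1] * 17)
        assert profile_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_point_masses_similarity_zero(self):
        assert profile_similarity(point_mass("A"), point_mass("V")) == pytest.approx(0.0)

    def test_similarity_matches_termwise_oracle(self):
        # p = (1/2, 1/2, 0, ...), q = (1, 0, 0, ...): direct base-2 summation
        p = np.zeros(20); p[:2] = 0.5
        q = np.zeros(20); q[0] = 1.0
        m = (p + q) / 2
        def kl(a, b):
            mask = a > 0
            return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
        js = 0.5 * kl(p, m) + 0.5 * kl(q, m)
        got = profile_similarity(PositionProfile("p", p), PositionProfile("q", q))
        assert got == pytest.approx(1.0 - js, abs=1e-12)

    def test_entropy_closed_forms(self):
        assert sequence_entropy(point_mass("A")) == 0.0
        assert sequence_entropy(profile([1.0] * 20)) == pytest.approx(1.0)
        assert sequence_entropy(profile([1, 1] + [0] * 18)) == pytest.approx(
            math.log(2) / math.log(20)
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=20, max_size=20), st.data())
    def test_entropy_schur_concavity(self, weights, data):
        """Moving mass from a more- to a less-probable residue never lowers H."""
        p = np.asarray(weights) / np.sum(weights)
        i, j = np.argmax(p), np.argmin(p)
        if i == j:
            return
        eps = data.draw(st.floats(0.0, float(p[i] - p[j]) / 2))
        q = p.copy()
        q[i] -= eps
        q[j] += eps
        assert sequence_entropy(PositionProfile("q", q)) >= sequence_entropy(
            PositionProfile("p", p)
        ) - 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.001, 10.0), min_size=20, max_size=20),
        st.lists(st.floats(0.001, 10.0), min_size=20, max_size=20),
    )
    def test_similarity_symmetric_and_bounded(self, a, b):
        p = profile(a)
        q = profile(b)
        s_pq = profile_similarity(p, q)
        s_qp = profile_similarity(q, p)
        assert s_pq == pytest.approx(s_qp, abs=1e-12)
        assert 0.0 <= s_pq <= 1.0


class TestNullAndTertiles:
    def test_uniform_natural_similarity_one(self):
        assert uniform_null_similarity([profile([1.0] * 20)])[0] == pytest.approx(1.0)

    def test_point_mass_null_matches_closed_form(self):
        p = np.zeros(20); p[0] = 1.0
        u = np.full(20, 1 / 20)
        m = (p + u) / 2
        js = 0.5 * (1.0 * np.log2(1.0 / m[0])) + 0.5 * float(
            np.sum(u * np.log2(u / m))
        )
        got = uniform_null_similarity([point_mass("A")])[0]
        assert got == pytest.approx(1.0 - js, abs=1e-12)

    def test_label_permutation_invariance(self):
        a = profile([5, 1, 1, 3] + [1] * 16)
        perm = np.array(a.p)[::-1]
        s1 = uniform_null_similarity([a])[0]
        s2 = uniform_null_similarity([PositionProfile("b", perm)])[0]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_tertile_sizes(self):
        profs = [profile([1] * k + [10] * (20 - k)) for k in range(1, 10)]
        groups = entropy_tertiles(profs)
        assert [len(groups[g]) for g in ("low", "medium", "high")] == [3, 3, 3]
        profs10 = profs + [profile([1.0] * 20)]
        groups10 = entropy_tertiles(profs10)
        assert [len(groups10[g]) for g in ("low", "medium", "high")] == [4, 3, 3]

    def test_all_equal_entropies_deterministic(self):
        profs = [profile([1.0] * 20) for _ in range(6)]
        for p, label in zip(profs, "abcdef"):
            p.position = label
        g1 = entropy_tertiles(profs)
        g2 = entropy_tertiles(profs)
        assert g1 == g2  # stable sort decides ties


class TestDiagnosticsAndSignificance:
    def _trace(self, seqs, n_moves=10, n_accepted=4):
        ledger = [MoveRecord("protein", ("A", 1), 0.0, i < n_accepted) for i in range(n_moves)]
        return DesignTrace((("A", 1), ("A", 2)), seqs, ledger, {}, {})

    def test_glycine_fraction_and_acceptance(self):
        trace = self._trace(["GL", "GG"], n_moves=1000, n_accepted=400)
        frac, acc = design_diagnostics(trace)
        assert frac == pytest.approx(3 / 4)
        assert acc == pytest.approx(0.4)

    def test_all_rejected_zero_acceptance(self):
        trace = self._trace(["LL"], n_moves=10, n_accepted=0)
        _, acc = design_diagnostics(trace)
        assert acc == 0.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        p = fisher_correctness_pvalue([[10, 0], [0, 10]])
        expected = 2 / math.comb(20, 10)
        assert abs(p - expected) < 1e-12

    def test_fisher_no_association(self):
        assert fisher_correctness_pvalue([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fisher_degenerate_margin(self):
        with pytest.warns(UserWarning):
            assert fisher_correctness_pvalue([[0, 0], [5, 5]]) == 1.0

    def test_paired_t_identical_vectors(self):
        with pytest.warns(UserWarning):
            assert paired_similarity_pvalue([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == 1.0

    def test_paired_t_detects_shift(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.4, 0.6, size=30)
        b = a + 0.1 + rng.normal(0, 0.01, size=30)
        assert paired_similarity_pvalue(a, b) < 1e-6


class TestRmsdReport:
    def test_identity_zero(self, helix):
        out = rmsd_report(helix, helix, [("A", 5)])
        assert out[("A", 5)] == pytest.approx(0.0)

    def test_single_displaced_atom_closed_form(self, helix):
        moved = helix.copy()
        res = moved.residue(("A", 5))  # phenylalanine, 7 side-chain heavy atoms
        n = len(res.sidechain)
        res.sidechain[0].coords = res.sidechain[0].coords + np.array([1.0, 0, 0])
        out = rmsd_report(moved, helix, [("A", 5)])
        assert out[("A", 5)] == pytest.approx(1 / math.sqrt(n), abs=1e-6)

    def test_rigid_transform_invariance(self, helix):
        from scipy.spatial.transform import Rotation

        moved = helix.copy()
        res = moved.residue(("A", 5))
        res.sidechain[0].coords = res.sidechain[0].coords + np.array([0.7, 0, 0])
        before = rmsd_report(moved, helix, [("A", 5)])[("A", 5)]
        R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        for r in moved.residues:
            for a in r.atoms:
                a.coords = R @ a.coords + np.array([4.0, 5.0, -6.0])
        after = rmsd_report(moved, helix, [("A", 5)])[("A", 5)]
        assert after == pytest.approx(before, abs=1e-6)

    def test_identity_mismatch_warns_and_compares_common(self, helix, rotlib):
        from coupledmoves.rotamers import Rotamer, build_sidechain

        moved = helix.copy()
        build_sidechain(moved, ("A", 5), Rotamer("L", (-65.0, 175.0), 0.5))
        with pytest.warns(UserWarning, match="identity mismatch"):
            out = rmsd_report(moved, helix, [("A", 5)])
        assert ("A", 5) in out
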