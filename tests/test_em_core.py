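"""Clonotype universe construction, compatibility sets and the EM iteration."""

import numpy as np
import pytest

from eclipse_tcr import em_core
from eclipse_tcr.em_core import CompatibilityRecord, build_universe, compatibility, run_em
from eclipse_tcr.special_clones import SpecialClone

from conftest import make_cell, random_compat_instance


def brute_force_theta(candidate_sets, n_clonotypes, iters=200_000, tol=1e-13):
    """Independent dense fixed-point solver for the censored-multinomial MLE."""
    M = np.zeros((len(candidate_sets), n_clonotypes))
    for i, cands in enumerate(candidate_sets):
        M[i, list(cands)] = 1.0
    A = M / M.sum(axis=1, keepdims=True)
    theta = A.sum(axis=0) / len(candidate_sets)
    for _ in range(iters):
        W = M * theta
        A = W / W.sum(axis=1, keepdims=True)
        new = A.sum(axis=0) / len(candidate_sets)
        if np.abs(new - theta).max() < tol:
            return new
        theta = new
    return theta


class TestBuildUniverse:
    def test_direct_enumeration(self):
        cells = [make_cell(f"c{i}", {"A1"}, {"B1"}) for i in range(3)]
        cells.append(make_cell("c3", {"A2"}, {"B1"}))
        universe, index = build_universe(cells)
        assert sorted(ct.label for ct in universe) == ["A1|B1", "A2|B1"]
        assert index[("TRB", "B1")] == {0, 1}

    def test_multi_alpha_cell_contributes_cross_product(self):
        cells = [make_cell("c0", {"A1", "A2"}, {"B1"})]
        universe, _ = build_universe(cells)
        assert sorted(ct.label for ct in universe) == ["A1|B1", "A2|B1"]

    def test_empty_input(self):
        universe, index = build_universe([])
        assert universe == [] and index == {}

    def test_no_paired_cell_warns(self):
        with pytest.warns(UserWarning, match="both chain types"):
            universe, _ = build_universe([make_cell("c0", {"A1"}, set())])
        assert universe == []

    def test_special_claimed_subpairs_suppressed_unless_independent(self):
        sp = SpecialClone(
            alpha=frozenset({"A1", "A2"}), beta=frozenset({"B1"}), bitypic_type="TRA",
            monotypic_cdr3="B1", bitypic_major="A1", bitypic_minor="A2", rule="A",
        )
        claimed = [make_cell(f"c{i}", {"A1", "A2"}, {"B1"}) for i in range(3)]
        claimed.append(make_cell("c3", {"A1"}, {"B1"}))  # subset of the clone
        universe, _ = build_universe(claimed, [sp])
        assert [ct.label for ct in universe] == ["A1/A2|B1"]
        # independent evidence for the pair in a cell with a foreign chain set
        universe2, _ = build_universe(claimed + [make_cell("c4", {"A1"}, {"B1", "B9"})], [sp])
        assert "A1|B1" in {ct.label for ct in universe2}


class TestCompatibility:
    @pytest.fixture
    def small_universe(self):
        cells = [make_cell("u0", {"A1"}, {"B1"}), make_cell("u1", {"A2"}, {"B1"})]
        return build_universe(cells)

    def test_beta_only_cell_matches_all_pairings(self, small_universe):
        universe, index = small_universe
        rec = compatibility(make_cell("x", set(), {"B1"}), universe, index)
        assert set(rec.candidate_ids) == {0, 1} and rec.ambiguous and not rec.terminal

    def test_complete_pair_is_unambiguous(self, small_universe):
        universe, index = small_universe
        rec = compatibility(make_cell("x", {"A1"}, {"B1"}), universe, index)
        assert len(rec.candidate_ids) == 1 and not rec.ambiguous

    def test_unknown_chain_is_terminal(self, small_universe):
        universe, index = small_universe
        rec = compatibility(make_cell("x", set(), {"B9"}), universe, index)
        assert rec.terminal and rec.candidate_ids == ()

    def test_extra_chain_cell_candidates_are_observed_subsets(self, small_universe):
        universe, index = small_universe
        rec = compatibility(make_cell("x", {"A1", "A2"}, {"B1"}), universe, index)
        assert set(rec.candidate_ids) == {0, 1}


class TestRunEM:
    def test_all_unambiguous_matches_empirical_frequencies(self):
        cells = [make_cell(f"c{i}", {"A1"}, {"B1"}) for i in range(3)]
        cells += [make_cell("c3", {"A2"}, {"B2"})]
        universe, index = build_universe(cells)
        records = [compatibility(c, universe, index) for c in cells]
        result = run_em(records, len(universe))
        by_label = dict(zip([ct.label for ct in universe], result.theta))
        assert by_label["A1|B1"] == pytest.approx(0.75)
        assert by_label["A2|B2"] == pytest.approx(0.25)
        assert result.trace.iterations <= 2
        rows = result.assignment.toarray()
        assert np.allclose(rows.max(axis=1), 1.0)  # indicator rows

    def test_fixed_point_fixture(self, fixed_point_cells):
        universe, index = build_universe(fixed_point_cells)
        records = [compatibility(c, universe, index) for c in fixed_point_cells]
        result = run_em(records, len(universe))
        by_label = dict(zip([ct.label for ct in universe], result.theta))
        # x = (3 + x)/5 -> x = 0.75
        assert by_label["CAAAF|CBBBF"] == pytest.approx(0.75, abs=1e-6)
        assert by_label["CACCF|CBBBF"] == pytest.approx(0.25, abs=1e-6)
        posterior = result.assignment.getrow(4).toarray().ravel()
        assert posterior.sum() == pytest.approx(1.0)
        assert sorted(posterior, reverse=True)[:2] == pytest.approx([0.75, 0.25], abs=1e-6)

    def test_three_chain_cell_reaches_same_fixed_point(self):
        cells = [make_cell(f"c{i}", {"A1"}, {"B1"}) for i in range(3)]
        cells += [make_cell("c3", {"A2"}, {"B1"}), make_cell("c4", {"A1", "A2"}, {"B1"})]
        universe, index = build_universe(cells)
        records = [compatibility(c, universe, index) for c in cells]
        result = run_em(records, len(universe))
        posterior = result.assignment.getrow(4).toarray().ravel()
        assert sorted(posterior, reverse=True)[:2] == pytest.approx([0.75, 0.25], abs=1e-6)

    def test_agrees_with_brute_force_fixed_point(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            records, k = random_compat_instance(rng)
            result = run_em(records, k, epsilon=1e-10)
            expected = brute_force_theta([r.candidate_ids for r in records], k)
            assert np.abs(result.theta - expected).max() < 1e-6

    def test_loglik_monotone_and_theta_normalized(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            records, k = random_compat_instance(rng, max_cells=12, max_clonotypes=6)
            result = run_em(records, k)
            assert abs(result.theta.sum() - 1.0) < 1e-9
            assert (result.theta >= 0).all()
            diffs = np.diff(result.trace.loglik_history)
            assert (diffs >= -1e-8).all()
            rowsums = np.asarray(result.assignment.sum(axis=1)).ravel()
            assert np.allclose(rowsums, 1.0, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        records, k = random_compat_instance(rng, max_cells=6, max_clonotypes=4)
        base = run_em(records, k, epsilon=1e-10)
        perm = rng.permutation(k)  # clonotype id relabelling
        relabelled = [
            CompatibilityRecord(r.barcode, tuple(sorted(int(perm[c]) for c in r.candidate_ids)),
                                r.ambiguous, r.terminal)
            for r in records
        ]
        shuffled = [relabelled[i] for i in rng.permutation(len(relabelled))]
        other = run_em(shuffled, k, epsilon=1e-10)
        assert np.allclose(other.theta[perm], base.theta, atol=1e-9)

    def test_deterministic(self, fixed_point_cells):
        universe, index = build_universe(fixed_point_cells)
        records = [compatibility(c, universe, index) for c in fixed_point_cells]
        a = run_em(records, len(universe))
        b = run_em(records, len(universe))
        assert (a.theta == b.theta).all()

    def test_non_convergence_warns_but_returns(self, fixed_point_cells):
        universe, index = build_universe(fixed_point_cells)
        records = [compatibility(c, universe, index) for c in fixed_point_cells]
        with pytest.warns(UserWarning, match="did not converge"):
            result = run_em(records, len(universe), epsilon=1e-12, max_iter=2)
        assert not result.trace.converged
        assert abs(result.theta.sum() - 1.0) < 1e-9

    def test_invalid_arguments(self, fixed_point_cells):
        universe, index = build_universe(fixed_point_cells)
        records = [compatibility(c, universe, index) for c in fixed_point_cells]
        with pytest.raises(ValueError):
            run_em(records, len(universe), epsilon=0.0)
        terminal = [CompatibilityRecord("t", (), True, True)]
        with pytest.raises(ValueError, match="non-terminal"):
            run_em(terminal, 2)
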