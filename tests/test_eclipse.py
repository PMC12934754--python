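"""Assignment thresholds, partial-cell joining, annotation and export."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eclipse_tcr import eclipse, synth
from eclipse_tcr.eclipse import (
    AssignmentDecision,
    EclipseConfig,
    assignment_rule,
    decide,
    doublet_filter,
    flag_invariant_t,
    join_partial_cells,
    run_eclipse,
)
from eclipse_tcr.special_clones import SpecialClone

from conftest import make_cell


def oracle_rule(p1, p2):
    """Independently coded decision predicate for cross-checking."""
    r = float("inf") if p2 == 0 else p1 / p2
    if p1 >= 0.8:
        return "P80"
    elif (p1 >= 0.7) and (r > 5):
        return "P70R5"
    elif (p1 > 0.5) and (r > 10):
        return "P50R10"
    return "none"


class TestDecide:
    @pytest.mark.parametrize(
        "p1,p2,rule",
        [
            (0.995, 0.005, "P80"),
            (0.75, 0.0008, "P70R5"),
            (0.75, 0.25, "none"),  # r = 3: no rule fires
            (0.55, 0.05, "P50R10"),
            (0.8, 0.2, "P80"),  # inclusive boundary
            (0.7, 0.7 / 5, "none"),  # r = 5 exactly: strict
            (0.5, 0.04, "none"),  # p1 = 0.5 exactly: strict
        ],
    )
    def test_threshold_rules(self, p1, p2, rule):
        assert assignment_rule(p1, p2) == rule

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.5))
    def test_predicate_matches_independent_oracle(self, p1, raw_p2):
        p2 = min(raw_p2, p1)  # posterior ordering p1 >= p2
        assert assignment_rule(p1, p2) == oracle_rule(p1, p2)

    def test_monotone_in_p1(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            p2 = rng.uniform(0, 0.5)
            p1 = rng.uniform(p2, 1.0)
            if assignment_rule(p1, p2) != "none":
                bigger = p1 + (1 - p1) * rng.random()
                assert assignment_rule(bigger, p2) != "none"

    def test_decide_orders_posterior_and_sets_ratio(self):
        dec = decide({0: 0.2, 1: 0.75, 2: 0.05}, barcode="x")
        assert dec.c1 == 1 and dec.p1 == 0.75 and dec.p2 == 0.2
        assert dec.ratio == pytest.approx(3.75)
        assert not dec.assigned

    def test_ratio_infinite_when_runner_up_zero(self):
        dec = decide({3: 1.0})
        assert math.isinf(dec.ratio) and dec.assigned and dec.rule_fired == "P80"

    def test_singleton_guard_blocks_assignment(self):
        dec = decide({0: 0.9, 1: 0.1}, singleton_guard=True)
        assert not dec.assigned and dec.rule_fired == "none"

    def test_empty_posterior_is_terminal(self):
        dec = decide({}, barcode="t")
        assert not dec.assigned and dec.c1 is None


class TestJoinPartialCells:
    @pytest.fixture
    def clone(self):
        return SpecialClone(
            alpha=frozenset({"A1", "A2"}), beta=frozenset({"B1"}), bitypic_type="TRA",
            monotypic_cdr3="B1", bitypic_major="A1", bitypic_minor="A2", rule="A",
        )

    def test_two_of_three_pair_joined(self, clone):
        dec = AssignmentDecision("c", final_alpha=frozenset({"A1"}), final_beta=frozenset({"B1"}))
        (out,), amb = join_partial_cells([dec], [clone])
        assert out.final_alpha == {"A1", "A2"} and amb == []

    def test_unrelated_pair_unchanged(self, clone):
        dec = AssignmentDecision("c", final_alpha=frozenset({"A9"}), final_beta=frozenset({"B9"}))
        (out,), _ = join_partial_cells([dec], [clone])
        assert out.final_alpha == {"A9"}

    def test_pair_matching_two_clones_is_ambiguous(self, clone):
        other = SpecialClone(
            alpha=frozenset({"A1", "A7"}), beta=frozenset({"B1"}), bitypic_type="TRA",
            monotypic_cdr3="B1", bitypic_major="A1", bitypic_minor="A7", rule="A",
        )
        dec = AssignmentDecision("c", final_alpha=frozenset({"A1"}), final_beta=frozenset({"B1"}))
        (out,), amb = join_partial_cells([dec], [clone, other])
        assert out.final_alpha == {"A1"} and amb == ["c"]

    def test_single_chain_cells_not_joined(self, clone):
        dec = AssignmentDecision("c", final_alpha=frozenset(), final_beta=frozenset({"B1"}))
        (out,), _ = join_partial_cells([dec], [clone])
        assert out.final_beta == {"B1"} and out.final_alpha == frozenset()


class TestDoubletFilter:
    def test_chain_count_boundaries(self):
        five = make_cell("a", {"A1", "A2"}, {"B1", "B2", "B3"})
        three_alpha = make_cell("b", {"A1", "A2", "A3"}, {"B1"})
        boundary = make_cell("c", {"A1", "A2"}, {"B1", "B2"})
        kept, removed = doublet_filter([five, three_alpha, boundary])
        assert [c.barcode for c in removed] == ["a", "b"]
        assert [c.barcode for c in kept] == ["c"]

    def test_min_umis_excludes_weak_chains(self):
        cell = make_cell("a", {"A1", "A2", "A3"}, {"B1"}, umis={"A3": 1, "A1": 9, "A2": 9, "B1": 9})
        kept, removed = doublet_filter([cell], min_umis=2)
        assert kept and not removed


class TestInvariantTFlag:
    def _cell(self, v, j):
        cell = make_cell("x", {"CAF"}, set())
        cell.chain_meta[("TRA", "CAF")]["v_gene"] = v
        cell.chain_meta[("TRA", "CAF")]["j_gene"] = j
        return cell

    @pytest.mark.parametrize(
        "v,j,flag",
        [
            ("TRAV1-2", "TRAJ33", "MAIT"),
            ("TRAV1-2*01", "TRAJ20", "MAIT"),
            ("TRAV1-2", "TRAJ12", "MAIT"),
            ("TRAV10", "TRAJ18", "iNKT"),
            ("TRAV12-1", "TRAJ29", "none"),
            ("TRAV1-2", "TRAJ18", "none"),
        ],
    )
    def test_segment_rules(self, v, j, flag):
        assert flag_invariant_t(self._cell(v, j)) == flag


@pytest.fixture(scope="module")
def noise_free():
    config = synth.SimConfig(
        n_clones=40, seed=17, dropout_alpha=0.0, dropout_beta=0.0,
        ambient_rate=0.0, doublet_rate=0.0,
    )
    sim = synth.simulate(config)
    return sim, run_eclipse(sim.contigs, sim.cells)


class TestEndToEnd:
    def test_noise_free_exact_recovery(self, noise_free):
        sim, result = noise_free
        labels = {c["id"]: c["label"] for c in sim.truth["clones"]}
        ann = result.annotations.set_index("barcode")
        for cell in sim.truth["cells"]:
            assert ann.loc[cell["barcode"], "final_clonotype"] == labels[cell["clone_id"]]
        assert ann["annotated"].all()

    def test_row_conservation_with_tcrless_barcodes(self, noise_free):
        sim, _ = noise_free
        meta = pd.concat(
            [sim.cells, pd.DataFrame({"barcode": ["GHOST-1"], "sample": ["S1"], "cluster": [0]})],
            ignore_index=True,
        )
        result = run_eclipse(sim.contigs, meta)
        assert len(result.annotations) == len(meta)
        ghost = result.annotations.set_index("barcode").loc["GHOST-1"]
        assert ghost["final_clonotype"] == "" and not ghost["annotated"]

    def test_unannotated_fraction_not_worse_than_strict(self):
        from eclipse_tcr import io_contigs, repertoire

        sim = synth.simulate(synth.SimConfig(n_clones=60, seed=23))
        result = run_eclipse(sim.contigs, sim.cells)
        ann = result.annotations
        eclipse_pct = 100.0 * (~ann["annotated"]).mean()
        filtered = io_contigs.filter_contigs(sim.contigs, set(sim.cells["barcode"]))
        cells = io_contigs.collapse_to_cells(filtered)
        labels = repertoire.call_comparator(cells, "strict_1to1")
        for missing in set(sim.cells["barcode"]) - set(labels):
            labels[missing] = None
        assert eclipse_pct <= repertoire.pct_unannotated(labels)

    def test_clone_proportions_sum_to_one_per_sample(self, noise_free):
        _, result = noise_free
        ann = result.annotations
        grp = ann[ann["annotated"]].groupby("sample")
        for _, g in grp:
            per_clone = g.drop_duplicates("final_clonotype")
            assert per_clone["clone_proportion"].sum() == pytest.approx(1.0)

    def test_export_round_trip(self, noise_free, tmp_path):
        _, result = noise_free
        path = tmp_path / "annotations.tsv"
        eclipse.export_annotations(result.annotations, path)
        back = eclipse.read_annotations(path)
        pd.testing.assert_frame_equal(back, result.annotations, check_dtype=False)

    def test_predicted_cells_retain_observed_chains(self):
        sim = synth.simulate(synth.SimConfig(n_clones=40, seed=29))
        result = run_eclipse(sim.contigs, sim.cells)
        ann = result.annotations
        predicted = ann[ann["predicted"] & ann["assigned"]]
        assert len(predicted) > 0
        for row in predicted.itertuples():
            observed = set(filter(None, row.observed_alpha.split("/"))) | set(
                filter(None, row.observed_beta.split("/"))
            )
            assert observed  # observed chains are carried alongside the prediction
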