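"""Extra-helical base orientation calls and cleft measurements."""

import numpy as np
import pytest

from conftest import apply_rigid, random_rotation
from quadgeom.orientation import (
    ORIENTATION_CATEGORIES,
    classify_base_orientation,
    cleft_width,
    occupancy_table,
    orientation_summary,
)
from quadgeom.quartets import build_core, detect_quartets
from quadgeom.structures import Atom, Ensemble, Residue, Structure, StructureLookupError
from quadgeom.synthetic import (
    PerturbationSpec,
    QuadruplexSpec,
    build_quadruplex,
    copy_structure,
    perturb_ensemble,
)


def classify_planted(spec: QuadruplexSpec):
    st = build_quadruplex(spec)
    core = build_core(detect_quartets(st))
    loop_seqs = [s for loop in spec.loop_seq_numbers() for s in loop]
    selected = [st.residue("A", s) for s in loop_seqs]
    calls = [
        classify_base_orientation(r, core, stack_candidates=selected) for r in selected
    ]
    return st, core, selected, calls


class TestClassification:
    @pytest.mark.parametrize("category", ["out", "up", "down", "stack"])
    def test_planted_category_recovered(self, category):
        spec = QuadruplexSpec(loops=((1, category), (1, category), (1, category)))
        _, _, _, calls = classify_planted(spec)
        assert [c.category for c in calls] == [category] * 3

    def test_purely_radial_base_is_out(self):
        spec = QuadruplexSpec()  # planted "out": zero axial offset
        _, _, _, calls = classify_planted(spec)
        for call in calls:
            assert call.category == "out"
            assert abs(call.elevation_angle) < 30.0

    def test_stacked_base_names_nearest_core_guanine(self):
        spec = QuadruplexSpec(loops=((1, "stack"), (1, "out"), (1, "out")))
        st, core, selected, calls = classify_planted(spec)
        stack_call = calls[0]
        assert stack_call.category == "stack"
        # planted 3.4 A above the top guanine of column 0 (seq 3)
        assert stack_call.stack_partner.seq_number == 3
        assert 3.0 <= abs(stack_call.axial_component) <= 4.2 + 1e-6

    def test_loop_base_can_stack_on_another_loop_base(self):
        spec = QuadruplexSpec(loops=((2, "stack"), (1, "out"), (1, "out")))
        _, _, selected, calls = classify_planted(spec)
        assert calls[0].category == "stack" and calls[1].category == "stack"
        # the second piled base stacks on the first, not on the core
        assert calls[1].stack_partner.key == selected[0].key

    def test_exactly_one_category_and_stack_partner_consistency(self):
        spec = QuadruplexSpec(loops=((1, "up"), (2, "down"), (1, "stack")))
        _, _, _, calls = classify_planted(spec)
        for call in calls:
            assert call.category in ORIENTATION_CATEGORIES
            assert (call.category == "stack") == (call.stack_partner is not None)

    def test_invariant_under_rigid_motion(self, rng):
        spec = QuadruplexSpec(loops=((1, "up"), (1, "stack"), (1, "out")))
        st, core, selected, calls = classify_planted(spec)
        moved = apply_rigid(st, random_rotation(rng), rng.normal(size=3) * 15)
        core_m = build_core(detect_quartets(moved))
        loop_seqs = [s for loop in spec.loop_seq_numbers() for s in loop]
        sel_m = [moved.residue("A", s) for s in loop_seqs]
        calls_m = [
            classify_base_orientation(r, core_m, stack_candidates=sel_m) for r in sel_m
        ]
        assert [c.category for c in calls_m] == [c.category for c in calls]
        for a, b in zip(calls, calls_m):
            if a.stack_partner is not None:
                assert b.stack_partner.key == a.stack_partner.key

    def test_planted_margins_survive_threshold_perturbation(self):
        """Elevation-based categories planted with margin must not flip when
        the cuts are perturbed by +/-20% — the calls are not knife-edge
        artifacts. (A pi-stack sits at a fixed 3.4 A rise, so uniformly
        scaled axial windows are exactly the scan that *should* flip it.)"""
        spec = QuadruplexSpec(loops=((1, "up"), (1, "out"), (1, "down")))
        st, core, selected, _ = classify_planted(spec)
        expected = ["up", "out", "down"]
        for scale in (0.8, 1.2):
            calls = [
                classify_base_orientation(
                    r, core,
                    stack_candidates=selected,
                    stack_lateral_max=2.5 * scale,
                    elevation_cut=30.0 * scale,
                    plane_angle_max=30.0 * scale,
                )
                for r in selected
            ]
            assert [c.category for c in calls] == expected, scale

    def test_missing_ring_atoms_raise(self, parallel_core):
        stub = Residue(
            chain_id="A", seq_number=50, name="DT",
            atoms=[Atom(name="N1", element="N", position=[0, 0, 50])],
        )
        with pytest.raises(ValueError, match="ring atoms"):
            classify_base_orientation(stub, parallel_core)


class TestOccupancy:
    def test_identical_members_give_100_percent(self):
        spec = QuadruplexSpec(loops=((1, "stack"), (1, "out"), (1, "out")))
        st = build_quadruplex(spec)
        ens = Ensemble(members=[copy_structure(st, model_id=i + 1) for i in range(10)])
        seqs = [loop[0] for loop in spec.loop_seq_numbers()]
        table = orientation_summary(ens, seqs)
        first_label = st.residue("A", seqs[0]).label
        assert table.loc[first_label, "stack"] == pytest.approx(100.0)
        assert table.sum(axis=1).to_numpy() == pytest.approx([100.0] * 3)

    def test_planted_70_30_split(self):
        calls = [{"C9": "out"}] * 7 + [{"C9": "up"}] * 3
        table = occupancy_table(calls)
        assert table.loc["C9", "out"] == pytest.approx(70.0)
        assert table.loc["C9", "up"] == pytest.approx(30.0)

    def test_population_weighted_medoids(self):
        # weighting medoid calls by cluster populations: 0.6/0.4 split
        calls = [{"T12": "stack"}, {"T12": "out"}]
        table = occupancy_table(calls, weights=[0.6, 0.4])
        assert table.loc["T12", "stack"] == pytest.approx(60.0)
        assert table.loc["T12", "out"] == pytest.approx(40.0)

    def test_bad_weights_rejected(self):
        calls = [{"T12": "stack"}, {"T12": "out"}]
        with pytest.raises(ValueError, match="weights"):
            occupancy_table(calls, weights=[0.7, 0.7])

    def test_summary_over_noisy_ensemble(self):
        spec = QuadruplexSpec(loops=((1, "out"), (1, "out"), (1, "out")))
        st = build_quadruplex(spec)
        ens = perturb_ensemble(st, PerturbationSpec(sigma_profile=0.05, n_members=5, seed=2))
        seqs = [loop[0] for loop in spec.loop_seq_numbers()]
        table = orientation_summary(ens, seqs)
        assert (table["out"].to_numpy() == pytest.approx([100.0] * 3))


class TestCleft:
    def test_two_phosphorus_atoms_10_angstrom_apart(self):
        def residue(seq, x):
            return Residue(
                chain_id="A", seq_number=seq, name="DG",
                atoms=[Atom(name="P", element="P", position=[x, 0, 0])],
            )

        st = Structure(model_id=1, chains={"A": [residue(1, 0.0), residue(2, 10.0)]})
        m = cleft_width(st, res_a=1, res_b=2, chain_id="A")
        assert m.distance == pytest.approx(10.0)
        assert round(m.distance, 1) == 10.0

    def test_missing_phosphorus_names_residue(self):
        ra = Residue(chain_id="A", seq_number=1, name="DG",
                     atoms=[Atom(name="P", element="P", position=[0, 0, 0])])
        rb = Residue(chain_id="A", seq_number=2, name="DA",
                     atoms=[Atom(name="C1'", element="C", position=[5, 0, 0])])
        st = Structure(model_id=1, chains={"A": [ra, rb]})
        with pytest.raises(StructureLookupError, match="A2"):
            cleft_width(st, ra, rb)

    def test_on_synthetic_quadruplex(self, parallel_quadruplex):
        nts = parallel_quadruplex.nucleotides("A")
        m = cleft_width(parallel_quadruplex, nts[0], nts[7])
        a = nts[0].atom("P").position
        b = nts[7].atom("P").position
        assert m.distance == pytest.approx(float(np.linalg.norm(a - b)))
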