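"""Flexibility profiles: B factors, RMSF, theoretical B, comparisons."""

import numpy as np
import pytest

from conftest import apply_rigid, random_rotation
from quadgeom.flexibility import (
    B_FROM_MSF,
    FlexibilityProfile,
    compare_profiles,
    core_guanine_selection,
    ensemble_rmsf,
    normalize_profile,
    residue_bfactors,
    rmsf_to_bfactor,
    theoretical_bfactors,
)
from quadgeom.structures import Ensemble
from quadgeom.synthetic import (
    PerturbationSpec,
    backbone_ic_table,
    build_chain,
    copy_structure,
    perturb_ensemble,
)


def small_chain(n=6, seed=4):
    rng = np.random.default_rng(seed)
    torsions = [
        {k: float(rng.uniform(-170, 170))
         for k in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")}
        for _ in range(n)
    ]
    return build_chain(backbone_ic_table(torsions, names=["DG"] * n))


class TestResidueBfactors:
    def test_per_residue_mean(self, minimal_pdb):
        from quadgeom.structures import read_structures

        st = read_structures(minimal_pdb)[0]
        profile = residue_bfactors(st, chain_id="A")
        # residue 1 atoms carry B = 10, 12, 14
        assert profile.raw_values[0] == pytest.approx(12.0)
        assert profile.raw_values[1] == pytest.approx(21.0)

    def test_constant_bfactors_give_constant_profile(self):
        chain = small_chain()
        for res in chain.residues():
            for atom in res.atoms:
                atom.bfactor = 7.5
        profile = residue_bfactors(chain, chain_id="A")
        assert np.allclose(profile.raw_values, 7.5)

    def test_base_only_scope(self):
        chain = small_chain()
        for res in chain.residues():
            for atom in res.atoms:
                atom.bfactor = 30.0 if atom.name in ("N9", "C4") else 10.0
        profile = residue_bfactors(chain, atom_scope="base_only", chain_id="A")
        assert np.allclose(profile.raw_values, 30.0)

    def test_invalid_scope_rejected(self):
        with pytest.raises(ValueError):
            residue_bfactors(small_chain(), atom_scope="sidechain", chain_id="A")


class TestNormalization:
    def test_two_point_profile(self):
        p = FlexibilityProfile(("a", "b"), [0.0, 2.0], source="crystal_b")
        norm = normalize_profile(p)
        assert norm.normalized_values == pytest.approx([-1.0, 1.0])

    def test_zscore_properties_on_random_input(self, rng):
        p = FlexibilityProfile(
            tuple(f"r{i}" for i in range(20)), rng.uniform(5, 50, 20), source="crystal_b"
        )
        norm = normalize_profile(p)
        assert np.mean(norm.normalized_values) == pytest.approx(0.0, abs=1e-9)
        assert np.std(norm.normalized_values) == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_maps_to_zeros(self):
        p = FlexibilityProfile(("a", "b", "c"), [4.0, 4.0, 4.0], source="crystal_b")
        assert np.allclose(normalize_profile(p).normalized_values, 0.0)

    def test_idempotent(self, rng):
        p = FlexibilityProfile(
            tuple(f"r{i}" for i in range(10)), rng.uniform(0, 9, 10), source="crystal_b"
        )
        once = normalize_profile(p)
        twice = normalize_profile(once)
        assert twice.normalized_values == pytest.approx(once.normalized_values, abs=1e-12)

    def test_minmax_mode(self):
        p = FlexibilityProfile(("a", "b", "c"), [2.0, 4.0, 6.0], source="crystal_b")
        norm = normalize_profile(p, mode="minmax")
        assert norm.normalized_values == pytest.approx([0.0, 0.5, 1.0])


class TestEnsembleRmsf:
    def test_identical_members_give_zero(self):
        chain = small_chain()
        ens = Ensemble(members=[copy_structure(chain, model_id=i) for i in range(1, 4)])
        profile = ensemble_rmsf(ens)
        assert np.allclose(profile.raw_values, 0.0, atol=1e-12)

    def test_recovers_planted_sigma_sqrt3(self):
        """Isotropic per-coordinate noise sigma gives RMSF = sigma*sqrt(3)."""
        chain = small_chain()
        hot = chain.nucleotides("A")[3].seq_number
        sigma = {r.seq_number: (0.2 if r.seq_number == hot else 0.05)
                 for r in chain.residues()}
        ens = perturb_ensemble(chain, PerturbationSpec(sigma_profile=sigma,
                                                       n_members=500, seed=9))
        quiet = [r.seq_number for r in chain.residues() if r.seq_number != hot]

        def fit_quiet(res, atom):
            return res.seq_number in quiet

        profile = ensemble_rmsf(ens, fit_selection=fit_quiet)
        got = profile.raw_values[3]
        expected = 0.2 * np.sqrt(3.0)
        assert abs(got - expected) / expected < 0.05

    def test_single_member_rejected(self):
        chain = small_chain()
        with pytest.raises(ValueError):
            ensemble_rmsf(Ensemble(members=[chain]))

    def test_invariant_under_global_rigid_motion(self, rng):
        chain = small_chain()
        ens = perturb_ensemble(chain, PerturbationSpec(sigma_profile=0.1,
                                                       n_members=20, seed=1))
        ref = ensemble_rmsf(ens).raw_values
        rot, t = random_rotation(rng), rng.normal(size=3) * 30
        moved = Ensemble(members=[apply_rigid(m, rot, t) for m in ens])
        assert ensemble_rmsf(moved).raw_values == pytest.approx(ref, abs=1e-9)

    def test_core_guanine_selection_covers_core_only(self, parallel_core, parallel_quadruplex):
        select = core_guanine_selection(parallel_core)
        picked = {
            r.key
            for r in parallel_quadruplex.residues()
            for a in r.atoms
            if select(r, a)
        }
        assert picked == parallel_core.core_keys()

    def test_per_atom_output(self):
        chain = small_chain()
        ens = perturb_ensemble(chain, PerturbationSpec(sigma_profile=0.1,
                                                       n_members=10, seed=2))
        profile = ensemble_rmsf(ens, per="atom")
        assert len(profile.labels) == chain.n_atoms


class TestTheoreticalB:
    def test_zero_maps_to_zero(self):
        assert rmsf_to_bfactor(0.0) == 0.0

    def test_unit_rmsf_closed_form(self):
        assert rmsf_to_bfactor(1.0) == pytest.approx(8 * np.pi**2 / 3)
        assert B_FROM_MSF == pytest.approx(26.3189, abs=1e-4)

    def test_monotone_and_nonnegative(self, rng):
        x = np.sort(rng.uniform(0, 3, 50))
        y = rmsf_to_bfactor(x)
        assert np.all(np.diff(y) >= 0)
        with pytest.raises(ValueError):
            rmsf_to_bfactor(-0.1)

    def test_profile_conversion(self):
        p = FlexibilityProfile(("a", "b"), [0.5, 1.0], source="ensemble_rmsf")
        b = theoretical_bfactors(p)
        assert b.source == "theoretical_b"
        assert b.raw_values == pytest.approx([B_FROM_MSF * 0.25, B_FROM_MSF])


class TestCompareProfiles:
    def _profile(self, values):
        return FlexibilityProfile(
            tuple(f"r{i}" for i in range(len(values))), values, source="crystal_b"
        )

    def test_self_correlation_is_one(self, rng):
        p = self._profile(rng.uniform(0, 1, 15))
        _, corr = compare_profiles([("a", p), ("b", p)])
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_profile_correlation_is_minus_one(self, rng):
        vals = rng.uniform(0, 1, 15)
        _, corr = compare_profiles(
            [("a", self._profile(vals)), ("b", self._profile(-vals))]
        )
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_disjoint_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="different index sets"):
            compare_profiles(
                [("a", self._profile(rng.uniform(0, 1, 5))),
                 ("b", self._profile(rng.uniform(0, 1, 6)))]
            )
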