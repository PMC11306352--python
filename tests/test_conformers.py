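"""SASA oracles, axial-coordination geometry, folding classification,
ensemble thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rotaphot.conformers import (
    BONDI_RADII,
    HARTREE_TO_KCAL,
    Conformer,
    EnergyComponents,
    boltzmann_weights,
    classify,
    detect_axial_coordination,
    ensemble_report,
    gibbs_energy,
    relative_energies,
    sasa,
)
from rotaphot.synthetic import gen_conformer_ensemble

PROBE = 1.4


def _single(element="C"):
    return Conformer([element], np.zeros((1, 3)))


def _pair(element, d):
    return Conformer([element] * 2, np.array([[0.0, 0, 0], [d, 0, 0]]))


class TestSasa:
    def test_isolated_atom_is_full_expanded_sphere(self):
        r = BONDI_RADII["C"] + PROBE
        res = sasa(_single("C"))
        assert res.total == pytest.approx(4 * np.pi * r**2, rel=1e-3)
        assert res.total == pytest.approx(120.76, abs=0.2)

    def test_distant_atoms_add_independently(self):
        res = sasa(_pair("C", 20.0))
        assert res.total == pytest.approx(2 * sasa(_single("C")).total, rel=1e-9)

    @pytest.mark.parametrize("d_frac", [0.5, 0.8, 0.95])
    def test_two_sphere_overlap_matches_cap_formula(self, d_frac):
        # equal expanded radii R at distance d < 2R: each sphere loses a cap
        # of height R - d/2, leaving 2 pi R (R + d/2) accessible
        R = BONDI_RADII["C"] + PROBE
        d = d_frac * 2 * R
        analytic = 2 * (2 * np.pi * R * (R + d / 2))
        assert sasa(_pair("C", d)).total == pytest.approx(analytic, rel=0.01)

    def test_rigid_motion_invariance(self):
        ens = gen_conformer_ensemble((1, 0, 1), seed=17)
        rng = np.random.default_rng(5)
        for lc in ens:
            ref = sasa(lc.conformer).total
            for _ in range(3):
                rot = Rotation.random(rng=rng).as_matrix()
                shift = rng.uniform(-20, 20, 3)
                moved = Conformer(lc.conformer.elements,
                                  lc.conformer.coordinates @ rot.T + shift)
                assert sasa(moved).total == pytest.approx(ref, rel=0.005)

    def test_quadrature_convergence_in_point_count(self):
        (lc,) = gen_conformer_ensemble((0, 1, 0), seed=19)
        a = sasa(lc.conformer, n_sphere_points=960).total
        b = sasa(lc.conformer, n_sphere_points=3840).total
        assert abs(a - b) / b < 0.005

    def test_folding_reduces_area(self):
        # moving two atoms closer along their axis cannot increase SASA
        far = sasa(_pair("C", 5.0)).total
        near = sasa(_pair("C", 3.0)).total
        assert near <= far

    def test_missing_radius_names_element(self):
        c = _single("C")
        with pytest.raises(ValueError, match="'C'"):
            sasa(c, radii={"N": 1.55})


class TestAxialCoordination:
    def test_empty_axial_site_not_coordinated(self, toy_porphyrin):
        res = detect_axial_coordination(toy_porphyrin)
        assert not res.coordinated and res.ligand_atom_index is None

    def test_axial_oxygen_detected_with_distance(self, toy_porphyrin):
        c = Conformer(toy_porphyrin.elements + ["O"],
                      np.vstack([toy_porphyrin.coordinates, [0.0, 0.0, 2.3]]))
        res = detect_axial_coordination(c)
        assert res.coordinated
        assert res.ligand_atom_index == 5
        assert res.zn_ligand_distance == pytest.approx(2.3)

    def test_off_axis_oxygen_rejected_by_cone(self, toy_porphyrin):
        # 2.3 A from Zn but 80 degrees off the plane normal
        pos = 2.3 * np.array([np.sin(np.deg2rad(80)), 0.0, np.cos(np.deg2rad(80))])
        c = Conformer(toy_porphyrin.elements + ["O"],
                      np.vstack([toy_porphyrin.coordinates, pos]))
        assert not detect_axial_coordination(c).coordinated

    def test_distant_oxygen_rejected_by_cutoff(self, toy_porphyrin):
        c = Conformer(toy_porphyrin.elements + ["O"],
                      np.vstack([toy_porphyrin.coordinates, [0.0, 0.0, 3.5]]))
        assert not detect_axial_coordination(c).coordinated

    def test_carbon_is_not_a_donor(self, toy_porphyrin):
        c = Conformer(toy_porphyrin.elements + ["C"],
                      np.vstack([toy_porphyrin.coordinates, [0.0, 0.0, 2.3]]))
        assert not detect_axial_coordination(c).coordinated

    def test_requires_one_zinc(self, toy_porphyrin):
        no_zn = Conformer(["C"] + toy_porphyrin.elements[1:], toy_porphyrin.coordinates)
        with pytest.raises(ValueError, match="Zn"):
            detect_axial_coordination(no_zn)


class TestClassify:
    def test_max_sasa_uncoordinated_is_open(self):
        assert classify(0.0, coordinated=False) == "open"

    def test_min_sasa_coordinated_is_closed(self):
        assert classify(1.0, coordinated=True) == "closed"

    def test_coordination_alone_never_yields_open(self):
        assert classify(0.0, coordinated=True) == "half-open"

    def test_intermediate_fraction_is_half_open(self):
        assert classify(0.5, coordinated=False) == "half-open"

    def test_degenerate_ensemble_uses_coordination(self):
        assert classify(None, coordinated=True) == "closed"
        assert classify(None, coordinated=False) == "open"


class TestThermodynamics:
    def test_gibbs_sum_is_exact(self):
        assert gibbs_energy(EnergyComponents(0.0, 0.0, 0.0)) == 0.0
        assert gibbs_energy(EnergyComponents(-10.0, 2.0, -3.0)) == pytest.approx(-11.0)

    def test_hartree_conversion_uses_codata_constant(self):
        assert gibbs_energy(EnergyComponents(-1.0, 0.0, 0.0, unit="hartree")) == pytest.approx(
            -HARTREE_TO_KCAL)

    def test_relative_energies_reference_the_minimum(self):
        dg = relative_energies([-5.0, 3.7])
        assert dg == pytest.approx([0.0, 8.7])
        assert relative_energies([2.0, 2.0, 2.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_relative_energies_permutation_equivariant(self):
        g = np.array([3.0, -1.0, 0.5, 7.0])
        perm = np.array([2, 0, 3, 1])
        assert relative_energies(g[perm]) == pytest.approx(relative_energies(g)[perm])

    def test_boltzmann_two_state_worked_example(self):
        w = boltzmann_weights([0.0, 1.0], temperature=298.15)
        assert w == pytest.approx([0.8440, 0.1560], abs=1e-4)
        assert w[1] / w[0] == pytest.approx(np.exp(-1.0 / 0.59248), rel=1e-3)

    def test_boltzmann_degenerate_states_split_evenly(self):
        assert boltzmann_weights([0.0, 0.0]) == pytest.approx([0.5, 0.5])
        assert boltzmann_weights([0.0]) == pytest.approx([1.0])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.0, 50.0), min_size=1, max_size=10),
           st.floats(10.0, 1000.0))
    def test_boltzmann_weights_sum_to_one_and_order_inversely(self, dg, temp):
        w = boltzmann_weights(dg, temp)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        order = np.argsort(dg)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_weights([0.0], temperature=0.0)


class TestEnsembleReport:
    def test_protonated_like_ensemble_is_closed_dominated(self, labelled_ensemble):
        rep = ensemble_report([lc.conformer for lc in labelled_ensemble])
        assert rep.category_weights["closed"] > 0.9
        assert sum(rep.category_weights.values()) == pytest.approx(1.0)
        assert rep.table.delta_g.min() == 0.0

    def test_classification_recovers_generator_labels(self, labelled_ensemble):
        rep = ensemble_report([lc.conformer for lc in labelled_ensemble])
        truth = np.array([lc.true_category for lc in labelled_ensemble])
        assert np.mean(rep.table.category.to_numpy() == truth) >= 0.95

    def test_deprotonated_like_ensemble_has_no_dominant_category(self):
        ens = gen_conformer_ensemble((10, 10, 10), seed=1, kind="deprotonated")
        rep = ensemble_report([lc.conformer for lc in ens])
        assert max(rep.category_weights.values()) <= 0.9

    def test_uniform_energies_weight_by_category_counts(self):
        ens = gen_conformer_ensemble((2, 3, 5), seed=7)
        confs = [lc.conformer for lc in ens]
        for c in confs:
            c.energy = EnergyComponents(1.0, 0.0, 0.0)
        rep = ensemble_report(confs)
        assert rep.category_weights["open"] == pytest.approx(0.2)
        assert rep.category_weights["half-open"] == pytest.approx(0.3)
        assert rep.category_weights["closed"] == pytest.approx(0.5)

    def test_classification_invariant_to_conformer_order(self, labelled_ensemble):
        confs = [lc.conformer for lc in labelled_ensemble]
        rep = ensemble_report(confs)
        rev = ensemble_report(confs[::-1])
        assert list(rev.table.category) == list(rep.table.category)[::-1]

    def test_single_conformer_classified_by_coordination(self):
        (lc,) = gen_conformer_ensemble((0, 0, 1), seed=23)
        rep = ensemble_report([lc.conformer])
        assert rep.table.category.iloc[0] == "closed"
        assert rep.table.boltzmann_weight.iloc[0] == pytest.approx(1.0)

    def test_mixed_units_rejected(self):
        ens = gen_conformer_ensemble((1, 0, 1), seed=2)
        confs = [lc.conformer for lc in ens]
        confs[0].energy = EnergyComponents(0.0, 0.0, 0.0, unit="hartree")
        with pytest.raises(ValueError, match="mixed"):
            ensemble_report(confs)
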