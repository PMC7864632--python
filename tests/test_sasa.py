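"""SASA against analytic and dense-sampling oracles; interface areas."""

import math

import numpy as np
import pytest

import statewalk as sw
from statewalk.model import CoordinateSet
from statewalk.sasa import VDW_RADII, interface, interface_track, sasa
from statewalk.synth import rotation_matrix

from oracles import dense_sasa, sphere_sasa, two_sphere_sasa


def cset(name, coords, elements):
    coords = np.asarray(coords, dtype=float)
    keys = [(name, i + 1, "", f"X{i}") for i in range(len(coords))]
    return CoordinateSet(name, keys, coords, list(elements), ["ALA"] * len(coords))


def test_single_atom_matches_analytic_sphere():
    _, total = sasa(np.zeros((1, 3)), ["C"])
    assert total == pytest.approx(sphere_sasa(1.7, 1.4), rel=0.01)


def test_distant_atoms_additive():
    coords = [[0, 0, 0], [100, 0, 0]]
    _, total = sasa(coords, ["C", "O"])
    assert total == pytest.approx(sphere_sasa(1.7, 1.4) + sphere_sasa(1.52, 1.4), rel=0.01)


@pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
def test_two_sphere_overlap_matches_cap_formula(d):
    coords = [[0, 0, 0], [d, 0, 0]]
    _, total = sasa(coords, ["C", "C"])
    assert total == pytest.approx(two_sphere_sasa(1.7, 1.7, d, 1.4), rel=0.015)


def test_rigid_transform_invariance(rng):
    coords = rng.uniform(-5, 5, size=(25, 3))
    elements = list(rng.choice(["C", "N", "O", "S"], size=25))
    _, t0 = sasa(coords, elements)
    R = rotation_matrix(rng.normal(size=3), 37.0)
    _, t1 = sasa(coords @ R.T + np.array([7.0, -3.0, 11.0]), elements)
    assert abs(t1 - t0) / t0 < 0.005


def test_point_count_convergence(rng):
    coords = rng.uniform(-4, 4, size=(15, 3))
    elements = ["C"] * 15
    totals = [sasa(coords, elements, n_points=n)[1] for n in (96, 960, 9600)]
    for a, b in zip(totals, totals[1:]):
        assert abs(a - b) / b < 0.02


def test_dense_grid_oracle_agreement(rng):
    """Golden-spiral SASA vs an independent 0.2 Å latitude-longitude
    sampler on a compact 20-atom cluster: within 3%."""
    coords = rng.uniform(-4, 4, size=(20, 3))
    elements = list(rng.choice(["C", "N", "O"], size=20))
    _, mine = sasa(coords, elements)
    radii = np.array([VDW_RADII[e] for e in elements])
    ref = dense_sasa(coords, radii, probe=1.4, spacing=0.2)
    assert abs(mine - ref) / ref < 0.03


def test_unknown_element_fallback_and_error():
    with pytest.warns(UserWarning):
        _, total = sasa(np.zeros((1, 3)), ["Zz"])
    assert total == pytest.approx(sphere_sasa(1.8, 1.4), rel=0.01)
    with pytest.raises(ValueError):
        sasa(np.zeros((1, 3)), ["Zz"], allow_fallback=False)


class TestInterface:
    def test_far_apart_zero(self):
        a = cset("a", [[0, 0, 0], [3, 0, 0]], ["C", "C"])
        b = cset("b", [[200, 0, 0], [203, 0, 0]], ["C", "C"])
        rep = interface(a, b)
        assert rep.interface_area == 0.0

    def test_symmetric_in_arguments(self, rng):
        a = cset("a", rng.uniform(-4, 4, size=(10, 3)), ["C"] * 10)
        b = cset("b", rng.uniform(-4, 4, size=(10, 3)) + np.array([5.0, 0, 0]), ["N"] * 10)
        r1 = interface(a, b)
        r2 = interface(b, a)
        assert r1.interface_area == pytest.approx(r2.interface_area, abs=1e-9)

    def test_overlapping_selections_error(self):
        a = cset("a", [[0, 0, 0], [3, 0, 0]], ["C", "C"])
        with pytest.raises(ValueError, match="overlap"):
            interface(a, a)

    def test_two_helix_interface_vs_dense_oracle(self, rng):
        """Two planted parallel Cα 'helix' rods 6 Å apart: buried area from
        the golden-spiral SASA matches the dense-sampler computation of the
        same buried-area formula within 3%."""
        z = np.arange(10) * 1.5
        rod1 = np.column_stack([np.zeros(10), np.zeros(10), z])
        rod2 = rod1 + np.array([5.0, 0.0, 0.0])
        a = cset("a", rod1, ["C"] * 10)
        b = cset("b", rod2, ["C"] * 10)
        rep = interface(a, b)
        assert rep.interface_area > 50.0  # genuinely in contact
        radii = np.full(10, VDW_RADII["C"])
        da = dense_sasa(rod1, radii, 1.4)
        db = dense_sasa(rod2, radii, 1.4)
        dab = dense_sasa(np.vstack([rod1, rod2]), np.full(20, VDW_RADII["C"]), 1.4)
        ref = (da + db - dab) / 2.0
        assert rep.interface_area == pytest.approx(ref, rel=0.03)

    def test_interface_track_argmax(self):
        """Planted growing interface across three states peaks where planted:
        two Cα rods whose separation closes 12 -> 6 -> 5 Å."""
        from statewalk.model import AtomSite, Selection, SelectionTerm
        from statewalk.model import StructureModel

        def rods(label, sep):
            atoms = []
            for i in range(10):
                atoms.append(AtomSite("A", i + 1, "", "ALA", "CA", "C", [0, 0, 1.5 * i]))
                atoms.append(AtomSite("B", i + 1, "", "ALA", "CA", "C", [sep, 0, 1.5 * i]))
            return StructureModel(label, atoms)

        from statewalk.model import DomainRegistry
        reg = DomainRegistry()
        reg.add(Selection("rod_a", [SelectionTerm("A")]), "synthetic")
        reg.add(Selection("rod_b", [SelectionTerm("B")]), "synthetic")
        ens = sw.synth.make_ensemble(
            [("S1", rods("S1", 12.0), "ATP"), ("S2", rods("S2", 6.0), "ATP"),
             ("S3", rods("S3", 5.0), "ATP")], reg)
        reports, mean, peak, argmax = interface_track(ens, "rod_a", "rod_b", n_points=960)
        assert argmax == "S3"
        assert reports["S1"].interface_area < reports["S2"].interface_area \
            < reports["S3"].interface_area
        assert math.isclose(
            mean,
            np.mean([r.interface_area for r in reports.values()]),
            rel_tol=1e-12,
        )
        assert peak == reports["S3"].interface_area

    def test_constant_interface_mean_equals_each_state(self):
        base, reg, _ = sw.synth.make_multidomain(2, 30, seed=33, domain_spacing=12.0)
        ens = sw.synth.make_ensemble(
            [("S1", base, "ATP"), ("S2", base, "ATP"), ("S3", base, "ATP")], reg
        )
        reports, mean, peak, _ = interface_track(ens, "dom1", "dom2", n_points=240)
        vals = [r.interface_area for r in reports.values()]
        assert np.ptp(vals) < 1e-9
        assert mean == pytest.approx(vals[0], abs=1e-9)
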