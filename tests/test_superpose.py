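"""Superposition: Kabsch fits, iterative outlier rejection, RMSD matrices."""

import numpy as np
import pytest

import statewalk as sw
from statewalk.superpose import DegenerateGeometryError, iterative_align, kabsch
from statewalk.synth import rotation_matrix

from oracles import grid_fit_rmsd


@pytest.fixture()
def cloud(rng):
    return rng.uniform(-10, 10, size=(10, 3))


def test_identity_fit(cloud):
    t, rmsd = kabsch(cloud, cloud)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)


def test_pure_translation_recovered(cloud):
    t, rmsd = kabsch(cloud, cloud + np.array([5.0, 0.0, 0.0]))
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(t.translation, [-5.0, 0.0, 0.0], atol=1e-9)


def test_rotation_90deg_recovered(cloud):
    R = rotation_matrix([0, 0, 1], 90.0)
    t, rmsd = kabsch(cloud, cloud @ R.T)
    assert rmsd == pytest.approx(0.0, abs=1e-8)
    angle, axis = sw.rotation_angle_axis(t.rotation)
    assert angle == pytest.approx(90.0, abs=1e-6)


def test_noisy_fit_angle_and_rmsd_band(rng):
    """Known transform + Gaussian noise σ=0.2: the recovered angle stays
    within 0.5° and the rmsd falls in the Monte-Carlo band around σ·√2
    established over repeated draws (two noisy copies of the truth differ by
    √(2)·σ per coordinate in expectation)."""
    sigma = 0.2
    P0 = rng.uniform(-15, 15, size=(200, 3))
    R = rotation_matrix([1, 2, 3], 25.0)
    angles, rmsds = [], []
    for _ in range(30):
        P = P0 + rng.normal(scale=sigma, size=P0.shape)
        Q = P0 @ R.T + np.array([1.0, -2.0, 0.5]) + rng.normal(scale=sigma, size=P0.shape)
        t, rmsd = kabsch(P, Q)
        ang, _ = sw.rotation_angle_axis(t.rotation)
        angles.append(ang)
        rmsds.append(rmsd)
    assert np.max(np.abs(np.array(angles) - 25.0)) < 0.5
    # per-atom rmsd: 3 coordinates, each with variance 2σ² (noise on both sides)
    expected = sigma * np.sqrt(6.0)
    assert 0.8 * expected < np.mean(rmsds) < 1.2 * expected


def test_degenerate_inputs_error():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        kabsch(line, line)
    with pytest.raises(DegenerateGeometryError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def test_reflection_excluded(rng):
    P = rng.uniform(-5, 5, size=(20, 3))
    Q = P.copy()
    Q[:, 0] *= -1  # mirrored cloud
    t, _ = kabsch(P, Q)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


def test_grid_oracle_equivalence(rng):
    """On ≤8 points the SVD solution matches brute-force rotation-grid
    minimization to 5e-3 Å."""
    for n in (4, 6, 8):
        P = rng.uniform(-8, 8, size=(n, 3))
        R = rotation_matrix(rng.normal(size=3), float(rng.uniform(10, 170)))
        Q = P @ R.T + rng.normal(scale=0.5, size=(n, 3))
        _, rmsd = kabsch(P, Q)
        assert abs(rmsd - grid_fit_rmsd(P, Q)) < 5e-3


def test_rigid_pretransform_invariance(cloud, rng):
    Q = cloud + rng.normal(scale=0.5, size=cloud.shape)
    _, rmsd_base = kabsch(cloud, Q)
    R = rotation_matrix(rng.normal(size=3), 77.0)
    shift = np.array([3.0, -8.0, 2.0])
    _, rmsd_moved = kabsch(cloud @ R.T + shift, Q @ R.T + shift)
    assert rmsd_moved == pytest.approx(rmsd_base, abs=1e-9)


class TestIterativeAlign:
    def test_clean_data_equals_single_kabsch(self, cloud):
        res = iterative_align(cloud, cloud + np.array([1.0, 2.0, 3.0]))
        assert res.n_kept == res.n_start == len(cloud)
        assert res.rmsd_kept == pytest.approx(0.0, abs=1e-9)

    def test_planted_outliers_rejected(self, rng):
        P = rng.uniform(-20, 20, size=(100, 3))
        R = rotation_matrix([0, 1, 0], 30.0)
        Q = P @ R.T + np.array([4.0, 0.0, 0.0])
        Q[:5] += 20.0  # 5 displaced pairs
        res = iterative_align(P, Q)
        assert res.n_kept == 95
        assert set(np.where(~res.kept_mask)[0]) == set(range(5))
        assert res.rmsd_kept == pytest.approx(0.0, abs=1e-6)
        assert res.rmsd_all > 10 * max(res.rmsd_kept, 1e-9)

    def test_infinite_reject_factor_is_plain_kabsch(self, rng):
        P = rng.uniform(-10, 10, size=(50, 3))
        Q = P + rng.normal(scale=1.0, size=P.shape)
        res = iterative_align(P, Q, reject_factor=np.inf)
        _, rmsd = kabsch(P, Q)
        assert res.n_kept == 50
        assert res.rmsd_kept == pytest.approx(rmsd, abs=1e-12)

    def test_rmsd_kept_not_above_rmsd_all(self, rng):
        P = rng.uniform(-10, 10, size=(80, 3))
        Q = P + rng.normal(scale=0.8, size=P.shape)
        res = iterative_align(P, Q)
        assert res.rmsd_kept <= res.rmsd_all + 1e-9


class TestMatrix:
    def test_repeated_model_gives_zero_matrix(self):
        base, reg, _ = sw.synth.make_multidomain(1, 30, seed=3)
        ens = sw.synth.make_ensemble(
            [("S1", base, "ATP"), ("S2", base, "ATP"), ("S3", base, "ATP")], reg
        )
        m = sw.pairwise_rmsd_matrix(ens, "dom1", mode="all")
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    def test_planted_perturbation_rmsds(self, rng):
        """Successive exact-RMSD perturbations: adding a fixed random
        displacement field of RMS d to a model must show up as d in the
        full-pairing matrix entries involving the base state."""
        base, reg, _ = sw.synth.make_multidomain(1, 60, seed=5)
        coords = base.coords()
        states = [("S1", base, "ATP")]
        for i, scale in enumerate((2.0, 4.0), start=2):
            disp = rng.normal(size=coords.shape)
            disp -= disp.mean(axis=0)  # no net translation
            disp *= scale / np.sqrt((disp**2).sum(axis=1).mean())
            atoms = [
                sw.AtomSite(a.chain_id, a.residue_number, a.insertion_code,
                            a.residue_name, a.atom_name, a.element,
                            a.position + disp[j])
                for j, a in enumerate(base.atoms)
            ]
            states.append((f"S{i}", sw.StructureModel(f"S{i}", atoms), "ATP"))
        ens = sw.synth.make_ensemble(states, reg)
        m = sw.pairwise_rmsd_matrix(ens, "dom1", mode="all", reject_factor=np.inf)
        # the fit can only reduce the planted rms; it stays within a few percent
        assert m.entry("S1", "S2") == pytest.approx(2.0, rel=0.05)
        assert m.entry("S1", "S3") == pytest.approx(4.0, rel=0.05)

    def test_matrix_symmetry_and_diagonal(self, two_domain_ensemble):
        m = sw.pairwise_rmsd_matrix(two_domain_ensemble, "dom2", mode="kept")
        assert np.abs(m.values - m.values.T).max() < 1e-9
        assert np.abs(np.diag(m.values)).max() == 0.0
        assert (m.values >= 0).all()
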