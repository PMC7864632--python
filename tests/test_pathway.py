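"""Anchor-state selection, exact path enumeration, two-group partitioning."""

import math

import numpy as np
import pytest

import statewalk as sw
from statewalk.pathway import (
    AmbiguousAnchorError,
    NoGapError,
    anchor_state,
    loading_vs_cycle_partition,
    min_cumulative_path,
)
from statewalk.superpose import RMSDMatrix

from oracles import enumerate_best_path


def toy_matrix(labels, values):
    return RMSDMatrix(labels, np.asarray(values, dtype=float), "all", "toy")


class TestMinCumulativePath:
    def test_two_states_single_path(self):
        m = toy_matrix(["a", "b"], [[0, 2.5], [2.5, 0]])
        p = min_cumulative_path(m, "a")
        assert p.labels == ["a", "b"]
        assert p.cumulative_rmsd == pytest.approx(2.5)
        assert p.enumeration_size == 1

    def test_planted_chain_recovered(self):
        """Chain 0-1-2-3 with 1 Å consecutive links and 10 Å elsewhere."""
        v = np.full((4, 4), 10.0)
        np.fill_diagonal(v, 0.0)
        for i in range(3):
            v[i, i + 1] = v[i + 1, i] = 1.0
        m = toy_matrix(["s0", "s1", "s2", "s3"], v)
        p = min_cumulative_path(m, "s0")
        assert p.labels == ["s0", "s1", "s2", "s3"]
        assert p.cumulative_rmsd == pytest.approx(3.0)
        # independent recursive enumeration agrees
        dist = {(a, b): m.entry(a, b) for a in m.labels for b in m.labels if a != b}
        seq, cost = enumerate_best_path(m.labels, dist, "s0")
        assert seq == p.labels
        assert cost == pytest.approx(p.cumulative_rmsd)

    def test_oracle_agreement_random_matrices(self, rng):
        for trial in range(5):
            n = 6
            x = rng.uniform(1, 20, size=(n, n))
            v = (x + x.T) / 2.0
            np.fill_diagonal(v, 0.0)
            labels = [f"s{i}" for i in range(n)]
            m = toy_matrix(labels, v)
            p = min_cumulative_path(m, "s0")
            dist = {(a, b): m.entry(a, b) for a in labels for b in labels if a != b}
            seq, cost = enumerate_best_path(labels, dist, "s0")
            assert p.labels == seq
            assert p.cumulative_rmsd == pytest.approx(cost)
            assert p.enumeration_size == math.factorial(n - 1)

    def test_relabeling_invariance(self, rng):
        n = 5
        x = rng.uniform(1, 9, size=(n, n))
        v = (x + x.T) / 2.0
        np.fill_diagonal(v, 0.0)
        labels = [f"s{i}" for i in range(n)]
        p1 = min_cumulative_path(toy_matrix(labels, v), "s0")
        perm = [0, 3, 1, 4, 2]
        v2 = v[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        p2 = min_cumulative_path(toy_matrix(labels2, v2), "s0")
        assert p1.labels == p2.labels
        assert p1.cumulative_rmsd == pytest.approx(p2.cumulative_rmsd)

    def test_never_worse_than_identity_ordering(self, rng):
        n = 7
        x = rng.uniform(1, 30, size=(n, n))
        v = (x + x.T) / 2.0
        np.fill_diagonal(v, 0.0)
        labels = [f"s{i}" for i in range(n)]
        m = toy_matrix(labels, v)
        p = min_cumulative_path(m, "s0")
        identity_cost = sum(v[i, i + 1] for i in range(n - 1))
        assert p.cumulative_rmsd <= identity_cost + 1e-12
        assert sorted(p.labels) == sorted(labels)

    def test_closed_cycle_counts_return_leg(self):
        m = toy_matrix(["a", "b", "c"], [[0, 1, 4], [1, 0, 2], [4, 2, 0]])
        open_p = min_cumulative_path(m, "a")
        closed_p = min_cumulative_path(m, "a", closed=True)
        assert closed_p.cumulative_rmsd == pytest.approx(
            open_p.cumulative_rmsd + m.entry(closed_p.labels[-1], "a")
        )

    def test_too_many_states_rejected(self):
        n = 13
        v = np.zeros((n, n))
        m = toy_matrix([f"s{i}" for i in range(n)], v)
        with pytest.raises(ValueError, match="exceeds"):
            min_cumulative_path(m, "s0")


class TestAnchorState:
    def test_reference_identical_to_one_state(self):
        # 'far' differs by an internal (non-rigid) domain motion, which a
        # whole-model superposition cannot remove
        base, reg, _ = sw.synth.make_multidomain(2, 40, seed=21)
        other, _ = sw.synth.apply_motion(base, reg, "dom2", 60.0, [0, 0, 1], [5, 0, 0],
                                         new_id="far")
        from statewalk.model import Selection, SelectionTerm
        reg.add(Selection("whole", [SelectionTerm("A", atom_names=("CA",))]), "synthetic")
        ens = sw.synth.make_ensemble([("near", base, "ATP"), ("far", other, "ATP")], reg)
        label, table = anchor_state(ens, base, "whole")
        assert label == "near"
        assert table["near"] == pytest.approx(0.0, abs=1e-9)
        assert table["far"] > 1.0

    def test_planted_distances_pick_smallest(self, rng):
        """States at increasing rms displacement from the reference: the
        smallest one is the anchor."""
        base, reg, _ = sw.synth.make_multidomain(1, 50, seed=23)
        coords = base.coords()
        states = []
        planted = {"s8": 8.0, "s35": 35.0, "s40": 40.0}
        for name, scale in planted.items():
            disp = rng.normal(size=coords.shape)
            disp -= disp.mean(axis=0)
            disp *= scale / np.sqrt((disp**2).sum(axis=1).mean())
            atoms = [
                sw.AtomSite(a.chain_id, a.residue_number, a.insertion_code,
                            a.residue_name, a.atom_name, a.element,
                            a.position + disp[j])
                for j, a in enumerate(base.atoms)
            ]
            states.append((name, sw.StructureModel(name, atoms), "ATP"))
        ens = sw.synth.make_ensemble(states, reg)
        label, table = anchor_state(ens, base, "dom1", reject_factor=np.inf)
        assert label == "s8"
        assert table["s8"] < table["s35"] < table["s40"]

    def test_tie_demands_explicit_choice(self):
        base, reg, _ = sw.synth.make_multidomain(1, 40, seed=25)
        ens = sw.synth.make_ensemble([("t1", base, "ATP"), ("t2", base, "ATP")], reg)
        with pytest.raises(AmbiguousAnchorError):
            anchor_state(ens, base, "dom1")


def test_study_like_ensemble_end_to_end():
    """Loading-plus-cycle ensemble: the full pipeline (matrix -> partition
    -> path) recovers the planted two-group structure and state order."""
    ens, truth = sw.synth.make_study_like_ensemble(seed=5)
    m = sw.pairwise_rmsd_matrix(ens, "whole", mode="all")
    g1, g2, stats = loading_vs_cycle_partition(m)
    groups = {frozenset(g1), frozenset(g2)}
    assert groups == {frozenset(truth["loading"]), frozenset(truth["cycle"])}
    p = min_cumulative_path(m, "L1")
    assert p.labels == truth["path"]


class TestPartition:
    def test_two_planted_clusters(self):
        labels = ["L1", "L2", "C1", "C2", "C3"]
        v = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                same = (i < 2) == (j < 2)
                v[i, j] = 2.0 if same else 30.0
        g1, g2, stats = loading_vs_cycle_partition(toy_matrix(labels, v))
        groups = {frozenset(g1), frozenset(g2)}
        assert groups == {frozenset({"L1", "L2"}), frozenset({"C1", "C2", "C3"})}
        assert stats["within_max"] == pytest.approx(2.0)
        assert stats["between_min"] == pytest.approx(30.0)

    def test_equidistant_states_error(self):
        v = np.full((4, 4), 5.0)
        np.fill_diagonal(v, 0.0)
        with pytest.raises(NoGapError):
            loading_vs_cycle_partition(toy_matrix(list("abcd"), v))

    def test_too_few_states_error(self):
        with pytest.raises(ValueError):
            loading_vs_cycle_partition(toy_matrix(["a", "b"], [[0, 1], [1, 0]]))
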