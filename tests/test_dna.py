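"""DNA geometry: frames, bend/kink, minor-groove widths, contact footprints."""

import numpy as np
import pytest

import statewalk as sw
from statewalk.dna import bend_and_kink, build_frames, contact_footprint, \
    footprint_shift, minor_groove_widths
from statewalk.model import Selection, SelectionTerm, select_coordinates
from statewalk.synth import (
    BDNA_RISE,
    BDNA_TWIST,
    P_OFFSET_DEG,
    P_RADIUS,
    add_contact_probes,
    make_bdna,
    rotation_matrix,
)

from oracles import fiber_minor_groove_width

SEQ30 = "ACGTTGCAACGGATCCGATCGGTACCGTAA"


class TestFrames:
    def test_frame_count_equals_mapped_pairs(self, straight_duplex):
        model, regmap = straight_duplex
        frames = build_frames(model, "T", "N", regmap)
        assert len(frames) == len(regmap)
        regs = [f.register for f in frames]
        assert regs == sorted(regmap)

    def test_straight_duplex_axes_parallel(self, straight_duplex):
        model, regmap = straight_duplex
        frames = build_frames(model, "T", "N", regmap)
        ref = frames[len(frames) // 2].axis_vector
        for f in frames:
            ang = np.degrees(np.arccos(np.clip(abs(f.axis_vector @ ref), -1, 1)))
            assert ang < 0.5

    def test_axes_differ_across_planted_kink(self):
        model, regmap, _ = make_bdna(SEQ30, start_register=-14, kink=(20.0, -24))
        frames = build_frames(model, "T", "N", regmap)
        by_reg = {f.register: f for f in frames}
        # fully upstream vs fully downstream of the junction
        u = by_reg[-30].axis_vector
        v = by_reg[-18].axis_vector
        ang = np.degrees(np.arccos(np.clip(abs(u @ v), -1, 1)))
        assert ang == pytest.approx(20.0, abs=0.5)

    def test_too_few_pairs_error(self):
        model, regmap, _ = make_bdna("ACGTACGTAC", start_register=-1)
        small = {r: regmap[r] for r in sorted(regmap)[:4]}
        with pytest.raises(ValueError):
            build_frames(model, "T", "N", small)


class TestBendKink:
    def test_straight_duplex_no_bend(self, straight_duplex):
        model, regmap = straight_duplex
        bend, (reg, ang) = bend_and_kink(build_frames(model, "T", "N", regmap))
        assert bend < 0.5

    @pytest.mark.parametrize("angle", [7.0, 15.0, 20.0])
    def test_planted_kink_recovered(self, angle):
        model, regmap, _ = make_bdna(SEQ30, start_register=-14, kink=(angle, -24))
        frames = build_frames(model, "T", "N", regmap)
        bend, (kreg, _) = bend_and_kink(frames)
        assert bend == pytest.approx(angle, abs=1.0)
        assert abs(kreg - (-24)) <= 1

    def test_bend_invariant_under_frame_reversal(self, straight_duplex):
        model, regmap, _ = make_bdna(SEQ30, start_register=-14, kink=(12.0, -24))
        frames = build_frames(model, "T", "N", regmap)
        bend_fwd, _ = bend_and_kink(frames)
        bend_rev, _ = bend_and_kink(list(reversed(frames)))
        assert bend_fwd == pytest.approx(bend_rev, abs=1e-9)


class TestMinorGroove:
    def test_flat_profile_matches_closed_form(self, straight_duplex):
        """Ideal fiber: every interior register equals the value computed
        from the generator's own cylindrical geometry, in closed form."""
        model, regmap = straight_duplex
        widths = minor_groove_widths(model, "T", "N", regmap)
        expected = fiber_minor_groove_width(P_RADIUS, P_OFFSET_DEG, BDNA_RISE, BDNA_TWIST)
        # interior = registers with the full +2..+5 partner set
        interior = [w for r, w in widths.items()
                    if w is not None and r + 5 <= max(regmap)]
        assert len(interior) > 10
        for w in interior:
            assert w == pytest.approx(expected, abs=1e-9)

    def test_planted_widening_bump(self):
        base, regmap, _ = make_bdna(SEQ30, start_register=-14)
        wide, _, man = make_bdna(SEQ30, start_register=-14,
                                 groove_widening=(3.0, (-30, -27)))
        w0 = minor_groove_widths(base, "T", "N", regmap)
        w1 = minor_groove_widths(wide, "T", "N", regmap)
        for r in range(-30, -26):
            assert w1[r] - w0[r] == pytest.approx(3.0, abs=0.1)
        for r in w0:
            if (r < -36 or r > -22) and w0[r] is not None and w1[r] is not None:
                assert w1[r] == pytest.approx(w0[r], abs=1e-9)

    def test_rigid_transform_invariance(self, straight_duplex):
        model, regmap = straight_duplex
        w0 = minor_groove_widths(model, "T", "N", regmap)
        R = rotation_matrix([1, 2, -1], 71.0)
        moved = model.transformed(R, np.array([10.0, -4.0, 2.0]))
        w1 = minor_groove_widths(moved, "T", "N", regmap)
        for r in w0:
            if w0[r] is None:
                assert w1[r] is None
            else:
                assert w1[r] == pytest.approx(w0[r], abs=1e-9)

    def test_missing_phosphate_reported_not_fabricated(self, straight_duplex):
        model, regmap = straight_duplex
        t_res_of = {r: regmap[r][0] for r in regmap}
        target = sorted(regmap)[8]
        pruned = sw.StructureModel(
            "pruned",
            [a for a in model.atoms
             if not (a.chain_id == "T" and a.residue_number == t_res_of[target]
                     and a.atom_name == "P")],
        )
        widths = minor_groove_widths(pruned, "T", "N", regmap)
        assert widths[target] is None


class TestContacts:
    def test_distant_protein_empty_footprint(self, straight_duplex):
        model, regmap = straight_duplex
        probe = sw.StructureModel("far", list(model.atoms) + [
            sw.AtomSite("E", 1, "", "ARG", "NH1", "N", [500.0, 0.0, 0.0])
        ])
        cs = select_coordinates(probe, Selection("p", [SelectionTerm("E")]))
        fp = contact_footprint(probe, cs, "T", "N", regmap)
        assert fp.contacts == []
        assert fp.t_strand_fraction is None

    def test_planted_arginine_contact_is_hbond(self, straight_duplex):
        model, regmap = straight_duplex
        reg = sorted(regmap)[10]
        planted, _ = add_contact_probes(model, regmap, "T", "N", [reg], [], distance=3.0)
        cs = select_coordinates(planted, Selection("p", [SelectionTerm("E")]))
        fp = contact_footprint(planted, cs, "T", "N", regmap)
        assert len(fp.contacts) == 1
        c = fp.contacts[0]
        assert (c.register, c.strand, c.contact_class) == (reg, "t", "hbond")
        assert c.distance == pytest.approx(3.0, abs=1e-9)

    def test_contact_counts_monotone_in_cutoffs(self, straight_duplex):
        model, regmap = straight_duplex
        regs = sorted(regmap)[4:16]
        planted, _ = add_contact_probes(model, regmap, "T", "N", regs[::2], regs[1::2],
                                        distance=3.3)
        cs = select_coordinates(planted, Selection("p", [SelectionTerm("E")]))
        n_prev = -1
        for scale in (0.8, 1.0, 1.2):
            fp = contact_footprint(
                planted, cs, "T", "N", regmap,
                hbond_cutoff=3.5 * scale, ionic_cutoff=4.5 * scale,
                vdw_cutoff=4.0 * scale,
            )
            assert len(fp.contacts) >= n_prev
            n_prev = len(fp.contacts)

    def test_strand_preference_fraction(self, fixture_suite):
        fx = next(f for f in fixture_suite if f["name"] == "footprint_walk_plus9")
        cs = select_coordinates(fx["model_a"], Selection("p", [SelectionTerm("E")]))
        fp = contact_footprint(fx["model_a"], cs, "T", "N", fx["register_map"])
        # planted ~60% template-strand contacts, as in the study system
        assert fp.t_strand_fraction == pytest.approx(0.6, abs=0.15)


class TestFootprintShift:
    def test_identical_footprints_zero_shift(self, straight_duplex):
        model, regmap = straight_duplex
        regs = sorted(regmap)[3:9]
        planted, _ = add_contact_probes(model, regmap, "T", "N", regs, [])
        cs = select_coordinates(planted, Selection("p", [SelectionTerm("E")]))
        fp = contact_footprint(planted, cs, "T", "N", regmap)
        assert footprint_shift(fp, fp) == (0, 0.0)

    def test_planted_nine_register_walk(self, fixture_suite):
        fx = next(f for f in fixture_suite if f["name"] == "footprint_walk_plus9")
        sel = Selection("p", [SelectionTerm("E")])
        fp_a = contact_footprint(
            fx["model_a"], select_coordinates(fx["model_a"], sel), "T", "N",
            fx["register_map"])
        fp_b = contact_footprint(
            fx["model_b"], select_coordinates(fx["model_b"], sel), "T", "N",
            fx["register_map"])
        shift, frac = footprint_shift(fp_a, fp_b)
        assert shift == 9
        assert frac == pytest.approx(9.0, abs=0.5)

    def test_empty_footprint_errors(self, straight_duplex):
        model, regmap = straight_duplex
        regs = sorted(regmap)[3:9]
        planted, _ = add_contact_probes(model, regmap, "T", "N", regs, [])
        cs = select_coordinates(planted, Selection("p", [SelectionTerm("E")]))
        fp = contact_footprint(planted, cs, "T", "N", regmap)
        from statewalk.dna import ContactFootprint
        empty = ContactFootprint([], None, None)
        with pytest.raises(ValueError):
            footprint_shift(fp, empty)
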