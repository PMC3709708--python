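import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hairpinpath.annotators import (
    AnnotationError,
    DEFAULT_CRITERIA,
    HBondCriteria,
    HBondDefinition,
    TurnDefinition,
    assign_secondary_structure,
    detect_hbond,
    hbond_tracks,
    residue_propensities,
    turn_track,
)
from hairpinpath.geometry import build_backbone
from hairpinpath.model_io import AnnotationTrack, frameset_from_backbone


def _frame_with_bond_geometry(topology, base_frame, donor, acceptor,
                              h_pos, o_pos, n_pos):
    """Overwrite the three atoms a bond test reads."""
    frame = base_frame.copy()
    frame[topology.atom_index(donor, "H")] = h_pos
    frame[topology.atom_index(donor, "N")] = n_pos
    frame[topology.atom_index(acceptor, "O")] = o_pos
    return frame


from oracles import naive_hbond


def _naive_hbond(n, h, o, criteria):
    return naive_hbond(
        n, h, o, criteria.max_h_acceptor_distance, criteria.min_dha_angle
    )


class TestHBondDetection:
    BOND = HBondDefinition(6, 2)

    def test_linear_short_contact_is_bond(self, topology, helix_frame):
        frame = _frame_with_bond_geometry(
            topology, helix_frame, 6, 2,
            h_pos=[5.0, 5.0, 5.0], o_pos=[5.0, 5.0, 5.19],
            n_pos=[5.0, 5.0, 4.9],
        )
        assert detect_hbond(frame, topology, self.BOND)

    def test_boundaries_are_strict(self, topology, helix_frame):
        # distance exactly at the cutoff
        frame = _frame_with_bond_geometry(
            topology, helix_frame, 6, 2,
            h_pos=[5.0, 5.0, 5.0], o_pos=[5.0, 5.0, 5.25],
            n_pos=[5.0, 5.0, 4.9],
        )
        assert not detect_hbond(frame, topology, self.BOND)
        # angle exactly at the cutoff (135 deg), distance fine
        ang = math.radians(135.0)
        frame = _frame_with_bond_geometry(
            topology, helix_frame, 6, 2,
            h_pos=[5.0, 5.0, 5.0],
            o_pos=[5.0 + 0.2 * math.sin(ang), 5.0, 5.0 - 0.2 * math.cos(ang)],
            n_pos=[5.0, 5.0, 4.9],
        )
        assert not detect_hbond(frame, topology, self.BOND)

    def test_matches_naive_recomputation_on_random_geometries(
        self, topology, helix_frame, rng
    ):
        hits = 0
        for _ in range(1000):
            n = rng.uniform(0, 0.5, 3)
            h = n + 0.1 * _unit(rng.normal(size=3))
            o = h + rng.uniform(0.05, 0.45) * _unit(rng.normal(size=3))
            frame = _frame_with_bond_geometry(
                topology, helix_frame, 6, 2, h, o, n
            )
            got = detect_hbond(frame, topology, self.BOND)
            assert got == _naive_hbond(n, h, o, DEFAULT_CRITERIA)
            hits += got
        assert 0 < hits < 1000  # both outcomes exercised

    def test_nterminal_donor_without_h_is_an_error(
        self, topology, helix_frame
    ):
        with pytest.raises(AnnotationError, match="no amide H"):
            detect_hbond(
                helix_frame, topology, HBondDefinition(1, 5)
            )

    def test_rigid_transform_invariance(self, topology, hairpin_frame, rng):
        bond = HBondDefinition(9, 6)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = hairpin_frame @ rot.T + np.array([3.0, -1.0, 2.0])
        assert detect_hbond(hairpin_frame, topology, bond) == detect_hbond(
            moved, topology, bond
        )

    @given(
        d=st.floats(0.05, 0.45),
        ang=st.floats(95.0, 179.0),
        tighter_d=st.floats(0.0, 0.1),
        tighter_a=st.floats(0.0, 30.0),
    )
    def test_tightening_criteria_is_monotone(self, d, ang, tighter_d,
                                             tighter_a):
        """Shrinking the distance cutoff / raising the angle cutoff can only
        switch a bond off, never on."""
        loose = HBondCriteria(0.25, 135.0)
        tight = HBondCriteria(
            max(1e-3, 0.25 - tighter_d), min(179.0, 135.0 + tighter_a)
        )
        present_loose = d < loose.max_h_acceptor_distance and \
            ang > loose.min_dha_angle
        present_tight = d < tight.max_h_acceptor_distance and \
            ang > tight.min_dha_angle
        assert not (present_tight and not present_loose)


def _unit(v):
    return v / np.linalg.norm(v)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helical(self, topology, helix_frame,
                                             frameset_from_frame):
        codes = assign_secondary_structure(
            frameset_from_frame(topology, helix_frame)
        )[0]
        assert all(c == "H" for c in codes[2:-2])
        # Dihedrals are undefined at the chain ends.
        assert codes[0] == "C" and codes[-1] == "C"

    def test_hairpin_turn_window_detected(self, topology, hairpin_frame,
                                          frameset_from_frame):
        frames = frameset_from_frame(topology, hairpin_frame)
        codes = assign_secondary_structure(frames)[0]
        assert all(c in "TE" for c in codes[5:9])
        track = turn_track(frames, TurnDefinition(6))
        assert bool(track.values[0])

    def test_extended_chain_has_no_turns(self, topology, frameset_from_frame):
        bb = build_backbone(np.full(12, 180.0), np.full(12, 180.0))
        frames = frameset_from_backbone(topology, bb)
        codes = assign_secondary_structure(frames)[0]
        assert "T" not in codes
        assert not turn_track(frames, TurnDefinition(6)).values[0]

    def test_helix_trajectory_never_shows_turn(self, small_frameset):
        track = turn_track(small_frameset, TurnDefinition(6))
        assert not track.values.any()

    def test_turn_window_outside_peptide(self, small_frameset):
        with pytest.raises(AnnotationError, match="outside"):
            turn_track(small_frameset, TurnDefinition(10))

    def test_external_all_turn_tracks(self):
        ss = [
            AnnotationTrack(f"ss_res_{r}", np.full(5, "T"))
            for r in range(1, 13)
        ]
        track = turn_track(None, TurnDefinition(6), "external", ss)
        assert track.values.all()


class TestTracksAndPropensities:
    def test_hairpin_registry_bonds_all_true(
        self, topology, hairpin_frame, frameset_from_frame
    ):
        defs = [HBondDefinition(*p)
                for p in ((9, 6), (6, 9), (11, 4), (4, 11))]
        tracks = hbond_tracks(
            frameset_from_frame(topology, hairpin_frame), defs
        )
        assert all(t.values.all() for t in tracks)

    def test_helix_has_no_hairpin_bonds(self, small_frameset):
        defs = [HBondDefinition(*p)
                for p in ((9, 6), (6, 9), (11, 4), (4, 11))]
        tracks = hbond_tracks(small_frameset, defs)
        assert not any(t.values.any() for t in tracks)

    def test_empty_definition_list(self, small_frameset):
        assert hbond_tracks(small_frameset, []) == []

    def test_constant_assignment_gives_unit_propensity(self):
        codes = np.full((10, 12), "T")
        table = residue_propensities(codes)
        assert np.allclose(table["P_turn"], 1.0)
        assert np.allclose(table["P_strand"], 0.0)

    def test_half_and_half_mix(self):
        codes = np.vstack([np.full((5, 12), "T"), np.full((5, 12), "E")])
        table = residue_propensities(codes)
        assert np.allclose(table["P_turn"], 0.5)
        assert np.allclose(table["P_strand"], 0.5)

    def test_programmed_occupancy_recovered(self, topology):
        """Turn occupancy programmed at 0.8 is recovered from the inner
        turn-window residues at n = 5000 frames (binomial bound)."""
        from hairpinpath.synthetic import (
            MechanismScript,
            generate_transition_trajectory,
        )

        script = MechanismScript.with_turn_occupancy(
            0.8, n_frames=5000, seed=9
        )
        synth = generate_transition_trajectory(script)
        codes = assign_secondary_structure(synth.frames)
        table = residue_propensities(codes)
        inner = table.set_index("residue").loc[[7, 8], "P_turn"]
        assert np.allclose(inner, 0.8, atol=0.02)
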