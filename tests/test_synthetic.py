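import numpy as np
import pytest

from hairpinpath.annotators import (
    HBondDefinition,
    TurnDefinition,
    assign_secondary_structure,
    hbond_tracks,
    turn_track,
)
from hairpinpath.geometry import distance
from hairpinpath.model_io import frameset_from_backbone
from hairpinpath.superposition import superpose
from hairpinpath.synthetic import (
    CONDITION_HBONDS,
    CONDITION_TURNS,
    ConstructionError,
    MechanismScript,
    alpha_syn12_topology,
    generate_transition_trajectory,
    make_ideal_hairpin,
    make_ideal_helix,
)

PHYS_BONDS = CONDITION_HBONDS["physiological"]
ACID_BONDS = CONDITION_HBONDS["acidic"]


class TestIdealTemplates:
    def test_helix_is_assigned_helical(self, topology, helix_frame,
                                       frameset_from_frame):
        codes = assign_secondary_structure(
            frameset_from_frame(topology, helix_frame)
        )[0]
        assert all(c == "H" for c in codes[2:-2])

    def test_helix_geometry_and_absence_of_hairpin_bonds(
        self, topology, helix_frame, frameset_from_frame
    ):
        ca = helix_frame[topology.ca_indices]
        d13 = distance(ca[:-3], ca[3:])
        assert np.all((0.48 < d13) & (d13 < 0.56))
        tracks = hbond_tracks(
            frameset_from_frame(topology, helix_frame), list(PHYS_BONDS)
        )
        assert not any(t.values[0] for t in tracks)

    def test_helix_deterministic(self, topology):
        assert np.array_equal(
            make_ideal_helix(topology), make_ideal_helix(topology)
        )

    def test_physiological_hairpin_registry_satisfied(
        self, topology, hairpin_frame, frameset_from_frame
    ):
        frames = frameset_from_frame(topology, hairpin_frame)
        tracks = hbond_tracks(frames, list(PHYS_BONDS))
        assert all(t.values[0] for t in tracks)
        assert turn_track(frames, TurnDefinition(6)).values[0]

    def test_acidic_hairpin_five_bonds_satisfied(self, frameset_from_frame):
        topo = alpha_syn12_topology("acidic")
        frame = make_ideal_hairpin(topo, TurnDefinition(5), ACID_BONDS)
        frames = frameset_from_frame(topo, frame)
        tracks = hbond_tracks(frames, list(ACID_BONDS))
        assert all(t.values[0] for t in tracks)
        assert turn_track(frames, TurnDefinition(5)).values[0]

    def test_inconsistent_registry_fails_loudly(self, topology):
        # Registry lacking the turn-closing pair.
        with pytest.raises(ConstructionError, match="turn-closing"):
            make_ideal_hairpin(
                topology, TurnDefinition(6),
                (HBondDefinition(4, 11), HBondDefinition(11, 4)),
            )
        # Residue 1 cannot donate (no amide H).
        with pytest.raises(ConstructionError, match="no\\s+amide H"):
            make_ideal_hairpin(
                topology, TurnDefinition(6),
                (HBondDefinition(9, 6), HBondDefinition(6, 9),
                 HBondDefinition(1, 12)),
            )

    def test_helix_hairpin_rmsd_separation(self, topology, helix_frame,
                                           hairpin_frame):
        r = superpose(helix_frame, hairpin_frame, topology.ca_indices).rmsd
        assert r > 0.3

    def test_template_bond_lengths_near_ideal(self, templates, topology):
        """Every template is a chemically sane backbone: bond lengths within
        5% of their ideal values."""
        from hairpinpath.geometry import BOND_C_N, BOND_CA_C, BOND_N_CA

        for t in templates.values():
            bb = t.backbone()
            n_ca = distance(bb["N"], bb["CA"])
            ca_c = distance(bb["CA"], bb["C"])
            c_n = distance(bb["C"][:-1], bb["N"][1:])
            assert np.allclose(n_ca, BOND_N_CA, rtol=0.05)
            assert np.allclose(ca_c, BOND_CA_C, rtol=0.05)
            assert np.allclose(c_n, BOND_C_N, rtol=0.05)


class TestGenerator:
    def test_same_seed_bit_identical(self):
        s1 = generate_transition_trajectory(
            MechanismScript.turn_first(n_frames=300, seed=42)
        )
        s2 = generate_transition_trajectory(
            MechanismScript.turn_first(n_frames=300, seed=42)
        )
        assert np.array_equal(
            s1.frames.coordinates, s2.frames.coordinates
        )

    def test_different_seed_differs(self):
        s1 = generate_transition_trajectory(
            MechanismScript.turn_first(n_frames=300, seed=1)
        )
        s2 = generate_transition_trajectory(
            MechanismScript.turn_first(n_frames=300, seed=2)
        )
        assert not np.array_equal(
            s1.frames.coordinates, s2.frames.coordinates
        )

    def test_zero_noise_turn_onset_is_exact(self):
        script = MechanismScript(
            mode="turn_first",
            basin_schedule=[("helix", 300), ("turn_only", 100),
                            ("partial", 100), ("folded", 100)],
            noise_sigma=0.0,
            seed=0,
        )
        synth = generate_transition_trajectory(script)
        detected = turn_track(synth.frames, synth.turn).values
        onset = int(np.argmax(detected))
        turn_onset, bond_onsets = script.onset_frames(
            synth.templates, synth.turn
        )
        assert turn_onset == 300
        assert onset == 300
        assert detected[300:].all() and not detected[:300].any()
        # Bonds appear exactly at their scheduled onsets too.
        tracks = {t.name: t.values
                  for t in hbond_tracks(synth.frames,
                                        list(synth.hbond_registry))}
        assert bond_onsets["HB_9-6"] == 400
        assert int(np.argmax(tracks["HB_9-6"])) == 400

    def test_turn_first_never_bonds_before_turn(self):
        """The zipper constraint holds on the detected tracks, not just the
        programmed ones."""
        for seed in range(3):
            synth = generate_transition_trajectory(
                MechanismScript.turn_first(n_frames=2000, seed=seed)
            )
            turn = turn_track(synth.frames, synth.turn).values
            for t in hbond_tracks(synth.frames, list(synth.hbond_registry)):
                assert not (t.values & ~turn).any()

    def test_detected_tracks_match_ground_truth_at_default_noise(self):
        """At the generator's default noise (0.005 nm) geometric detection
        reproduces every programmed track on >= 99% of frames."""
        for seed in range(5):
            synth = generate_transition_trajectory(
                MechanismScript.turn_first(n_frames=1000, seed=seed)
            )
            turn = turn_track(synth.frames, synth.turn)
            assert (turn.values == synth.turn_track.values).mean() >= 0.99
            detected = hbond_tracks(synth.frames,
                                    list(synth.hbond_registry))
            for det, truth in zip(detected, synth.hbond_tracks):
                assert (det.values == truth.values).mean() >= 0.99

    def test_tracks_degrade_gracefully_at_double_noise(self):
        """At 0.01 nm noise (twice the default) bond and turn labels jitter
        at the geometric thresholds but agreement with the programmed truth
        stays above 95% per track."""
        for seed in range(5):
            synth = generate_transition_trajectory(
                MechanismScript.turn_first(
                    n_frames=1000, seed=seed, noise_sigma=0.01
                )
            )
            detected = hbond_tracks(synth.frames,
                                    list(synth.hbond_registry))
            for det, truth in zip(detected, synth.hbond_tracks):
                assert (det.values == truth.values).mean() >= 0.95
            turn = turn_track(synth.frames, synth.turn)
            assert (turn.values == synth.turn_track.values).mean() >= 0.95

    def test_schedule_validation(self):
        with pytest.raises(ConstructionError):
            MechanismScript("turn_first", [("helix", 0)])
        with pytest.raises(ConstructionError):
            MechanismScript("two_path", [("helix", 10)],
                            path_mixture=(0.7, 0.2))
        with pytest.raises(ConstructionError):
            MechanismScript("turn_first", [("helix", 10)], noise_sigma=-0.1)

    def test_frame_count_consistency_check(self):
        script = MechanismScript.turn_first(n_frames=200, seed=0)
        with pytest.raises(ConstructionError, match="schedule"):
            generate_transition_trajectory(script, n_frames=500)

    def test_two_path_mixture_recovery(self):
        """Programmed 70/30 routing is recovered from detected basin labels
        within the multinomial bound over 200 events."""
        from hairpinpath.landscape import (
            StateCodingScheme,
            encode_states,
            label_basins,
        )
        from hairpinpath.mechanism import enumerate_transition_paths
        from hairpinpath.superposition import rmsd_series

        synth = generate_transition_trajectory(
            MechanismScript.two_path(
                n_frames=5000, seed=13, mixture=(0.7, 0.3), n_events=200
            )
        )
        turn = turn_track(synth.frames, synth.turn)
        bonds = hbond_tracks(synth.frames, list(synth.hbond_registry))
        series = encode_states(
            turn, bonds,
            rmsd_series(synth.frames, synth.folded_reference),
            StateCodingScheme(synth.turn, synth.hbond_registry),
        )
        labels = label_basins(series, synth.regions)
        rep = enumerate_transition_paths(labels, ["U1", "U2"], "F")
        assert rep.n_events >= 190
        assert rep.probability("U1->F") == pytest.approx(0.7, abs=0.07)
        assert rep.probability("U2->F") == pytest.approx(0.3, abs=0.07)
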