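import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hairpinpath.annotators import HBondDefinition, TurnDefinition
from hairpinpath.landscape import (
    BasinLabeling,
    BasinRegion,
    FreeEnergySurface,
    LandscapeError,
    StateCodingScheme,
    StateSeries,
    build_fes,
    encode_states,
    find_minima,
    label_basins,
)
from hairpinpath.model_io import AnnotationTrack

SCHEME = StateCodingScheme(
    TurnDefinition(6),
    tuple(HBondDefinition(*p) for p in ((9, 6), (6, 9), (11, 4), (4, 11))),
)


def _series(turn_bits, bond_bit_rows, rmsd=None):
    n = len(turn_bits)
    turn = AnnotationTrack("Turn_9-6", np.asarray(turn_bits, dtype=bool))
    bonds = [
        AnnotationTrack(f"HB_{k}", np.asarray(row, dtype=bool))
        for k, row in enumerate(bond_bit_rows)
    ]
    if rmsd is None:
        rmsd = np.zeros(n)
    return encode_states(turn, bonds, rmsd, SCHEME)


class TestStateEncoding:
    def test_exhaustive_truth_table(self):
        """All 2^5 combinations of (turn, 4 bonds) against hand encoding:
        turn absent -> -1, otherwise the number of set bonds."""
        combos = list(itertools.product([False, True], repeat=5))
        turn_bits = [c[0] for c in combos]
        bond_rows = [[c[k + 1] for c in combos] for k in range(4)]
        series = _series(turn_bits, bond_rows)
        expected = [
            (sum(c[1:]) if c[0] else -1) for c in combos
        ]
        assert series.ycode.tolist() == expected

    def test_non_set_bonds_are_ignored(self):
        turn = AnnotationTrack("Turn_9-6", np.array([True]))
        set_bond = AnnotationTrack("HB_9-6", np.array([False]))
        series = encode_states(turn, [set_bond], np.zeros(1))
        assert series.ycode[0] == 0

    def test_length_mismatch_rejected(self):
        turn = AnnotationTrack("Turn_9-6", np.array([True, False]))
        bond = AnnotationTrack("HB_9-6", np.array([True]))
        with pytest.raises(LandscapeError):
            encode_states(turn, [bond], np.zeros(2))

    @given(st.lists(st.tuples(*([st.booleans()] * 5)), min_size=1,
                    max_size=64))
    def test_encoding_is_pure_function_of_booleans(self, rows):
        turn_bits = [r[0] for r in rows]
        bond_rows = [[r[k + 1] for r in rows] for k in range(4)]
        series = _series(turn_bits, bond_rows)
        for code, row in zip(series.ycode, rows):
            assert code == (sum(row[1:]) if row[0] else -1)


class TestFreeEnergySurface:
    def test_all_frames_in_one_bin(self):
        series = _series([True] * 10, [[True] * 10] * 4,
                         rmsd=np.full(10, 0.005))
        fes = build_fes(series)
        assert np.nansum(fes.F) == 0.0
        assert fes.sampled.sum() == 1

    def test_two_bin_count_ratio_e_gives_kt(self):
        """Counts in ratio e:1 across two bins differ by exactly kT
        (2.494 kJ/mol at 300 K) on the free-energy surface."""
        n2 = 10000
        n1 = int(round(np.e * n2))
        rmsd = np.concatenate([np.full(n1, 0.005), np.full(n2, 0.015)])
        series = _series([True] * (n1 + n2), [[True] * (n1 + n2)] * 4, rmsd)
        fes = build_fes(series, temperature=300.0)
        sampled = fes.F[fes.sampled]
        delta = sampled.max() - sampled.min()
        assert delta == pytest.approx(2.494, abs=1e-3)
        assert fes.kT == pytest.approx(0.0083145 * 300.0)

    def test_uniform_occupancy_is_flat_zero(self):
        rmsd = np.concatenate([np.full(5, 0.005 + 0.01 * k) for k in range(4)])
        series = _series([True] * 20, [[True] * 20] * 4, rmsd)
        fes = build_fes(series)
        assert np.allclose(fes.F[fes.sampled], 0.0)

    def test_duplicating_frames_leaves_surface_unchanged(self):
        rmsd = np.array([0.005] * 6 + [0.015] * 3 + [0.025] * 1)
        turn = [True] * 10
        series = _series(turn, [[True] * 10] * 4, np.asarray(rmsd))
        series2 = _series(turn * 3, [[True] * 30] * 4, np.tile(rmsd, 3))
        f1 = build_fes(series).F
        f2 = build_fes(series2).F
        assert np.allclose(f1[~np.isnan(f1)], f2[~np.isnan(f2)])

    def test_zero_frames_rejected(self):
        series = StateSeries(np.zeros(0), np.zeros(0, dtype=int))
        with pytest.raises(LandscapeError):
            build_fes(series)

    def test_global_minimum_is_zero_everywhere_nonnegative(self):
        rng = np.random.default_rng(5)
        rmsd = rng.uniform(0, 0.3, 2000)
        ycode = rng.integers(-1, 5, 2000)
        fes = build_fes(StateSeries(rmsd, ycode, SCHEME))
        sampled = fes.F[fes.sampled]
        assert sampled.min() == 0.0
        assert np.all(sampled >= 0.0)


from oracles import loop_minima as _loop_minima_oracle


class TestMinima:
    def _fes_from_grid(self, F):
        nx, ny = F.shape
        return FreeEnergySurface(
            x_edges=np.arange(nx + 1) * 0.01,
            y_levels=np.arange(ny),
            F=F,
            kT=2.494,
        )

    def test_single_bin_surface(self):
        fes = self._fes_from_grid(np.array([[0.0]]))
        assert find_minima(fes) == [(0.005, 0, 0.0)]

    def test_two_well_surface_excludes_saddle(self):
        F = np.array(
            [
                [1.0, 2.0, 3.0, 2.0, 1.5],
                [0.0, 2.0, 2.5, 2.0, 0.3],
                [1.0, 2.0, 3.0, 2.0, 1.5],
            ]
        ).T  # x index runs over rows
        fes = self._fes_from_grid(F)
        minima = find_minima(fes)
        assert [(m[1], m[2]) for m in minima] == [(1, 0.0), (1, 0.3)]
        assert minima[0][0] == pytest.approx(0.005)
        assert minima[1][0] == pytest.approx(0.045)

    def test_plateau_has_no_minimum(self):
        fes = self._fes_from_grid(np.zeros((3, 3)))
        assert find_minima(fes) == []

    def test_matches_loop_oracle_on_random_grids(self, rng):
        for _ in range(20):
            F = rng.uniform(0, 5, (8, 6))
            F[rng.random((8, 6)) < 0.3] = np.nan
            if np.isnan(F).all():
                continue
            F = F - np.nanmin(F)
            fes = self._fes_from_grid(F)
            got = sorted(
                (int(round(x / 0.01 - 0.5)), int(y))
                for x, y, _d in find_minima(fes)
            )
            assert got == _loop_minima_oracle(F)


class TestBasins:
    REGIONS = BasinLabeling(
        [
            BasinRegion("F", 0.03, 0.13, (3,)),
            BasinRegion("U1", 0.18, 0.28, (0,)),
            BasinRegion("U2", 0.33, 0.43, (2,)),
        ]
    )

    def test_frame_in_folded_region(self):
        series = StateSeries(np.array([0.08]), np.array([3]))
        assert label_basins(series, self.REGIONS)[0] == "F"

    def test_frame_outside_all_regions(self):
        series = StateSeries(np.array([0.08]), np.array([0]))
        assert label_basins(series, self.REGIONS)[0] == "unassigned"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(LandscapeError, match="overlap"):
            BasinLabeling(
                [
                    BasinRegion("A", 0.0, 0.2, (1, 2)),
                    BasinRegion("B", 0.1, 0.3, (2,)),
                ]
            )

    def test_same_rectangle_different_levels_allowed(self):
        BasinLabeling(
            [
                BasinRegion("A", 0.0, 0.2, (1,)),
                BasinRegion("B", 0.0, 0.2, (2,)),
            ]
        )

    def test_synthetic_series_labels_match_programmed_schedule(self):
        """Basin labels recovered from detected coordinates agree with the
        generator's programmed schedule on >= 95% of frames."""
        from hairpinpath.annotators import hbond_tracks, turn_track
        from hairpinpath.superposition import rmsd_series
        from hairpinpath.synthetic import (
            MechanismScript,
            generate_transition_trajectory,
        )

        synth = generate_transition_trajectory(
            MechanismScript.two_path(n_frames=2000, seed=11)
        )
        turn = turn_track(synth.frames, synth.turn)
        bonds = hbond_tracks(synth.frames, list(synth.hbond_registry))
        series = encode_states(
            turn, bonds, rmsd_series(synth.frames, synth.folded_reference),
            StateCodingScheme(synth.turn, synth.hbond_registry),
        )
        labels = label_basins(series, synth.regions)
        agree = np.mean(labels == synth.basin_labels)
        assert agree >= 0.95
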