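"""SAPTF translation search, rotation search, refinement, multi-copy docking."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from saptfit.density import simulate_density
from saptfit.fitting import (
    Placement,
    apply_placement,
    local_rotation_search,
    place_n_copies,
    rigid_body_refine,
    saptf_translation_search,
    so3_grid,
)
from saptfit.structures_io import Atom, AtomicModel, Chain, DensityMap, Residue


def _angular_distance_deg(r1, r2):
    return np.degrees(Rotation.from_matrix(r1 @ r2.T).magnitude())


def _rmsd(a, b):
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


class TestTranslationSearch:
    def test_self_consistent_peak_within_one_voxel(self, single_copy_case):
        c = single_copy_case
        grid, peaks = saptf_translation_search(c["map"], c["model"], c["resolution"])
        assert peaks
        # one of the leading peaks must sit on the true centre (the
        # spherically averaged landscape is broad, so allow a short list)
        errs = [np.linalg.norm(p.position - c["center"]) for p in peaks[:3]]
        assert min(errs) <= 2.0 * float(c["map"].voxel_size.max())
        true_idx = tuple(
            np.round(c["map"].world_to_index(c["center"])).astype(int)
        )
        assert grid.scores[true_idx] >= np.quantile(grid.scores[grid.searched], 0.99)

    def test_uniform_map_degenerate(self, subunit):
        m = DensityMap(np.full((24, 24, 24), 2.0), 2.0, (-24.0, -24.0, -24.0))
        grid, peaks = saptf_translation_search(m, subunit, 8.0)
        assert grid.degenerate
        assert peaks == []

    def test_two_copy_map_peaks_in_top_percentile(self, subunit):
        com = subunit.center_of_mass()
        shift = np.array([36.0, 0.0, 0.0])
        other = subunit.transformed(np.eye(3), shift)
        both = AtomicModel(
            [subunit.chains[0], Chain("B", other.chains[0].residues)]
        )
        m = simulate_density(both, 8.0, voxel_size=2.0, pad=10.0)
        grid, peaks = saptf_translation_search(m, subunit, 8.0)
        searched = grid.scores[grid.searched]
        q99 = np.quantile(searched, 0.99)
        for center in (com, com + shift):
            idx = tuple(np.round(m.world_to_index(center)).astype(int))
            assert grid.scores[idx] > q99

    def test_constant_offset_leaves_peak_fixed(self, single_copy_case):
        c = single_copy_case
        _, peaks = saptf_translation_search(c["map"], c["model"], c["resolution"])
        shifted = DensityMap(
            c["map"].data + 5.0, c["map"].voxel_size, c["map"].origin
        )
        _, peaks2 = saptf_translation_search(shifted, c["model"], c["resolution"])
        assert peaks[0].index == peaks2[0].index

    def test_model_larger_than_map_rejected(self, subunit):
        m = DensityMap(np.zeros((8, 8, 8)), 1.0, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="bounding sphere"):
            saptf_translation_search(m, subunit, 8.0)

    def test_true_peak_tfz_beats_random_positions(self, single_copy_case):
        c = single_copy_case
        grid, peaks = saptf_translation_search(c["map"], c["model"], c["resolution"])
        d = [np.linalg.norm(p.position - c["center"]) for p in peaks]
        true_peak = peaks[int(np.argmin(d))]
        rng = np.random.default_rng(0)
        searched_idx = np.argwhere(grid.searched)
        peak_positions = {p.index for p in peaks}
        count = 0
        tfz = lambda s: (s - grid.mean) / grid.sd
        while count < 100:
            i = tuple(searched_idx[rng.integers(len(searched_idx))])
            if i in peak_positions:
                continue
            assert true_peak.tfz > tfz(grid.scores[i])
            count += 1


class TestRotationSearch:
    def test_so3_grid_covers_rotations(self):
        grid = so3_grid(20.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            r = Rotation.random(rng=rng).as_matrix()
            nearest = min(_angular_distance_deg(g, r) for g in grid)
            assert nearest < 20.0

    def test_identity_orientation_recovered(self, single_copy_case):
        c = single_copy_case
        rot, cc = local_rotation_search(
            c["map"], c["model"], c["center"], c["resolution"]
        )
        # truth is the fixture's generating rotation
        assert _angular_distance_deg(rot, c["rotation"]) <= 2.0
        assert cc > 0.9

    def test_known_30deg_rotation_recovered(self, subunit):
        com = subunit.center_of_mass()
        truth = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        placed = subunit.transformed(truth, com - truth @ com)
        m = simulate_density(placed, 8.0, voxel_size=2.0, pad=10.0)
        rot, cc = local_rotation_search(m, subunit, com, 8.0)
        assert _angular_distance_deg(rot, truth) <= 2.0

    def test_spherically_symmetric_model_orientation_free(self):
        from saptfit.fitting import _placement_cc_local

        atom = AtomicModel(
            [Chain("A", [Residue(1, "ALA", [Atom("CA", "C", np.zeros(3))])])]
        )
        m = simulate_density(atom, 6.0, voxel_size=1.0)
        rng = np.random.default_rng(0)
        ccs = [
            _placement_cc_local(
                m, atom, Rotation.random(rng=rng).as_matrix(), np.zeros(3), 6.0
            )
            for _ in range(8)
        ]
        # a single atom is spherically symmetric: every orientation ties
        assert max(ccs) - min(ccs) < 1e-6
        assert ccs[0] == pytest.approx(1.0, abs=1e-6)


class TestRigidBodyRefine:
    def test_fixed_point_at_truth(self, single_copy_case):
        c = single_copy_case
        start = Placement(c["rotation"], c["center"])
        out = rigid_body_refine(c["map"], c["model"], start, resolution=8.0)
        assert np.linalg.norm(out.translation - c["center"]) < 0.1
        assert _angular_distance_deg(out.rotation, c["rotation"]) < 0.5

    def test_displaced_start_converges(self, single_copy_case):
        c = single_copy_case
        wobble = Rotation.from_euler("x", 5, degrees=True).as_matrix()
        start = Placement(
            wobble @ c["rotation"], c["center"] + np.array([2.0, 0.0, 0.0])
        )
        out = rigid_body_refine(c["map"], c["model"], start, resolution=8.0)
        assert np.linalg.norm(out.translation - c["center"]) < 0.5
        assert _angular_distance_deg(out.rotation, c["rotation"]) < 1.0

    def test_cc_never_decreases(self, single_copy_case):
        c = single_copy_case
        rng = np.random.default_rng(3)
        for _ in range(3):
            wob = Rotation.from_rotvec(rng.normal(scale=0.1, size=3)).as_matrix()
            start = Placement(
                wob @ c["rotation"], c["center"] + rng.normal(scale=1.0, size=3)
            )
            before = rigid_body_refine(
                c["map"], c["model"], start, n_cycles=0, resolution=8.0
            ).cc_local
            out = rigid_body_refine(c["map"], c["model"], start, resolution=8.0)
            assert out.cc_local >= before - 1e-9


class TestPlacementInvariants:
    def test_rotation_must_be_proper(self):
        improper = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            Placement(improper, np.zeros(3))
        with pytest.raises(ValueError):
            Placement(np.eye(3) * 2.0, np.zeros(3))

    def test_packing_score_bounds(self):
        with pytest.raises(ValueError):
            Placement(np.eye(3), np.zeros(3), packing_score=1.5)


@pytest.fixture(scope="module")
def ring_placements(ring7_case):
    """Place up to 14 copies into the 7-copy ring map (shared run)."""
    return place_n_copies(
        ring7_case["map"], ring7_case["subunit"], 14, ring7_case["resolution"]
    )


class TestMultiCopy:
    def test_seven_copies_found_on_ring(self, ring7_case, ring_placements):
        placements = ring_placements[:7]
        assert len(placements) == 7
        com = ring7_case["subunit"].center_of_mass()
        true_centers = np.array([r @ com + t for r, t in ring7_case["transforms"]])
        for p in placements:
            err = np.linalg.norm(true_centers - p.translation, axis=1).min()
            assert err < 2.0

    def test_overplacement_collapses_after_seven(self, ring7_case, ring_placements):
        """Asking for 14 copies of a 7-copy map stops or degrades after 7."""
        assert len(ring_placements) >= 7
        if len(ring_placements) > 7:
            good = ring_placements[:7]
            floor_tfz = min(p.tfz for p in good)
            floor_pack = min(p.packing_score for p in good)
            for extra in ring_placements[7:]:
                assert extra.packing_score < floor_pack or extra.tfz < floor_tfz

    def test_accepted_copies_mutually_compatible(self, ring7_case, ring_placements):
        from scipy.spatial import cKDTree

        coords = [
            apply_placement(ring7_case["subunit"], p).coordinates()
            for p in ring_placements[:7]
        ]
        for i in range(len(coords)):
            tree = cKDTree(coords[i])
            for j in range(i + 1, len(coords)):
                d, _ = tree.query(coords[j], k=1)
                assert d.min() >= 2.0

    def test_single_copy_matches_pipeline(self, single_copy_case):
        c = single_copy_case
        placements = place_n_copies(c["map"], c["model"], 1, c["resolution"])
        assert len(placements) == 1
        truth = c["placed"].coordinates()
        got = apply_placement(c["model"], placements[0]).coordinates()
        assert _rmsd(truth, got) < 1.5

    def test_n_zero_rejected(self, single_copy_case):
        with pytest.raises(ValueError):
            place_n_copies(single_copy_case["map"], single_copy_case["model"], 0, 8.0)
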