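"""Bilayer trajectory geometry: leaflets, depths, hydrogen bonds, orientations."""

import numpy as np
import pytest

from conftest import brute_force_hbonds, build_system

from memprobe.gro import Frame, read_gro, write_gro
from memprobe.synth import gen_membrane_traj
from memprobe.traj import (
    HBondCriteria,
    assign_leaflets,
    bond_vector_angles,
    count_hbonds,
    depth_profile,
    hbond_timeseries,
    ring_normal_angles,
)


def minimal_lipid(resid, x, y, zP, mirror=False):
    """One headgroup-only pseudo-lipid: P plus an OG glycerol bead 0.5 nm inward."""
    s = -1.0 if mirror else 1.0
    return (
        [(resid, "LIP", "P"), (resid, "LIP", "OG")],
        [(x, y, zP), (x, y, zP - s * 0.5)],
    )


def slab(z_upper=6.0, z_lower=2.0, n_side=4, box=(4.0, 4.0, 8.0)):
    """Symmetric two-leaflet slab of minimal lipids around z = 4."""
    rows, coords = [], []
    resid = 0
    for z, mirror in ((z_upper, False), (z_lower, True)):
        for k in range(n_side * n_side):
            resid += 1
            r, c = minimal_lipid(resid, (k % n_side) + 0.5, (k // n_side) + 0.5, z, mirror)
            rows += r
            coords += c
    return rows, coords, box


class TestGroRoundTrip:
    def test_multi_frame_write_read(self, tmp_path, rng):
        sys_, _, _ = gen_membrane_traj(n_lipids=8, n_solutes=2, n_frames=3, box_z=8.0)
        path = tmp_path / "t.gro"
        write_gro(path, sys_.atoms, sys_.frames)
        atoms, frames = read_gro(path)
        assert len(frames) == 3
        assert list(atoms["name"]) == list(sys_.atoms["name"])
        assert np.allclose(frames[1].coords, sys_.frames[1].coords, atol=1e-3)
        assert frames[2].time == pytest.approx(sys_.frames[2].time)

    def test_malformed_file_reports_line(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text("title\n2\n    1LIP      P    1 bad line here\n")
        with pytest.raises(ValueError):
            read_gro(p)


class TestLeaflets:
    def test_symmetric_slab_splits_evenly(self):
        rows, coords, box = slab()
        sys_ = build_system(rows, np.array(coords), box=box)
        labels = assign_leaflets(sys_.frames[0], sys_.selections)
        assert (labels == "upper").sum() == 16 and (labels == "lower").sum() == 16

    def test_generator_ground_truth_agreement(self):
        sys_, _, truth = gen_membrane_traj(n_lipids=32, n_solutes=4, n_frames=1)
        labels = assign_leaflets(sys_.frames[0], sys_.selections)
        assert list(labels) == truth["lipid_leaflet"]

    def test_one_sided_arrangement_warns(self):
        rows, coords, box = slab()
        coords = np.array(coords)
        coords[:, 2] = np.abs(coords[:, 2] - 4.0) + 4.2  # everything above the COM? no: collapse upward
        sys_ = build_system(rows, coords, box=box)
        with pytest.warns(UserWarning, match="bilayer"):
            assign_leaflets(sys_.frames[0], sys_.selections)


class TestDepthProfile:
    def test_prescribed_depth_recovered_exactly(self):
        sys_, _, truth = gen_membrane_traj(depth=1.2, n_frames=2)
        dp = depth_profile(sys_)
        assert np.allclose(dp["solute_z"], truth["depth"], atol=1e-6)
        assert dp["phosphate_z"][0] == pytest.approx(2.0, abs=1e-6)
        assert dp["glycerol_z"][0] == pytest.approx(1.5, abs=1e-6)

    def test_solute_at_bilayer_centre_gives_zero(self):
        sys_, _, _ = gen_membrane_traj(depth=0.0, n_frames=1)
        dp = depth_profile(sys_)
        assert dp["solute_z"][0] == pytest.approx(0.0, abs=1e-6)

    def test_interfacial_scenario_matches_phosphate_depth(self):
        sys_, _, _ = gen_membrane_traj(depth=2.0, n_frames=1, box_z=10.0)
        dp = depth_profile(sys_)
        assert abs(dp["solute_z"][0] - dp["phosphate_z"][0]) < 0.05

    def test_rigid_translation_invariance(self):
        sys_, _, _ = gen_membrane_traj(depth=1.2, n_frames=1)
        dp0 = depth_profile(sys_)
        shift = np.array([1.3, -0.7, 2.9])
        for fr in sys_.frames:
            fr.coords = fr.coords + shift  # may push atoms across the boundary
        dp1 = depth_profile(sys_)
        assert np.allclose(dp0["solute_z"], dp1["solute_z"], atol=1e-9)
        assert np.allclose(dp0["phosphate_z"], dp1["phosphate_z"], atol=1e-9)

    def test_depths_bounded_by_half_box(self, rng):
        rows, coords, box = slab()
        # add one solute at random coordinates, possibly outside the box
        rid = 100
        rows += [(rid, "ALK", "C1"), (rid, "ALK", "N"), (rid, "ALK", "HN")]
        base = rng.uniform(-10, 10, size=3)
        coords = np.vstack([coords, base, base + [0.1, 0, 0.2], base + [0.15, 0, 0.3]])
        sys_ = build_system(rows, coords, box=box)
        dp = depth_profile(sys_)
        assert (dp[["solute_z", "phosphate_z", "glycerol_z"]].to_numpy() <= box[2] / 2 + 1e-9).all()

    def test_empty_selection_names_role(self):
        rows, coords, box = slab()
        sys_ = build_system(rows, np.array(coords), box=box)  # no solutes
        with pytest.raises(ValueError, match="solute"):
            depth_profile(sys_)


def donor_acceptor_frame(pairs, decoys=()):
    """Build a frame with explicit donor/H/acceptor triplets.

    ``pairs``: list of (D, H, A, acceptor_name) positions; each D/H belongs to
    its own solute molecule, each acceptor to its own lipid.
    """
    rows, coords = [], []
    rid = 0
    for d, h, a, acc_name in pairs:
        rid += 1
        rows += [(rid, "ALK", "N"), (rid, "ALK", "HN")]
        coords += [d, h]
        rid += 1
        rows += [(rid, "LIP", acc_name)]
        coords += [a]
    for pos in decoys:
        rid += 1
        rows += [(rid, "LIP", "OP1")]
        coords += [pos]
    return rows, np.array(coords, float)


class TestHydrogenBonds:
    def test_distance_cutoff_excludes_far_pair(self):
        rows, coords = donor_acceptor_frame(
            [((1, 1, 1), (1, 1, 1.1), (1, 1, 1.5), "OP1")]  # 0.50 nm apart
        )
        sys_ = build_system(rows, coords)
        counts = count_hbonds(sys_.frames[0], sys_.selections)
        assert sum(counts.values()) == 0

    def test_ideal_collinear_geometry_counts_one(self):
        rows, coords = donor_acceptor_frame(
            [((1, 1, 1), (1, 1, 1.1), (1, 1, 1.28), "OP1")]  # 0.28 nm, angle 0
        )
        sys_ = build_system(rows, coords)
        counts = count_hbonds(sys_.frames[0], sys_.selections)
        assert counts == {"phosphate": 1, "ester": 0, "glycerol": 0}

    def test_angle_cutoff_excludes_bent_geometry(self):
        # acceptor at 90 degrees off the N-H direction, still within d_max
        rows, coords = donor_acceptor_frame(
            [((1, 1, 1), (1, 1, 1.1), (1.3, 1, 1), "OP1")]
        )
        sys_ = build_system(rows, coords)
        assert sum(count_hbonds(sys_.frames[0], sys_.selections).values()) == 0

    def test_classification_by_lipid_group(self):
        rows, coords = donor_acceptor_frame(
            [
                ((1, 1, 1), (1, 1, 1.1), (1, 1, 1.3), "OE1"),
                ((3, 3, 1), (3, 3, 1.1), (3, 3, 1.3), "OG"),
            ]
        )
        sys_ = build_system(rows, coords)
        counts = count_hbonds(sys_.frames[0], sys_.selections)
        assert counts == {"phosphate": 0, "ester": 1, "glycerol": 1}

    def test_constructed_frame_with_seven_bonds_matches_oracle(self):
        pairs = []
        for i in range(7):
            x = 0.8 * (i + 1)
            pairs.append(((x, 1, 1), (x, 1, 1.1), (x, 1, 1.32), "OP1"))
        decoys = [(0.8 * (i + 1), 3.0, 1.0) for i in range(5)]
        rows, coords = donor_acceptor_frame(pairs, decoys)
        sys_ = build_system(rows, coords, box=(8.0, 8.0, 8.0))
        counts = count_hbonds(sys_.frames[0], sys_.selections)
        oracle = brute_force_hbonds(sys_.frames[0], sys_.selections)
        assert counts == oracle
        assert sum(counts.values()) == 7

    def test_random_frames_agree_with_brute_force(self, rng):
        for _ in range(10):
            pairs, decoys = [], []
            for i in range(8):
                d = rng.uniform(0.5, 5.5, 3)
                h = d + 0.1 * rng.normal(size=3)
                a = d + rng.uniform(-0.5, 0.5, 3)
                pairs.append((tuple(d), tuple(h), tuple(a), rng.choice(["OP1", "OE1", "OG"])))
            for _ in range(10):
                decoys.append(tuple(rng.uniform(0, 6, 3)))
            rows, coords = donor_acceptor_frame(pairs, decoys)
            sys_ = build_system(rows, coords, box=(6.0, 6.0, 6.0))
            assert count_hbonds(sys_.frames[0], sys_.selections) == brute_force_hbonds(
                sys_.frames[0], sys_.selections
            )

    def test_minimal_image_bond_across_boundary(self):
        # donor near the box edge, acceptor just across the periodic wall
        rows, coords = donor_acceptor_frame(
            [((0.1, 1, 1), (0.02, 1, 1), (5.9, 1, 1), "OP1")]
        )
        sys_ = build_system(rows, coords, box=(6.0, 6.0, 6.0))
        counts = count_hbonds(sys_.frames[0], sys_.selections)
        assert counts["phosphate"] == 1

    def test_donor_without_hydrogen_rejected_at_load(self):
        rows = [(1, "ALK", "N"), (2, "LIP", "OP1")]
        coords = np.array([[1, 1, 1], [1, 1, 1.3]])
        with pytest.raises(ValueError, match="hydrogen"):
            build_system(rows, coords)


class TestHBondTimeseries:
    def test_constant_series_mean(self):
        sys_, _, _ = gen_membrane_traj(depth=0.6, hbond_schedule=[2, 2, 2, 2])
        df, means = hbond_timeseries(sys_, window=40.0)
        assert np.allclose(df["total"], 2.0)
        assert means["total"] == pytest.approx(2.0)

    def test_step_schedule_window_selects_second_half(self):
        sys_, _, _ = gen_membrane_traj(depth=0.6, hbond_schedule=[0, 0, 4, 4], frame_dt_ns=10.0)
        df, means = hbond_timeseries(sys_, window=15.0)  # last two frames
        assert means["total"] == pytest.approx(4.0)
        assert np.allclose(df["total"], [0, 0, 4, 4])

    def test_prescribed_schedule_reproduced_exactly(self):
        schedule = [1, 3, 2, 4, 0]
        sys_, _, truth = gen_membrane_traj(depth=0.6, hbond_schedule=schedule)
        df, _ = hbond_timeseries(sys_, window=50.0)
        assert list(df["phosphate"]) == schedule
        assert list(df["total"]) == schedule

    def test_invalid_window_rejected(self):
        sys_, _, _ = gen_membrane_traj(depth=0.6, hbond_schedule=[1, 1])
        with pytest.raises(ValueError):
            hbond_timeseries(sys_, window=0.0)


class TestOrientationAngles:
    def test_vector_along_normal_is_zero_degrees(self):
        rows = [(1, "ALK", "C1"), (1, "ALK", "N"), (1, "ALK", "HN")]
        coords = np.array([[1, 1, 1], [1, 1, 1.4], [1, 1, 1.5]])
        sys_ = build_system(rows, coords, config_extra={
            "orient_vector": {"residue": "ALK", "from": "C1", "to": "N"}})
        assert bond_vector_angles(sys_).mode == pytest.approx(0.0, abs=1.0)

    def test_vector_in_plane_is_ninety_degrees(self):
        rows = [(1, "ALK", "C1"), (1, "ALK", "N"), (1, "ALK", "HN")]
        coords = np.array([[1, 1, 1], [1.4, 1, 1], [1.5, 1, 1]])
        sys_ = build_system(rows, coords, config_extra={
            "orient_vector": {"residue": "ALK", "from": "C1", "to": "N"}})
        assert bond_vector_angles(sys_).mode == pytest.approx(90.0, abs=1e-6)

    def test_mirrored_leaflets_give_supplementary_modes(self):
        sys_, _, _ = gen_membrane_traj(depth=1.2, bond_tilt_deg=35.0, n_frames=2)
        unfolded = bond_vector_angles(sys_)
        modes = sorted(unfolded.modes(2))
        assert modes[0] == pytest.approx(35.0, abs=0.5)
        assert modes[1] == pytest.approx(145.0, abs=0.5)
        folded = bond_vector_angles(sys_, fold=True)
        assert folded.mode == pytest.approx(35.0, abs=0.5)

    def test_folding_preserves_probability_mass(self):
        sys_, _, _ = gen_membrane_traj(depth=1.2, bond_tilt_deg=35.0, n_frames=2)
        for dist in (bond_vector_angles(sys_), bond_vector_angles(sys_, fold=True)):
            w = np.diff(dist.bin_edges)
            assert float((dist.density * w).sum()) == pytest.approx(1.0, abs=1e-9)
        assert bond_vector_angles(sys_, fold=True).n_samples == bond_vector_angles(sys_).n_samples

    def test_ring_plane_in_bilayer_plane_gives_axial_normal(self):
        sys_, _, _ = gen_membrane_traj(depth=1.2, ring_tilt_deg=0.0, n_frames=1)
        assert ring_normal_angles(sys_, fold=True).mode == pytest.approx(0.0, abs=0.5)

    def test_ring_plane_containing_normal_gives_ninety(self):
        sys_, _, _ = gen_membrane_traj(depth=1.2, ring_tilt_deg=90.0, n_frames=1)
        assert ring_normal_angles(sys_).mode == pytest.approx(90.0, abs=0.5)

    def test_tilted_ring_plane_folded_mode(self):
        sys_, _, _ = gen_membrane_traj(depth=1.2, ring_tilt_deg=30.0, n_frames=1)
        assert ring_normal_angles(sys_, fold=True).mode == pytest.approx(30.0, abs=0.5)

    def test_degenerate_ring_triplet_skipped_with_count(self):
        rows = [(1, "ALK", "C1"), (1, "ALK", "C2"), (1, "ALK", "C3"),
                (1, "ALK", "N"), (1, "ALK", "HN")]
        coords = np.array([[1, 1, 1], [1.2, 1, 1], [1.4, 1, 1], [1, 1, 1.3], [1, 1, 1.4]])
        sys_ = build_system(rows, coords, config_extra={
            "ring_triplet": {"residue": "ALK", "atoms": ["C1", "C2", "C3"]}})
        dist = ring_normal_angles(sys_)
        assert dist.n_samples == 0 and dist.n_skipped == 1
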