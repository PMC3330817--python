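"""Geometry construction: spindles, asters, maturation schedules, energids."""

import numpy as np
import pytest
from pydantic import ValidationError

from mtseq.geometry import (EnergidDomain, GeometryError, MaturationSchedule,
                            MicrotubuleSet, SpindleSpec, build_aster,
                            build_energid_domain, build_spindle,
                            cone_solid_angle_fraction, merge)


class TestSpindle:
    def test_cone_solid_angle_matches_15_percent(self):
        # a 45-degree half-angle cone covers (1 - cos 45°)/2 of the sphere
        assert cone_solid_angle_fraction(45.0) == pytest.approx(0.1464, abs=5e-4)

    def test_minus_ends_on_nucleation_sphere(self, small_spindle):
        d = np.linalg.norm(small_spindle.minus
                           - small_spindle.pole_positions[small_spindle.pole_id], axis=1)
        assert np.abs(d - 1.0).max() < 1e-9

    def test_plus_ends_on_midplane_or_cortex(self):
        spec = SpindleSpec(n_spindle=200, n_astral=200)
        mts = build_spindle(spec, seed=0)
        r = np.linalg.norm(mts.plus, axis=1)
        on_sphere = np.isclose(r, spec.cell_radius, atol=1e-9)
        on_plane = np.isclose(mts.plus[:, 0], 0.0, atol=1e-9)
        assert np.all(on_sphere | on_plane)
        assert np.all(r <= spec.cell_radius + 1e-9)

    def test_cone_astral_partition_is_exact(self):
        spec = SpindleSpec(n_spindle=300, n_astral=150)
        mts = build_spindle(spec, seed=3)
        for pid, axis in ((0, np.array([1.0, 0, 0])), (1, np.array([-1.0, 0, 0]))):
            sel = mts.pole_id == pid
            dirs = (mts.minus[sel] - spec.pole_positions[pid]) / 1.0
            cos_t = dirs @ axis
            inside = cos_t >= np.cos(np.deg2rad(45.0)) - 1e-12
            assert inside.sum() == 300
            assert (~inside).sum() == 150

    def test_empty_spindle(self):
        mts = build_spindle(SpindleSpec(n_spindle=0, n_astral=0), seed=0)
        assert len(mts) == 0

    def test_coincident_poles_rejected(self):
        with pytest.raises(ValidationError):
            SpindleSpec(pole_separation=0.0)

    def test_poles_outside_cell_rejected(self):
        with pytest.raises(ValidationError):
            SpindleSpec(pole_separation=25.0)

    def test_csv_round_trip(self, small_spindle, tmp_path):
        p = tmp_path / "mts.csv"
        small_spindle.to_csv(p)
        back = MicrotubuleSet.from_csv(p)
        np.testing.assert_allclose(back.minus, small_spindle.minus)
        np.testing.assert_allclose(back.plus, small_spindle.plus)
        np.testing.assert_array_equal(back.pole_id, small_spindle.pole_id)

    def test_degenerate_filament_rejected(self):
        with pytest.raises(GeometryError):
            MicrotubuleSet([[0, 0, 0]], [[0, 0, 0]], [0], [[0, 0, 0]])


class TestBarrel:
    def test_barrel_links_and_overlap(self):
        spec = SpindleSpec(n_spindle=100, n_astral=0, midzone_style="barrel",
                           barrel_overlap=2.0)
        mts = build_spindle(spec, seed=0)
        bent = np.nonzero(mts.next_link >= 0)[0]
        assert bent.size > 0
        for a in bent:
            b = mts.next_link[a]
            assert mts.prev_link[b] == a
            # continuation starts where the first segment ends
            np.testing.assert_allclose(mts.plus[a], mts.minus[b], atol=1e-12)
            # second segment is axis-parallel and ends overlap/2 past x = 0
            d = mts.direction[b]
            assert abs(abs(d[0]) - 1.0) < 1e-9
            assert abs(abs(mts.plus[b][0]) - 1.0) < 1e-9


class TestAster:
    def test_fixed_length_segments(self):
        mts = build_aster((0, 0, 0), 500, seed=1, length=2.0)
        assert np.allclose(mts.length, 2.0, atol=1e-12)

    def test_fixed_length_truncated_by_cortex(self):
        mts = build_aster((8.0, 0, 0), 500, seed=1, length=5.0)
        r = np.linalg.norm(mts.plus, axis=1)
        assert np.all(r <= 10.0 + 1e-9)
        truncated = ~np.isclose(mts.length, 5.0)
        assert truncated.any()
        assert np.allclose(r[truncated], 10.0, atol=1e-9)

    def test_empty_aster(self):
        assert len(build_aster((0, 0, 0), 0, seed=0)) == 0

    def test_direction_isotropy(self):
        n = 10_000
        mts = build_aster((0, 0, 0), n, seed=0)
        dirs = (mts.minus - 0.0) / 1.0
        tol = 3.0 * (3 * n) ** -0.5
        assert np.abs(dirs.mean(axis=0)).max() < tol

    def test_invalid_inputs(self):
        with pytest.raises(GeometryError):
            build_aster((0, 0, 0), 10, seed=0, length=-1.0)
        with pytest.raises(GeometryError):
            build_aster((11.0, 0, 0), 10, seed=0)

    def test_midplane_truncation(self):
        mts = build_aster((-5.0, 0, 0), 500, seed=2,
                          truncate_plane=((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)))
        assert mts.plus[:, 0].max() <= 1e-9


class TestMaturation:
    def _schedule(self):
        return MaturationSchedule(
            count_schedules=[([0.0, 100.0], [20, 80]), ([0.0, 100.0], [5, 5])],
            trajectories=[([0.0, 100.0], [[-5, 0, 0], [-5, 0, 0]]),
                          ([0.0, 100.0], [[-4, 0, 0], [5, 0, 0]])],
            seed=0)

    def test_counts_interpolate(self):
        s = self._schedule()
        assert s.count_at(0.0, 0) == 20
        assert s.count_at(50.0, 0) == 50
        assert s.count_at(100.0, 0) == 80
        assert s.count_at(30.0, 1) == 5

    def test_active_mask_matches_count(self):
        s = self._schedule()
        mts, active = s.mt_set_at(50.0)
        assert active[mts.pole_id == 0].sum() == 50
        assert active[mts.pole_id == 1].sum() == 5

    def test_rigid_translation_keeps_ids(self):
        s = self._schedule()
        m0, _ = s.mt_set_at(0.0)
        m1, _ = s.mt_set_at(100.0)
        assert len(m0) == len(m1)
        # pole 1 moved; its minus ends moved with it
        sel = m0.pole_id == 1
        shift = m1.pole_positions[1] - m0.pole_positions[1]
        assert np.linalg.norm(shift) > 1.0

    def test_invalid_schedules_rejected(self):
        with pytest.raises(GeometryError):
            MaturationSchedule([([0, 1], [-5, 5])], [([0, 1], [[0, 0, 0], [0, 0, 0]])])
        with pytest.raises(GeometryError):
            MaturationSchedule([([0, 1], [5, 5])], [([0, 1], [[0, 0, 0], [20, 0, 0]])])


class TestEnergidDomain:
    def test_default_subdomains(self):
        d = EnergidDomain()
        sx, sy, sz = d.subdomain_slices(0, 0)
        assert (sx.stop - sx.start) * d.spacing == 7.0
        assert (sz.stop - sz.start) * d.spacing == 7.0
        assert d.n_sub ** 2 == 25

    def test_volume_independent_of_wall_depth(self):
        for wd in (0.0, 7.0, 13.0):
            d = EnergidDomain(spacing=0.5, wall_depth=wd)
            vol = np.prod(d.shape) * d.cell_volume
            assert vol == pytest.approx(35 * 35 * 14)

    def test_zero_wall_depth_is_plain_box(self):
        d = EnergidDomain(wall_depth=0.0)
        assert d.n_blocked_faces() == 0

    def test_blocked_face_count_matches_brute_force(self):
        d = EnergidDomain(spacing=0.5, wall_depth=7.0)
        # brute force: count grid faces lying on the 4+4 wall planes in the
        # top 7 µm, using the raw face/cell enumeration
        nx, ny, nz = d.shape
        kz = int(7.0 / 0.5)
        planes = [7.0, 14.0, 21.0, 28.0]
        expected = 0
        for _ in planes:          # x-normal faces: one per (y, z) cell pair
            expected += ny * kz
        for _ in planes:          # y-normal faces
            expected += nx * kz
        assert d.n_blocked_faces() == expected

    def test_misaligned_spacing_rejected(self):
        with pytest.raises(GeometryError):
            build_energid_domain(spacing=0.6)
        with pytest.raises(GeometryError):
            build_energid_domain(spacing=2.0)  # 2 does not divide the 7 µm walls

    def test_sequestration_mask_is_top_layer(self):
        d = EnergidDomain(spacing=1.0)
        m = d.sequestration_mask()
        assert m[:, :, :7].all()
        assert not m[:, :, 7:].any()


def test_merge_reindexes_links():
    a = build_aster((-5, 0, 0), 10, seed=0, pole_id=0)
    b = build_aster((5, 0, 0), 10, seed=1, pole_id=1)
    m = merge([a, b], [[-5, 0, 0], [5, 0, 0]])
    assert len(m) == 20
    assert (m.pole_id[:10] == 0).all() and (m.pole_id[10:] == 1).all()
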