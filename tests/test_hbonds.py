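"""Geometric hydrogen-bond detection and census statistics."""

import numpy as np
import pytest

from crystalhabit import (
    band_probability,
    detect_hbonds,
    gen_hbond_scene,
    length_angle_densities,
    summarize_hbonds,
)
from crystalhabit.hbonds import HBondRecord, census_identities

BOX = np.array([100.0, 100.0, 100.0])


def triple(length, angle_deg, origin=(50.0, 50.0, 50.0)):
    """Coordinates for one D-H...A triple with the given geometry."""
    h = np.asarray(origin, dtype=float)
    a = h + np.array([length, 0.0, 0.0])
    th = np.radians(angle_deg)
    d = h + np.array([np.cos(th), np.sin(th), 0.0])
    return np.array([d, h, a])


class TestDetect:
    def test_good_geometry_is_one_bond(self):
        coords = triple(2.5, 160.0)
        recs = detect_hbonds(coords, [(0, 1)], [2], BOX)
        assert len(recs) == 1
        assert recs[0].length == pytest.approx(2.5, abs=1e-9)
        assert recs[0].angle == pytest.approx(160.0, abs=1e-9)

    def test_beyond_distance_cutoff(self):
        assert detect_hbonds(triple(3.5, 160.0), [(0, 1)], [2], BOX) == []

    def test_below_angle_cutoff(self):
        assert detect_hbonds(triple(2.5, 100.0), [(0, 1)], [2], BOX) == []

    def test_minimum_image_across_boundary(self):
        coords = triple(2.5, 160.0)
        coords[2, 0] = coords[1, 0] + 2.5 - BOX[0]  # acceptor wrapped to other side
        recs = detect_hbonds(coords, [(0, 1)], [2], BOX,
                             periodic=(True, True, True))
        assert len(recs) == 1
        assert recs[0].length == pytest.approx(2.5, abs=1e-9)

    def test_missing_topology(self):
        with pytest.raises(ValueError, match="donor"):
            detect_hbonds(triple(2.5, 160.0), [(1, 1)], [2], BOX)

    def test_planted_scene_recovered_exactly(self):
        scene = gen_hbond_scene(40, 60, (100.0, 100.0, 100.0), seed=12)
        recs = detect_hbonds(scene.coords, scene.donors, scene.acceptors,
                             scene.box)
        assert len(recs) == 40
        got = {(r.hydrogen, r.acceptor) for r in recs}
        want = {(r.hydrogen, r.acceptor) for r in scene.planted}
        assert got == want
        for rec, truth in zip(sorted(recs, key=lambda r: r.hydrogen),
                              sorted(scene.planted, key=lambda r: r.hydrogen)):
            assert rec.length == pytest.approx(truth.length, abs=1e-9)
            assert rec.angle == pytest.approx(truth.angle, abs=1e-6)

    def test_rigid_motion_invariance(self):
        scene = gen_hbond_scene(15, 15, (100.0, 100.0, 100.0), seed=3)
        base = detect_hbonds(scene.coords, scene.donors, scene.acceptors,
                             scene.box, periodic=(False, False, False))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = scene.coords @ rot.T + np.array([3.0, -2.0, 1.0])
        after = detect_hbonds(moved, scene.donors, scene.acceptors,
                              scene.box * 10, periodic=(False, False, False))
        assert len(after) == len(base)
        for r1, r2 in zip(base, after):
            assert r2.length == pytest.approx(r1.length, abs=1e-9)
            assert r2.angle == pytest.approx(r1.angle, abs=1e-6)

    def test_loosening_cutoffs_is_monotone(self):
        scene = gen_hbond_scene(20, 40, (100.0, 100.0, 100.0), seed=7)
        n = {}
        for d_max, a_min in [(2.6, 140.0), (3.1, 140.0), (3.1, 120.0),
                             (4.5, 100.0)]:
            n[(d_max, a_min)] = len(detect_hbonds(
                scene.coords, scene.donors, scene.acceptors, scene.box,
                d_max=d_max, angle_min=a_min))
        counts = list(n.values())
        assert counts == sorted(counts)


class TestSummary:
    def test_tabulated_derived_columns(self, hbond_census_tables):
        """The per-donor, per-area and per-unit-cell-face identities
        reproduce every tabulated row at printed precision."""
        expected = {
            "ch2cl2": {"1 0 0": (1.38, 0.0102, 1.03),
                       "1 1 0": (0.98, 0.0137, 1.97),
                       "1 1 1": (0.87, 0.0031, 0.87),
                       "1 1 -1": (1.03, 0.0074, 2.06),
                       "1 0 -1": (0.98, 0.0076, 1.96)},
            "ch2cl2_c6h14": {"1 0 0": (1.27, 0.0094, 0.95),
                             "1 1 0": (0.84, 0.0117, 1.68),
                             "1 1 1": (0.86, 0.0031, 0.86),
                             "1 1 -1": (0.83, 0.0060, 1.66),
                             "1 0 -1": (0.88, 0.0068, 1.76)},
        }
        for system, table in hbond_census_tables.items():
            for _, row in table.iterrows():
                got = census_identities(row["N_HB"], row["N_H1"],
                                        row["A_box"], row["A_hkl"])
                per_h1, unit_area, n_hkl = expected[system][row["face"]]
                assert got["N_HB-per H1"] == pytest.approx(per_h1, abs=0.005)
                assert got["N_HB-unit area"] == pytest.approx(unit_area,
                                                              abs=5e-5)
                assert got["N_HB-hkl"] == pytest.approx(n_hkl, abs=0.005)

    def test_summary_from_records(self):
        recs = [HBondRecord(0, 0, 1, 2, 2.3, 155.0),
                HBondRecord(0, 3, 4, 5, 2.7, 145.0),
                HBondRecord(1, 0, 1, 2, 2.4, 160.0)]
        s = summarize_hbonds(recs, n_frames=2, a_box=1000.0, a_hkl=100.0)
        assert s.n_hb == pytest.approx(1.5)
        assert s.n_h1 == 2
        assert s.n_hb_per_h1 == pytest.approx(0.75)
        assert s.s1_percent == pytest.approx(2 / 3 * 100)
        assert s.s2_percent == pytest.approx(2 / 3 * 100)
        assert s.n_hb_unit_area == pytest.approx(0.0015)
        assert s.n_hb_hkl == pytest.approx(0.15)
        assert s.mean_length == pytest.approx((2.3 + 2.7 + 2.4) / 3)

    def test_scene_summary_matches_planted_means(self):
        scene = gen_hbond_scene(60, 30, (100.0, 100.0, 100.0), seed=21)
        recs = detect_hbonds(scene.coords, scene.donors, scene.acceptors,
                             scene.box)
        s = summarize_hbonds(recs, n_frames=1, a_box=1e4, a_hkl=100.0)
        lengths = [r.length for r in scene.planted]
        angles = [r.angle for r in scene.planted]
        assert s.mean_length == pytest.approx(np.mean(lengths), abs=1e-9)
        assert s.mean_angle == pytest.approx(np.mean(angles), abs=1e-6)
        assert s.n_h1 == 60

    def test_no_bonds_flagged_undefined(self):
        s = summarize_hbonds([], n_frames=5, a_box=1000.0, a_hkl=100.0)
        assert s.n_hb == 0.0
        assert not s.defined
        assert np.isnan(s.s1_percent) and np.isnan(s.n_hb_per_h1)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            summarize_hbonds([], n_frames=0, a_box=1.0, a_hkl=1.0)


class TestDensities:
    def records(self, lengths, angles):
        return [HBondRecord(0, 3 * i, 3 * i + 1, 3 * i + 2, l, a)
                for i, (l, a) in enumerate(zip(lengths, angles))]

    def test_identical_records_single_bin(self):
        recs = self.records([2.57] * 10, [150.0] * 10)
        ld, ad = length_angle_densities(recs)
        assert np.count_nonzero(ld.density) == 1
        assert ld.density.max() == pytest.approx(1.0 / ld.bin_width)
        assert np.count_nonzero(ad.density) == 1

    def test_integral_is_one(self):
        rng = np.random.default_rng(5)
        recs = self.records(rng.normal(2.57, 0.1, 500),
                            rng.normal(150.0, 10.0, 500))
        ld, ad = length_angle_densities(recs)
        assert ld.integral() == pytest.approx(1.0, abs=1e-6)
        assert ad.integral() == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_sample_mean_recovered(self):
        rng = np.random.default_rng(17)
        n, mu, sd = 2000, 2.57, 0.08
        lengths = rng.normal(mu, sd, n)
        recs = self.records(lengths, np.full(n, 150.0))
        ld, _ = length_angle_densities(recs)
        est_mean = float((ld.centers * ld.density).sum() * ld.bin_width)
        assert abs(est_mean - lengths.mean()) < ld.bin_width
        assert abs(est_mean - mu) < 2 * sd / np.sqrt(n) + ld.bin_width

    def test_band_probability(self):
        recs = self.records(np.linspace(2.0, 3.0, 50), np.linspace(121, 179, 50))
        _, ad = length_angle_densities(recs)
        assert band_probability(ad, 0.0, 360.0) == pytest.approx(1.0, abs=1e-6)
        assert band_probability(ad, 500.0, 600.0) == 0.0
        with pytest.raises(ValueError):
            band_probability(ad, 150.0, 120.0)

    def test_uniform_band_closed_form(self):
        # angles uniform on [0, 180): P(120 <= x <= 133) ~ 13/180
        rng = np.random.default_rng(31)
        angles = rng.uniform(0.0, 180.0, 40000)
        recs = self.records(np.full(angles.size, 2.5), angles)
        _, ad = length_angle_densities(recs)
        assert band_probability(ad, 120.0, 133.0) == pytest.approx(
            13.0 / 180.0, abs=0.01
        )
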