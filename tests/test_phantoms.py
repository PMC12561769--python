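"""Phantom-generator checks: determinism, statistics, geometry, IO."""

import numpy as np
import pytest

import protorange as pr
from protorange import media
from protorange.phantoms import save_grid, load_grid


def _cfg(**kw):
    base = dict(kind="thermal_water", shape=(40, 40, 1), spacing=1.0, seed=7)
    base.update(kw)
    return pr.PhantomConfig(**base)


class TestThermalWater:
    def test_zero_sd_is_exactly_baseline(self):
        g = pr.make_thermal_water_phantom(_cfg(temperature_sd=0.0))
        assert np.all(g.speed == 1498.0)
        assert np.all(g.density == 997.0)

    def test_speed_spread_matches_delta_method(self):
        # sd_c ~ sd_T * dc/dT at 25 degC, within 5% at this sample size
        sd_t = 15.0
        cfg = _cfg(
            heterogeneity="nonuniform", temperature_sd=sd_t, shape=(80, 80, 1), seed=3
        )
        g = pr.make_thermal_water_phantom(cfg)
        eps = 1e-4
        slope = (
            pr.water_speed_of_sound(25 + eps) - pr.water_speed_of_sound(25 - eps)
        ) / (2 * eps)
        assert g.speed.std() == pytest.approx(sd_t * slope, rel=0.05)

    def test_mean_temperature_preserved(self):
        cfg = _cfg(heterogeneity="nonuniform", temperature_sd=10.0, shape=(100, 100, 1))
        g = pr.make_thermal_water_phantom(cfg)
        n = g.temperature.size
        assert abs(g.temperature.mean() - 25.0) < 3 * 10.0 / np.sqrt(n)
        # linear conversion keeps the bulk speed unchanged too
        assert abs(g.speed.mean() - 1498.0) < 3 * 10.0 * 2.7 / np.sqrt(n)

    def test_polynomial_conversion_shifts_bulk_speed_down(self):
        # the anchored speed polynomial is concave at 25 degC, so the full
        # curve lowers the bulk mean for a wide symmetric temperature field
        cfg = _cfg(heterogeneity="nonuniform", temperature_sd=15.0, shape=(100, 100, 1))
        lin = pr.make_thermal_water_phantom(cfg, conversion="linear")
        poly = pr.make_thermal_water_phantom(cfg, conversion="polynomial")
        assert poly.speed.mean() < lin.speed.mean() - 5.0

    def test_seed_determinism(self):
        a = pr.make_thermal_water_phantom(_cfg(heterogeneity="nonuniform", temperature_sd=5.0))
        b = pr.make_thermal_water_phantom(_cfg(heterogeneity="nonuniform", temperature_sd=5.0))
        assert np.array_equal(a.speed, b.speed)
        assert np.array_equal(a.density, b.density)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            _cfg(temperature_sd=-1.0)


class TestTissuePhantoms:
    def test_uniform_lung_constant(self):
        g = pr.make_tissue_phantom(
            _cfg(kind="homogeneous", tissues=("lung",), heterogeneity="uniform")
        )
        assert np.all(g.speed == 652.8)
        assert np.all(g.density == 234.0)

    def test_nonuniform_mean_matches_table(self):
        g = pr.make_tissue_phantom(
            pr.PhantomConfig(
                kind="homogeneous",
                tissues=("bone",),
                heterogeneity="nonuniform",
                shape=(60, 60, 1),
                seed=11,
            )
        )
        assert g.speed.mean() == pytest.approx(2153.9, rel=0.01)
        assert g.speed.std() == pytest.approx(21.6, rel=0.1)
        assert g.density.mean() == pytest.approx(1574.4, rel=0.01)

    def test_unknown_tissue_rejected(self):
        with pytest.raises(KeyError):
            pr.make_tissue_phantom(_cfg(kind="homogeneous", tissues=("cartilage",)))

    def test_uniform_flag_overrides_sd(self):
        a = pr.make_tissue_phantom(
            _cfg(kind="homogeneous", tissues=("soft_tissue",), heterogeneity="uniform")
        )
        assert np.all(a.speed == 1567.1)


class TestBimaterial:
    def test_segment_mean_speed_is_pair_mean(self):
        g = pr.make_bimaterial_phantom(
            _cfg(kind="bimaterial", tissues=("bone", "lung"), shape=(200, 200, 1))
        )
        c_avg, prof = pr.path_average_speed(g, (50, 100, 0), (150, 100, 0))
        assert c_avg == pytest.approx((2153.9 + 652.8) / 2, abs=1e-9)
        assert prof.length_mm == pytest.approx(100.0)

    def test_soft_tissue_bone_pair_mean(self):
        g = pr.make_bimaterial_phantom(
            _cfg(kind="bimaterial", tissues=("soft_tissue", "bone"), shape=(200, 200, 1))
        )
        c_avg, _ = pr.path_average_speed(g, (50, 100, 0), (150, 100, 0))
        assert c_avg == pytest.approx(1860.5, abs=1e-9)

    def test_swap_preserves_segment_mean(self):
        a = pr.make_bimaterial_phantom(_cfg(kind="bimaterial", tissues=("bone", "lung")))
        b = pr.make_bimaterial_phantom(_cfg(kind="bimaterial", tissues=("lung", "bone")))
        ca, _ = pr.path_average_speed(a, (10, 20, 0), (30, 20, 0))
        cb, _ = pr.path_average_speed(b, (10, 20, 0), (30, 20, 0))
        assert ca == pytest.approx(cb)
        assert np.array_equal(np.unique(a.labels), np.unique(b.labels))

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError):
            pr.make_bimaterial_phantom(_cfg(kind="bimaterial", tissues=("bone", "bone")))

    def test_matched_means_uniform_vs_nonuniform(self):
        u = pr.make_bimaterial_phantom(
            _cfg(kind="bimaterial", tissues=("lung", "bone"), shape=(120, 120, 1))
        )
        n = pr.make_bimaterial_phantom(
            _cfg(
                kind="bimaterial",
                tissues=("lung", "bone"),
                heterogeneity="nonuniform",
                shape=(120, 120, 1),
            )
        )
        assert n.speed.mean() == pytest.approx(u.speed.mean(), rel=0.01)
        assert n.density.mean() == pytest.approx(u.density.mean(), rel=0.01)


class TestCtVolumes:
    def test_round_trip_npz(self, tmp_path):
        g = pr.make_ct_like_volume(shape=(40, 40, 1), seed=2, hu_sd_scale=1.0)
        path = tmp_path / "vol.npz"
        np.savez(path, hu=g.hu.squeeze(), spacing=1.0)
        loaded = pr.load_ct_volume(path, hu_scale="offset")
        assert np.allclose(loaded.speed, g.speed)
        assert np.allclose(loaded.density, g.density)

    def test_all_water_volume_uniform(self, tmp_path):
        path = tmp_path / "water.npz"
        np.savez(path, hu=np.full((20, 20), 1000.0), spacing=2.0)
        g = pr.load_ct_volume(path, hu_scale="offset")
        assert np.all(g.speed == 1498.0)
        assert g.spacing == 2.0

    def test_air_pocket_lowers_path_average(self):
        clean = pr.make_ct_like_volume(shape=(100, 100, 1), bone_shell_mm=0.0)
        pocket = pr.make_ct_like_volume(
            shape=(100, 100, 1),
            bone_shell_mm=0.0,
            air_pocket=((50.0, 50.0, 0.0), 8.0),
        )
        c_clean, _ = pr.path_average_speed(clean, (30, 50, 0), (70, 50, 0))
        c_pocket, _ = pr.path_average_speed(pocket, (30, 50, 0), (70, 50, 0))
        assert c_pocket < c_clean < 1567.1 + 1e-9

    def test_undeclared_scale_rejected(self, tmp_path):
        path = tmp_path / "x.npz"
        np.savez(path, hu=np.full((5, 5), 1000.0), spacing=1.0)
        with pytest.raises(TypeError):
            pr.load_ct_volume(path)  # hu_scale is keyword-required
        with pytest.raises(ValueError):
            pr.load_ct_volume(path, hu_scale="bogus")

    def test_missing_file_rejected(self):
        with pytest.raises(FileNotFoundError):
            pr.load_ct_volume("does-not-exist.npz", hu_scale="offset")

    def test_nifti_round_trip(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        hu = np.full((12, 12, 3), 1000.0)
        hu[4:8, 4:8, 1] = 1850.0
        img = nib.Nifti1Image(hu, affine=np.eye(4))
        path = tmp_path / "ct.nii"
        nib.save(img, str(path))
        g = pr.load_ct_volume(path, hu_scale="offset")
        assert g.speed[5, 5, 1] == pytest.approx(2153.9)
        assert g.speed[0, 0, 0] == pytest.approx(1498.0)


def test_grid_save_load_round_trip(tmp_path):
    g = pr.make_tissue_phantom(
        _cfg(kind="homogeneous", tissues=("lung",), heterogeneity="nonuniform")
    )
    save_grid(g, tmp_path / "g.npz")
    h = load_grid(tmp_path / "g.npz")
    assert np.array_equal(g.speed, h.speed)
    assert np.array_equal(g.labels, h.labels)
    assert h.spacing == g.spacing


def test_grid_invariants_enforced():
    with pytest.raises(ValueError):
        pr.MediumGrid(spacing=1.0, speed=np.zeros((4, 4, 1)), density=np.ones((4, 4, 1)))
    with pytest.raises(ValueError):
        pr.MediumGrid(
            spacing=-1.0, speed=np.ones((4, 4, 1)), density=np.ones((4, 4, 1))
        )
    with pytest.raises(ValueError):
        pr.MediumGrid(
            spacing=1.0, speed=np.ones((4, 4, 1)), density=np.ones((5, 4, 1))
        )
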