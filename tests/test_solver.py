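"""Wave-solver validation: oracles, invariances, boundaries, stability."""

import numpy as np
import pytest

import protorange as pr
from protorange.solver import SolverConfig, check_stability, convergence_probe, propagate
from protorange.sources import SourceTerm, gaussian_pulse


def _uniform(n, c=1498.0, rho=997.0, spacing=1.0, three_d=False):
    shape = (n, n, n) if three_d else (n, n, 1)
    return pr.MediumGrid(
        spacing=spacing, speed=np.full(shape, c), density=np.full(shape, rho)
    )


def _point_source(pos, amp=12e-3, dt=1e-7, width=10e-6):
    return SourceTerm(
        positions=np.array([pos]),
        amplitudes=np.array([amp]),
        pulse=gaussian_pulse(width, dt),
        dt=dt,
        pulse_width=width,
    )


def _peak_time(trace):
    return trace.t0 + int(np.argmax(trace.samples)) * trace.dt


class TestArrivalOracle:
    def test_water_peak_within_retarded_time_window(self):
        # 60 mm separation in water: the global peak must arrive between the
        # geometric time d/c and d/c + pulse width
        g = _uniform(100)
        src = _point_source((20, 50, 0))
        cfg = SolverConfig(dt=1e-7, n_steps=700)
        (tr,) = propagate(g, src, [(80, 50, 0)], cfg)
        t = _peak_time(tr)
        d_over_c = 60e-3 / 1498.0
        assert d_over_c <= t <= d_over_c + 10e-6

    def test_zero_amplitude_source_silent(self):
        g = _uniform(40)
        src = _point_source((10, 20, 0), amp=0.0)
        cfg = SolverConfig(dt=1e-7, n_steps=100)
        (tr,) = propagate(g, src, [(30, 20, 0)], cfg)
        assert np.all(tr.samples == 0)

    def test_3d_spherical_spreading(self):
        # amplitude at doubled distance is about halved (1/r law)
        g = _uniform(64, spacing=2.0, three_d=True)
        src = _point_source((8, 32, 32), dt=2e-7)
        cfg = SolverConfig(dt=2e-7, n_steps=320)
        tr1, tr2 = propagate(g, src, [(28, 32, 32), (48, 32, 32)], cfg)
        ratio = tr2.samples.max() / tr1.samples.max()
        assert ratio == pytest.approx(0.5, rel=0.10)

    def test_peak_not_before_layered_first_arrival(self):
        # fast layer then slow layer: peak must respect sum(d_i / c_i)
        shape = (100, 60, 1)
        speed = np.full(shape, 2153.9)
        speed[50:] = 652.8
        dens = np.full(shape, 1574.4)
        dens[50:] = 234.0
        g = pr.MediumGrid(spacing=1.0, speed=speed, density=dens)
        src = _point_source((10, 30, 0), dt=1e-7)
        cfg = SolverConfig(dt=1e-7, n_steps=1200)
        (tr,) = propagate(g, src, [(90, 30, 0)], cfg)
        t_first = 40e-3 / 2153.9 + 40e-3 / 652.8
        assert _peak_time(tr) >= t_first


class TestInvariances:
    def test_linearity_in_amplitude(self):
        g = _uniform(60)
        cfg = SolverConfig(dt=1e-7, n_steps=400, precision="double")
        (a,) = propagate(g, _point_source((15, 30, 0), amp=1e-3), [(45, 30, 0)], cfg)
        (b,) = propagate(g, _point_source((15, 30, 0), amp=5e-3), [(45, 30, 0)], cfg)
        assert np.allclose(b.samples, 5.0 * a.samples, rtol=1e-9, atol=1e-18)

    def test_reciprocity_homogeneous(self):
        g = _uniform(60)
        cfg = SolverConfig(dt=1e-7, n_steps=400)
        (ab,) = propagate(g, _point_source((15, 25, 0)), [(45, 40, 0)], cfg)
        (ba,) = propagate(g, _point_source((45, 40, 0)), [(15, 25, 0)], cfg)
        scale = np.abs(ab.samples).max()
        assert np.allclose(ab.samples, ba.samples, atol=1e-3 * scale)

    def test_energy_non_increasing_after_source_off(self):
        g = _uniform(80)
        dt = 1e-7
        src = _point_source((40, 40, 0), dt=dt)
        energies = {}

        def watch(n, p, u):
            if n % 20 == 0:
                # acoustic energy of the interior state
                e = float(np.sum(p[20:-20, 20:-20] ** 2))
                energies[n] = e

        cfg = SolverConfig(dt=dt, n_steps=400)
        propagate(g, src, [(60, 40, 0)], cfg, on_step=watch)
        after_off = {n: e for n, e in energies.items() if n * dt > 12e-6}
        keys = sorted(after_off)
        vals = [after_off[k] for k in keys]
        # allow 2% numerical wiggle between snapshots (potential/kinetic exchange)
        assert all(b <= a * 1.02 for a, b in zip(vals, vals[1:]))

    def test_absorption_attenuates_amplitude(self):
        g0 = _uniform(80)
        g1 = pr.MediumGrid(
            spacing=1.0,
            speed=np.full((80, 80, 1), 1498.0),
            density=np.full((80, 80, 1), 997.0),
            alpha0=np.full((80, 80, 1), 1e-9),
        )
        cfg = SolverConfig(dt=1e-7, n_steps=500)
        src = _point_source((15, 40, 0))
        (a,) = propagate(g0, src, [(65, 40, 0)], cfg)
        (b,) = propagate(g1, src, [(65, 40, 0)], cfg)
        assert 0 < b.samples.max() < a.samples.max()


class TestBoundaries:
    def test_pml_reflection_below_one_percent(self):
        # same interior run against an oversized reference domain: any
        # difference after the direct wave is boundary reflection
        dt, n_steps = 1e-7, 700
        src_small = _point_source((30, 30, 0), dt=dt)
        g_small = _uniform(60)
        cfg = SolverConfig(dt=dt, n_steps=n_steps)
        (small,) = propagate(g_small, src_small, [(45, 30, 0)], cfg)
        g_big = _uniform(200)
        src_big = _point_source((100, 100, 0), dt=dt)
        (big,) = propagate(g_big, src_big, [(115, 100, 0)], cfg)
        peak = big.samples.max()
        resid = np.abs(small.samples - big.samples)
        assert resid.max() <= 0.01 * peak


class TestStability:
    def test_cfl_report_water(self):
        g = _uniform(20)
        rep = check_stability(g, SolverConfig(dt=1e-8))
        assert rep.max_cfl == pytest.approx(1498 * 1e-8 / 1e-3, rel=1e-6)
        assert rep.stable

    def test_cfl_violation_raises_with_voxel(self):
        shape = (20, 20, 1)
        speed = np.full(shape, 1498.0)
        speed[5, 7, 0] = 4000.0
        g = pr.MediumGrid(spacing=1.0, speed=speed, density=np.full(shape, 1000.0))
        rep = check_stability(g, SolverConfig(dt=1e-7))
        assert rep.limiting_voxel == (5, 7, 0)
        assert not rep.stable
        with pytest.raises(ValueError, match=r"\(5, 7, 0\)"):
            propagate(g, _point_source((2, 2, 0)), [(10, 10, 0)], SolverConfig(dt=1e-7, n_steps=10))

    def test_source_dt_mismatch_rejected(self):
        g = _uniform(20)
        src = _point_source((5, 5, 0), dt=2e-7)
        with pytest.raises(ValueError, match="solver dt"):
            propagate(g, src, [(10, 10, 0)], SolverConfig(dt=1e-7, n_steps=10))

    def test_detector_outside_grid_rejected(self):
        g = _uniform(20)
        with pytest.raises(ValueError, match="detector"):
            propagate(g, _point_source((5, 5, 0)), [(25, 5, 0)], SolverConfig(dt=1e-7, n_steps=10))


class TestSchemes:
    def test_fdtd_matches_kspace_arrival(self):
        g = _uniform(80)
        src = _point_source((20, 40, 0))
        cfg_k = SolverConfig(dt=1e-7, n_steps=500, scheme="kspace")
        cfg_f = SolverConfig(dt=1e-7, n_steps=500, scheme="fdtd")
        (a,) = propagate(g, src, [(60, 40, 0)], cfg_k)
        (b,) = propagate(g, src, [(60, 40, 0)], cfg_f)
        assert abs(_peak_time(a) - _peak_time(b)) <= 5e-7

    def test_metadata_records_scheme_and_absorption(self):
        g = _uniform(30)
        (_, meta) = propagate(
            g,
            _point_source((5, 15, 0)),
            [(25, 15, 0)],
            SolverConfig(dt=1e-7, n_steps=50),
            return_metadata=True,
        )
        assert meta["scheme"] == "kspace"
        assert meta["absorption"] == "none"


class TestConvergence:
    def test_arrival_converges_under_refinement(self):
        g = _uniform(120, spacing=1.0)
        src = _point_source((20, 60, 0), dt=5e-8)
        cfg = SolverConfig(dt=5e-8, n_steps=1600)
        times = convergence_probe(g, src, (100, 60, 0), cfg, [4.0, 2.0, 1.0])
        d_over_c = 80e-3 / 1498.0
        assert abs(times[2] - times[1]) <= abs(times[1] - times[0]) + 1e-7
        assert d_over_c <= times[2] <= d_over_c + 10e-6

    def test_probe_deterministic(self):
        g = _uniform(60)
        src = _point_source((10, 30, 0), dt=1e-7)
        cfg = SolverConfig(dt=1e-7, n_steps=500)
        a = convergence_probe(g, src, (50, 30, 0), cfg, [2.0, 1.0])
        b = convergence_probe(g, src, (50, 30, 0), cfg, [2.0, 1.0])
        assert a == b

    def test_single_level_rejected(self):
        g = _uniform(20)
        src = _point_source((5, 10, 0))
        with pytest.raises(ValueError):
            convergence_probe(g, src, (15, 10, 0), SolverConfig(dt=1e-7, n_steps=10), [1.0])


def test_trace_io_round_trip(tmp_path):
    g = _uniform(40)
    cfg = SolverConfig(dt=1e-7, n_steps=200)
    traces, meta = propagate(
        g, _point_source((10, 20, 0)), [(30, 20, 0)], cfg, return_metadata=True
    )
    from protorange.solver import load_traces, save_traces

    save_traces(traces, tmp_path / "tr.npz", metadata=meta)
    loaded = load_traces(tmp_path / "tr.npz")
    assert np.allclose(loaded[0].samples, traces[0].samples)
    assert loaded[0].detector_position == traces[0].detector_position
    assert (tmp_path / "tr.json").exists()
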