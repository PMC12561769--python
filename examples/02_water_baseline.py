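"""Water-phantom baseline: simulate a Bragg-peak pulse and pick its arrival.

A 12 mPa thermoacoustic source with a 10 us Gaussian pulse radiates through
uniform 25 degC water to a detector 100 mm away (2-D section for speed).
The global-maximum arrival time obeys the retarded-time bound
d/c = 66.76 us and lags it by a pulse-shape-dependent offset.
"""

import protorange as pr

grid = pr.make_thermal_water_phantom(
    pr.PhantomConfig(kind="thermal_water", shape=(200, 200, 1), spacing=1.0)
)
dt = 1e-7
source = pr.build_study_sources(
    bragg_position=(50, 100, 0),
    beam_axis=(0, 1, 0),
    entrance_length=0.0,
    medium=grid,
    dt=dt,
)
cfg = pr.SolverConfig(dt=dt, n_steps=850)
(trace,) = pr.propagate(grid, source, [(150, 100, 0)], cfg)

t_peak = pr.detect_peak_time(trace)
c_avg, _ = pr.path_average_speed(grid, (50, 100, 0), (150, 100, 0))
d_tof = pr.tof_to_distance(t_peak, c_avg)

print(f"geometric arrival d/c       : {100e-3 / 1498.0 * 1e6:.2f} us")
print(f"detected global-peak arrival: {t_peak * 1e6:.2f} us")
print(f"path-averaged sound speed   : {c_avg:.1f} m/s")
print(f"TOF range estimate          : {d_tof:.2f} mm  (true separation 100 mm)")
print("The overshoot is the finite-pulse arrival offset; it is common to")
print("all media simulated with the same pulse and cancels in differences.")
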