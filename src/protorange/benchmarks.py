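"""Bundled benchmark inputs for worked examples and arithmetic checks.

Two small reference tables accompany the package:

* ``BIMATERIAL_TOF_US`` — measured time-of-flight readings [us] for the
  twelve ATOM-phantom two-material configurations (three tissue pairs, two
  Bragg-peak placements, uniform and non-uniform variants).  Combined with
  the Table-of-tissues mean speeds these serve as inputs to the
  ``D_TOF = T_peak * c_avg`` arithmetic.
* ``CLINICAL_RANGES`` — known (D_real) and TOF-estimated (D_TOF) ranges
  [mm] for five clinical treatment sites with five candidate detector
  positions each, used as inputs to the error arithmetic
  ``dD = |D_real - D_TOF|`` and ``eps_D = dD / D_real * 100``.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["BIMATERIAL_TOF_US", "bimaterial_tof_frame", "CLINICAL_RANGES", "clinical_range_frame"]

#: (bragg tissue, detector tissue, variant) -> measured TOF [us]
BIMATERIAL_TOF_US: dict[tuple[str, str, str], float] = {
    ("bone", "lung", "uniform"): 101.05,
    ("bone", "lung", "nonuniform"): 103.63,
    ("lung", "bone", "uniform"): 102.14,
    ("lung", "bone", "nonuniform"): 104.79,
    ("bone", "soft_tissue", "uniform"): 56.07,
    ("bone", "soft_tissue", "nonuniform"): 56.15,
    ("soft_tissue", "bone", "uniform"): 56.25,
    ("soft_tissue", "bone", "nonuniform"): 56.34,
    ("lung", "soft_tissue", "uniform"): 111.65,
    ("lung", "soft_tissue", "nonuniform"): 114.31,
    ("soft_tissue", "lung", "uniform"): 110.74,
    ("soft_tissue", "lung", "nonuniform"): 113.33,
}

#: site -> detector position -> (D_real [mm], D_TOF [mm])
CLINICAL_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "brain": {
        "a": (94.7, 93.97),
        "b": (111.14, 112.97),
        "c": (141.03, 249.15),
        "d": (116.5, 171.678),
        "e": (74.65, 91.19),
    },
    "head_neck": {
        "a": (104.66, 189.52),
        "b": (99.02, 112.76),
        "c": (93.01, 130.86),
        "d": (100.22, 115.15),
        "e": (72.8, 103.34),
    },
    "liver": {
        "a": (130.6, 143.14),
        "b": (134.62, 107.94),
        "c": (215.18, 296.83),
        "d": (265.19, 282.79),
        "e": (282.18, 331.46),
    },
    "prostate": {
        "a": (163.03, 202.09),
        "b": (121.02, 117.63),
        "c": (127.26, 90.35),
        "d": (132.97, 121.63),
        "e": (130.38, 172.1),
    },
    "lung": {
        "a": (130.0, 95.71),
        "b": (143.69, 175.28),
        "c": (241.05, 322.37),
        "d": (252.56, 444.95),
        "e": (182.22, 245.62),
    },
}


def bimaterial_tof_frame() -> pd.DataFrame:
    """The bimaterial TOF readings as a tidy DataFrame."""
    rows = [
        {"bragg": b, "detector": d, "variant": v, "tof_us": t}
        for (b, d, v), t in BIMATERIAL_TOF_US.items()
    ]
    return pd.DataFrame(rows)


def clinical_range_frame() -> pd.DataFrame:
    """The clinical D_real / D_TOF pairs as a tidy DataFrame."""
    rows = [
        {"site": site, "position": pos, "d_real": dr, "d_tof": dt}
        for site, posmap in CLINICAL_RANGES.items()
        for pos, (dr, dt) in posmap.items()
    ]
    return pd.DataFrame(rows)
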