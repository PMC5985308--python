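"""Published reference values used as regression fixtures.

Transcribed from the open-access article on WISC short forms for gifted
screening: printed equating formulas, index panels, group descriptives
and headline comparison statistics.  These are *outputs* of the original
study — no proprietary manual tables — and serve as cross-checks, never
as inputs to the computational path.

Panel tuples are ordered
(r_cc, omega_h, fsiq_r_prime, fsiq_icc, fsiq_c_acc,
 gai_r_prime, gai_icc, gai_c_acc, r_c).
"""

from __future__ import annotations

PANEL_FIELDS = (
    "r_cc", "omega_h",
    "fsiq_r_prime", "fsiq_icc", "fsiq_c_acc",
    "gai_r_prime", "gai_icc", "gai_c_acc",
    "r_c",
)

# ---- printed equating formulas: form -> (slope, intercept) ----------

WISC4_FORMULAS: dict[str, tuple[float, float]] = {
    "SiMr": (3.01, 39.81), "SiPc": (3.05, 38.92), "SiBd": (3.02, 39.59),
    "VoMr": (3.00, 40.02), "VoPc": (3.04, 39.14), "VoBd": (3.08, 38.45),
    "CoMr": (3.13, 37.50), "CoPc": (3.11, 37.74), "CoBd": (3.21, 35.72),
    "SiVoMrPc": (1.67, 33.33), "SiVoMrBd": (1.66, 33.55),
    "SiVoPcBd": (1.70, 31.88), "SiCoMrPc": (1.73, 30.99),
    "SiCoMrBd": (1.73, 30.83), "SiCoPcBd": (1.77, 29.38),
    "VoCoMrPc": (1.72, 31.32), "VoCoMrBd": (1.73, 30.66),
    "VoCoPcBd": (1.77, 29.20),
}

WISC5_FORMULAS: dict[str, tuple[float, float]] = {
    "SiMr": (2.91, 41.88), "SiBd": (2.95, 41.07), "SiFw": (2.93, 41.48),
    "VoMr": (2.99, 40.24), "VoBd": (3.03, 39.37), "VoFw": (2.97, 40.66),
    "CoMr": (2.99, 40.24), "CoBd": (3.10, 37.98), "CoFw": (3.05, 38.92),
    "SiVoMrBd": (1.61, 35.52), "SiVoFwBd": (1.63, 34.97),
    "SiVoMrFw": (1.60, 35.98), "SiCoFwBd": (1.67, 33.18),
    "SiCoMrBd": (1.64, 34.35), "SiCoMrFw": (1.63, 34.70),
    "VoCoFwBd": (1.68, 32.66), "VoCoMrBd": (1.66, 33.55),
    "VoCoMrFw": (1.64, 34.20),
}

# ---- printed index panels (simulated-population evaluation) ---------

WISC4_PANELS: dict[str, tuple[float, ...]] = {
    "SiMr": (0.877, 0.550, 0.786, 0.820, 0.797, 0.833, 0.882, 0.909, 0.807),
    "VoMr": (0.871, 0.561, 0.783, 0.818, 0.804, 0.826, 0.877, 0.907, 0.806),
    "VoBd": (0.845, 0.484, 0.771, 0.813, 0.828, 0.801, 0.862, 0.907, 0.789),
    "SiBd": (0.858, 0.540, 0.759, 0.797, 0.791, 0.791, 0.848, 0.872, 0.782),
    "SiPc": (0.825, 0.507, 0.741, 0.788, 0.813, 0.795, 0.864, 0.919, 0.781),
    "VoPc": (0.819, 0.518, 0.737, 0.786, 0.818, 0.788, 0.860, 0.918, 0.781),
    "CoMr": (0.836, 0.437, 0.741, 0.784, 0.795, 0.790, 0.853, 0.897, 0.767),
    "CoBd": (0.806, 0.347, 0.729, 0.779, 0.820, 0.765, 0.837, 0.898, 0.748),
    "CoPc": (0.787, 0.449, 0.680, 0.736, 0.786, 0.737, 0.819, 0.882, 0.734),
    "SiVoMrBd": (0.917, 0.733, 0.851, 0.891, 0.856, 0.892, 0.952, 0.987, 0.885),
    "SiVoPcBd": (0.898, 0.723, 0.840, 0.889, 0.874, 0.887, 0.959, 0.996, 0.883),
    "SiVoMrPc": (0.908, 0.733, 0.839, 0.884, 0.851, 0.893, 0.959, 0.994, 0.883),
    "VoCoMrBd": (0.900, 0.684, 0.845, 0.893, 0.879, 0.889, 0.958, 0.995, 0.881),
    "SiCoMrBd": (0.903, 0.692, 0.844, 0.890, 0.871, 0.890, 0.957, 0.994, 0.880),
    "VoCoPcBd": (0.880, 0.672, 0.830, 0.886, 0.888, 0.879, 0.961, 0.998, 0.874),
    "SiCoMrPc": (0.894, 0.694, 0.827, 0.878, 0.855, 0.885, 0.959, 0.996, 0.874),
    "SiCoPcBd": (0.883, 0.677, 0.829, 0.883, 0.881, 0.880, 0.959, 0.997, 0.873),
    "VoCoMrPc": (0.893, 0.700, 0.823, 0.874, 0.852, 0.879, 0.954, 0.993, 0.871),
}

WISC5_PANELS: dict[str, tuple[float, ...]] = {
    "SiMr": (0.885, 0.648, 0.833, 0.874, 0.866, 0.855, 0.907, 0.922, 0.849),
    "SiBd": (0.875, 0.611, 0.826, 0.870, 0.870, 0.840, 0.896, 0.913, 0.838),
    "SiFw": (0.911, 0.630, 0.829, 0.861, 0.804, 0.861, 0.901, 0.880, 0.835),
    "VoMr": (0.882, 0.571, 0.826, 0.866, 0.856, 0.849, 0.901, 0.914, 0.833),
    "VoBd": (0.871, 0.529, 0.819, 0.863, 0.863, 0.834, 0.890, 0.904, 0.822),
    "VoFw": (0.912, 0.591, 0.810, 0.841, 0.766, 0.843, 0.882, 0.836, 0.810),
    "CoMr": (0.868, 0.571, 0.741, 0.786, 0.744, 0.735, 0.793, 0.753, 0.749),
    "CoBd": (0.850, 0.461, 0.750, 0.799, 0.785, 0.734, 0.798, 0.784, 0.745),
    "CoFw": (0.892, 0.507, 0.747, 0.784, 0.707, 0.751, 0.798, 0.724, 0.739),
    "SiVoMrBd": (0.928, 0.773, 0.898, 0.943, 0.948, 0.917, 0.976, 0.998, 0.923),
    "SiVoFwBd": (0.936, 0.767, 0.900, 0.941, 0.934, 0.925, 0.978, 0.999, 0.922),
    "SiVoMrFw": (0.940, 0.782, 0.896, 0.935, 0.911, 0.925, 0.975, 0.997, 0.920),
    "SiCoFwBd": (0.927, 0.741, 0.877, 0.922, 0.906, 0.887, 0.944, 0.959, 0.895),
    "SiCoMrBd": (0.921, 0.762, 0.867, 0.917, 0.902, 0.871, 0.935, 0.944, 0.890),
    "SiCoMrFw": (0.933, 0.767, 0.867, 0.909, 0.869, 0.881, 0.936, 0.934, 0.887),
    "VoCoFwBd": (0.927, 0.723, 0.867, 0.911, 0.884, 0.877, 0.934, 0.937, 0.883),
    "VoCoMrBd": (0.921, 0.740, 0.860, 0.910, 0.890, 0.865, 0.929, 0.930, 0.881),
    "VoCoMrFw": (0.933, 0.753, 0.857, 0.899, 0.846, 0.871, 0.926, 0.910, 0.874),
}

# ---- group descriptives: variable -> per-group (mean, sd) + d_s -----

N_GIFTED = 117
N_TYPICAL = 52
MALE_PROP = {"gifted": 0.735, "typical": 0.7885}

GROUP_DESCRIPTIVES: dict[str, dict] = {
    "age_months": {"gifted": (124.65, 12.34), "typical": (126.87, 31.88),
                   "d_s": -0.109},
    "Bd": {"gifted": (13.46, 2.62), "typical": (9.85, 2.67), "d_s": 1.372},
    "Si": {"gifted": (17.17, 1.99), "typical": (12.48, 2.32), "d_s": 2.239},
    "Ds": {"gifted": (12.97, 2.94), "typical": (10.08, 2.68), "d_s": 1.013},
    "Pc": {"gifted": (14.30, 2.21), "typical": (9.44, 2.34), "d_s": 2.159},
    "Vo": {"gifted": (16.44, 2.02), "typical": (12.25, 2.22), "d_s": 2.014},
    "Ln": {"gifted": (13.13, 2.28), "typical": (10.15, 2.73), "d_s": 1.228},
    "Mr": {"gifted": (13.72, 2.38), "typical": (10.75, 1.79), "d_s": 1.338},
    "Co": {"gifted": (15.63, 2.44), "typical": (11.58, 2.84), "d_s": 1.579},
    "Cd": {"gifted": (11.26, 2.96), "typical": (9.06, 3.08), "d_s": 0.734},
    "Sy": {"gifted": (11.72, 3.00), "typical": (9.69, 3.46), "d_s": 0.643},
    "FSIQ": {"gifted": (134.92, 9.43), "typical": (104.37, 8.35), "d_s": 3.353},
    "GAI": {"gifted": (137.09, 7.66), "typical": (107.58, 5.84), "d_s": 4.127},
}

# ---- screening performance of the selected forms (empirical) --------

SCREENING_REFERENCE: dict[str, dict] = {
    "SiMr": {"auc": 0.970, "sensitivity": 0.744, "specificity": 0.981,
             "fpr": 0.019, "fnr": 0.256},
    "VoMr": {"auc": 0.962, "sensitivity": 0.718, "specificity": 0.981,
             "fpr": 0.019, "fnr": 0.282},
    "VoBd": {"auc": 0.958, "sensitivity": 0.675, "specificity": 0.962,
             "fpr": 0.038, "fnr": 0.325},
    "SiVoPcBd": {"auc": 0.999, "sensitivity": 0.957, "specificity": 1.000,
                 "fpr": 0.000, "fnr": 0.043},
    "SiVoMrPc": {"auc": 0.996, "sensitivity": 0.906, "specificity": 1.000,
                 "fpr": 0.000, "fnr": 0.094},
    "SiVoMrBd": {"auc": 0.994, "sensitivity": 0.880, "specificity": 1.000,
                 "fpr": 0.000, "fnr": 0.120},
}

# ---- pooled 2- vs 4-subtest correlation comparison ------------------

POOLED_CORRELATION_COMPARISON = {
    "FSIQ": {"r_2sub": 0.791, "r_4sub": 0.885, "n": 9_000_000,
             "ci": (-0.094, -0.094)},
    "GAI": {"r_2sub": 0.856, "r_4sub": 0.957, "n": 9_000_000,
            "ci": (-0.102, -0.102)},
}

HEADLINE_R_C = {
    ("WISC-IV", "SiMr"): 0.807,
    ("WISC-IV", "SiVoMrBd"): 0.885,
    ("WISC-V", "SiMr"): 0.849,
    ("WISC-V", "SiVoMrBd"): 0.923,
}
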