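"""Frozen effect-size calibration tables (2 dp) used by the unit and
acceptance tests.

TABLE_PVE: rows (pve, pattern, effects) for noise variance 1 — the PVE
parameterization.  TABLE_VARIANCE: rows (variance, pattern, effects) for
the additive-variance parameterization.
"""

TABLE_PVE = [
    (0.00, "4:4", (0.00,) * 8),
    (0.00, "1:7", (0.00,) * 8),
    (0.00, "3:2:3", (0.00,) * 8),
    (0.00, "2:4:2", (0.00,) * 8),
    (0.00, "2:2:2:2", (0.00,) * 8),
    (0.00, "1:1:1:1:1:1:1:1", (0.00,) * 8),
    (0.02, "4:4", (0.28, 0.28, 0.28, 0.28, 0, 0, 0, 0)),
    (0.02, "1:7", (0.43, 0, 0, 0, 0, 0, 0, 0)),
    (0.02, "3:2:3", (0.33, 0.33, 0.33, 0.16, 0.16, 0, 0, 0)),
    (0.02, "2:4:2", (0.40, 0.40, 0.20, 0.20, 0.20, 0.20, 0, 0)),
    (0.02, "2:2:2:2", (0.38, 0.38, 0.26, 0.26, 0.13, 0.13, 0, 0)),
    (0.02, "1:1:1:1:1:1:1:1", (0.43, 0.37, 0.31, 0.25, 0.19, 0.12, 0.06, 0)),
    (0.04, "4:4", (0.41, 0.41, 0.41, 0.41, 0, 0, 0, 0)),
    (0.04, "1:7", (0.62, 0, 0, 0, 0, 0, 0, 0)),
    (0.04, "3:2:3", (0.47, 0.47, 0.47, 0.24, 0.24, 0, 0, 0)),
    (0.04, "2:4:2", (0.58, 0.58, 0.29, 0.29, 0.29, 0.29, 0, 0)),
    (0.04, "2:2:2:2", (0.55, 0.55, 0.36, 0.36, 0.18, 0.18, 0, 0)),
    (0.04, "1:1:1:1:1:1:1:1", (0.62, 0.53, 0.45, 0.36, 0.27, 0.18, 0.09, 0)),
    (0.06, "4:4", (0.50, 0.50, 0.50, 0.50, 0, 0, 0, 0)),
    (0.06, "1:7", (0.76, 0, 0, 0, 0, 0, 0, 0)),
    (0.06, "3:2:3", (0.58, 0.58, 0.58, 0.29, 0.29, 0, 0, 0)),
    (0.06, "2:4:2", (0.71, 0.71, 0.36, 0.36, 0.36, 0.36, 0, 0)),
    (0.06, "2:2:2:2", (0.68, 0.68, 0.45, 0.45, 0.23, 0.23, 0, 0)),
    (0.06, "1:1:1:1:1:1:1:1", (0.77, 0.66, 0.55, 0.44, 0.33, 0.22, 0.11, 0)),
]

TABLE_VARIANCE = [
    (0.03, "4:4", (0.35, 0.35, 0.35, 0.35, 0, 0, 0, 0)),
    (0.04, "4:4", (0.40, 0.40, 0.40, 0.40, 0, 0, 0, 0)),
    (0.05, "4:4", (0.45, 0.45, 0.45, 0.45, 0, 0, 0, 0)),
    (0.06, "4:4", (0.49, 0.49, 0.49, 0.49, 0, 0, 0, 0)),
    (0.07, "4:4", (0.53, 0.53, 0.53, 0.53, 0, 0, 0, 0)),
    (0.03, "2:6", (0.40, 0.40, 0, 0, 0, 0, 0, 0)),
    (0.04, "2:6", (0.46, 0.46, 0, 0, 0, 0, 0, 0)),
    (0.05, "2:6", (0.52, 0.52, 0, 0, 0, 0, 0, 0)),
    (0.06, "2:6", (0.57, 0.57, 0, 0, 0, 0, 0, 0)),
    (0.07, "2:6", (0.61, 0.61, 0, 0, 0, 0, 0, 0)),
    (0.03, "1:7", (0.52, 0, 0, 0, 0, 0, 0, 0)),
    (0.04, "1:7", (0.60, 0, 0, 0, 0, 0, 0, 0)),
    (0.05, "1:7", (0.68, 0, 0, 0, 0, 0, 0, 0)),
    (0.06, "1:7", (0.74, 0, 0, 0, 0, 0, 0, 0)),
    (0.07, "1:7", (0.80, 0, 0, 0, 0, 0, 0, 0)),
    (0.03, "3:2:3", (0.40, 0.40, 0.40, 0.20, 0.20, 0, 0, 0)),
    (0.04, "3:2:3", (0.46, 0.46, 0.46, 0.23, 0.23, 0, 0, 0)),
    (0.05, "3:2:3", (0.52, 0.52, 0.52, 0.26, 0.26, 0, 0, 0)),
    (0.06, "3:2:3", (0.57, 0.57, 0.57, 0.28, 0.28, 0, 0, 0)),
    (0.07, "3:2:3", (0.61, 0.61, 0.61, 0.31, 0.31, 0, 0, 0)),
    (0.03, "2:4:2", (0.49, 0.49, 0.24, 0.24, 0.24, 0.24, 0, 0)),
    (0.04, "2:4:2", (0.57, 0.57, 0.28, 0.28, 0.28, 0.28, 0, 0)),
    (0.05, "2:4:2", (0.63, 0.63, 0.32, 0.32, 0.32, 0.32, 0, 0)),
    (0.06, "2:4:2", (0.69, 0.69, 0.35, 0.35, 0.35, 0.35, 0, 0)),
    (0.07, "2:4:2", (0.75, 0.75, 0.37, 0.37, 0.37, 0.37, 0, 0)),
    (0.03, "2:2:2:2", (0.46, 0.46, 0.31, 0.31, 0.15, 0.15, 0, 0)),
    (0.04, "2:2:2:2", (0.54, 0.54, 0.36, 0.36, 0.18, 0.18, 0, 0)),
    (0.05, "2:2:2:2", (0.60, 0.60, 0.40, 0.40, 0.20, 0.20, 0, 0)),
    (0.06, "2:2:2:2", (0.66, 0.66, 0.44, 0.44, 0.22, 0.22, 0, 0)),
    (0.07, "2:2:2:2", (0.71, 0.71, 0.47, 0.47, 0.24, 0.24, 0, 0)),
    (0.03, "1:1:1:1:1:1:1:1", (0.53, 0.45, 0.38, 0.30, 0.23, 0.15, 0.08, 0)),
    (0.04, "1:1:1:1:1:1:1:1", (0.61, 0.52, 0.44, 0.35, 0.26, 0.17, 0.09, 0)),
    (0.05, "1:1:1:1:1:1:1:1", (0.68, 0.59, 0.49, 0.39, 0.29, 0.20, 0.10, 0)),
    (0.06, "1:1:1:1:1:1:1:1", (0.75, 0.64, 0.53, 0.43, 0.32, 0.21, 0.11, 0)),
    (0.07, "1:1:1:1:1:1:1:1", (0.81, 0.69, 0.58, 0.46, 0.35, 0.23, 0.12, 0)),
]
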