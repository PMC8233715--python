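"""Reference-study statistics packaged as defaults and cross-check fixtures.

The package emulates a 332-animal freeze-dried beef study (15 European
cattle breeds, longissimus thoracis) in which every fatty acid was
quantified by gas chromatography twice — in the phospholipid fraction and
in the total lipid extract — and NIR calibrations were built per analyte
and fraction.  The raw spectra and chromatography values of that study are
not public, so this module carries what *is* public:

* ``DESCRIPTIVE`` — per analyte/fraction/set (calibration, validation)
  descriptive statistics (mean, min, max, sample SD, CV%), in mg FA per
  100 g meat.  These parameterise the synthetic concentration generator
  and anchor the fraction-share arithmetic.
* ``MODEL_CHAINS`` — the 48 optimal pretreatment chains and factor counts,
  one per analyte and fraction, in the package's chain grammar.
* ``MODEL_PERFORMANCE`` — the reported validation statistics
  (n, SEC, R²c, SEP, R²p, RPD, Consistency) per analyte and fraction, used
  to cross-check the metric identities RPD = SD/SEP and
  Consistency = SEC·100/SEP.

Group membership used by the generator: the SFA sum includes the two
plasmalogen aldehydes; the 20 reported fatty acids cover >90% of the total,
so TotalFA carries an unreported remainder above the three group sums.
"""

from __future__ import annotations

from .spectra_io import ANALYTES, FATTY_ACIDS

SFA_MEMBERS = ("12:0", "14:0", "16:0", "16:0ald", "18:0", "18:0ald")
MUFA_MEMBERS = ("16:1", "18:1t9", "18:1c9", "18:1c11", "20:1")
PUFA_MEMBERS = ("18:2n-6", "18:3n-3", "9c11tCLA", "20:3n-6", "20:4n-6",
                "20:5n-3", "22:4n-6", "22:5n-3", "22:6n-3")

# fraction -> analyte -> set -> (mean, min, max, sd, cv_percent)
DESCRIPTIVE: dict[str, dict[str, dict[str, tuple[float, float, float, float, float]]]] = {
    "phospholipid": {
        "12:0":     {"calibration": (0.06, 0.00, 0.53, 0.08, 133.33),
                     "validation": (0.09, 0.57, 1.32, 0.16, 177.78)},
        "14:0":     {"calibration": (1.64, 0.34, 6.34, 1.13, 68.90),
                     "validation": (1.62, 2.49, 4.96, 1.05, 64.81)},
        "16:0":     {"calibration": (64.42, 34.05, 109.85, 14.34, 22.26),
                     "validation": (65.92, 64.20, 103.23, 14.93, 22.65)},
        "16:0ald":  {"calibration": (23.42, 3.91, 43.46, 6.42, 27.41),
                     "validation": (24.00, 4.65, 40.99, 7.27, 30.29)},
        "16:1":     {"calibration": (7.36, 3.07, 19.35, 2.33, 31.66),
                     "validation": (7.47, 6.17, 13.79, 2.30, 30.79)},
        "18:0":     {"calibration": (52.38, 29.16, 83.93, 8.85, 16.90),
                     "validation": (53.44, 69.77, 73.38, 8.81, 16.49)},
        "18:0ald":  {"calibration": (15.87, 3.47, 26.64, 4.48, 28.23),
                     "validation": (16.64, 3.36, 31.87, 5.47, 32.87)},
        "18:1t9":   {"calibration": (4.39, 0.93, 14.20, 2.75, 62.64),
                     "validation": (4.47, 6.95, 16.85, 2.91, 65.10)},
        "18:1c9":   {"calibration": (76.72, 26.06, 182.51, 24.35, 31.74),
                     "validation": (77.08, 53.77, 137.56, 24.19, 31.38)},
        "18:1c11":  {"calibration": (14.58, 7.87, 25.92, 3.43, 23.53),
                     "validation": (14.79, 11.29, 26.03, 3.69, 24.95)},
        "18:2n-6":  {"calibration": (124.47, 62.45, 210.43, 29.61, 23.79),
                     "validation": (127.88, 67.43, 199.28, 29.67, 23.20)},
        "20:1":     {"calibration": (0.57, 0.00, 1.20, 0.22, 38.60),
                     "validation": (0.59, 0.30, 1.26, 0.23, 38.98)},
        "18:3n-3":  {"calibration": (6.37, 1.51, 22.07, 4.35, 68.29),
                     "validation": (6.57, 3.58, 19.57, 4.55, 69.25)},
        "9c11tCLA": {"calibration": (0.75, 0.18, 2.49, 0.41, 54.67),
                     "validation": (0.77, 0.70, 2.71, 0.45, 58.44)},
        "20:3n-6":  {"calibration": (8.43, 4.94, 15.00, 2.00, 23.72),
                     "validation": (8.44, 3.60, 13.66, 2.22, 26.30)},
        "20:4n-6":  {"calibration": (37.84, 20.29, 69.55, 9.39, 24.82),
                     "validation": (38.63, 16.27, 69.77, 9.69, 25.08)},
        "20:5n-3":  {"calibration": (4.02, 1.00, 12.07, 2.01, 50.00),
                     "validation": (4.20, 1.23, 10.97, 2.27, 54.05)},
        "22:4n-6":  {"calibration": (4.59, 1.34, 10.40, 1.82, 39.65),
                     "validation": (4.67, 1.10, 10.21, 1.94, 41.54)},
        "22:5n-3":  {"calibration": (9.17, 4.26, 21.13, 2.94, 32.06),
                     "validation": (9.35, 3.43, 20.38, 3.30, 35.29)},
        "22:6n-3":  {"calibration": (0.87, 0.00, 4.85, 0.48, 55.17),
                     "validation": (0.85, 0.00, 2.28, 0.40, 47.06)},
        "TotalFA":  {"calibration": (493.81, 270.43, 813.78, 85.49, 17.31),
                     "validation": (504.13, 467.25, 726.78, 89.74, 17.80)},
        "SFA":      {"calibration": (157.80, 89.26, 252.16, 28.679, 18.17),
                     "validation": (161.71, 101.33, 228.035, 31.09, 19.23)},
        "MUFA":     {"calibration": (103.61, 46.35, 228.31, 28.18, 27.20),
                     "validation": (104.40, 47.82, 169.93, 28.26, 27.07)},
        "PUFA":     {"calibration": (196.51, 107.55, 319.65, 39.61, 20.16),
                     "validation": (201.36, 103.90, 297.84, 40.64, 20.18)},
    },
    "total": {
        "12:0":     {"calibration": (2.10, 0.00, 8.86, 1.87, 89.05),
                     "validation": (2.06, 0.06, 8.69, 1.80, 87.38)},
        "14:0":     {"calibration": (73.63, 0.87, 313.13, 58.97, 80.09),
                     "validation": (71.57, 2.49, 256.53, 55.15, 77.06)},
        "16:0":     {"calibration": (651.20, 51.20, 2878.25, 480.58, 73.80),
                     "validation": (639.85, 64.20, 2420.91, 442.30, 69.13)},
        "16:0ald":  {"calibration": (23.42, 3.91, 43.46, 6.42, 27.41),
                     "validation": (24.00, 4.65, 40.99, 7.27, 30.29)},
        "16:1":     {"calibration": (92.50, 5.55, 414.79, 73.77, 79.75),
                     "validation": (89.04, 6.17, 266.67, 64.18, 72.08)},
        "18:0":     {"calibration": (401.08, 50.04, 1741.09, 254.19, 63.38),
                     "validation": (398.22, 69.77, 1497.58, 237.68, 59.69)},
        "18:0ald":  {"calibration": (15.87, 3.47, 26.64, 4.48, 28.23),
                     "validation": (16.64, 3.36, 31.87, 5.47, 32.87)},
        "18:1t9":   {"calibration": (77.48, 3.47, 625.86, 76.14, 98.27),
                     "validation": (75.20, 6.95, 363.93, 68.72, 91.38)},
        "18:1c9":   {"calibration": (854.17, 31.86, 4125.90, 658.56, 77.10),
                     "validation": (831.04, 53.77, 2866.55, 573.11, 68.96)},
        "18:1c11":  {"calibration": (49.02, 11.24, 191.83, 29.18, 59.53),
                     "validation": (47.77, 11.29, 119.64, 25.02, 52.38)},
        "18:2n-6":  {"calibration": (183.30, 83.15, 500.18, 62.86, 34.29),
                     "validation": (183.30, 67.43, 314.36, 54.76, 29.87)},
        "20:1":     {"calibration": (4.03, 0.27, 22.16, 3.28, 81.39),
                     "validation": (3.77, 0.30, 13.58, 2.58, 68.44)},
        "18:3n-3":  {"calibration": (15.16, 2.70, 69.20, 12.27, 80.94),
                     "validation": (14.99, 3.58, 48.81, 11.81, 78.79)},
        "9c11tCLA": {"calibration": (8.14, 0.45, 43.18, 6.39, 78.50),
                     "validation": (7.84, 0.70, 27.41, 5.26, 67.09)},
        "20:3n-6":  {"calibration": (9.14, 5.15, 16.12, 2.48, 27.13),
                     "validation": (9.11, 3.60, 16.29, 2.67, 29.31)},
        "20:4n-6":  {"calibration": (38.56, 20.29, 71.23, 9.60, 24.90),
                     "validation": (39.32, 16.27, 70.47, 10.01, 25.46)},
        "20:5n-3":  {"calibration": (4.18, 1.00, 15.56, 2.18, 52.15),
                     "validation": (4.35, 1.23, 11.41, 2.37, 54.48)},
        "22:4n-6":  {"calibration": (4.91, 1.34, 11.33, 2.15, 43.79),
                     "validation": (4.96, 1.10, 11.70, 2.26, 45.56)},
        "22:5n-3":  {"calibration": (9.61, 4.26, 21.85, 3.11, 32.36),
                     "validation": (9.82, 3.43, 20.65, 3.47, 35.34)},
        "22:6n-3":  {"calibration": (0.91, 0.00, 4.95, 0.61, 67.03),
                     "validation": (0.89, 0.00, 5.56, 0.60, 67.42)},
        "TotalFA":  {"calibration": (2701.26, 452.75, 10922.01, 1780.47, 65.91),
                     "validation": (2652.12, 467.25, 8701.06, 1596.84, 60.21)},
        "SFA":      {"calibration": (1167.30, 133.90, 4981.92, 790.24, 67.70),
                     "validation": (1152.34, 157.41, 4182.02, 734.39, 63.73)},
        "MUFA":     {"calibration": (1077.19, 54.47, 4916.56, 818.18, 75.96),
                     "validation": (1046.83, 78.48, 3570.11, 713.46, 68.15)},
        "PUFA":     {"calibration": (265.76, 139.73, 607.29, 79.13, 29.77),
                     "validation": (266.73, 114.32, 439.52, 72.54, 27.20)},
    },
}

# fraction -> analyte -> (chain_spec, n_factors)
MODEL_CHAINS: dict[str, dict[str, tuple[str, int]]] = {
    "phospholipid": {
        "12:0": ("Offset|EMSC", 6),
        "14:0": ("Offset|EMSC|SG-1-2-5", 5),
        "16:0": ("Offset|Area|SNV+D|SG-1-2-3", 4),
        "16:0ald": ("SG-1-2-3", 3),
        "16:1": ("Offset", 4),
        "18:0": ("Offset|Area|EMSC", 4),
        "18:0ald": ("Offset|Area|SNV+D", 6),
        "18:1t9": ("EMSC", 3),
        "18:1c9": ("SG-1-2-5", 2),
        "18:1c11": ("Offset|Area|SNV+D", 3),
        "18:2n-6": ("None", 8),
        "20:1": ("Offset|Area|SNV", 6),
        "18:3n-3": ("Offset", 10),
        "9c11tCLA": ("Offset|Area|SNV+D", 5),
        "20:3n-6": ("EMSC", 3),
        "20:4n-6": ("Area|SNV", 12),
        "20:5n-3": ("Offset|Area|EMSC+D", 8),
        "22:4n-6": ("SG-1-2-3", 5),
        "22:5n-3": ("Offset|Area", 10),
        "22:6n-3": ("Area", 1),
        "TotalFA": ("Offset|Area|SG-1-2-5", 5),
        "SFA": ("Offset|SNV", 6),
        "MUFA": ("SNV", 5),
        "PUFA": ("Offset|Area|SG-1-2-3", 5),
    },
    "total": {
        "12:0": ("SNV+D|SG-1-2-3", 4),
        "14:0": ("Area|SNV+D|SG-1-2-3", 3),
        "16:0": ("Area|SNV+D|SG-1-2-3", 3),
        "16:0ald": ("None", 2),
        "16:1": ("SG1-1-1", 8),
        "18:0": ("None", 5),
        "18:0ald": ("SNV+D", 8),
        "18:1t9": ("SNV+D", 2),
        "18:1c9": ("NG-1-13", 7),
        "18:1c11": ("Area|SNV+D", 11),
        "18:2n-6": ("SG1-2-2|SG-1-2-3", 5),
        "20:1": ("SG-1-2-3", 4),
        "18:3n-3": ("Offset", 9),
        "9c11tCLA": ("MSC|SG-1-2-3", 4),
        "20:3n-6": ("NG-1-7", 7),
        "20:4n-6": ("SG-1-2-3", 7),
        "20:5n-3": ("NG-1-15", 7),
        "22:4n-6": ("SG-1-2-3", 6),
        "22:5n-3": ("SNV|NG-1-7", 5),
        "22:6n-3": ("None", 1),
        "TotalFA": ("Offset", 9),
        "SFA": ("None", 9),
        "MUFA": ("NG-1-27", 7),
        "PUFA": ("NG-1-11", 6),
    },
}

# fraction -> analyte -> (n, SEC, R2c, SEP, R2p, RPD, Consistency)
MODEL_PERFORMANCE: dict[str, dict[str, tuple[int, float, float, float, float, float, float]]] = {
    "phospholipid": {
        "12:0": (206, 0.04, 0.48, 0.15, 0.07, 1.06, 26.67),
        "14:0": (215, 0.46, 0.77, 0.73, 0.52, 1.44, 63.01),
        "16:0": (210, 7.52, 0.67, 10.45, 0.48, 1.43, 71.96),
        "16:0ald": (210, 5.31, 0.24, 6.70, 0.13, 1.08, 79.25),
        "16:1": (205, 1.35, 0.44, 1.85, 0.32, 1.24, 72.97),
        "18:0": (211, 5.72, 0.50, 6.92, 0.36, 1.27, 82.66),
        "18:0ald": (210, 3.10, 0.40, 5.17, 0.10, 1.06, 59.96),
        "18:1t9": (200, 1.56, 0.19, 2.89, 0.03, 1.01, 53.98),
        "18:1c9": (205, 14.91, 0.50, 18.81, 0.37, 1.29, 79.27),
        "18:1c11": (212, 2.66, 0.20, 3.51, 0.09, 1.05, 75.78),
        "18:2n-6": (200, 18.81, 0.42, 33.94, 0.04, 0.87, 55.42),
        "20:1": (215, 0.15, 0.49, 0.20, 0.27, 1.16, 75.00),
        "18:3n-3": (207, 2.26, 0.69, 3.11, 0.53, 1.46, 72.67),
        "9c11tCLA": (200, 0.25, 0.36, 0.43, 0.06, 1.04, 58.14),
        "20:3n-6": (201, 1.56, 0.26, 2.08, 0.11, 1.07, 75.00),
        "20:4n-6": (201, 5.88, 0.55, 7.59, 0.29, 1.28, 77.47),
        "20:5n-3": (202, 1.34, 0.56, 1.74, 0.41, 1.30, 77.01),
        "22:4n-6": (207, 1.10, 0.59, 1.58, 0.29, 1.23, 69.62),
        "22:5n-3": (200, 1.73, 0.58, 2.47, 0.41, 1.33, 70.04),
        "22:6n-3": (198, 0.28, 0.12, 0.38, 0.05, 1.07, 73.68),
        "TotalFA": (199, 39.14, 0.67, 63.88, 0.44, 1.40, 61.27),
        "SFA": (202, 14.80, 0.65, 20.68, 0.57, 1.50, 71.57),
        "MUFA": (210, 17.46, 0.53, 18.85, 0.50, 1.50, 92.63),
        "PUFA": (198, 19.77, 0.65, 31.84, 0.14, 1.24, 62.09),
    },
    "total": {
        "12:0": (222, 1.02, 0.70, 0.97, 0.72, 1.9, 105.15),
        "14:0": (219, 26.05, 0.77, 27.97, 0.74, 2.0, 93.14),
        "16:0": (222, 233.56, 0.71, 234.99, 0.72, 1.9, 99.39),
        "16:0ald": (222, 5.98, 0.13, 6.66, 0.16, 1.0, 89.79),
        "16:1": (218, 32.17, 0.76, 30.31, 0.78, 2.1, 106.14),
        "18:0": (222, 158.17, 0.61, 129.39, 0.70, 1.8, 122.24),
        "18:0ald": (222, 3.79, 0.53, 4.85, 0.21, 1.1, 78.14),
        "18:1t9": (219, 41.01, 0.47, 50.16, 0.47, 1.4, 81.76),
        "18:1c9": (217, 244.72, 0.80, 274.92, 0.77, 2.1, 88.59),
        "18:1c11": (218, 12.14, 0.77, 12.69, 0.74, 2.0, 95.67),
        "18:2n-6": (222, 41.63, 0.56, 41.32, 0.43, 1.3, 100.75),
        "20:1": (220, 1.40, 0.80, 1.10, 0.71, 1.8, 127.27),
        "18:3n-3": (222, 7.73, 0.60, 7.07, 0.65, 1.7, 109.34),
        "9c11tCLA": (222, 4.00, 0.61, 3.25, 0.62, 1.6, 123.08),
        "20:3n-6": (217, 1.45, 0.64, 2.09, 0.39, 1.3, 69.38),
        "20:4n-6": (222, 4.89, 0.74, 8.60, 0.26, 1.2, 56.86),
        "20:5n-3": (210, 1.71, 0.39, 1.90, 0.38, 1.3, 90.00),
        "22:4n-6": (217, 1.00, 0.78, 1.74, 0.39, 1.3, 57.47),
        "22:5n-3": (211, 2.47, 0.37, 2.79, 0.36, 1.2, 88.53),
        "22:6n-3": (222, 0.61, 0.01, 0.60, 0.01, 1.0, 101.67),
        "TotalFA": (222, 908.22, 0.74, 730.79, 0.79, 2.2, 124.28),
        "SFA": (222, 412.56, 0.73, 355.68, 0.77, 2.1, 115.99),
        "MUFA": (222, 393.64, 0.77, 340.36, 0.77, 2.1, 115.65),
        "PUFA": (222, 53.35, 0.54, 53.81, 0.45, 1.3, 99.15),
    },
}


def calibration_mean(fraction: str, analyte: str) -> float:
    return DESCRIPTIVE[fraction][analyte]["calibration"][0]


def calibration_cv(fraction: str, analyte: str) -> float:
    return DESCRIPTIVE[fraction][analyte]["calibration"][4]


def validation_sd(fraction: str, analyte: str) -> float:
    return DESCRIPTIVE[fraction][analyte]["validation"][3]


assert set(DESCRIPTIVE["total"]) == set(ANALYTES)
assert set(DESCRIPTIVE["phospholipid"]) == set(ANALYTES)
assert set(MODEL_CHAINS["total"]) == set(ANALYTES)
assert set(MODEL_PERFORMANCE["total"]) == set(ANALYTES)
assert set(SFA_MEMBERS) | set(MUFA_MEMBERS) | set(PUFA_MEMBERS) == set(FATTY_ACIDS)
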