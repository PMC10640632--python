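"""Published reference values for the NZ/PN eye-drop chemometric assay.

These are the reported validation benchmarks of the five-component system
(naphazoline HCl, pheniramine maleate and three official impurities):
per-mixture validation recoveries, regression/figure-of-merit parameters,
standard-addition recoveries on the dosage form, and the summary statistics
used for comparison against the official chromatographic method. They serve
as arithmetic cross-checks for the merit layer and as fixed inputs to the
reproduction script — not as fit targets.

Note: feeding the per-mixture recoveries back through the summary
arithmetic reproduces every reported "Mean +/- SD" cell at 1 d.p. except
the NZ-impurity-B/PLS SD (recomputed 1.7 vs reported 1.9), which appears to
be a typographical slip in the source table.
"""

from __future__ import annotations

COMPONENTS = ("NZ", "PN", "NZ_impB", "PN_impA", "PN_impB")
MODELS = ("PLS", "ANN")

#: Actual validation-set concentrations (ug/mL), 10 mixtures per component.
VALIDATION_ACTUAL: dict[str, tuple[float, ...]] = {
    "NZ": (11.0, 13.0, 5.0, 5.0, 9.0, 11.0, 5.0, 11.0, 7.0, 7.0),
    "PN": (60.0, 10.0, 10.0, 35.0, 47.5, 10.0, 47.5, 22.5, 22.5, 35.0),
    "NZ_impB": (1.0, 1.0, 3.0, 4.0, 1.0, 4.0, 2.0, 2.0, 3.0, 1.0),
    "PN_impA": (2.0, 8.0, 11.0, 2.0, 11.0, 5.0, 5.0, 8.0, 2.0, 5.0),
    "PN_impB": (8.0, 11.0, 2.0, 11.0, 5.0, 5.0, 8.0, 2.0, 5.0, 2.0),
}

#: Reported per-mixture validation recoveries (%), keyed (component, model).
VALIDATION_RECOVERIES: dict[tuple[str, str], tuple[float, ...]] = {
    ("NZ", "PLS"): (102.6, 100.3, 99.0, 96.5, 101.2, 97.8, 98.3, 100.5, 100.6, 98.4),
    ("NZ", "ANN"): (97.4, 102.9, 100.8, 102.9, 99.3, 97.4, 100.2, 101.7, 97.9, 101.5),
    ("PN", "PLS"): (98.6, 99.5, 99.1, 97.0, 100.9, 100.7, 99.7, 98.5, 103.9, 100.0),
    ("PN", "ANN"): (98.0, 98.0, 97.4, 102.2, 102.1, 101.1, 101.2, 98.9, 99.9, 101.4),
    ("NZ_impB", "PLS"): (102.4, 100.8, 101.4, 98.5, 99.0, 97.5, 102.4, 101.4, 97.3, 99.6),
    ("NZ_impB", "ANN"): (98.6, 99.3, 98.7, 101.0, 100.9, 97.8, 99.9, 100.4, 102.5, 100.6),
    ("PN_impA", "PLS"): (101.5, 102.2, 102.6, 101.5, 103.0, 102.0, 98.6, 97.2, 101.6, 99.9),
    ("PN_impA", "ANN"): (97.8, 102.1, 100.2, 100.3, 98.6, 98.3, 98.7, 102.3, 100.9, 103.2),
    ("PN_impB", "PLS"): (96.8, 98.7, 102.4, 101.4, 97.6, 99.2, 97.9, 101.5, 99.5, 98.3),
    ("PN_impB", "ANN"): (98.4, 99.9, 100.0, 100.5, 100.3, 96.3, 101.2, 96.3, 97.3, 97.1),
}

#: Reported "Mean +/- SD" summary cells (%), keyed (component, model).
VALIDATION_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("NZ", "PLS"): (99.5, 1.8),
    ("NZ", "ANN"): (100.2, 2.1),
    ("PN", "PLS"): (99.8, 1.8),
    ("PN", "ANN"): (100.0, 1.8),
    ("NZ_impB", "PLS"): (100.0, 1.9),
    ("NZ_impB", "ANN"): (100.0, 1.4),
    ("PN_impA", "PLS"): (101.0, 1.9),
    ("PN_impA", "ANN"): (100.2, 1.9),
    ("PN_impB", "PLS"): (99.3, 1.9),
    ("PN_impB", "ANN"): (98.7, 1.9),
}

#: Reported validation-set regression parameters and figures of merit,
#: keyed (component, model): slope, intercept, r, lod, loq (ug/mL),
#: sep, rmsep (ug/mL).
REGRESSION_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("NZ", "PLS"): dict(slope=1.0209, intercept=-0.1881, r=0.9989,
                        lod=0.447, loq=1.354, sep=0.161549, rmsep=0.144494),
    ("NZ", "ANN"): dict(slope=1.0046, intercept=-0.0224, r=0.9987,
                        lod=0.494, loq=1.497, sep=0.160227, rmsep=0.143312),
    ("PN", "PLS"): dict(slope=0.9901, intercept=0.1796, r=0.9996,
                        lod=1.750, loq=5.303, sep=0.602116, rmsep=0.538549),
    ("PN", "ANN"): dict(slope=1.0025, intercept=0.0281, r=0.9994,
                        lod=2.093, loq=6.344, sep=0.686162, rmsep=0.613722),
    ("NZ_impB", "PLS"): dict(slope=0.9739, intercept=0.0468, r=0.9994,
                             lod=0.138, loq=0.419, sep=0.056296, rmsep=0.050353),
    ("NZ_impB", "ANN"): dict(slope=0.9959, intercept=0.0074, r=0.9994,
                             lod=0.144, loq=0.435, sep=0.046329, rmsep=0.041438),
    ("PN_impA", "PLS"): dict(slope=1.0245, intercept=-0.0763, r=0.9992,
                             lod=0.454, loq=1.375, sep=0.190702, rmsep=0.170569),
    ("PN_impA", "ANN"): dict(slope=1.0010, intercept=0.0144, r=0.9994,
                             lod=0.384, loq=1.163, sep=0.125570, rmsep=0.112314),
    ("PN_impB", "PLS"): dict(slope=0.9925, intercept=-0.0112, r=0.9994,
                             lod=0.389, loq=1.180, sep=0.141630, rmsep=0.126678),
    ("PN_impB", "ANN"): dict(slope=1.0084, intercept=-0.0925, r=0.9997,
                             lod=0.277, loq=0.839, sep=0.106399, rmsep=0.095166),
}

#: Standard-addition recoveries (% of added) on the dosage form, keyed
#: (drug, model): added levels (ug/mL), per-level recoveries, reported
#: mean and SD.
STANDARD_ADDITION: dict[tuple[str, str], dict] = {
    ("NZ", "PLS"): dict(taken=4.0, added=(2.0, 4.0, 8.0),
                        recoveries=(102.0, 100.1, 99.6), mean=100.6, sd=1.3),
    ("PN", "PLS"): dict(taken=10.0, added=(5.0, 10.0, 20.0),
                        recoveries=(100.3, 100.4, 101.1), mean=100.6, sd=0.4),
    ("NZ", "ANN"): dict(taken=4.0, added=(2.0, 4.0, 8.0),
                        recoveries=(100.3, 99.9, 99.0), mean=99.7, sd=0.7),
    ("PN", "ANN"): dict(taken=10.0, added=(5.0, 10.0, 20.0),
                        recoveries=(100.2, 99.3, 100.0), mean=99.8, sd=0.5),
}

#: Summary statistics used in the reference-method comparison, keyed by
#: (drug, method): mean recovery (%), SD, n. The reference is the official
#: pharmacopoeial HPLC assay.
METHOD_SUMMARIES: dict[tuple[str, str], dict[str, float]] = {
    ("NZ", "PLS"): dict(mean=99.5, sd=1.82, n=10),
    ("PN", "PLS"): dict(mean=99.8, sd=1.84, n=10),
    ("NZ", "ANN"): dict(mean=100.2, sd=2.12, n=10),
    ("PN", "ANN"): dict(mean=100.0, sd=1.83, n=10),
    ("NZ", "reference"): dict(mean=99.6, sd=0.98, n=5),
    ("PN", "reference"): dict(mean=99.7, sd=1.15, n=5),
}

#: Reported t statistics (two-sided, df 13) per (drug, model); the reported
#: critical value is 2.16.
REPORTED_T: dict[tuple[str, str], float] = {
    ("NZ", "PLS"): 0.11,
    ("PN", "PLS"): 0.08,
    ("NZ", "ANN"): 0.56,
    ("PN", "ANN"): 0.35,
}
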