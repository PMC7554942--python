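"""Reference p-values from the original clinical two-stage screen.

These are the printed results of the study that introduced the
periportal parameter family: 28 parameters were significantly different
(SGH cohort) between F1 cases that were re-staged to F2/3 at a consensus
read and cases whose stage did not change, and 26 of those 28 remained
significant when re-tested on true-F1 vs true-F2 cases.  The tables are
shipped so the panel-construction rule can be applied to the published
numbers; parameter names are as printed (the perisinusoidal rows of the
discovery table use the legacy "PS" spelling).
"""

from __future__ import annotations

__all__ = ["SCREEN_PVALUES", "VALIDATION_PVALUES"]

#: Discovery screen: parameter -> (PKUH p-value, SGH p-value).
SCREEN_PVALUES: dict[str, tuple[float, float]] = {
    "%PeriportalDis": (0.825, 0.022),
    "#StrPeriportal": (0.414, 0.003),
    "#ShortStrPeriportal": (0.710, 0.003),
    "#LongStrPeriportal": (0.604, 0.009),
    "#ThinStrPeriportal": (0.710, 0.024),
    "#ThickStrPeriportal": (0.439, 0.004),
    "StrLengthPeriportal": (1.000, 0.019),
    "StrWidthPeriportal": (0.330, 0.004),
    "#StrPeriportalAgg": (0.825, 0.005),
    "#ShortStrPeriportalAgg": (0.940, 0.004),
    "#LongStrPeriportalAgg": (0.484, 0.008),
    "#ThickStrPeriportalAgg": (0.629, 0.005),
    "StrWidthPeriportalAgg": (0.199, 0.006),
    "#StrPeriportalDis": (0.825, 0.009),
    "#ShortStrPeriportalDis": (0.940, 0.005),
    "#ThinStrPeriportalDis": (0.940, 0.013),
    "#ThickStrPeriportalDis": (0.710, 0.009),
    "StrAreaPeriportalDis": (0.825, 0.022),
    "StrLengthPeriportalDis": (0.604, 0.013),
    "StrWidthPeriportalDis": (0.825, 0.019),
    "#StrPS": (0.454, 0.049),
    "#ThickStrPS": (0.454, 0.049),
    "StrLengthPS": (0.635, 0.049),
    "StrWidthPS": (0.539, 0.026),
    "#StrPSAgg": (0.839, 0.042),
    "#LongStrPSAgg": (0.733, 0.036),
    "#ThickStrPSAgg": (0.733, 0.042),
    "StrWidthPSAgg": (0.635, 0.036),
}

#: Validation screen (true F1 vs true F2): parameter -> p-value.
VALIDATION_PVALUES: dict[str, float] = {
    "%PeriportalDis": 0.011,
    "#StrPeriportal": 0.003,
    "#ShortStrPeriportal": 0.003,
    "#LongStrPeriportal": 0.005,
    "#ThinStrPeriportal": 0.054,
    "#ThickStrPeriportal": 0.005,
    "StrLengthPeriportal": 0.005,
    "StrWidthPeriportal": 0.011,
    "#StrPeriportalAgg": 0.005,
    "#ShortStrPeriportalAgg": 0.005,
    "#LongStrPeriportalAgg": 0.005,
    "#ThickStrPeriportalAgg": 0.008,
    "StrWidthPeriportalAgg": 0.011,
    "#StrPeriportalDis": 0.003,
    "#ShortStrPeriportalDis": 0.003,
    "#ThinStrPeriportalDis": 0.054,
    "#ThickStrPeriportalDis": 0.004,
    "StrAreaPeriportalDis": 0.011,
    "StrLengthPeriportalDis": 0.011,
    "StrWidthPeriportalDis": 0.008,
    "#StrRPS": 0.022,
    "#ThickStrRPS": 0.022,
    "StrLengthRPS": 0.022,
    "StrWidthRPS": 0.022,
    "#StrRPSAgg": 0.018,
    "#LongStrRPSAgg": 0.018,
    "#ThickStrRPSAgg": 0.022,
    "StrWidthRPSAgg": 0.022,
}
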