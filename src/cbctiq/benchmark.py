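"""Published benchmark measurements for FBP-vs-IR CBCT image quality.

Task-based image-quality outcomes measured on a Catphan 504 phantom for the
three CBCT acquisition modes of an O-ring radiotherapy linac (head, thorax,
pelvis large), each reconstructed with filtered back projection (FBP) and
iterative reconstruction (IR): noise magnitude (square root of the 2D NPS
area, HU), NPS peak frequencies (mm^-1), TTF50 per insert (mm^-1), insert
contrast (HU) and NPWE detectability index per 10-mm lesion task.

These values serve as reference arithmetic for the summary statistics the
report module computes (percent changes and across-insert mean +/- SD), and
as the source of the default study conditions of the synthetic phantom.
"""

from __future__ import annotations

from .report import mean_change_over_inserts, percent_change

MODES = ("head", "thorax", "pelvis_large")
INSERTS = ("air", "ldpe", "delrin", "teflon")

NOISE_MAGNITUDE_HU = {
    "head": {"FBP": 40.0, "IR": 26.0},
    "thorax": {"FBP": 10.6, "IR": 8.6},
    "pelvis_large": {"FBP": 4.8, "IR": 3.6},
}

NPS_PEAKS_MM = {
    "head": {"FBP": [0.29], "IR": [0.20]},
    "thorax": {"FBP": [0.02, 0.22], "IR": [0.02, 0.13]},
    "pelvis_large": {"FBP": [0.02, 0.22], "IR": [0.02, 0.13]},
}

F50_MM = {
    "head": {
        "FBP": {"air": 0.41, "ldpe": 0.39, "delrin": 0.40, "teflon": 0.39},
        "IR": {"air": 0.44, "ldpe": 0.41, "delrin": 0.42, "teflon": 0.40},
    },
    "thorax": {
        "FBP": {"air": 0.29, "ldpe": 0.28, "delrin": 0.32, "teflon": 0.28},
        "IR": {"air": 0.32, "ldpe": 0.31, "delrin": 0.36, "teflon": 0.31},
    },
    "pelvis_large": {
        "FBP": {"air": 0.29, "ldpe": 0.29, "delrin": 0.33, "teflon": 0.28},
        "IR": {"air": 0.32, "ldpe": 0.32, "delrin": 0.36, "teflon": 0.31},
    },
}

DPRIME = {
    "head": {
        "FBP": {"air": 14.7, "ldpe": 2.5, "delrin": 3.4, "teflon": 11.8},
        "IR": {"air": 22.5, "ldpe": 4.0, "delrin": 5.3, "teflon": 18.1},
    },
    "thorax": {
        "FBP": {"air": 44.9, "ldpe": 8.0, "delrin": 10.5, "teflon": 35.2},
        "IR": {"air": 67.2, "ldpe": 11.6, "delrin": 16.7, "teflon": 51.5},
    },
    "pelvis_large": {
        "FBP": {"air": 105.2, "ldpe": 18.5, "delrin": 25.1, "teflon": 81.6},
        "IR": {"air": 192.0, "ldpe": 33.4, "delrin": 46.7, "teflon": 143.4},
    },
}

CONTRAST_HU = {
    "head": {
        "FBP": {"air": -1005.6, "ldpe": -181.3, "delrin": 237.7, "teflon": 808.3},
        "IR": {"air": -1004.5, "ldpe": -180.8, "delrin": 239.4, "teflon": 812.8},
    },
    "thorax": {
        "FBP": {"air": -1024.0, "ldpe": -178.3, "delrin": 234.7, "teflon": 786.8},
        "IR": {"air": -1023.0, "ldpe": -178.6, "delrin": 236.5, "teflon": 792.0},
    },
    "pelvis_large": {
        "FBP": {"air": -1025.0, "ldpe": -177.9, "delrin": 233.1, "teflon": 776.1},
        "IR": {"air": -1024.8, "ldpe": -178.0, "delrin": 234.4, "teflon": 781.0},
    },
}


def noise_change_pct(mode: str) -> float:
    """Percent change in noise magnitude, IR vs FBP, for one mode."""
    v = NOISE_MAGNITUDE_HU[mode]
    return percent_change(v["FBP"], v["IR"])


def _insert_change(table: dict, mode: str) -> tuple[float, float]:
    fbp = [table[mode]["FBP"][i] for i in INSERTS]
    ir = [table[mode]["IR"][i] for i in INSERTS]
    return mean_change_over_inserts(fbp, ir)


def f50_mean_change_pct(mode: str) -> tuple[float, float]:
    """Mean +/- sample SD of the four per-insert TTF50 percent changes."""
    return _insert_change(F50_MM, mode)


def dprime_mean_change_pct(mode: str) -> tuple[float, float]:
    """Mean +/- sample SD of the four per-task d' percent changes."""
    return _insert_change(DPRIME, mode)


def mean_insert_contrast_hu(insert: str) -> float:
    """Mean contrast of one insert across all modes and reconstructions."""
    vals = [CONTRAST_HU[m][r][insert] for m in MODES for r in ("FBP", "IR")]
    return float(sum(vals) / len(vals))
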