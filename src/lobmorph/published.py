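"""Published reference values for lobular carcinoma nuclear morphometry.

These are the per-variant and per-case nuclear size summaries reported for a
59-lesion lobular carcinoma cohort (classic and pleomorphic LCIS; classic,
solid and pleomorphic ILC), measured by automated nucleus detection on H&E
whole-slide images. They serve two purposes here:

* calibration inputs for :mod:`lobmorph.synthetic` (the generator reproduces
  these medians and quartiles), and
* regression fixtures for the summary and classification code paths.

All linear measures are in μm, areas in μm². Each entry stores the printed
median, 25th and 75th percentile, and the printed IQR (which is *not* always
equal to ``q3 - q1`` at one-decimal rounding; see
:func:`iqr_is_self_consistent`).
"""

from __future__ import annotations

PARAMETERS = ("area", "perimeter", "min_feret", "max_feret")

#: Per-variant pooled nuclear size summaries.
#: variant -> parameter -> (median, q1, q3, printed_iqr)
VARIANT_SIZE_TABLE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "cLCIS": {
        "area": (32.7, 25.9, 40.0, 14.1),
        "perimeter": (21.0, 18.8, 23.3, 4.5),
        "min_feret": (5.7, 4.9, 6.3, 1.4),
        "max_feret": (7.5, 6.7, 8.5, 1.8),
    },
    "pLCIS": {
        "area": (53.0, 41.1, 67.9, 26.2),
        "perimeter": (27.1, 24.0, 30.4, 6.4),
        "min_feret": (7.0, 6.1, 8.1, 2.0),
        "max_feret": (9.9, 8.8, 11.2, 2.4),
    },
    "cILC_score1": {
        "area": (34.1, 28.0, 41.7, 13.7),
        "perimeter": (21.2, 19.3, 23.6, 4.3),
        "min_feret": (5.8, 5.2, 6.4, 1.2),
        "max_feret": (7.6, 6.8, 8.5, 1.7),
    },
    "cILC_score2": {
        "area": (43.0, 34.7, 52.2, 17.5),
        "perimeter": (24.0, 21.5, 26.6, 5.1),
        "min_feret": (6.4, 5.8, 7.2, 1.4),
        "max_feret": (8.6, 7.6, 9.7, 2.1),
    },
    "sILC_score2": {
        "area": (40.4, 33.8, 48.0, 14.3),
        "perimeter": (23.1, 21.1, 25.1, 4.0),
        "min_feret": (6.5, 5.9, 7.1, 1.2),
        "max_feret": (8.1, 7.3, 8.9, 1.6),
    },
    "pILC": {
        "area": (66.6, 50.1, 86.4, 36.3),
        "perimeter": (30.0, 26.2, 34.2, 8.0),
        "min_feret": (7.9, 6.7, 9.2, 2.5),
        "max_feret": (10.9, 9.4, 12.5, 3.1),
    },
}

#: Per-case median nuclear area for the 14 pleomorphic ILC cases:
#: case -> (median, q1, q3, printed_iqr, apocrine_cytomorphology)
PILC_CASE_TABLE: dict[str, tuple[float, float, float, float, bool]] = {
    "case_01": (75.7, 57.4, 98.2, 40.7, False),
    "case_02": (47.0, 29.0, 66.1, 37.1, False),
    "case_03": (56.2, 46.6, 67.5, 20.9, False),
    "case_04": (76.7, 58.9, 94.7, 35.8, False),
    "case_05": (82.5, 60.5, 107.9, 45.4, False),
    "case_06": (80.7, 65.0, 92.8, 27.8, False),
    "case_07": (76.2, 58.4, 96.4, 38.0, False),
    "case_08": (61.9, 46.7, 75.9, 28.9, True),
    "case_09": (58.7, 48.3, 70.3, 22.0, False),
    "case_10": (62.4, 52.1, 75.7, 23.7, True),
    "case_11": (62.0, 52.9, 63.9, 21.0, True),
    "case_12": (51.5, 36.7, 72.3, 35.6, False),
    "case_13": (50.4, 40.0, 61.6, 21.6, False),
    "case_14": (52.5, 30.3, 63.1, 32.8, False),
}


def iqr_is_self_consistent(median: float, q1: float, q3: float,
                           printed_iqr: float) -> bool:
    """True when the printed IQR equals ``q3 - q1`` at one-decimal rounding.

    A handful of published entries fail this check (rounding slippage in the
    source statistics software); those entries are excluded from any exact
    regression comparison and only the self-consistent ones are asserted on.
    """
    return round(round(q3 - q1, 10), 1) == round(printed_iqr, 1)
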