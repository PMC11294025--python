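"""Reference cohort bookkeeping.

The multicentre acute-pulmonary-embolism cohort that motivates this
pipeline screened 981 patients, excluded 152 (62 of them for CT artefacts),
analysed 829, and observed 70 deaths within 7 days and 121 within 30 days;
the 829 analysed patients were split 580/249 into training and test sets.
The synthetic generator defaults are calibrated to these marginals. The
helpers below recompute the derived percentages from the raw counts.
"""

from __future__ import annotations

REFERENCE_COHORT: dict[str, int] = {
    "n_screened": 981,
    "n_excluded": 152,
    "n_excluded_artefact": 62,
    "n_included": 829,
    "deaths_7day": 70,
    "deaths_30day": 121,
    "n_train": 580,
    "n_test": 249,
}


def percentage(part: int, whole: int, digits: int = 2) -> float:
    """``100 * part / whole`` rounded to the reported precision."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, digits)


def cohort_percentages(counts: dict[str, int] = REFERENCE_COHORT) -> dict[str, float]:
    """Derived cohort percentages recomputed from the raw counts."""
    return {
        "mortality_7day_pct": percentage(counts["deaths_7day"], counts["n_included"]),
        "mortality_30day_pct": percentage(counts["deaths_30day"], counts["n_included"]),
        "excluded_pct": percentage(counts["n_excluded"], counts["n_screened"]),
        "excluded_artefact_pct": percentage(counts["n_excluded_artefact"], counts["n_screened"]),
        "train_fraction_pct": percentage(counts["n_train"], counts["n_included"]),
    }
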