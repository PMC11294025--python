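"""Simplified pulmonary embolism severity index (sPESI) clinical baseline.

The score sums six equally weighted binary items — age > 80 years, history
of cancer, chronic cardiopulmonary disease, heart rate >= 110/min, systolic
blood pressure < 100 mmHg and arterial oxygen saturation < 90% — giving an
integer 0..6. As a prognostic model the integer score itself is the
ranking statistic, with the conventional cut-off of 1 (any positive item
flags the patient as at risk), which yields the typical high-sensitivity /
low-specificity operating point in cohorts where few patients score 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import BOOTSTRAP_DEFAULT, EvalReport, evaluate_scores
from .synthetic import SPESI_COMPONENTS

SPESI_CUTOFF = 1.0


def spesi_score(components: pd.DataFrame | dict) -> pd.Series | int:
    """Unweighted sum of the six sPESI items (0..6).

    Accepts a single record (dict of booleans) or a DataFrame with the six
    component columns.
    """
    if isinstance(components, dict):
        missing = [c for c in SPESI_COMPONENTS if c not in components]
        if missing:
            raise ValueError(f"missing sPESI components: {missing}")
        return int(sum(bool(components[c]) for c in SPESI_COMPONENTS))
    missing = [c for c in SPESI_COMPONENTS if c not in components.columns]
    if missing:
        raise ValueError(f"missing sPESI components: {missing}")
    return components[list(SPESI_COMPONENTS)].astype(int).sum(axis=1)


def spesi_model(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    cutoff: float = SPESI_CUTOFF,
    b: int = BOOTSTRAP_DEFAULT,
    seed: int = 0,
) -> EvalReport:
    """Evaluate the integer sPESI score as a prognostic model.

    The score is used directly as the ranking statistic; patients with
    score >= ``cutoff`` are predicted to die within the endpoint window.
    """
    return evaluate_scores(
        np.asarray(scores, dtype=float), np.asarray(labels, dtype=int),
        cutoff=cutoff, b=b, seed=seed,
    )
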