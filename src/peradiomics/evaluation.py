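"""Discrimination, cut-off, calibration and model-comparison statistics.

AUC uses the Mann-Whitney estimator with half credit for ties; its 95%
confidence interval comes from a bias-corrected (BC) stratified bootstrap;
correlated AUCs are compared with the DeLong test; classification cut-offs
maximize Youden's J on training scores and are transferred unchanged to
test scores; calibration is assessed with the Hosmer-Lemeshow test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import wald_z

logger = logging.getLogger(__name__)

BOOTSTRAP_DEFAULT = 2000


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_ci_bootstrap(
    scores: np.ndarray,
    labels: np.ndarray,
    b: int = BOOTSTRAP_DEFAULT,
    seed: int = 0,
) -> tuple[float, float]:
    """Bias-corrected stratified bootstrap 95% CI for the AUC.

    Patients are resampled within class (so every resample keeps both
    classes); the interval uses the BC percentile adjustment from the
    proportion of bootstrap AUCs below the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    theta = roc_auc(scores, labels)
    # vectorized: ranks per resample via broadcasting would be heavy; loop is fine
    boots = np.empty(b)
    lab = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
    for i in range(b):
        sp = pos[rng.integers(0, n1, n1)]
        sn = neg[rng.integers(0, n0, n0)]
        boots[i] = roc_auc(np.concatenate([sp, sn]), lab)
    prop = np.mean(boots < theta) + 0.5 * np.mean(boots == theta)
    prop = min(max(prop, 1.0 / (b + 1)), b / (b + 1.0))
    z0 = stats.norm.ppf(prop)
    z = stats.norm.ppf(0.975)
    lo_q = stats.norm.cdf(2 * z0 - z)
    hi_q = stats.norm.cdf(2 * z0 + z)
    return float(np.quantile(boots, lo_q)), float(np.quantile(boots, hi_q))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one marker."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float)
    cmp_mat += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)
    v01 = cmp_mat.mean(axis=0)
    return v10, v01, float(cmp_mat.sum() / (m * n))


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs.

    Returns (auc_a - auc_b, z, two-sided p). Identical score vectors give
    difference 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    va10, va01, auc_a = _placements(scores_a, labels)
    vb10, vb01, auc_b = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    if m < 2 or n < 2:
        logger.warning("delong_test: fewer than 2 members in a class; "
                       "variance undefined, returning p = 1")
        return float(auc_a - auc_b), 0.0, 1.0
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return float(diff), 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(z), float(p)


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cut-off maximizing J = sensitivity + specificity - 1.

    Classification rule: score >= cutoff predicts the event. Ties in J
    break toward higher sensitivity (lower cut-off); the returned value is
    the midpoint between the chosen threshold and the next lower score,
    so separable data yield the midpoint of the gap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    best_j, best_thr, best_sens = -np.inf, uniq[0], -1.0
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    for thr in uniq:
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sens > best_sens):
            best_j, best_thr, best_sens = j, thr, sens
    below = uniq[uniq < best_thr]
    if len(below):
        return float((best_thr + below.max()) / 2.0)
    return float(best_thr)


def confusion_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> dict[str, int]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    return {
        "tp": int((pred & (labels == 1)).sum()),
        "fp": int((pred & (labels == 0)).sum()),
        "fn": int((~pred & (labels == 1)).sum()),
        "tn": int((~pred & (labels == 0)).sum()),
    }


def hosmer_lemeshow(
    probs: np.ndarray, labels: np.ndarray, g: int = 10
) -> tuple[float, float, int]:
    """Hosmer-Lemeshow goodness-of-fit over equal-frequency probability groups.

    Returns (chi2, p, groups used); adjacent groups with zero expected
    counts are merged (logged).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, g + 1)[1:-1]))
    grp = np.digitize(probs, edges)
    groups = []
    for gid in np.unique(grp):
        sel = grp == gid
        groups.append([labels[sel].sum(), probs[sel].sum(), sel.sum()])
    merged = []
    for obs, exp, n in groups:  # merge zero-expected cells into the neighbour
        if merged and (exp <= 1e-12 or n - exp <= 1e-12):
            logger.info("hosmer_lemeshow: merging a degenerate probability group")
            merged[-1][0] += obs
            merged[-1][1] += exp
            merged[-1][2] += n
        else:
            merged.append([obs, exp, n])
    chi2 = 0.0
    for obs, exp, n in merged:
        exp0 = n - exp
        obs0 = n - obs
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
        if exp0 > 0:
            chi2 += (obs0 - exp0) ** 2 / exp0
    df = max(len(merged) - 2, 1)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), p, len(merged)


def wald_importance(
    table: pd.DataFrame, labels: np.ndarray | pd.Series, features: list[str]
) -> pd.Series:
    """Two-sided Wald p-value of each feature in a univariate logistic fit."""
    labels = np.asarray(labels, dtype=int)
    out = {}
    for feat in features:
        z = wald_z(table[feat].to_numpy(dtype=float), labels)
        out[feat] = 2.0 * float(stats.norm.sf(abs(z)))
    return pd.Series(out, name="wald_p")


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC-curve coordinates (threshold, sensitivity, 1-specificity) at
    every observed score, for plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = []
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        rows.append({
            "threshold": thr,
            "sensitivity": (pred & (labels == 1)).sum() / n1,
            "fpr": (pred & (labels == 0)).sum() / n0,
        })
    return pd.DataFrame(rows)


def calibration_points(probs: np.ndarray, labels: np.ndarray, g: int = 10) -> pd.DataFrame:
    """Observed vs expected event rate per probability group, for
    calibration plots."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, g + 1)[1:-1]))
    grp = np.digitize(probs, edges)
    rows = []
    for gid in np.unique(grp):
        sel = grp == gid
        rows.append({
            "mean_predicted": probs[sel].mean(),
            "observed_rate": labels[sel].mean(),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Evaluation of one model's scores against binary labels."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int]
    hl_chi2: float
    hl_p: float
    n: int
    prevalence: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "cutoff": self.cutoff, "sensitivity": self.sensitivity,
            "specificity": self.specificity, **self.confusion,
            "hl_chi2": self.hl_chi2, "hl_p": self.hl_p,
            "n": self.n, "prevalence": self.prevalence,
        }


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float | None = None,
    probs: np.ndarray | None = None,
    b: int = BOOTSTRAP_DEFAULT,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation report; the cut-off is fitted here only when not
    supplied (training), otherwise applied unchanged (test transfer)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(scores, labels)
    lo, hi = auc_ci_bootstrap(scores, labels, b=b, seed=seed)
    if cutoff is None:
        cutoff = youden_cutoff(scores, labels)
    conf = confusion_at(scores, labels, cutoff)
    sens = conf["tp"] / (conf["tp"] + conf["fn"])
    spec = conf["tn"] / (conf["tn"] + conf["fp"])
    probs = scores if probs is None else np.asarray(probs, dtype=float)
    if probs.min() >= 0 and probs.max() <= 1:
        hl_chi2, hl_p, _ = hosmer_lemeshow(probs, labels)
    else:
        hl_chi2, hl_p = np.nan, np.nan
    return EvalReport(
        auc=auc, ci_low=lo, ci_high=hi, cutoff=float(cutoff),
        sensitivity=float(sens), specificity=float(spec), confusion=conf,
        hl_chi2=hl_chi2, hl_p=hl_p, n=len(labels),
        prevalence=float(labels.mean()),
    )
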