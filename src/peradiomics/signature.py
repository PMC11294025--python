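"""Signature derivation by repeated cross-validated feature selection.

Within each of 30 runs (10 repeats x 3 stratified folds) on the training
data, features are Yeo-Johnson transformed and z-scored (parameters fitted
on the internal-training part only), three selectors — minimal-redundancy
maximum-relevance (MRMR), mutual-information maximization (MIM) and
univariate logistic regression — each pick their top-5 features, and three
learners (logistic regression, gradient-boosted linear model, random
forest) are tuned and scored on the internal-validation fold.

Features are then ranked by their occurrence across the 30 runs: the
signature consists of features occurring in more than 50% of runs for at
least two of the three selectors, pruned so that no retained pair has
training Spearman |rho| > 0.5 (the feature with the higher mean occurrence
wins). The final model refits the transformation and the best learner on
the entire training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from ._logistic import wald_z
from .evaluation import roc_auc
from .redundancy import MI_BINS, mutual_information_binary

logger = logging.getLogger(__name__)

SELECTORS = ("mrmr", "mim", "univariate")
LEARNERS = ("glm_logistic", "xgb_lm", "rf")
TOP_K = 5
OCCURRENCE_THRESHOLD = 50.0  # percent
PRUNE_RHO = 0.5
TUNE_DRAWS_DEFAULT = 32


class ConsensusError(RuntimeError):
    """No feature satisfied the occurrence-consensus rule."""


# ------------------------------------------------------------- transform

def yeo_johnson(x: np.ndarray | float, lam: float) -> np.ndarray | float:
    """The Yeo-Johnson power transform (defined for all real x)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) > 1e-12:
        out[pos] = ((x[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -(((-x[~pos] + 1.0) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out if out.ndim else float(out)


@dataclass
class TransformParams:
    """Per-feature Yeo-Johnson lambda and post-transform z-scaling."""

    lam: dict[str, float] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def fit(self, table: pd.DataFrame) -> "TransformParams":
        for col in table.columns:
            x = table[col].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                lam = 1.0
            else:
                try:
                    lam = float(stats.yeojohnson_normmax(x))
                except Exception:  # pathological columns: fall back to identity
                    lam = 1.0
            t = yeo_johnson(x, lam)
            sd = float(t.std())
            self.lam[col] = lam
            self.mean[col] = float(t.mean())
            self.sd[col] = sd if sd > 0 else 1.0
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in table.columns if c not in self.lam]
        if missing:
            raise ValueError(f"transform not fitted for {missing[:3]}...")
        out = {}
        for col in table.columns:
            t = yeo_johnson(table[col].to_numpy(dtype=float), self.lam[col])
            out[col] = (t - self.mean[col]) / self.sd[col]
        return pd.DataFrame(out, index=table.index)


# ------------------------------------------------------------- selectors

def _mi_continuous(x: np.ndarray, y: np.ndarray, n_bins: int = MI_BINS) -> float:
    """Plug-in MI between two continuous vectors via equal-frequency bins."""
    def binned(v: np.ndarray) -> np.ndarray:
        edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1]))
        return np.digitize(v, edges)

    bx, by = binned(x), binned(y)
    joint = np.zeros((bx.max() + 1, by.max() + 1))
    np.add.at(joint, (bx, by), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.sum(p[nz] * np.log2((p / (px * py))[nz])))


def select_mim(table: pd.DataFrame, labels: np.ndarray, k: int = TOP_K) -> list[str]:
    """Top-k features by marginal mutual information with the endpoint.

    Ties break lexicographically by feature name.
    """
    mi = {c: mutual_information_binary(table[c], labels) for c in table.columns}
    ranked = sorted(table.columns, key=lambda c: (-mi[c], c))
    return ranked[: min(k, len(ranked))]


def select_mrmr(table: pd.DataFrame, labels: np.ndarray, k: int = TOP_K) -> list[str]:
    """Greedy MRMR (difference criterion): maximize
    MI(f; y) - mean over selected MI(f; f_sel); first pick is max relevance.
    """
    cols = list(table.columns)
    rel = {c: mutual_information_binary(table[c], labels) for c in cols}
    selected: list[str] = []
    red: dict[str, float] = {c: 0.0 for c in cols}
    data = {c: table[c].to_numpy(dtype=float) for c in cols}
    while len(selected) < min(k, len(cols)):
        remaining = [c for c in cols if c not in selected]
        if selected:
            last = selected[-1]
            for c in remaining:
                red[c] += _mi_continuous(data[c], data[last])
            score = {c: rel[c] - red[c] / len(selected) for c in remaining}
        else:
            score = {c: rel[c] for c in remaining}
        pick = min(remaining, key=lambda c: (-score[c], c))
        selected.append(pick)
    return selected


def select_univariate(table: pd.DataFrame, labels: np.ndarray, k: int = TOP_K,
                      ridge: float = 1.0) -> list[str]:
    """Top-k features by |Wald z| of a univariate ridge-stabilized logistic
    fit — equivalently by ascending p-value.

    Features are standardized before the fit and the ridge is deliberately
    non-trivial: an unpenalized Wald statistic collapses to zero under
    complete separation (Hauck-Donner effect), which would rank a perfect
    predictor last.
    """
    zs = {}
    for c in table.columns:
        x = table[c].to_numpy(dtype=float)
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else x * 0.0
        zs[c] = abs(wald_z(x, labels, ridge=ridge))
    ranked = sorted(table.columns, key=lambda c: (-zs[c], c))
    return ranked[: min(k, len(ranked))]


_SELECTOR_FUNCS = {
    "mrmr": select_mrmr,
    "mim": select_mim,
    "univariate": select_univariate,
}


# ------------------------------------------------------------- learners

_XGB_GRID = {
    "learning_rate": (0.1, 0.3, 0.5),
    "n_estimators": (20, 50, 100),
    "reg_lambda": (0.0, 0.1, 1.0),
}
_RF_GRID = {
    "n_estimators": (100,),
    "max_depth": (2, 4, None),
    "min_samples_leaf": (1, 5, 10),
    "max_features": ("sqrt", 1.0),
}


def _make_learner(name: str, params: dict, seed: int):
    if name == "glm_logistic":
        # effectively unpenalized maximum-likelihood logistic regression
        return LogisticRegression(C=1e12, max_iter=1000)
    if name == "xgb_lm":
        return XGBClassifier(
            booster="gblinear", objective="binary:logistic", base_score=0.5,
            updater="coord_descent", n_jobs=1, verbosity=0,
            random_state=seed, **params,
        )
    if name == "rf":
        return RandomForestClassifier(n_jobs=1, random_state=seed, **params)
    raise ValueError(f"unknown learner {name!r}")


def _grid_for(name: str) -> dict:
    return {"glm_logistic": {}, "xgb_lm": _XGB_GRID, "rf": _RF_GRID}[name]


def tune_and_fit(
    name: str,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_draws: int = TUNE_DRAWS_DEFAULT,
):
    """Random-search hyperparameter tuning scored by out-of-bag bootstrap AUC.

    Each draw samples one grid point, fits on a class-stratified bootstrap
    sample and scores the held-out (out-of-bag) rows; the best grid point
    is refit on all rows. Learners without hyperparameters skip tuning.
    """
    grid = _grid_for(name)
    seed = int(rng.integers(2**31))
    if not grid:
        model = _make_learner(name, {}, seed)
        model.fit(x, y)
        return model, {}
    keys = list(grid)
    best_score, best_params = -np.inf, None
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    for _ in range(n_draws):
        params = {k: grid[k][rng.integers(len(grid[k]))] for k in keys}
        bag = np.concatenate([
            idx_pos[rng.integers(0, len(idx_pos), len(idx_pos))],
            idx_neg[rng.integers(0, len(idx_neg), len(idx_neg))],
        ])
        oob = np.setdiff1d(np.arange(len(y)), bag)
        if len(oob) == 0 or len(np.unique(y[oob])) < 2:
            oob = np.arange(len(y))  # degenerate OOB: score in-sample (logged)
            logger.info("tune_and_fit: degenerate OOB sample, scoring in-bag")
        model = _make_learner(name, params, seed)
        model.fit(x[bag], y[bag])
        score = roc_auc(model.predict_proba(x[oob])[:, 1], y[oob])
        if score > best_score:
            best_score, best_params = score, params
    model = _make_learner(name, best_params, seed)
    model.fit(x, y)
    return model, best_params


def linear_parameters(model) -> tuple[np.ndarray, float]:
    """Coefficients and intercept of a linear-score learner.

    Both the logistic model and the boosted linear model reduce to a
    single linear score in the transformed features.
    """
    if isinstance(model, LogisticRegression):
        return model.coef_.ravel().copy(), float(model.intercept_[0])
    if isinstance(model, XGBClassifier):
        booster = model.get_booster()
        import json

        dump = json.loads(booster.get_dump(dump_format="json")[0])
        weights = np.asarray(dump["weight"], dtype=float)
        bias = float(np.asarray(dump["bias"], dtype=float).ravel()[0])
        return weights, bias
    raise TypeError(f"{type(model).__name__} has no linear reduction")


# ------------------------------------------------------------------- CV

@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified cross-validation layout."""

    folds: int = 3
    repeats: int = 10
    seed: int = 0

    @property
    def n_runs(self) -> int:
        return self.folds * self.repeats


@dataclass
class CVResult:
    """Occurrence table and validation-AUC summary of one CV experiment."""

    occurrence: pd.DataFrame          # features x selectors, percent of runs
    auc_summary: pd.DataFrame         # selectors x learners, median val AUC
    run_aucs: pd.DataFrame            # long format: repeat, fold, selector, learner, auc
    scheme: CVScheme = field(default_factory=CVScheme)


def run_cv(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    scheme: CVScheme = CVScheme(),
    selectors: tuple[str, ...] = SELECTORS,
    learners: tuple[str, ...] = LEARNERS,
    top_k: int = TOP_K,
    tune_draws: int = TUNE_DRAWS_DEFAULT,
) -> CVResult:
    """The 30-run CV experiment: transform, select, tune, validate.

    All statistics (transform parameters, selection, tuning) are computed
    on the internal-training part of each run only.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if y.sum() < scheme.folds:
        raise ValueError(
            f"too few events ({y.sum()}) for {scheme.folds}-fold stratified CV"
        )
    x_all = table.to_numpy(dtype=float)
    counts = {s: pd.Series(0.0, index=table.columns) for s in selectors}
    rows = []
    for rep in range(scheme.repeats):
        rep_seed = int(np.random.SeedSequence([scheme.seed, rep]).generate_state(1)[0] % 2**31)
        skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, va) in enumerate(skf.split(x_all, y)):
            transformer = TransformParams().fit(table.iloc[tr])
            t_train = transformer.transform(table.iloc[tr])
            t_val = transformer.transform(table.iloc[va])
            for s_idx, sel in enumerate(selectors):
                chosen = _SELECTOR_FUNCS[sel](t_train, y[tr], top_k)
                counts[sel][chosen] += 1.0
                for l_idx, lrn in enumerate(learners):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([scheme.seed, rep, fold, s_idx, l_idx])
                    )
                    model, _ = tune_and_fit(
                        lrn, t_train[chosen].to_numpy(), y[tr], rng, tune_draws
                    )
                    val_scores = model.predict_proba(t_val[chosen].to_numpy())[:, 1]
                    rows.append({
                        "repeat": rep, "fold": fold, "selector": sel,
                        "learner": lrn, "auc": roc_auc(val_scores, y[va]),
                    })
    occurrence = pd.DataFrame(
        {s: 100.0 * counts[s] / scheme.n_runs for s in selectors}
    )
    run_aucs = pd.DataFrame(rows)
    auc_summary = run_aucs.pivot_table(
        index="selector", columns="learner", values="auc", aggfunc="median"
    ).loc[list(selectors), list(learners)]
    return CVResult(occurrence=occurrence, auc_summary=auc_summary,
                    run_aucs=run_aucs, scheme=scheme)


# ------------------------------------------------------------ consensus

@dataclass
class Signature:
    """Ordered selected features for one ROI and endpoint."""

    features: list[str]
    learner: str = ""
    tissue: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("signature must be non-empty")


def consensus_signature(
    occurrence: pd.DataFrame,
    training_table: pd.DataFrame,
    rho_max: float = PRUNE_RHO,
    threshold: float = OCCURRENCE_THRESHOLD,
) -> list[str]:
    """Apply the occurrence-consensus rule and the correlation pruning.

    Candidates are features with occurrence above ``threshold`` percent in
    at least two selectors; among any candidate pair with training
    Spearman |rho| > ``rho_max``, only the feature with the higher mean
    occurrence is kept. The result is ordered by mean occurrence.
    """
    above = (occurrence > threshold).sum(axis=1)
    candidates = occurrence.index[above >= 2]
    if len(candidates) == 0:
        raise ConsensusError(
            "no feature exceeded the occurrence threshold in at least two "
            "selectors; relax the threshold or enlarge the CV experiment"
        )
    mean_occ = occurrence.loc[candidates].mean(axis=1)
    ordered = sorted(candidates, key=lambda c: (-mean_occ[c], c))
    rho = training_table[ordered].corr(method="spearman").abs()
    kept: list[str] = []
    for cand in ordered:
        if all(rho.loc[cand, k] <= rho_max for k in kept):
            kept.append(cand)
    return kept


# ----------------------------------------------------------- final model

@dataclass
class ModelFit:
    """Final fitted model: transformation + learner on the signature."""

    features: list[str]
    learner: str
    transformer: TransformParams
    model: object
    tuned_params: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Event probability per patient; transforms applied unchanged."""
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"missing signature features: {missing}")
        sub = table[self.features]
        bad = sub.isna()
        if bad.to_numpy().any():
            pid = bad.index[bad.any(axis=1)][0]
            feat = bad.columns[bad.loc[pid]][0]
            raise ValueError(f"missing value for patient {pid!r}, feature {feat!r}")
        t = self.transformer.transform(sub)
        probs = self.model.predict_proba(t.to_numpy())[:, 1]
        return pd.Series(probs, index=table.index, name="probability")

    def linear_score(self, table: pd.DataFrame) -> pd.Series:
        """Explicit linear score (logit scale) for linear-reducible learners."""
        coef, intercept = linear_parameters(self.model)
        t = self.transformer.transform(table[self.features])
        return pd.Series(t.to_numpy() @ coef + intercept, index=table.index)

    def to_dict(self) -> dict:
        out = {
            "features": self.features,
            "learner": self.learner,
            "tuned_params": {k: (None if v is None else v) for k, v in self.tuned_params.items()},
            "yeo_johnson_lambda": {f: self.transformer.lam[f] for f in self.features},
            "z_mean": {f: self.transformer.mean[f] for f in self.features},
            "z_sd": {f: self.transformer.sd[f] for f in self.features},
        }
        try:
            coef, intercept = linear_parameters(self.model)
            out["coefficients"] = dict(zip(self.features, coef.tolist()))
            out["intercept"] = intercept
        except TypeError:
            pass
        return out


def fit_final(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    features: list[str],
    learner: str,
    seed: int = 0,
    tune_draws: int = TUNE_DRAWS_DEFAULT,
) -> ModelFit:
    """Refit transforms and the chosen learner on the full training data."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"signature features not in table: {missing}")
    sub = table[features]
    transformer = TransformParams().fit(sub)
    t = transformer.transform(sub)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 997]))
    model, params = tune_and_fit(learner, t.to_numpy(), y, rng, tune_draws)
    return ModelFit(features=list(features), learner=learner,
                    transformer=transformer, model=model, tuned_params=params)


def best_learner(auc_summary: pd.DataFrame) -> str:
    """Learner with the highest median validation AUC (median over selectors)."""
    return str(auc_summary.median(axis=0).idxmax())
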