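"""End-to-end orchestration: generate -> prep -> extract -> screen ->
cluster -> cross-validate -> finalize -> evaluate, per ROI and endpoint.

The cohort is split 70/30 stratified by outcome; all statistics — ICC
screening, clustering, transforms, selection, tuning, the Youden cut-off —
are computed on training patients only and transferred unchanged to the
held-out test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    calibration_points,
    delong_test,
    evaluate_scores,
    roc_points,
    wald_importance,
)
from .features import build_feature_table, manifest_frame
from .io import save_config, write_json, write_table
from .redundancy import reduce_features
from .robustness import PerturbationSpec, filter_robust, perturbed_feature_tables
from .signature import (
    LEARNERS,
    SELECTORS,
    CVScheme,
    best_learner,
    consensus_signature,
    fit_final,
    run_cv,
)
from .spesi import spesi_model, spesi_score
from .synthetic import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and sizes of one pipeline run (recorded verbatim in
    the run manifest)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    split_fraction: float = 0.70
    rois: tuple[str, ...] = ("SM", "IMAT", "SM_IMAT")
    endpoints: tuple[str, ...] = ("7d", "30d")
    icc_threshold: float = 0.8
    cluster_rho: float = 0.8
    occurrence_threshold: float = 50.0
    prune_rho: float = 0.5
    top_k: int = 5
    folds: int = 3
    repeats: int = 10
    bootstrap_b: int = 2000
    tune_draws_cv: int = 8
    tune_draws_final: int = 32
    selectors: tuple[str, ...] = SELECTORS
    learners: tuple[str, ...] = LEARNERS
    n_bins: int = 24


def stratified_split(
    ids: list[str] | pd.Index,
    labels: np.ndarray | pd.Series,
    fraction: float = 0.70,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Per-class proportional split with largest-remainder rounding.

    Returns (train ids, test ids); disjoint and exhaustive, deterministic
    given the seed.
    """
    ids = list(ids)
    y = np.asarray(labels)
    if len(ids) != len(y):
        raise ValueError("ids and labels length mismatch")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 131]))
    classes, counts = np.unique(y, return_counts=True)
    total_train = int(round(fraction * len(ids)))
    quotas = fraction * counts
    base = np.floor(quotas).astype(int)
    leftover = total_train - base.sum()
    order = np.argsort(-(quotas - base))  # largest remainder first
    take = base.copy()
    for i in range(int(leftover)):
        take[order[i % len(classes)]] += 1
    train: list[str] = []
    test: list[str] = []
    for cls, n_train in zip(classes, take):
        members = [i for i, v in zip(ids, y) if v == cls]
        perm = rng.permutation(len(members))
        chosen = {members[j] for j in perm[:n_train]}
        train.extend(m for m in members if m in chosen)
        test.extend(m for m in members if m not in chosen)
    return train, test


def _joint_stratum(clinical: pd.DataFrame) -> np.ndarray:
    """Joint 7-/30-day stratum so one split preserves both event rates."""
    return (clinical["dead30"].astype(int) + clinical["dead7"].astype(int)).to_numpy()


@dataclass
class EndpointResult:
    """Artifacts of one ROI x endpoint analysis."""

    tissue: str
    endpoint: str
    signature: list[str]
    learner: str
    occurrence: pd.DataFrame
    auc_summary: pd.DataFrame
    train_report: dict
    test_report: dict
    spesi_train: dict
    spesi_test: dict
    delong_vs_spesi: dict
    wald_p: pd.Series
    model: dict
    funnel: dict


def run_all(config: RunConfig, outdir: str | Path | None = None,
            cohort: Cohort | None = None) -> dict:
    """Run the full pipeline; optionally write all artifacts to ``outdir``.

    Returns a nested dict {(tissue, endpoint): EndpointResult} plus split
    metadata under the "meta" key.
    """
    out: dict = {}
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    clinical = cohort.clinical
    train_ids, test_ids = stratified_split(
        clinical.index, _joint_stratum(clinical), config.split_fraction, config.seed
    )
    spesi = spesi_score(clinical)
    out["meta"] = {
        "n_patients": len(clinical), "n_train": len(train_ids),
        "n_test": len(test_ids),
        "train_event_rate_30d": float(clinical.loc[train_ids, "dead30"].mean()),
        "test_event_rate_30d": float(clinical.loc[test_ids, "dead30"].mean()),
    }
    if outdir is not None:
        import sklearn
        import xgboost

        from . import __version__

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_config(config.cohort, outdir / "cohort_config.yaml")
        manifest = {k: str(v) for k, v in config.__dict__.items() if k != "cohort"}
        manifest["versions"] = {
            "peradiomics": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        }
        write_json(manifest, outdir / "run_config.json")
        write_json(out["meta"], outdir / "split.json")
        write_table(manifest_frame().set_index("name"), outdir / "feature_manifest.csv")

    idx = {pid: i for i, pid in enumerate(clinical.index)}
    tr_pos = [idx[p] for p in train_ids]

    for tissue in config.rois:
        logger.info("extracting %s features for %d patients", tissue, len(clinical))
        baseline = build_feature_table(
            cohort.slices, cohort.compartments, tissue, config.n_bins
        ).frame
        # features must be complete for modelling; incomplete columns are
        # dropped up front (missingness is a generator edge case, logged)
        incomplete = baseline.columns[baseline.isna().any()]
        if len(incomplete):
            logger.warning("%s: dropping %d incomplete features", tissue, len(incomplete))
            baseline = baseline.drop(columns=incomplete)
        train_slices = [cohort.slices[i] for i in tr_pos]
        train_comps = [cohort.compartments[i] for i in tr_pos]
        spec = PerturbationSpec(seed=config.seed)
        replicate_frames = perturbed_feature_tables(
            train_slices, train_comps, tissue, spec, config.n_bins
        )
        replicate_frames = [f[baseline.columns] for f in replicate_frames]
        robust_train, rob_result = filter_robust(
            baseline.loc[train_ids], replicate_frames, config.icc_threshold
        )
        funnel = {"extracted": int(baseline.shape[1]),
                  "post_icc": int(robust_train.shape[1])}
        logger.info("%s: %d features survive the ICC screen", tissue, robust_train.shape[1])

        for endpoint in config.endpoints:
            y_train = cohort.labels(endpoint).loc[train_ids]
            y_test = cohort.labels(endpoint).loc[test_ids]
            reduced_train, clusters = reduce_features(
                robust_train, y_train, config.cluster_rho
            )
            funnel_e = dict(funnel, post_cluster=int(reduced_train.shape[1]))
            logger.info("%s/%s: %d features after clustering",
                        tissue, endpoint, reduced_train.shape[1])
            scheme = CVScheme(folds=config.folds, repeats=config.repeats,
                              seed=config.seed)
            cv = run_cv(reduced_train, y_train, scheme, config.selectors,
                        config.learners, config.top_k, config.tune_draws_cv)
            sig_features = consensus_signature(
                cv.occurrence, reduced_train, config.prune_rho,
                config.occurrence_threshold,
            )
            learner = best_learner(cv.auc_summary)
            fit = fit_final(baseline.loc[train_ids], y_train, sig_features,
                            learner, config.seed, config.tune_draws_final)
            p_train = fit.predict(baseline.loc[train_ids])
            p_test = fit.predict(baseline.loc[test_ids])
            rep_train = evaluate_scores(p_train.to_numpy(), y_train.to_numpy(),
                                        b=config.bootstrap_b, seed=config.seed)
            rep_test = evaluate_scores(p_test.to_numpy(), y_test.to_numpy(),
                                       cutoff=rep_train.cutoff,
                                       b=config.bootstrap_b, seed=config.seed)
            sp_train = spesi_model(spesi.loc[train_ids], y_train,
                                   b=config.bootstrap_b, seed=config.seed)
            sp_test = spesi_model(spesi.loc[test_ids], y_test,
                                  b=config.bootstrap_b, seed=config.seed)
            d_diff, d_z, d_p = delong_test(
                p_test.to_numpy(), spesi.loc[test_ids].to_numpy(), y_test.to_numpy()
            )
            transformer = fit.transformer
            wald = wald_importance(
                transformer.transform(baseline.loc[train_ids, sig_features]),
                y_train, sig_features,
            )
            res = EndpointResult(
                tissue=tissue, endpoint=endpoint, signature=sig_features,
                learner=learner, occurrence=cv.occurrence,
                auc_summary=cv.auc_summary,
                train_report=rep_train.to_dict(), test_report=rep_test.to_dict(),
                spesi_train=sp_train.to_dict(), spesi_test=sp_test.to_dict(),
                delong_vs_spesi={"auc_diff": d_diff, "z": d_z, "p": d_p},
                wald_p=wald, model=fit.to_dict(), funnel=funnel_e,
            )
            out[(tissue, endpoint)] = res
            if outdir is not None:
                sub = outdir / f"{tissue}_{endpoint}"
                sub.mkdir(exist_ok=True)
                write_table(rob_result.table, sub / "robustness.csv")
                write_table(clusters.table, sub / "clusters.csv")
                write_table(cv.occurrence, sub / "occurrence.csv")
                write_table(cv.auc_summary, sub / "cv_auc.csv")
                write_json(fit.to_dict(), sub / "model.json")
                write_table(roc_points(p_test.to_numpy(), y_test.to_numpy()),
                            sub / "roc_test.csv")
                write_table(calibration_points(p_test.to_numpy(), y_test.to_numpy()),
                            sub / "calibration_test.csv")
                write_json({
                    "signature": sig_features, "learner": learner,
                    "train": rep_train.to_dict(), "test": rep_test.to_dict(),
                    "spesi_train": sp_train.to_dict(), "spesi_test": sp_test.to_dict(),
                    "delong_vs_spesi": res.delong_vs_spesi,
                    "wald_p": wald.to_dict(), "funnel": funnel_e,
                }, sub / "evaluation.json")
    if outdir is not None:
        write_table(summary_table(out), outdir / "summary.csv")
    return out


def summary_table(results: dict) -> pd.DataFrame:
    """Headline per-signature summary (signature | features | mortality |
    train AUC | test AUC | sens/spec | cut-off)."""
    rows = []
    for key, res in results.items():
        if key == "meta":
            continue
        rows.append({
            "signature": f"Radiomics {res.tissue}",
            "features": " ".join(res.signature),
            "mortality": res.endpoint,
            "train_auc": "%.2f (%.2f-%.2f)" % (
                res.train_report["auc"], res.train_report["ci_low"],
                res.train_report["ci_high"]),
            "test_auc": "%.2f (%.2f-%.2f)" % (
                res.test_report["auc"], res.test_report["ci_low"],
                res.test_report["ci_high"]),
            "sens_spec_train": "%.2f/%.2f" % (
                res.train_report["sensitivity"], res.train_report["specificity"]),
            "sens_spec_test": "%.2f/%.2f" % (
                res.test_report["sensitivity"], res.test_report["specificity"]),
            "cutoff": "%.2f" % res.train_report["cutoff"],
        })
        rows.append({
            "signature": "Clinical sPESI",
            "features": "sPESI",
            "mortality": res.endpoint,
            "train_auc": "%.2f (%.2f-%.2f)" % (
                res.spesi_train["auc"], res.spesi_train["ci_low"],
                res.spesi_train["ci_high"]),
            "test_auc": "%.2f (%.2f-%.2f)" % (
                res.spesi_test["auc"], res.spesi_test["ci_low"],
                res.spesi_test["ci_high"]),
            "sens_spec_train": "%.2f/%.2f" % (
                res.spesi_train["sensitivity"], res.spesi_train["specificity"]),
            "sens_spec_test": "%.2f/%.2f" % (
                res.spesi_test["sensitivity"], res.spesi_test["specificity"]),
            "cutoff": "%.2f" % res.spesi_train["cutoff"],
        })
    return pd.DataFrame(rows).drop_duplicates()
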