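"""End-to-end orchestration: discovery runs, validation and robustness.

Ties the modules together the way a study would use them: run the
three-stage discovery on a training cohort and report per-stage
survivor counts; validate a signature on a cohort (Kaplan-Meier per
predicted group, log-rank, univariate and covariate-adjusted Cox of the
predicted label, concordance index); cross-tabulate predictions against
pathological response states; compare predicted groups across cohorts;
and measure label stability under batch-effect and degradation
perturbations for both the rank-based vote and the median-anchored
comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    NON_RESPONDER,
    RESPONDER,
    GenePairSignature,
    PredictionResult,
    QuantSignatureSpec,
    quant_score_classify,
    vote_classify,
)
from .data import ClinicalTable, DataError, ExpressionMatrix, code_covariates, truncate_followup
from .discovery import (
    enumerate_candidate_pairs,
    forward_select_signature,
    select_de_genes,
    select_prognostic_genes,
    select_prognostic_pairs,
)
from .simulate import apply_monotone_distortion, degrade_samples
from .stats import (
    ContingencyResult,
    CoxFit,
    KMCurve,
    LogRankResult,
    StatsError,
    SurvivalData,
    concordance_index,
    cox_fit,
    cox_screen_univariate,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageError",
    "DiscoveryParams",
    "ValidationReport",
    "RobustnessReport",
    "run_discovery",
    "validate_signature",
    "response_crosstab",
    "subgroup_survival",
    "cross_cohort_comparison",
    "robustness_experiment",
]

#: Screening threshold for clinical covariates entering the adjusted model.
COVARIATE_SCREEN_ALPHA = 0.2


class StageError(RuntimeError):
    """A discovery stage left no survivors."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class DiscoveryParams:
    """Thresholds of the three screening stages."""

    de_alpha: float = 0.05
    cox_alpha: float = 0.05
    pair_fdr: float = 0.05
    followup_horizon: float = 60.0


@dataclass
class ValidationReport:
    """Signature performance on one cohort.

    Statistics that cannot be computed (e.g. log-rank with an empty
    predicted group) are None with the reason recorded in
    ``not_computable``.
    """

    n_responders: int
    n_non_responders: int
    logrank: LogRankResult | None = None
    cox_univariate: CoxFit | None = None
    cox_multivariate: CoxFit | None = None
    screened_covariates: list[str] = field(default_factory=list)
    cindex: float | None = None
    km_curves: dict[str, KMCurve] = field(default_factory=dict)
    not_computable: dict[str, str] = field(default_factory=dict)

    @property
    def hazard_ratio(self) -> float | None:
        if self.cox_univariate is None:
            return None
        return float(self.cox_univariate.hazard_ratios[0])


@dataclass
class RobustnessReport:
    """Label stability of both classifiers under a perturbation grid."""

    settings: list[dict]
    vote_concordance: list[float]
    comparator_concordance: list[float | None]
    replicates: int
    seed: int


def _aligned_survival(clinical: ClinicalTable, sample_ids) -> SurvivalData:
    df = clinical.data.loc[list(sample_ids)]
    return SurvivalData(df["rfs_months"].to_numpy(), df["event"].to_numpy())


def run_discovery(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    params: DiscoveryParams = DiscoveryParams(),
) -> tuple[GenePairSignature, dict[str, int]]:
    """Execute the full discovery pipeline on a training cohort.

    Stages: follow-up truncation -> differential expression (CR vs
    non-CR) -> prognostic genes (Cox on expression) -> candidate pair
    enumeration -> prognostic pairs (Cox on ordering indicator, BH FDR)
    -> seeded greedy forward selection.  Returns the signature and the
    survivor count of every stage; a stage with zero survivors raises
    :class:`StageError` naming it.  Deterministic given data and
    thresholds.
    """
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise DataError("no samples shared between expression and clinical data")
    expr = expr.subset_samples(common)
    clinical = truncate_followup(clinical.subset(common), params.followup_horizon)
    survival = SurvivalData.from_clinical(clinical)
    counts: dict[str, int] = {"samples": len(common)}

    de_genes = select_de_genes(
        expr, clinical.data["response_state"], alpha=params.de_alpha
    )
    counts["de_genes"] = len(de_genes)
    if not de_genes:
        raise StageError("de_genes", "no differentially expressed genes")

    prog_genes = select_prognostic_genes(expr, survival, de_genes, alpha=params.cox_alpha)
    counts["prognostic_genes"] = len(prog_genes)
    if len(prog_genes) < 2:
        raise StageError("prognostic_genes", f"{len(prog_genes)} survivors (need >= 2)")

    candidate_pairs = enumerate_candidate_pairs(prog_genes)
    counts["candidate_pairs"] = len(candidate_pairs)

    prog_pairs = select_prognostic_pairs(
        expr, candidate_pairs, survival, fdr=params.pair_fdr
    )
    counts["prognostic_pairs"] = len(prog_pairs)
    if not prog_pairs:
        raise StageError("prognostic_pairs", "no pair survived FDR control")

    signature, _ = forward_select_signature(expr, prog_pairs, survival)
    counts["signature_pairs"] = len(signature)
    return signature, counts


def _validate_from_labels(
    labels: np.ndarray, clinical: ClinicalTable
) -> ValidationReport:
    survival = SurvivalData.from_clinical(clinical)
    non_resp = (labels == NON_RESPONDER).astype(float)
    report = ValidationReport(
        n_responders=int((labels == RESPONDER).sum()),
        n_non_responders=int(non_resp.sum()),
    )
    for name, mask in ((RESPONDER, labels == RESPONDER),
                       (NON_RESPONDER, labels == NON_RESPONDER)):
        if mask.any():
            report.km_curves[name] = km_estimate(survival.subset(mask))
    if report.n_responders == 0 or report.n_non_responders == 0:
        report.not_computable["logrank"] = "one predicted group is empty"
        report.not_computable["cox_univariate"] = "one predicted group is empty"
        report.not_computable["cox_multivariate"] = "one predicted group is empty"
        try:
            report.cindex = concordance_index(non_resp, survival)
        except StatsError as exc:
            report.not_computable["cindex"] = str(exc)
        return report

    try:
        report.logrank = logrank_test(labels, survival)
    except StatsError as exc:
        report.not_computable["logrank"] = str(exc)
    try:
        report.cox_univariate = cox_fit(
            pd.DataFrame({"non_responder": non_resp}), survival
        )
    except StatsError as exc:
        report.not_computable["cox_univariate"] = str(exc)
    try:
        report.cindex = concordance_index(non_resp, survival)
    except StatsError as exc:
        report.not_computable["cindex"] = str(exc)

    covariates = code_covariates(clinical)
    usable = [c for c in covariates.columns if covariates[c].notna().sum() >= 3]
    report.screened_covariates = cox_screen_univariate(
        covariates[usable], survival, alpha=COVARIATE_SCREEN_ALPHA
    )
    X = pd.DataFrame({"non_responder": non_resp}, index=clinical.data.index)
    for c in report.screened_covariates:
        X[c] = covariates[c].to_numpy()
    complete = X.notna().all(axis=1).to_numpy()
    try:
        report.cox_multivariate = cox_fit(
            X[complete].reset_index(drop=True), survival.subset(complete)
        )
    except StatsError as exc:
        report.not_computable["cox_multivariate"] = str(exc)
    return report


def validate_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: GenePairSignature,
) -> ValidationReport:
    """Validate a signature on a cohort.

    Classifies by strict-majority vote, then reports per-group
    Kaplan-Meier curves, the log-rank test, the univariate Cox fit of
    the predicted label (non-responder vs responder), the multivariate
    Cox fit adjusted for clinical covariates screened at univariate
    p < 0.2 (complete cases only, n_used reported), and the concordance
    index of the predicted label.
    """
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise DataError("no samples shared between expression and clinical data")
    predictions = vote_classify(expr.subset_samples(common), signature)
    return _validate_from_labels(predictions.labels, clinical.subset(common))


def response_crosstab(
    predictions: PredictionResult, clinical: ClinicalTable
) -> ContingencyResult:
    """Fisher's exact test of predicted labels vs pathological response.

    Builds the 2x2 table with rows CR / non-CR and columns responder /
    non-responder over samples holding both a prediction and a
    non-missing response state.
    """
    pred = predictions.to_frame()["label"]
    states = clinical.data["response_state"]
    common = pred.index.intersection(states.dropna().index)
    if len(common) == 0:
        raise DataError("no sample has both a prediction and a response state")
    table = np.zeros((2, 2), dtype=int)
    for row, state in enumerate(("CR", "nonCR")):
        for col, label in enumerate((RESPONDER, NON_RESPONDER)):
            table[row, col] = int(
                ((states.loc[common] == state) & (pred.loc[common] == label)).sum()
            )
    return fisher_exact_2x2(table)


def subgroup_survival(
    predictions: PredictionResult,
    clinical: ClinicalTable,
    subgroup_filter,
) -> ValidationReport:
    """Validation restricted to the samples selected by the predicate.

    ``subgroup_filter`` receives the clinical DataFrame and returns a
    boolean mask (e.g. ``lambda df: df["response_state"] == "CR"``).
    """
    mask = np.asarray(subgroup_filter(clinical.data), dtype=bool)
    ids = [s for s, keep in zip(clinical.sample_ids, mask) if keep]
    ids = [s for s in ids if s in predictions.sample_ids]
    if not ids:
        raise DataError("subgroup filter matched no sample")
    sub_pred = predictions.subset(ids)
    return _validate_from_labels(sub_pred.labels, clinical.subset(ids))


def cross_cohort_comparison(
    labels_a: np.ndarray,
    survival_a: SurvivalData,
    labels_b: np.ndarray,
    survival_b: SurvivalData,
    contrast: tuple[str, str] = (RESPONDER, NON_RESPONDER),
) -> LogRankResult:
    """Log-rank test pooling one predicted group from each cohort.

    ``contrast`` names the label taken from cohort A and from cohort B;
    e.g. responders of the training cohort vs non-responders of a test
    cohort.
    """
    mask_a = np.asarray(labels_a) == contrast[0]
    mask_b = np.asarray(labels_b) == contrast[1]
    if not mask_a.any() or not mask_b.any():
        raise DataError("empty group selected for cross-cohort comparison")
    times = np.concatenate([survival_a.times[mask_a], survival_b.times[mask_b]])
    events = np.concatenate([survival_a.events[mask_a], survival_b.events[mask_b]])
    groups = np.concatenate(
        [np.repeat("A", mask_a.sum()), np.repeat("B", mask_b.sum())]
    )
    return logrank_test(groups, SurvivalData(times, events))


def robustness_experiment(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: GenePairSignature,
    comparator_spec: QuantSignatureSpec | None,
    perturbation_grid: list[dict],
    reps: int = 1,
    seed: int = 0,
) -> RobustnessReport:
    """Label stability of both classifiers under perturbations.

    Each grid point is a dict with optional keys ``monotone`` (family
    name) and ``noise_sd`` / ``dropout`` (degradation parameters).  For
    every point and replicate the perturbation is applied and both
    classifiers re-run; the report records the mean fraction of labels
    agreeing with the clean-data labels.  Under pure monotone
    distortion the vote concordance is exactly 1 because the vote sees
    only within-sample orderings.
    """
    if reps < 1:
        raise DataError("reps must be >= 1")
    for point in perturbation_grid:
        unknown = set(point) - {"monotone", "noise_sd", "dropout"}
        if unknown:
            raise DataError(f"unknown perturbation keys {sorted(unknown)}")
    clean_vote = vote_classify(expr, signature).labels
    clean_quant = None
    if comparator_spec is not None:
        clean_quant = quant_score_classify(expr, comparator_spec)[0].labels

    rng = np.random.default_rng(seed)
    vote_conc: list[float] = []
    quant_conc: list[float | None] = []
    for point in perturbation_grid:
        v_acc, q_acc = [], []
        for _ in range(reps):
            sub = int(rng.integers(0, 2**31 - 1))
            perturbed = expr
            if point.get("monotone"):
                perturbed = apply_monotone_distortion(
                    perturbed, family=point["monotone"], seed=sub
                )
            if point.get("noise_sd") or point.get("dropout"):
                perturbed = degrade_samples(
                    perturbed,
                    noise_sd=point.get("noise_sd", 0.0),
                    dropout_fraction=point.get("dropout", 0.0),
                    seed=sub + 1,
                )
            v_labels = vote_classify(perturbed, signature).labels
            v_acc.append(float((v_labels == clean_vote).mean()))
            if comparator_spec is not None:
                q_labels = quant_score_classify(perturbed, comparator_spec)[0].labels
                q_acc.append(float((q_labels == clean_quant).mean()))
        vote_conc.append(float(np.mean(v_acc)))
        quant_conc.append(float(np.mean(q_acc)) if q_acc else None)
    return RobustnessReport(
        settings=list(perturbation_grid),
        vote_concordance=vote_conc,
        comparator_concordance=quant_conc,
        replicates=reps,
        seed=seed,
    )
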