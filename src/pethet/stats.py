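"""Correlation screening and ROC analysis of texture features vs response.

The screening stage mirrors a conventional biomarker workup: Spearman rank
correlation of each per-patient, per-site feature against the clinical
deltas (two-sided, alpha = 0.05, no multiplicity correction -- the number of
tests performed is reported instead); features that correlate with the PSA
delta are then taken to ROC analysis against the binary responder label.

AUC is the Mann-Whitney statistic (ties count 1/2) with the Hanley-McNeil
standard error and a normal-approximation confidence interval; the operating
point is chosen by maximizing the Youden index J = sensitivity +
specificity - 1 over all candidate thresholds. The reported orientation is
chosen so the AUC of the reported test is >= 0.5, and the direction
("greater" / "less_equal") is always recorded explicitly.

The default positive class is the *non-responder* (risk-type orientation),
which is what makes predictive values reproducible from printed
sensitivity/specificity with a 28-positive / 42-negative split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "AUCResult",
    "ROCResult",
    "CombinedTestResult",
    "VolumeIndependenceResult",
    "ScreenConfig",
    "ScreenResult",
    "spearman",
    "roc_auc",
    "hanley_mcneil_se",
    "youden_cutoff",
    "confusion_metrics",
    "combined_and_rule",
    "volume_independence",
    "roc_curve_points",
    "run_screen",
]

SCREEN_FEATURES = ("entropy", "homogeneity", "cov", "contrast", "size_variation", "suv_mean")


@dataclass
class CorrelationResult:
    feature_name: str
    clinical_name: str
    rs: float
    p_value: float
    n: int


@dataclass
class AUCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    positive_n: int
    negative_n: int


@dataclass
class ROCResult:
    feature_name: str
    auc: float
    se: float
    ci_low: float
    ci_high: float
    youden_cutoff: float
    direction: str  # 'greater': positive if score > cutoff; 'less_equal': if score <= cutoff
    youden_j: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    positive_n: int
    negative_n: int
    tp: int
    fp: int
    tn: int
    fn: int
    tied_cutoffs: tuple = ()

    @property
    def cutoff_display(self) -> str:
        op = ">" if self.direction == "greater" else "<="
        return f"{op}{self.youden_cutoff:g}"


@dataclass
class CombinedTestResult:
    sensitivity_combined: float
    specificity_combined: float
    rule: str = "AND"


@dataclass
class VolumeIndependenceResult:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def spearman(
    feature_values, clinical_deltas, feature_name: str = "", clinical_name: str = ""
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Average ranks are used for ties. A constant input vector has no defined
    rank correlation and raises.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(clinical_deltas, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1D vectors")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant input vector")
    res = sps.spearmanr(x, y)
    return CorrelationResult(
        feature_name=feature_name,
        clinical_name=clinical_name,
        rs=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be paired 1D vectors")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both classes non-empty, got {n_pos} positive / {n_neg} negative")
    return scores, labels, n_pos, n_neg


def _mann_whitney_auc(scores, labels, n_pos, n_neg) -> float:
    # rank-sum formulation; midranks handle ties as 1/2-credit pairs
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a nonparametric AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(scores, labels, ci_level: float = 0.95) -> AUCResult:
    """Nonparametric AUC with Hanley-McNeil SE and a normal-approx CI.

    AUC equals the probability that a random positive outscores a random
    negative, with ties counted half. The CI is clipped to [0, 1] (clipping
    is logged).
    """
    scores, labels, n_pos, n_neg = _check_labels(scores, labels)
    auc = _mann_whitney_auc(scores, labels, n_pos, n_neg)
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = auc - z * se, auc + z * se
    if lo < 0.0 or hi > 1.0:
        logger.info("AUC confidence interval [%.4f, %.4f] clipped to [0, 1]", lo, hi)
    return AUCResult(
        auc=auc, se=se,
        ci_low=float(max(lo, 0.0)), ci_high=float(min(hi, 1.0)),
        positive_n=n_pos, negative_n=n_neg,
    )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV from a 2x2 table (NaN if undefined)."""
    def _ratio(a, b):
        return float(a) / float(b) if b > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def youden_cutoff(scores, labels, feature_name: str = "", ci_level: float = 0.95) -> ROCResult:
    """Youden-optimal operating point with full confusion metrics.

    Candidate thresholds are the midpoints between adjacent distinct scores
    plus -inf and +inf; the direction is chosen so the reported test has
    AUC >= 0.5. Ties in J are broken toward the cutoff of smallest absolute
    value (all maximizers are reported in ``tied_cutoffs``).
    """
    scores, labels, n_pos, n_neg = _check_labels(scores, labels)
    auc_res = roc_auc(scores, labels, ci_level=ci_level)
    direction = "greater" if auc_res.auc >= 0.5 else "less_equal"
    oriented = scores if direction == "greater" else -scores
    # test is "positive if oriented score > t"
    uniq = np.unique(oriented)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate(([-np.inf], mids, [np.inf]))

    best_j, best = -np.inf, []
    for t in cands:
        pred = oriented > t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, [(t, tp, fp, tn, fn)]
        elif abs(j - best_j) <= 1e-12:
            best.append((t, tp, fp, tn, fn))

    def _orig(t: float) -> float:
        return t if direction == "greater" else -t

    best.sort(key=lambda rec: (abs(_orig(rec[0])), _orig(rec[0])))
    t, tp, fp, tn, fn = best[0]
    cutoff = _orig(t)
    metrics = confusion_metrics(tp, fp, tn, fn)
    auc_rep = auc_res.auc if direction == "greater" else 1.0 - auc_res.auc
    se = hanley_mcneil_se(auc_rep, n_pos, n_neg)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    return ROCResult(
        feature_name=feature_name,
        auc=auc_rep,
        se=se,
        ci_low=float(max(auc_rep - z * se, 0.0)),
        ci_high=float(min(auc_rep + z * se, 1.0)),
        youden_cutoff=float(cutoff),
        direction=direction,
        youden_j=float(best_j),
        **metrics,
        positive_n=n_pos,
        negative_n=n_neg,
        tp=tp, fp=fp, tn=tn, fn=fn,
        tied_cutoffs=tuple(float(_orig(rec[0])) for rec in best),
    )


def combined_and_rule(
    sens1: float, spec1: float, sens2: float, spec2: float
) -> CombinedTestResult:
    """Combine two tests with an AND rule under conditional independence.

    Declaring positive only when both tests are positive multiplies the
    sensitivities and multiplies the false-positive rates:
    sens_c = sens1*sens2, spec_c = 1 - (1-spec1)(1-spec2).
    """
    for name, v in (("sens1", sens1), ("spec1", spec1), ("sens2", sens2), ("spec2", spec2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return CombinedTestResult(
        sensitivity_combined=float(sens1 * sens2),
        specificity_combined=float(1.0 - (1.0 - spec1) * (1.0 - spec2)),
    )


def volume_independence(feature_values, volumes) -> VolumeIndependenceResult:
    """Pearson correlation and least-squares fit of a feature against volume."""
    x = np.asarray(volumes, dtype=np.float64)
    y = np.asarray(feature_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired 1D vectors with n >= 3")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return VolumeIndependenceResult(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
    )


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) for 'score > threshold' tests."""
    scores, labels, n_pos, n_neg = _check_labels(scores, labels)
    uniq = np.unique(scores)
    thresholds = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    rows = []
    for t in thresholds:
        pred = scores > t
        rows.append(
            {
                "threshold": t,
                "sensitivity": (pred & labels).sum() / n_pos,
                "specificity": (~pred & ~labels).sum() / n_neg,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScreenConfig:
    """Settings for the full correlation + ROC screen."""

    alpha: float = 0.05
    positive_class: str = "non_responder"  # or "responder"
    features: tuple = SCREEN_FEATURES
    clinical_deltas: tuple = ("delta_psa", "delta_ap", "delta_bap")
    roc_clinical: str = "delta_psa"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.positive_class not in ("non_responder", "responder"):
            raise ValueError("positive_class must be 'non_responder' or 'responder'")
        if self.roc_clinical not in self.clinical_deltas:
            raise ValueError("roc_clinical must be one of clinical_deltas")


@dataclass
class ScreenResult:
    """Bundle of screening outputs: correlation table, ROC results, counts."""

    correlations: pd.DataFrame
    roc_results: list
    n_tests: int
    config: ScreenConfig

    def correlation_table(self, clinical: str = "delta_psa", site: str = "bone") -> pd.DataFrame:
        """Feature-vs-one-delta correlation table for one site."""
        sel = self.correlations
        sel = sel[(sel["clinical"] == clinical) & (sel["site"] == site)]
        return sel[["feature", "clinical", "rs", "p_value", "n"]].reset_index(drop=True)

    def roc_table(self) -> pd.DataFrame:
        rows = []
        for site, r in self.roc_results:
            rows.append(
                {
                    "site": site,
                    "feature": r.feature_name,
                    "auc": r.auc,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "cutoff": r.cutoff_display,
                }
            )
        return pd.DataFrame(
            rows, columns=["site", "feature", "auc", "se", "ci_low", "ci_high", "cutoff"]
        )

    def outcome_table(self) -> pd.DataFrame:
        rows = []
        for site, r in self.roc_results:
            rows.append(
                {
                    "site": site,
                    "feature": r.feature_name,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "ppv": r.ppv,
                    "npv": r.npv,
                }
            )
        return pd.DataFrame(
            rows, columns=["site", "feature", "sensitivity", "specificity", "ppv", "npv"]
        )


def run_screen(
    patient_features: pd.DataFrame,
    clinical_deltas: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Spearman-screen every (site, feature, delta) and ROC the survivors.

    ``patient_features`` holds one row per (patient_id, site) with feature
    columns; ``clinical_deltas`` is the per-patient output of
    :func:`pethet.response.compute_deltas`. Features whose Spearman p-value
    against the configured PSA delta falls below alpha proceed to ROC
    analysis versus the responder label. Deterministic given inputs.
    """
    config = config or ScreenConfig()
    merged = patient_features.merge(clinical_deltas, on="patient_id", how="inner")
    if merged.empty:
        raise ValueError("no patients shared between feature and clinical tables")

    sites = [s for s in ("bone", "lymph_node", "other") if s in set(merged["site"])]
    corr_rows = []
    n_tests = 0
    for site in sites:
        sub = merged[merged["site"] == site]
        for feature in config.features:
            for clinical in config.clinical_deltas:
                x = sub[feature].to_numpy()
                y = sub[clinical].to_numpy()
                note = ""
                if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                    rs = p = float("nan")
                    note = "skipped: constant input or n < 3"
                else:
                    res = spearman(x, y, feature, clinical)
                    rs, p = res.rs, res.p_value
                    n_tests += 1
                corr_rows.append(
                    {
                        "site": site, "feature": feature, "clinical": clinical,
                        "rs": rs, "p_value": p, "n": len(x), "note": note,
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    marker = config.roc_clinical.removeprefix("delta_")
    roc_results = []
    for site in sites:
        sub = merged[merged["site"] == site]
        labels = (
            ~sub[f"responder_{marker}"].to_numpy(dtype=bool)
            if config.positive_class == "non_responder"
            else sub[f"responder_{marker}"].to_numpy(dtype=bool)
        )
        if labels.all() or not labels.any():
            continue
        hits = correlations[
            (correlations["site"] == site)
            & (correlations["clinical"] == config.roc_clinical)
            & (correlations["p_value"] < config.alpha)
        ]["feature"]
        for feature in hits:
            roc_results.append(
                (site, youden_cutoff(sub[feature].to_numpy(), labels, feature, config.ci_level))
            )

    return ScreenResult(
        correlations=correlations, roc_results=roc_results, n_tests=n_tests, config=config
    )
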