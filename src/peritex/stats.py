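"""Diagnostic-ability statistics: ROC/AUC, Youden cutoffs, predictive
values, DeLong confidence intervals and paired AUC comparisons, combination
stratification, and the classical group-comparison tests.

Conventions
-----------
* AUC is the Mann-Whitney estimator (ties count 1/2); higher score means
  more disease-like.
* A test is positive when score > cutoff (strict); Youden cutoffs are
  scanned over observed score values, ties broken toward the smallest
  cutoff (maximising sensitivity).
* DeLong variance/covariance uses the structural components of the
  placement values; the CI is a normal approximation truncated to [0, 1].
* Rates are percentages; presentation rounding (1 decimal for rates,
  3 decimals for AUC) is the caller's concern except in report helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "CutoffResult",
    "ROCSummary",
    "DeLongComparison",
    "roc_auc",
    "delong_variance",
    "delong_ci",
    "delong_paired_test",
    "youden_cutoff",
    "confusion_metrics",
    "confusion_from_predictions",
    "roc_summary",
    "stratify_combination",
    "dunn_posthoc",
    "group_tests",
]


# --- confusion counts and predictive values ---------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV in percent; NaN marks an undefined
    metric (zero denominator)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def rounded(self, ndigits: int = 1) -> "ConfusionMetrics":
        return ConfusionMetrics(*(round(v, ndigits) for v in
                                  (self.sensitivity, self.specificity, self.ppv, self.npv)))


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), each as a percentage."""
    return ConfusionMetrics(
        sensitivity=_rate(counts.tp, counts.tp + counts.fn),
        specificity=_rate(counts.tn, counts.tn + counts.fp),
        ppv=_rate(counts.tp, counts.tp + counts.fp),
        npv=_rate(counts.tn, counts.tn + counts.fn),
    )


def confusion_from_predictions(predicted: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    predicted = np.asarray(predicted, bool)
    labels = np.asarray(labels, bool)
    return ConfusionCounts(
        tp=int((predicted & labels).sum()),
        fp=int((predicted & ~labels).sum()),
        tn=int((~predicted & ~labels).sum()),
        fn=int((~predicted & labels).sum()),
    )


# --- AUC and DeLong ---------------------------------------------------------


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and aligned")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValidationError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over (positive, negative) pairs of
    [s_pos > s_neg] + 0.5 [tie]."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # rank formulation: AUC = (R_pos - m(m+1)/2) / (m n), midranks handle ties
    m, n = len(pos), len(neg)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _placements(scores, labels):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimator."""
    scores, labels = _check_scores_labels(scores, labels)
    v10, v01 = _placements(scores, labels)
    if len(v10) < 2 or len(v01) < 2:
        raise ValidationError("DeLong variance needs >= 2 members per class")
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for the AUC, truncated to [0, 1].

    Degenerate variance (e.g. perfect separation) collapses to a point
    interval at the AUC.
    """
    auc = roc_auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        return (auc, auc)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    z: float
    p: float
    p_adjusted: float
    m_comparisons: int


def delong_paired_test(scores_a, scores_b, labels, m_comparisons: int = 1) -> DeLongComparison:
    """Two-sided DeLong test for paired (same-patient) AUCs, with an optional
    Bonferroni family size; adjusted p = min(1, m * p).

    Identical score vectors give z = 0 and p = 1; a zero-variance difference
    with unequal AUCs is flagged as undefined (NaN z/p).
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, labels_b = _check_scores_labels(scores_b, labels)
    if not np.array_equal(labels, labels_b):
        raise ValidationError("paired comparison requires identical labels")
    if m_comparisons < 1:
        raise ValidationError("m_comparisons must be >= 1")
    auc_a = roc_auc(scores_a, labels)
    auc_b = roc_auc(scores_b, labels)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if auc_a == auc_b:
            z, p = 0.0, 1.0
        else:
            z, p = float("nan"), float("nan")
    else:
        z = float((auc_a - auc_b) / np.sqrt(var))
        p = float(2 * sps.norm.sf(abs(z)))
    p_adj = min(1.0, m_comparisons * p) if np.isfinite(p) else float("nan")
    return DeLongComparison(auc_a, auc_b, z, p, p_adj, m_comparisons)


# --- Youden cutoff and ROC summary ------------------------------------------


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    j: float
    sensitivity: float  # percent, at "score > cutoff"
    specificity: float


def youden_cutoff(scores, labels) -> CutoffResult:
    """Cutoff maximising J = sens + spec - 1 under the rule "positive iff
    score > cutoff", scanned at observed score values; ties broken toward
    the smallest cutoff."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for c in np.unique(scores):
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    j, c, sens, spec = best
    return CutoffResult(cutoff=float(c), j=float(j),
                        sensitivity=100 * sens, specificity=100 * spec)


@dataclass(frozen=True)
class ROCSummary:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    j: float
    n: int


def roc_summary(scores, labels, level: float = 0.95) -> ROCSummary:
    """Per-feature diagnostic summary: AUC with DeLong CI, Youden cutoff and
    the predictive values at that cutoff."""
    scores, labels = _check_scores_labels(scores, labels)
    auc = roc_auc(scores, labels)
    lo, hi = delong_ci(scores, labels, level)
    cut = youden_cutoff(scores, labels)
    counts = confusion_from_predictions(scores > cut.cutoff, labels)
    met = confusion_metrics(counts)
    return ROCSummary(
        auc=auc, ci_low=lo, ci_high=hi, cutoff=cut.cutoff,
        sensitivity=met.sensitivity, specificity=met.specificity,
        ppv=met.ppv, npv=met.npv, j=cut.j, n=len(scores),
    )


# --- combination stratification ---------------------------------------------


def stratify_combination(
    feature_values,
    feature_cutoff: float,
    node_findings,
    labels,
) -> pd.DataFrame:
    """Metastasis rates in the four strata (feature <=/> cutoff) x (node
    finding -/+).

    ``node_findings`` is binary (1 = positive read / SUVmax above its own
    cutoff); rows with a missing finding are excluded and their number
    reported in the frame's ``attrs['n_excluded']``.
    """
    feat = np.asarray(feature_values, dtype=float)
    node = np.asarray(node_findings, dtype=float)
    lab = np.asarray(labels).astype(float)
    if not (len(feat) == len(node) == len(lab)):
        raise ValidationError("inputs must be aligned")
    keep = ~np.isnan(node) & ~np.isnan(feat)
    n_excluded = int((~keep).sum())
    feat, node, lab = feat[keep], node[keep].astype(int), lab[keep].astype(int)
    rows = []
    for above in (False, True):
        for positive in (False, True):
            sel = ((feat > feature_cutoff) == above) & ((node == 1) == positive)
            total = int(sel.sum())
            met = int(lab[sel].sum())
            rows.append({
                "feature_stratum": f"> {feature_cutoff:g}" if above else f"<= {feature_cutoff:g}",
                "node_finding": "positive" if positive else "negative",
                "metastatic": met,
                "total": total,
                "rate_pct": _rate(met, total),
            })
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


# --- group comparison tests --------------------------------------------------


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str | None = None) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests for all group pairs after a
    Kruskal-Wallis test, with tie correction; unadjusted by default,
    ``adjust='bonferroni'`` multiplies by the number of pairs."""
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if any(len(d) < 2 for d in data):
        raise ValidationError("each group needs >= 2 observations")
    alln = np.concatenate(data)
    ranks = sps.rankdata(alln)
    big_n = len(alln)
    _, tie_counts = np.unique(alln, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (big_n - 1))
    sigma2_base = big_n * (big_n + 1) / 12.0 - tie_term
    mean_ranks, sizes, start = {}, {}, 0
    for g, d in zip(names, data):
        mean_ranks[g] = ranks[start:start + len(d)].mean()
        sizes[g] = len(d)
        start += len(d)
    rows = []
    pairs = [(a, b) for k, a in enumerate(names) for b in names[k + 1:]]
    for a, b in pairs:
        se = np.sqrt(sigma2_base * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * len(pairs)) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p),
                     "p_adjusted": float(p_adj)})
    return pd.DataFrame(rows)


def group_tests(
    cohort: pd.DataFrame,
    feature: str,
    contralateral_feature: str | None = None,
) -> dict:
    """The classical comparison battery for one feature column.

    Returns a dict of test results; tests whose grouping columns are absent
    or degenerate (a group with n < 2) are reported as skipped with a
    reason rather than raising.
    """
    if feature not in cohort.columns:
        raise ValidationError(f"feature column {feature!r} not in cohort")
    out: dict = {}
    x = cohort[feature].to_numpy(dtype=float)

    if contralateral_feature is not None and contralateral_feature in cohort.columns:
        y = cohort[contralateral_feature].to_numpy(dtype=float)
        diffs = x - y
        if np.allclose(diffs.std(), 0.0):
            # identical (or uniformly shifted by 0) pairs: no evidence at all
            t, p = 0.0, 1.0
            if not np.allclose(diffs.mean(), 0.0):
                t, p = float("nan"), float("nan")
        else:
            t, p = sps.ttest_rel(x, y)
        out["paired_t_peri_vs_contra"] = {"statistic": float(t), "p": float(p)}

    lab = cohort["label_metastasis"].to_numpy(dtype=int)
    g1, g0 = x[lab == 1], x[lab == 0]
    if min(len(g1), len(g0)) >= 2:
        t, p = sps.ttest_ind(g1, g0, equal_var=True)
        out["ttest_metastasis"] = {"statistic": float(t), "p": float(p)}
    else:
        out["ttest_metastasis"] = {"skipped": "a metastasis class has n < 2"}

    if "group" in cohort.columns:
        groups = {g: x[cohort["group"].to_numpy() == g] for g in cohort["group"].unique()}
        if len(groups) >= 3 and all(len(v) >= 2 for v in groups.values()):
            h, p = sps.kruskal(*groups.values())
            out["kruskal_visual_groups"] = {"statistic": float(h), "p": float(p)}
            out["dunn_visual_groups"] = dunn_posthoc(groups)
        else:
            out["kruskal_visual_groups"] = {"skipped": "need >= 3 groups with n >= 2"}

    if "subtype" in cohort.columns:
        groups = {g: x[cohort["subtype"].to_numpy() == g] for g in cohort["subtype"].unique()}
        if len(groups) >= 3 and all(len(v) >= 2 for v in groups.values()):
            h, p = sps.kruskal(*groups.values())
            out["kruskal_subtypes"] = {"statistic": float(h), "p": float(p)}
            out["dunn_subtypes"] = dunn_posthoc(groups)
        ct = pd.crosstab(cohort["subtype"], cohort["label_metastasis"])
        if ct.shape[0] >= 2 and (ct.to_numpy() > 0).all():
            chi2, p, dof, _ = sps.chi2_contingency(ct.to_numpy(), correction=False)
            out["chi2_subtype_metastasis"] = {"statistic": float(chi2), "p": float(p),
                                              "dof": int(dof)}

    if "tumor_size_cm" in cohort.columns and cohort["tumor_size_cm"].notna().sum() >= 3:
        sel = cohort["tumor_size_cm"].notna()
        rho, p = sps.spearmanr(cohort.loc[sel, "tumor_size_cm"], x[sel.to_numpy()])
        out["spearman_tumor_size"] = {"rho": float(rho), "p": float(p)}

    return out
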