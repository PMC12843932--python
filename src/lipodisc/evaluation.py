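"""Classifier performance metrics and metric-distribution comparisons.

SCH is the positive class and BD the negative class throughout.  The
confusion counts follow that convention: ``T_SCH`` are correctly classified
SCH observations, ``F_BD`` SCH observations misclassified as BD, ``T_BD``
correctly classified BD, and ``F_SCH`` BD observations misclassified as SCH.

Metrics::

    accuracy    = (T_SCH + T_BD) / n
    sensitivity = T_SCH / (T_SCH + F_BD)
    specificity = T_BD / (F_SCH + T_BD)
    class_error = (1 - sensitivity + 1 - specificity) / 2
    AUROC       = rank-based (Mann-Whitney) estimate, ties counted 1/2
    RMSECV      = sqrt(mean((yhat_cv - y)^2)) on the 0/1 coding

Distribution summaries use the adjusted Fisher-Pearson skewness and
small-sample-adjusted excess kurtosis; ensemble-vs-ensemble comparisons use
one-tailed Wilcoxon rank-sum tests (exact for small tie-free samples, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class MetricError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    T_SCH: int
    T_BD: int
    F_SCH: int
    F_BD: int


@dataclass
class MetricRecord:
    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    class_error: float = np.nan
    auroc: float = np.nan
    rmsecv: float = np.nan


def confusion_metrics(labels, predicted) -> tuple[ConfusionCounts, MetricRecord]:
    """Confusion counts and threshold-based metrics for SCH/BD labels."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise MetricError("labels and predictions differ in length")
    is_sch = labels == "SCH"
    is_bd = labels == "BD"
    if not is_sch.any() or not is_bd.any():
        raise MetricError("both classes must appear in the true labels")
    counts = ConfusionCounts(
        T_SCH=int(np.sum(is_sch & (predicted == "SCH"))),
        T_BD=int(np.sum(is_bd & (predicted == "BD"))),
        F_SCH=int(np.sum(is_bd & (predicted == "SCH"))),
        F_BD=int(np.sum(is_sch & (predicted == "BD"))),
    )
    n = len(labels)
    sens = counts.T_SCH / (counts.T_SCH + counts.F_BD)
    spec = counts.T_BD / (counts.F_SCH + counts.T_BD)
    rec = MetricRecord(
        accuracy=(counts.T_SCH + counts.T_BD) / n,
        sensitivity=sens,
        specificity=spec,
        class_error=((1.0 - sens) + (1.0 - spec)) / 2.0,
    )
    return counts, rec


def auroc(scores, labels) -> float:
    """Rank-based AUROC: P(score of a random SCH > score of a random BD)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "SCH"]
    neg = scores[labels == "BD"]
    if pos.size == 0 or neg.size == 0:
        raise MetricError("both classes must be present for AUROC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def rmsecv(yhat_cv, y_coded) -> float:
    """Root mean square error of cross-validated continuous predictions."""
    yhat_cv = np.asarray(yhat_cv, dtype=float)
    y_coded = np.asarray(y_coded, dtype=float)
    if yhat_cv.size == 0:
        raise MetricError("empty prediction vector")
    if yhat_cv.shape != y_coded.shape:
        raise MetricError("length mismatch")
    return float(np.sqrt(np.mean((yhat_cv - y_coded) ** 2)))


# ---------------------------------------------------------------------------
# Distribution summaries and comparisons
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    median: float
    mean: float
    skewness: float
    excess_kurtosis: float
    n: int
    degenerate: bool = False


def summarize_distribution(values) -> DistributionSummary:
    """Median/mean plus adjusted Fisher-Pearson skewness and excess kurtosis."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise MetricError("need at least 3 values to summarize")
    if np.isclose(v.std(ddof=1), 0.0):
        return DistributionSummary(
            float(np.median(v)), float(v.mean()), 0.0, 0.0, v.size, degenerate=True
        )
    return DistributionSummary(
        median=float(np.median(v)),
        mean=float(v.mean()),
        skewness=float(stats.skew(v, bias=False)),
        excess_kurtosis=float(stats.kurtosis(v, bias=False)),
        n=v.size,
    )


def compare_distributions_ranksum(a, b, tail: str = "right", alpha: float = 0.01):
    """One-tailed Wilcoxon rank-sum comparison of two metric distributions.

    ``tail="right"`` tests whether ``a`` tends to exceed ``b``;
    ``tail="left"`` the reverse.  Exact null distribution for small tie-free
    samples (n ≤ 20 each), normal approximation with tie correction
    otherwise.  Returns (statistic, p, significant at ``alpha``).
    """
    if tail not in {"left", "right"}:
        raise ValueError("tail must be 'left' or 'right'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        # permitted for exact small-sample checks in tests, but warn-free
        pass
    alternative = "greater" if tail == "right" else "less"
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


# ---------------------------------------------------------------------------
# LV-count selection
# ---------------------------------------------------------------------------

def select_lv_count(table, subsample, max_lv: int = 10, n_orth_choices=None) -> tuple[int, dict]:
    """Most frequently optimal total LV count over a subsampled CV ensemble.

    For every CV model of the ensemble, OPLS-DA fits with total LV = 2..max_lv
    (one predictive plus 1..max_lv−1 orthogonal components) are evaluated;
    per model, the LV minimizing RMSECV, the LV minimizing class error and
    the LV maximizing AUROC are each recorded as votes.  Returns the modal
    total LV (smallest on ties) and the vote histogram.
    """
    from .opls import bayes_thresholds, code_labels, fit_opls_da, predict_opls
    from .preprocess_qc import autoscale

    if max_lv < 2:
        raise ValueError("max_lv must be >= 2")
    lv_values = list(range(2, max_lv + 1))
    values = table.intensities
    labels = table.obs_meta["class_label"].to_numpy()
    y_all = code_labels(labels)
    ind_ids = table.obs_meta["individual_id"].to_numpy()
    iter1, iter2, F = subsample.iter1, subsample.iter2, subsample.F
    votes: dict[int, int] = {lv: 0 for lv in lv_values}

    for m in range(iter1 * iter2):
        part = subsample.partitions[m // iter2]
        fold_rows = np.array([part.fold_of_individual[i] for i in ind_ids])
        yhat_by_lv = {lv: np.full(table.n_obs, np.nan) for lv in lv_values}
        ok = True
        for f in range(1, F + 1):
            train = subsample.mask[m * F + (f - 1)]
            test = fold_rows == f
            y_train = y_all[train]
            if np.unique(y_train).size < 2:
                ok = False
                break
            X_train, params = autoscale(values[train])
            X_test = (values[test] - params.means) / params.sds
            for lv in lv_values:
                model = fit_opls_da(X_train, y_train, n_orth=lv - 1)
                yhat_by_lv[lv][test] = predict_opls(model, X_test)
        if not ok:
            continue
        recs = {}
        for lv in lv_values:
            yhat = yhat_by_lv[lv]
            thr = bayes_thresholds(yhat, labels)
            _, rec = confusion_metrics(labels, thr.classify(yhat))
            rec.auroc = auroc(yhat, labels)
            rec.rmsecv = rmsecv(yhat, y_all)
            recs[lv] = rec
        votes[min(lv_values, key=lambda lv: (recs[lv].rmsecv, lv))] += 1
        votes[min(lv_values, key=lambda lv: (recs[lv].class_error, lv))] += 1
        votes[max(lv_values, key=lambda lv: (recs[lv].auroc, -lv))] += 1

    best = min(votes, key=lambda lv: (-votes[lv], lv))
    return best, votes
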