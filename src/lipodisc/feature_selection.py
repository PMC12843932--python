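"""VIP/Borda feature ranking, validation curves, iterative subsetting,
best-model selection, permutation testing and PCA confirmation.

The selection pipeline is a wrapper method around the OPLS-DA classifier:

1. every model of a subsampled CV ensemble orders the features by its VIP
   scores; the orderings are aggregated by Borda count (a feature earns one
   point per feature ranked below it, per model);
2. validation curves evaluate cumulative prefixes of the aggregated ranking
   with independent CV ensembles per prefix size; curves start at
   ``n_lv + 1`` features (a model needs more features than components);
3. an iterative refinement locates the curve's best point, truncates the
   ranking there, repositions plateau features to the front to expose their
   (lack of) contribution, and removes features whose removal does not
   degrade the achievable optimum — reverting and locking a feature when it
   does (stepwise-backward-elimination flavour);
4. the final biomarker call is the VIP > 1 rule in the best model of a CV
   ensemble restricted to the smallest surviving subset, the best model
   being chosen by modal-histogram-bin intersection over accuracy,
   sensitivity and specificity with AUROC as the final arbiter.

Label permutation for the overfitting check is performed at the individual
level (all replicates of an individual keep a common permuted label), so the
permutation null respects the replicate dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricRecord, auroc, confusion_metrics, rmsecv
from .io_datamodel import FeatureTable
from .opls import code_labels, fit_opls_da, predict_opls
from .outlier_screen import PcaModel, fit_classical_pca
from .preprocess_qc import autoscale
from .resampling import CvEnsemble, make_block_folds, make_subsample_index, run_cv_ensemble


def _derive_seed(*parts) -> int:
    """Deterministic child seed below 2**31 from integer parts."""
    ss = np.random.SeedSequence(list(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class CvConfig:
    """Ensemble geometry used by the selection stages."""

    n_models: int = 100
    F: int = 5
    n_orth: int = 2
    seed: int = 0

    def split(self) -> tuple[int, int]:
        """Factor n_models into (iter1, iter2) with iter1 ≈ n_models/10."""
        iter1 = max(1, self.n_models // 10)
        iter2 = max(1, int(np.ceil(self.n_models / iter1)))
        return iter1, iter2


def make_ensemble(
    table: FeatureTable,
    cv: CvConfig,
    feature_subset=None,
    seed: int | None = None,
    compute_vip: bool = True,
) -> CvEnsemble:
    """Build a fold partition, subsampling index and CV ensemble in one go."""
    seed = cv.seed if seed is None else seed
    iter1, iter2 = cv.split()
    folds = make_block_folds(table, cv.F, seed=_derive_seed(seed, 1))
    sub = make_subsample_index(table, folds, iter1, iter2, seed=_derive_seed(seed, 2))
    return run_cv_ensemble(
        table, sub, n_orth=cv.n_orth, feature_subset=feature_subset, compute_vip=compute_vip
    )


# ---------------------------------------------------------------------------
# Borda aggregation
# ---------------------------------------------------------------------------

@dataclass
class RankedFeatureList:
    """Aggregated feature ordering, best first."""

    order: np.ndarray              # permutation of feature indices
    borda_score: np.ndarray        # per feature, aggregate score
    mean_vip: np.ndarray | None    # per feature, tie-break provenance
    provenance: int                # number of rankings aggregated


def aggregate_ranks_borda(rankings, mean_vip=None) -> RankedFeatureList:
    """Borda-count aggregation of feature rankings.

    ``rankings`` is a sequence of permutations (best-first feature indices)
    over one common feature set.  The Borda score of feature j is the total
    number of features ranked below it across rankings.  Output is ordered
    by descending score; ties break by descending mean VIP (when supplied),
    then by ascending feature index.
    """
    rankings = [np.asarray(r, dtype=int) for r in rankings]
    if not rankings:
        raise ValueError("no rankings to aggregate")
    p = rankings[0].size
    ref = np.arange(p)
    score = np.zeros(p)
    for r in rankings:
        if r.size != p or not np.array_equal(np.sort(r), ref):
            raise ValueError("rankings must all be permutations of the same feature set")
        # position_of[j] = rank of feature j (0 = best); award p-1-position points
        position = np.empty(p, dtype=int)
        position[r] = np.arange(p)
        score += (p - 1) - position
    vip_key = np.zeros(p) if mean_vip is None else np.asarray(mean_vip, dtype=float)
    order = np.lexsort((ref, -vip_key, -score))
    return RankedFeatureList(
        order=order,
        borda_score=score,
        mean_vip=None if mean_vip is None else vip_key,
        provenance=len(rankings),
    )


def rank_features(table: FeatureTable, cv: CvConfig) -> tuple[RankedFeatureList, CvEnsemble]:
    """Rank all features by ensemble VIP orderings aggregated by Borda count."""
    ens = make_ensemble(table, cv, compute_vip=True)
    if ens.vip_mean.shape[0] == 0:
        raise ValueError("ensemble produced no models")
    rankings = [np.argsort(-v, kind="stable") for v in ens.vip_mean]
    mean_vip = ens.vip_mean.mean(axis=0)
    return aggregate_ranks_borda(rankings, mean_vip=mean_vip), ens


# ---------------------------------------------------------------------------
# Validation curves
# ---------------------------------------------------------------------------

@dataclass
class ValidationCurve:
    subset_sizes: np.ndarray
    mean_accuracy: np.ndarray
    mean_auroc: np.ndarray
    mean_class_error: np.ndarray
    mean_rmsecv: np.ndarray

    def best_point(self) -> int:
        """Index of the best evaluated size by rank-sum across the four
        metrics (higher accuracy/AUROC, lower class error/RMSECV); ties go
        to the smallest size."""
        from scipy.stats import rankdata

        rs = (
            rankdata(-self.mean_accuracy)
            + rankdata(-self.mean_auroc)
            + rankdata(self.mean_class_error)
            + rankdata(self.mean_rmsecv)
        )
        return int(np.argmin(rs))  # argmin takes the first (smallest size) on ties


def default_size_grid(n_feat: int, start: int, dense_until: int = 16, factor: float = 1.3):
    """Coarse curve grid: step 1 up to ``dense_until``, geometric afterwards."""
    sizes = list(range(start, min(dense_until, n_feat) + 1))
    s = sizes[-1] if sizes else start
    while s < n_feat:
        s = min(n_feat, max(s + 1, int(round(s * factor))))
        sizes.append(s)
    return np.array(sizes, dtype=int)


def validation_curve(
    table: FeatureTable,
    ranked: RankedFeatureList,
    cv: CvConfig,
    n_models_per_point: int | None = None,
    sizes=None,
) -> ValidationCurve:
    """Mean CV metrics over cumulative prefixes of the ranked feature list.

    Each prefix size is evaluated with an independent ensemble whose seed is
    derived from (master seed, size), so points are statistically
    independent.  The first evaluated size is ``n_lv + 1``.
    """
    n_lv = 1 + cv.n_orth
    start = n_lv + 1
    order = np.asarray(ranked.order, dtype=int) if isinstance(
        ranked, RankedFeatureList
    ) else np.asarray(ranked, dtype=int)
    if sizes is None:
        sizes = default_size_grid(order.size, start)
    sizes = np.asarray(sorted({int(s) for s in sizes if start <= s <= order.size}))
    if sizes.size == 0:
        raise ValueError("no evaluable subset sizes")
    point_cv = CvConfig(
        n_models=n_models_per_point or cv.n_models, F=cv.F, n_orth=cv.n_orth, seed=cv.seed
    )
    acc, auc, cerr, rms = [], [], [], []
    for s in sizes:
        ens = make_ensemble(
            table,
            point_cv,
            feature_subset=order[:s],
            seed=_derive_seed(cv.seed, 101, s),
            compute_vip=False,
        )
        acc.append(ens.metric_values("accuracy").mean())
        auc.append(ens.metric_values("auroc").mean())
        cerr.append(ens.metric_values("class_error").mean())
        rms.append(ens.metric_values("rmsecv").mean())
    return ValidationCurve(
        sizes, np.array(acc), np.array(auc), np.array(cerr), np.array(rms)
    )


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class FeatureSubset:
    """A candidate subset: ordered member indices plus selection metadata."""

    member_indices: np.ndarray
    metrics_at_selection: MetricRecord
    vip_over_threshold: np.ndarray | None = None


def _detect_plateau(curve: ValidationCurve, epsilon: float, min_run: int = 5):
    """First maximal run of ≥min_run consecutive evaluated sizes whose mean
    AUROC changes by < epsilon step to step; returns (i_start, i_end) or None."""
    d = np.abs(np.diff(curve.mean_auroc))
    flat = d < epsilon
    run_start = None
    for i, ok in enumerate(flat):
        if ok and run_start is None:
            run_start = i
        if (not ok or i == len(flat) - 1) and run_start is not None:
            run_end = i if not ok else i + 1
            if run_end - run_start + 1 >= min_run:
                return run_start, run_end
            run_start = None
    return None


def _record_at(curve: ValidationCurve, idx: int) -> MetricRecord:
    return MetricRecord(
        accuracy=float(curve.mean_accuracy[idx]),
        auroc=float(curve.mean_auroc[idx]),
        class_error=float(curve.mean_class_error[idx]),
        rmsecv=float(curve.mean_rmsecv[idx]),
    )


def refine_subsets(
    table: FeatureTable,
    ranked: RankedFeatureList,
    cv: CvConfig,
    n_models_per_point: int = 100,
    epsilon: float = 0.002,
    plateau_min_run: int = 5,
    max_passes: int = 3,
    max_trials_per_pass: int = 10,
) -> tuple[RankedFeatureList, list[FeatureSubset]]:
    """Iterative plateau repositioning and pruning of the ranked list.

    Per pass: (1) evaluate the validation curve and truncate the list at its
    best point; (2) detect a plateau of flat mean-AUROC steps and flat-or-
    worse steps in the dense early region (a feature whose arrival raises no
    metric — e.g. a collinear duplicate of an earlier feature — is a removal
    candidate directly); (3) reposition the plateau's features to the front
    and re-evaluate — plateau features whose arrival at the front raises no
    metric's mean by more than epsilon also
    become removal candidates; (4) each candidate is removed singly and the
    curve re-run: if the best achievable point worsens on *any* of the four
    metrics by more than epsilon the removal is reverted and the feature
    locked (when classes are fully separable AUROC/accuracy saturate, so the
    unsaturated RMSECV is the effective guard); (5) stop when a pass changes
    nothing or ``max_passes`` is reached.  Candidate subsets (the prefix at
    each pass's best point) are returned in decreasing size.
    """
    order = list(int(j) for j in ranked.order)
    locked: set[int] = set()
    subsets: list[FeatureSubset] = []
    n_lv = 1 + cv.n_orth

    def curve_of(feat_order, seed_tag):
        rl = np.asarray(feat_order, dtype=int)
        return validation_curve(
            table,
            RankedFeatureList(rl, np.zeros(rl.size), None, 0),
            CvConfig(cv.n_models, cv.F, cv.n_orth, _derive_seed(cv.seed, seed_tag)),
            n_models_per_point=n_models_per_point,
        )

    def best_profile(curve: ValidationCurve) -> MetricRecord:
        return _record_at(curve, curve.best_point())

    def worsened(before: MetricRecord, after: MetricRecord) -> bool:
        return (
            before.accuracy - after.accuracy > epsilon
            or before.auroc - after.auroc > epsilon
            or after.class_error - before.class_error > epsilon
            or after.rmsecv - before.rmsecv > epsilon
        )

    for pass_i in range(max_passes):
        changed = False
        curve = curve_of(order, 300 + pass_i)
        best_idx = curve.best_point()
        best_size = int(curve.subset_sizes[best_idx])
        if best_size < len(order):
            order = order[:best_size]
            changed = True
        subsets.append(
            FeatureSubset(np.array(order[:best_size]), _record_at(curve, best_idx))
        )

        # flat-or-worse arrivals in the dense early region of the curve
        early_candidates: list[int] = []
        for t in range(1, len(curve.subset_sizes)):
            s_prev, s_cur = int(curve.subset_sizes[t - 1]), int(curve.subset_sizes[t])
            if s_cur != s_prev + 1 or s_cur > len(order):
                continue
            gain = max(
                curve.mean_accuracy[t] - curve.mean_accuracy[t - 1],
                curve.mean_auroc[t] - curve.mean_auroc[t - 1],
                curve.mean_class_error[t - 1] - curve.mean_class_error[t],
                curve.mean_rmsecv[t - 1] - curve.mean_rmsecv[t],
            )
            feat = order[s_cur - 1]
            if gain <= epsilon and feat not in locked:
                early_candidates.append(feat)

        plateau = _detect_plateau(curve, epsilon, plateau_min_run)
        plateau_candidates: list[int] = []
        if plateau is not None and len(order) > n_lv + 2:
            i0, i1 = plateau
            lo = int(curve.subset_sizes[i0])
            hi = min(int(curve.subset_sizes[i1]), len(order))
            plateau_feats = [f for f in order[lo:hi] if f not in locked]
            if plateau_feats:
                rest = [f for f in order if f not in set(plateau_feats)]
                fronted = plateau_feats + rest
                front_sizes = range(n_lv + 1, min(n_lv + 1 + len(plateau_feats), len(fronted)) + 1)
                curve2 = validation_curve(
                    table,
                    RankedFeatureList(np.array(fronted), np.zeros(len(fronted)), None, 0),
                    CvConfig(cv.n_models, cv.F, cv.n_orth, _derive_seed(cv.seed, 400 + pass_i)),
                    n_models_per_point=n_models_per_point,
                    sizes=list(front_sizes),
                )
                gains = {}
                for t in range(1, len(curve2.subset_sizes)):
                    feat = fronted[int(curve2.subset_sizes[t]) - 1]
                    gain = max(
                        curve2.mean_accuracy[t] - curve2.mean_accuracy[t - 1],
                        curve2.mean_auroc[t] - curve2.mean_auroc[t - 1],
                        curve2.mean_class_error[t - 1] - curve2.mean_class_error[t],
                        curve2.mean_rmsecv[t - 1] - curve2.mean_rmsecv[t],
                    )
                    gains[feat] = gain
                plateau_candidates = [f for f, g in gains.items() if g <= epsilon]

        seen: set[int] = set()
        candidates = [
            f
            for f in early_candidates + plateau_candidates
            if f in order and not (f in seen or seen.add(f))
        ][:max_trials_per_pass]
        if candidates:
            # baseline under the same derived seed as the trials, so the
            # revert comparison is not cross-seed noise
            baseline = best_profile(curve_of(order, 500 + pass_i))
            for feat in candidates:
                if len(order) <= n_lv + 2:
                    break
                trial = [f for f in order if f != feat]
                t_prof = best_profile(curve_of(trial, 500 + pass_i))
                if worsened(baseline, t_prof):
                    locked.add(feat)  # removal hurt: revert and lock
                else:
                    order = trial
                    baseline = t_prof
                    changed = True
        if not changed:
            break

    # final curve on the surviving order; smallest subset = prefix at best point
    final_curve = curve_of(order, 900)
    fb = final_curve.best_point()
    subsets.append(
        FeatureSubset(
            np.array(order[: int(final_curve.subset_sizes[fb])]),
            _record_at(final_curve, fb),
        )
    )
    # deduplicate by size, keep decreasing order
    uniq: dict[int, FeatureSubset] = {}
    for s in subsets:
        uniq[len(s.member_indices)] = s
    subsets = [uniq[k] for k in sorted(uniq, reverse=True)]
    revised = RankedFeatureList(
        np.array(order), np.zeros(len(order)), None, ranked.provenance
    )
    return revised, subsets


# ---------------------------------------------------------------------------
# Best-model selection and the final biomarker call
# ---------------------------------------------------------------------------

def select_best_model(
    ensemble: CvEnsemble, bin_width: float = 0.02
) -> tuple[int, MetricRecord]:
    """Pick the ensemble model in the most frequent metric ranges.

    Histograms (fixed ``bin_width``) of accuracy, sensitivity and
    specificity define modal bins; the candidate set is the intersection of
    models in all three modal bins, relaxed to ≥2 then ≥1 modal-bin
    membership when empty.  Among candidates the highest AUROC wins; ties go
    to the lowest model index.
    """
    if not ensemble.records:
        raise ValueError("empty ensemble")
    metrics = ["accuracy", "sensitivity", "specificity"]
    edges = np.arange(0.0, 1.0 + 2 * bin_width, bin_width)
    in_modal = []
    for name in metrics:
        v = ensemble.metric_values(name)
        which = np.clip(np.digitize(v, edges) - 1, 0, len(edges) - 2)
        counts = np.bincount(which, minlength=len(edges) - 1)
        modal = int(np.argmax(counts))
        in_modal.append(which == modal)
    in_modal = np.array(in_modal)  # (3, n_models)
    n_hits = in_modal.sum(axis=0)
    for need in (3, 2, 1):
        cand = np.flatnonzero(n_hits >= need)
        if cand.size:
            break
    aucs = ensemble.metric_values("auroc")[cand]
    best = int(cand[np.argmax(aucs)])  # argmax takes first (lowest index) on ties
    return best, ensemble.records[best]


def biomarkers_by_vip(
    table: FeatureTable, subset: FeatureSubset, cv: CvConfig, vip_threshold: float = 1.0
) -> tuple[FeatureSubset, int, CvEnsemble]:
    """Final biomarker call: features with VIP > threshold in the best model
    of an ensemble restricted to the subset."""
    ens = make_ensemble(
        table, cv, feature_subset=subset.member_indices, seed=_derive_seed(cv.seed, 7)
    )
    best_idx, best_rec = select_best_model(ens)
    vips = ens.vip_mean[best_idx]
    over = subset.member_indices[vips > vip_threshold]
    out = FeatureSubset(subset.member_indices, best_rec, vip_over_threshold=over)
    return out, best_idx, ens


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    table: FeatureTable,
    subset=None,
    n_perm: int = 500,
    cv: CvConfig | None = None,
    seed: int = 0,
) -> dict:
    """Individual-level label-permutation test against overfitting.

    For the observed labels and for each of ``n_perm`` permutations of the
    class labels over *individuals* (replicates move together), a reduced CV
    ensemble is refit and the cross-validated fraction of y-variance
    explained (Q²-style) recorded, along with the calibration fraction (R²)
    and the |correlation| between permuted and true label vectors.  The
    empirical p-value is ``(1 + #{perm Q² ≥ observed Q²}) / (n_perm + 1)``.

    Exchangeability of label assignments requires the CV geometry to ignore
    the labels, so the fold partitions here are *not* class-stratified, and
    — being label-independent — the scaled training/test splits are computed
    once and reused across permutations.  Training splits that end up
    single-class under some assignment are skipped for that assignment.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    cv = cv or CvConfig(n_models=20)
    values = table.intensities
    if subset is not None:
        sub_idx = subset.member_indices if isinstance(subset, FeatureSubset) else np.asarray(subset)
        values = values[:, np.asarray(sub_idx, dtype=int)]
    inds = table.individuals()
    ind_ids = inds["individual_id"].to_numpy()
    true_class = inds["class_label"].to_numpy()
    ind_pos = {i: k for k, i in enumerate(ind_ids)}
    ind_of_row = np.array([ind_pos[i] for i in table.obs_meta["individual_id"]])

    iter1, iter2 = cv.split()
    folds = make_block_folds(table, cv.F, seed=_derive_seed(seed, 11), stratify=False)
    sub = make_subsample_index(
        table, folds, iter1, iter2, seed=_derive_seed(seed, 12), stratify=False
    )

    # cache scaled splits (label-independent)
    splits = []
    for m in range(iter1 * iter2):
        part = sub.partitions[m // iter2]
        fold_of_ind = np.array([part.fold_of_individual[i] for i in ind_ids])
        model_splits = []
        for f in range(1, cv.F + 1):
            train = sub.mask[m * cv.F + (f - 1)]
            test = fold_of_ind[ind_of_row] == f
            X_train, params = autoscale(values[train])
            X_test = (values[test] - params.means) / params.sds
            model_splits.append(
                (X_train, X_test, ind_of_row[train], np.flatnonzero(test))
            )
        splits.append(model_splits)

    def ensemble_stats(class_of_ind: np.ndarray) -> tuple[float, float]:
        y_row = code_labels(class_of_ind[ind_of_row])
        q2s, r2s = [], []
        for model_splits in splits:
            yhat = np.full(table.n_obs, np.nan)
            r2_folds = []
            ok = True
            for X_train, X_test, train_inds, test_rows in model_splits:
                y_train = code_labels(class_of_ind[train_inds])
                if np.unique(y_train).size < 2:
                    ok = False
                    break
                model = fit_opls_da(X_train, y_train, n_orth=cv.n_orth)
                yhat[test_rows] = predict_opls(model, X_test)
                res = y_train - model.fitted()
                tss = np.sum((y_train - y_train.mean()) ** 2)
                r2_folds.append(1.0 - np.sum(res**2) / tss)
            if not ok:
                continue
            tss = np.sum((y_row - y_row.mean()) ** 2)
            q2s.append(1.0 - np.sum((yhat - y_row) ** 2) / tss)
            r2s.append(float(np.mean(r2_folds)))
        if not q2s:
            return -np.inf, -np.inf
        return float(np.mean(q2s)), float(np.mean(r2s))

    q2_obs, r2_obs = ensemble_stats(true_class)
    rng = np.random.default_rng(_derive_seed(seed, 13))
    y_true_rows = code_labels(true_class[ind_of_row])
    perm_q2, perm_r2, perm_corr = [], [], []
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(ind_ids))
        perm_class = true_class[perm]
        q2p, r2p = ensemble_stats(perm_class)
        yp = code_labels(perm_class[ind_of_row])
        corr = abs(float(np.corrcoef(yp, y_true_rows)[0, 1]))
        perm_q2.append(q2p)
        perm_r2.append(r2p)
        perm_corr.append(corr)
        if q2p >= q2_obs:
            exceed += 1
    return {
        "q2_observed": q2_obs,
        "r2_observed": r2_obs,
        "q2_permuted": np.array(perm_q2),
        "r2_permuted": np.array(perm_r2),
        "label_correlation": np.array(perm_corr),
        "p_value": (1 + exceed) / (n_perm + 1),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# PCA confirmation
# ---------------------------------------------------------------------------

def pca_confirmation(table: FeatureTable, subset=None, n_components: int = 4) -> dict:
    """Classical PCA on the (subset-restricted) autoscaled data with a
    class-separation statistic: the standardized mean difference of class
    scores on each leading component, compared against the all-features PCA.
    """
    labels = table.obs_meta["class_label"].to_numpy()

    def fit(values) -> tuple[PcaModel, np.ndarray]:
        X, _ = autoscale(values)
        k = min(n_components, X.shape[0] - 1, X.shape[1])
        model = fit_classical_pca(X, k)
        smd = np.empty(k)
        for c in range(k):
            s = model.scores[:, c]
            a, b = s[labels == "SCH"], s[labels == "BD"]
            pooled = np.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                / (a.size + b.size - 2)
            )
            smd[c] = abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        return model, smd

    full_model, full_smd = fit(table.intensities)
    if subset is None:
        sub_model, sub_smd = full_model, full_smd
    else:
        sub_idx = subset.member_indices if isinstance(subset, FeatureSubset) else np.asarray(subset)
        sub_model, sub_smd = fit(table.intensities[:, np.asarray(sub_idx, dtype=int)])
    return {
        "model": sub_model,
        "standardized_difference": sub_smd,
        "standardized_difference_all_features": full_smd,
        "explained_variance_pct": sub_model.explained_variance_pct,
        "explained_variance_pct_all_features": full_model.explained_variance_pct,
    }
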