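"""Replicate-aware cross-validation and the two-level subsampling scheme.

The unit of independence is the individual: all technical replicates of one
individual always share a fold, so no replicate of a test individual can
leak into training.  On top of the fold partition, a two-level subsampling
scheme re-randomizes the partition ``iter1`` times and, for every partition
and fold, draws ``iter2`` training sets containing exactly one randomly
chosen replicate per training individual.  The resulting logical selection
matrix has shape ``(iter1 · iter2 · fold, N)``; test folds always contain
*all* replicates of the held-out individuals (subsampling is a training-set
construction).

``run_cv_ensemble`` turns the index into an ensemble of ``iter1 · iter2``
cross-validated OPLS-DA models, re-estimating autoscaling parameters inside
every training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import MetricRecord, auroc, confusion_metrics, rmsecv
from .io_datamodel import FeatureTable
from .opls import bayes_thresholds, code_labels, fit_opls_da, predict_opls, vip
from .preprocess_qc import autoscale

#: refuse to materialize selection matrices larger than this many cells
DEFAULT_MASK_CELL_CAP = 200_000_000


@dataclass
class FoldAssignment:
    """Mapping individual_id → fold (1..F)."""

    fold_of_individual: dict[str, int]
    F: int

    def fold_of_rows(self, table: FeatureTable) -> np.ndarray:
        return np.array(
            [self.fold_of_individual[i] for i in table.obs_meta["individual_id"]]
        )


def make_block_folds(
    table: FeatureTable, F: int, seed: int = 0, stratify: bool = True
) -> FoldAssignment:
    """Contiguous-block folds of individuals.

    With ``stratify=True`` (the default for model fitting) individuals are
    shuffled (seeded) within each class and dealt into F contiguous blocks;
    blocks from each class are matched to folds so that overall fold sizes
    differ by at most one individual, and every fold must contain both
    classes.  With ``stratify=False`` the partition ignores the labels
    entirely — required wherever exchangeability of label assignments must
    hold exactly, as in the permutation test.
    """
    inds = table.individuals()
    if F > len(inds):
        raise ValueError(f"F={F} exceeds {len(inds)} individuals")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    fold_sizes = np.zeros(F, dtype=int)
    if stratify:
        groups = [
            inds.loc[inds["class_label"] == cls, "individual_id"].to_numpy()
            for cls in sorted(inds["class_label"].unique())
        ]
    else:
        groups = [inds["individual_id"].to_numpy()]
    for ids in groups:
        ids = ids[rng.permutation(len(ids))]
        base, rem = divmod(len(ids), F)
        chunk_sizes = [base + 1] * rem + [base] * (F - rem)
        # hand the larger chunks to the currently smallest folds
        fold_order = np.argsort(fold_sizes, kind="stable")
        pos = 0
        for chunk, f in zip(chunk_sizes, fold_order):
            for ind in ids[pos : pos + chunk]:
                fold_of[ind] = int(f) + 1
            fold_sizes[f] += chunk
            pos += chunk
    assignment = FoldAssignment(fold_of, F)
    if stratify:
        cls_of = dict(zip(inds["individual_id"], inds["class_label"]))
        for f in range(1, F + 1):
            members = {cls_of[i] for i, ff in fold_of.items() if ff == f}
            for cls in set(cls_of.values()) - {"QC"}:
                if cls not in members:
                    raise ValueError(f"fold {f} contains no {cls} individuals")
    return assignment


def venetian_folds(n_obs: int, F: int, replicate_of_row=None) -> np.ndarray:
    """Venetian-blinds row assignment: row i → fold (i mod F) + 1.

    Provided for comparison runs only; it does not respect replicate
    structure.  When ``replicate_of_row`` (an individual-id per row) is
    given and replicates of one individual straddle folds, a warning is
    emitted.
    """
    if F < 2:
        raise ValueError("F must be >= 2")
    folds = (np.arange(n_obs) % F) + 1
    if replicate_of_row is not None:
        ids = np.asarray(replicate_of_row)
        for ind in pd.unique(ids):
            if np.unique(folds[ids == ind]).size > 1:
                warnings.warn(
                    "venetian blinds split replicates of one individual across folds",
                    stacklevel=2,
                )
                break
    return folds


# ---------------------------------------------------------------------------
# Two-level subsampling index
# ---------------------------------------------------------------------------

@dataclass
class SubsampleIndex:
    """Logical training-selection matrix of shape (iter1·iter2·F, N)."""

    mask: np.ndarray
    row_meta: pd.DataFrame  # iter1_index, iter2_index, fold_index
    partitions: list[FoldAssignment]
    config: dict = field(default_factory=dict)

    @property
    def iter1(self) -> int:
        return self.config["iter1"]

    @property
    def iter2(self) -> int:
        return self.config["iter2"]

    @property
    def F(self) -> int:
        return self.config["F"]


def make_subsample_index(
    table: FeatureTable,
    folds: FoldAssignment,
    iter1: int,
    iter2: int,
    seed: int = 0,
    cell_cap: int = DEFAULT_MASK_CELL_CAP,
    stratify: bool = True,
) -> SubsampleIndex:
    """Materialize the (iter1·iter2·F, N) training-selection mask.

    Partition 1 is the supplied fold assignment; every further iter1
    iteration re-randomizes the partition with a fresh seeded shuffle.  For
    each (partition, fold, iter2 draw) the mask row selects one uniformly
    chosen replicate of every individual *outside* the test fold.  Rows are
    emitted in (iter1, iter2, fold) lexicographic order.
    """
    if iter1 < 1 or iter2 < 1:
        raise ValueError("iter1 and iter2 must be >= 1")
    N = table.n_obs
    F = folds.F
    n_cells = iter1 * iter2 * F * N
    if n_cells > cell_cap:
        raise MemoryError(
            f"selection matrix would hold {n_cells} cells (cap {cell_cap}); "
            "use iter_subsample_rows() to stream rows instead"
        )
    mask = np.zeros((iter1 * iter2 * F, N), dtype=bool)
    meta_rows = []
    partitions = []
    r = 0
    for i1, part, i2, f, row in iter_subsample_rows(
        table, folds, iter1, iter2, seed, stratify=stratify
    ):
        if len(partitions) <= i1:
            partitions.append(part)
        mask[r] = row
        meta_rows.append({"iter1_index": i1 + 1, "iter2_index": i2 + 1, "fold_index": f})
        r += 1
    return SubsampleIndex(
        mask,
        pd.DataFrame(meta_rows),
        partitions,
        {"iter1": iter1, "iter2": iter2, "F": F, "seed": seed, "N": N},
    )


def iter_subsample_rows(
    table: FeatureTable,
    folds: FoldAssignment,
    iter1: int,
    iter2: int,
    seed: int = 0,
    stratify: bool = True,
):
    """Yield (iter1_idx, partition, iter2_idx, fold, boolean row) lazily."""
    inds = table.individuals()
    ind_ids = inds["individual_id"].to_numpy()
    row_positions = [np.asarray(r) for r in inds["row_positions"]]
    F = folds.F
    rng = np.random.default_rng(seed)
    for i1 in range(iter1):
        part = folds if i1 == 0 else make_block_folds(
            table, F, seed=int(rng.integers(2**31 - 1)), stratify=stratify
        )
        fold_of_ind = np.array([part.fold_of_individual[i] for i in ind_ids])
        for i2 in range(iter2):
            for f in range(1, F + 1):
                row = np.zeros(table.n_obs, dtype=bool)
                train = np.flatnonzero(fold_of_ind != f)
                picks = rng.integers(0, [len(row_positions[i]) for i in train])
                for i, pick in zip(train, picks):
                    row[row_positions[i][pick]] = True
                yield i1, part, i2, f, row


# ---------------------------------------------------------------------------
# CV ensembles
# ---------------------------------------------------------------------------

@dataclass
class CvEnsemble:
    """Cross-validated OPLS-DA models from the subsampling index.

    ``yhat_cv`` holds one complete cross-validated prediction vector per
    model; ``vip_mean`` the per-model VIP averaged over fold submodels.
    """

    records: list[MetricRecord]
    yhat_cv: np.ndarray          # (n_models, N)
    vip_mean: np.ndarray         # (n_models, n_features_used)
    thresholds: list
    feature_subset: np.ndarray | None
    n_skipped: int

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records])


def run_cv_ensemble(
    table: FeatureTable,
    subsample: SubsampleIndex,
    n_orth: int = 2,
    feature_subset=None,
    compute_vip: bool = True,
) -> CvEnsemble:
    """Fit the full ensemble of iter1·iter2 cross-validated OPLS-DA models.

    ``table`` must be on the modelling scale (imputed + log10); autoscaling
    parameters are re-estimated inside every training split, so no
    information from held-out individuals reaches the model.  Each model
    assembles one complete cross-validated ŷ vector (all replicates of all
    held-out individuals), derives Bayesian thresholds and a metric record.
    Training splits with a single class are skipped and counted.
    """
    values = table.intensities
    if np.isnan(values).any():
        raise ValueError("table must be imputed before modelling")
    if feature_subset is not None:
        feature_subset = np.asarray(feature_subset, dtype=int)
        values = values[:, feature_subset]
    labels = table.obs_meta["class_label"].to_numpy()
    y_all = code_labels(labels)
    ind_ids = table.obs_meta["individual_id"].to_numpy()

    iter1, iter2, F = subsample.iter1, subsample.iter2, subsample.F
    N = table.n_obs
    records: list[MetricRecord] = []
    thresholds = []
    yhats = []
    vips = []
    n_skipped = 0
    mask = subsample.mask
    for m in range(iter1 * iter2):
        i1 = m // iter2
        part = subsample.partitions[i1]
        fold_rows = np.array([part.fold_of_individual[i] for i in ind_ids])
        yhat = np.full(N, np.nan)
        vip_acc = np.zeros(values.shape[1])
        ok = True
        for f in range(1, F + 1):
            r = m * F + (f - 1)
            train = mask[r]
            test = fold_rows == f
            # leakage guard: a training row must never belong to the test fold
            if (train & test).any():
                raise AssertionError("train mask overlaps test fold")
            y_train = y_all[train]
            if np.unique(y_train).size < 2:
                ok = False
                break
            X_train, params = autoscale(values[train])
            model = fit_opls_da(X_train, y_train, n_orth=n_orth)
            X_test = (values[test] - params.means) / params.sds
            yhat[test] = predict_opls(model, X_test)
            if compute_vip:
                vip_acc += vip(model)
        if not ok:
            n_skipped += 1
            continue
        thr = bayes_thresholds(yhat, labels)
        predicted = thr.classify(yhat)
        _, rec = confusion_metrics(labels, predicted)
        rec.auroc = auroc(yhat, labels)
        rec.rmsecv = rmsecv(yhat, y_all)
        records.append(rec)
        thresholds.append(thr)
        yhats.append(yhat)
        vips.append(vip_acc / F)
    return CvEnsemble(
        records=records,
        yhat_cv=np.array(yhats) if yhats else np.empty((0, N)),
        vip_mean=np.array(vips) if vips else np.empty((0, values.shape[1])),
        thresholds=thresholds,
        feature_subset=feature_subset,
        n_skipped=n_skipped,
    )
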