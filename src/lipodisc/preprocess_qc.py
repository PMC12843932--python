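"""Pretreatment and quality control: imputation, log10, autoscaling, QC CV
filtering and the batch-drift check.

Canonical pretreatment order is impute → log10 → autoscale.  Imputation runs
along the observation axis within each feature column, in table row order
(replicates of one individual are adjacent), because missingness in these
tables is per-feature ion detection.  Coefficients of variation for QC
filtering are computed on raw (untransformed) intensities, the usual LC-MS
convention.  Sample statistics use the n−1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_datamodel import FeatureTable, ScalingParams


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_missing(table: FeatureTable, method: str = "linear") -> FeatureTable:
    """Fill missing cells per feature column.

    ``linear``: straight-line interpolation between the nearest non-missing
    neighbours above and below; leading/trailing gaps are filled by
    nearest-value extension (a single neighbour cannot support a line).

    ``moving_median``: a centred 3-point window over the column with missing
    entries ignored, applied only at missing positions; a window with no
    observed value falls back to nearest-value extension.

    Observed cells are never altered.
    """
    if method not in {"linear", "moving_median"}:
        raise ValueError(f"unknown imputation method {method!r}")
    values = table.intensities.copy()
    n_obs, n_feat = values.shape
    rows = np.arange(n_obs, dtype=float)
    for j in range(n_feat):
        col_missing = table.missing[:, j]
        if not col_missing.any():
            continue
        if col_missing.all():
            raise PreprocessError(
                f"feature {table.feat_meta['name'].iloc[j]!r} is entirely missing"
            )
        obs_idx = np.flatnonzero(~col_missing)
        obs_val = values[obs_idx, j]
        if method == "linear":
            # np.interp extends by the nearest value beyond the support
            filled = np.interp(rows[col_missing], obs_idx.astype(float), obs_val)
            values[col_missing, j] = filled
        else:
            col = values[:, j]
            for i in np.flatnonzero(col_missing):
                lo, hi = max(0, i - 1), min(n_obs, i + 2)
                window = col[lo:hi]
                window = window[~np.isnan(window)]
                if window.size:
                    values[i, j] = float(np.median(window))
                else:
                    nearest = obs_idx[np.argmin(np.abs(obs_idx - i))]
                    values[i, j] = values[nearest, j]
    return table.with_values(values, np.zeros_like(table.missing))


def log10_transform(table: FeatureTable) -> FeatureTable:
    """Replace every intensity x by log10(x); zeros/negatives are an error."""
    if table.missing.any():
        raise PreprocessError("log10_transform requires an imputed (complete) table")
    bad = table.intensities <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PreprocessError(
            f"non-positive intensity at obs {table.obs_meta['obs_id'].iloc[i]!r}, "
            f"feature {table.feat_meta['name'].iloc[j]!r} "
            f"({int(bad.sum())} offending cell(s))"
        )
    return table.with_values(
        np.log10(table.intensities), table.missing.copy(), transformed=True
    )


def autoscale(matrix: np.ndarray, feature_names=None) -> tuple[np.ndarray, ScalingParams]:
    """Mean-centre each column and divide by its sample standard deviation."""
    X = np.asarray(matrix, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = sds <= 0
    if zero.any():
        j = int(np.flatnonzero(zero)[0])
        name = feature_names[j] if feature_names is not None else f"column {j}"
        raise PreprocessError(f"zero-variance feature {name!r} cannot be autoscaled")
    return (X - means) / sds, ScalingParams(means, sds)


def preprocess_table(table: FeatureTable, impute_method: str = "linear") -> FeatureTable:
    """Canonical pretreatment to the modelling scale: impute then log10.

    Autoscaling is deliberately *not* applied here: centring and scaling
    depend on sample size, so each training split re-estimates them (see the
    resampling module).
    """
    return log10_transform(impute_missing(table, impute_method))


# ---------------------------------------------------------------------------
# QC coefficient-of-variation filter
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    intra_day_cv_pct: np.ndarray
    inter_day_cv_pct: np.ndarray
    retained_features: set[int]
    threshold_pct: float


def qc_cv_filter(qc: FeatureTable, threshold_pct: float = 30.0) -> QcReport:
    """Flag features whose QC coefficient of variation exceeds a threshold.

    Intra-day CV% = 100·sd/mean within each batch, averaged over batches;
    inter-day CV% = 100·sd/mean over all QC observations.  Both computed on
    raw intensities.  A feature is retained when both CVs are below the
    threshold.
    """
    if qc.missing.any():
        raise PreprocessError("QC table must be complete for CV computation")
    values = qc.intensities
    batches = qc.obs_meta["batch"].to_numpy()
    uniq = np.unique(batches)
    per_batch = []
    for b in uniq:
        rows = values[batches == b]
        if rows.shape[0] < 2:
            raise PreprocessError(f"batch {b} has fewer than 2 QC observations")
        per_batch.append(100.0 * rows.std(axis=0, ddof=1) / rows.mean(axis=0))
    intra = np.mean(per_batch, axis=0)
    inter = 100.0 * values.std(axis=0, ddof=1) / values.mean(axis=0)
    retained = {
        int(j) for j in range(qc.n_feat) if intra[j] < threshold_pct and inter[j] < threshold_pct
    }
    return QcReport(intra, inter, retained, threshold_pct)


# ---------------------------------------------------------------------------
# Batch-drift check
# ---------------------------------------------------------------------------

def batch_drift_check(
    table: FeatureTable,
    n_components: int = 2,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation test for acquisition-batch drift in PCA score space.

    PCA is run on the autoscaled log10 data; the statistic is the mean
    pairwise Euclidean distance between batch centroids in the first
    ``n_components`` scores, and its p-value comes from random permutations
    of the batch labels.
    """
    batches = table.obs_meta["batch"].to_numpy()
    uniq = np.unique(batches)
    if uniq.size < 2:
        raise PreprocessError("batch drift check needs at least 2 batches")
    for b in uniq:
        if (batches == b).sum() == 0:  # pragma: no cover - unreachable via unique
            raise PreprocessError(f"batch {b} has no observations")

    complete = impute_missing(table, "linear") if table.missing.any() else table
    X, _ = autoscale(np.log10(complete.intensities))
    # PCA scores via SVD of the centred matrix (autoscaled ⇒ already centred)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = (U * s)[:, :n_components]

    def centroid_spread(labels: np.ndarray) -> float:
        cents = np.stack([scores[labels == b].mean(axis=0) for b in uniq])
        d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
        iu = np.triu_indices(len(uniq), 1)
        return float(d[iu].mean())

    observed = centroid_spread(batches)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if centroid_spread(rng.permutation(batches)) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    per_batch_centroid = {
        int(b): scores[batches == b].mean(axis=0).tolist() for b in uniq
    }
    return {
        "statistic": observed,
        "p_value": p,
        "n_permutations": n_permutations,
        "batch_centroids": per_batch_centroid,
    }
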