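"""Outlier screening with classical PCA and ROBPCA outlier maps.

ROBPCA follows the projection-pursuit + MCD formulation: Stahel–Donoho
outlyingness over directions through pairs of data points selects an
h-subset of least outlying observations, classical PCA of that subset fixes
a k-dimensional subspace, and a reweighted minimum-covariance-determinant
fit of the projected scores supplies robust centre and eigenvalues.  Each
observation then gets a *score distance* (robust Mahalanobis distance within
the subspace) and an *orthogonal distance* (Euclidean residual to the
subspace).  Observations beyond both cutoffs — large score distance *and*
large orthogonal distance — are "bad leverage points", the operational
definition of a relevant outlier in this pipeline.

Cutoffs: SD uses sqrt(chi2(k, 0.975)); OD uses the Wilson–Hilferty normal
approximation on OD^(2/3) with median/MAD location and scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet

from .io_datamodel import FeatureTable
from .preprocess_qc import autoscale, impute_missing, log10_transform

CATEGORIES = ("regular", "good_leverage", "orthogonal_outlier", "bad_leverage")


@dataclass
class PcaModel:
    """A fitted PCA basis: loadings (p × k), scores (n × k), eigenvalues."""

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    center: np.ndarray
    explained_variance_pct: np.ndarray


@dataclass
class OutlierMap:
    score_distance: np.ndarray
    orthogonal_distance: np.ndarray
    sd_cutoff: float
    od_cutoff: float
    category: np.ndarray  # dtype=object strings from CATEGORIES


def fit_classical_pca(X: np.ndarray, k: int) -> PcaModel:
    """Standard SVD PCA of the column-centred matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    return PcaModel(
        loadings=Vt[:k].T,
        scores=(U * s)[:, :k],
        eigenvalues=eig[:k],
        center=center,
        explained_variance_pct=100.0 * eig[:k] / total,
    )


def choose_k_scree(
    eigenvalues: np.ndarray, variance_fraction: float = 0.80, k_max: int = 10
) -> int:
    """Smallest k whose cumulative eigenvalue fraction reaches the threshold.

    The fraction is computed against the sum of the *provided* eigenvalues,
    so passing a truncated spectrum interprets the scree plot locally.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    pos = eig[eig > 0]
    cum = np.cumsum(pos) / pos.sum()
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    return min(k, len(pos), k_max)


# ---------------------------------------------------------------------------
# ROBPCA
# ---------------------------------------------------------------------------

def _stahel_donoho_outlyingness(
    Z: np.ndarray, n_directions: int, rng: np.random.Generator
) -> np.ndarray:
    """Max over sampled pair-directions of |proj - median| / MAD."""
    n = Z.shape[0]
    out = np.zeros(n)
    if n <= 50:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pairs = []
    n_random = max(0, n_directions)
    idx_a = rng.integers(0, n, size=n_random)
    idx_b = rng.integers(0, n, size=n_random)
    all_pairs = pairs + [(a, b) for a, b in zip(idx_a, idx_b) if a != b]
    for i, j in all_pairs:
        v = Z[i] - Z[j]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            continue
        proj = Z @ (v / nv)
        med = np.median(proj)
        mad = np.median(np.abs(proj - med)) * 1.4826
        if mad < 1e-12:
            continue
        out = np.maximum(out, np.abs(proj - med) / mad)
    return out


def _od_cutoff(od: np.ndarray) -> float:
    """Wilson–Hilferty cutoff: OD^(2/3) is ~normal; use median/MAD + z_.975."""
    d = od ** (2.0 / 3.0)
    med = np.median(d)
    mad = np.median(np.abs(d - med)) * 1.4826
    z = stats.norm.ppf(0.975)
    return float(max(med + mad * z, 0.0) ** 1.5)


def fit_robpca(
    X: np.ndarray,
    k: int,
    alpha: float = 0.75,
    n_directions: int | None = None,
    seed: int = 0,
) -> tuple[PcaModel, OutlierMap]:
    """Robust PCA with score/orthogonal-distance outlier map.

    Parameters
    ----------
    X : matrix (n_obs × n_feat)
    k : number of robust components to retain
    alpha : coverage; h = ceil(alpha · n) observations are treated as clean
    n_directions : random pair directions for the outlyingness step
        (default 250·k; all exact pair directions are added when n ≤ 50)
    seed : direction sampling and MCD subsampling seed
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (0.5 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0.5, 1)")
    h = int(np.ceil(alpha * n))
    if h <= k:
        raise ValueError(f"h={h} must exceed k={k}")
    if n <= k + 1:
        raise ValueError("need n_obs > k + 1")
    rng = np.random.default_rng(seed)
    if n_directions is None:
        n_directions = 250 * k

    # (1) reduce to the data's affine span
    colmean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - colmean, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    B = Vt[:rank].T            # p × r basis of the span
    Z = (X - colmean) @ B      # n × r

    # (2) Stahel–Donoho outlyingness; keep the h least outlying points
    outl = _stahel_donoho_outlyingness(Z, n_directions, rng)
    keep = np.argsort(outl, kind="stable")[:h]

    # (3) classical PCA of the kept subset fixes the k-dim subspace
    mu_h = Z[keep].mean(axis=0)
    _, s_h, Vt_h = np.linalg.svd(Z[keep] - mu_h, full_matrices=False)
    Vk = Vt_h[:k].T            # r × k

    # (4) reweighted MCD of the projected scores → robust centre/eigenvalues
    T = (Z - mu_h) @ Vk
    mcd = MinCovDet(support_fraction=alpha, random_state=int(rng.integers(2**31 - 1)))
    mcd.fit(T)
    eigval, eigvec = np.linalg.eigh(mcd.covariance_)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    center_scores = mcd.location_
    Tc = T - center_scores
    sd = np.sqrt(np.maximum(np.sum((Tc @ eigvec) ** 2 / np.maximum(eigval, 1e-30), axis=1), 0.0))

    # orthogonal distances: residual to the robust subspace
    resid = (Z - mu_h) - T @ Vk.T
    od = np.linalg.norm(resid, axis=1)

    sd_cut = float(np.sqrt(stats.chi2.ppf(0.975, df=k)))
    od_cut = _od_cutoff(od)

    category = np.empty(n, dtype=object)
    big_sd = sd > sd_cut
    big_od = od > od_cut
    category[~big_sd & ~big_od] = "regular"
    category[big_sd & ~big_od] = "good_leverage"
    category[~big_sd & big_od] = "orthogonal_outlier"
    category[big_sd & big_od] = "bad_leverage"

    loadings = B @ Vk @ eigvec                       # p × k, orthonormal
    center = colmean + B @ (mu_h + Vk @ center_scores)
    scores = (X - center) @ loadings
    total_var = eigval.sum()
    model = PcaModel(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigval,
        center=center,
        explained_variance_pct=100.0 * eigval / total_var if total_var > 0 else eigval * 0,
    )
    return model, OutlierMap(sd, od, sd_cut, od_cut, category)


# ---------------------------------------------------------------------------
# Screening policy on feature tables
# ---------------------------------------------------------------------------

def screen_outliers(
    table: FeatureTable,
    policy: str = "robust_only",
    alpha: float = 0.75,
    k: int | None = None,
    k_max: int = 10,
    variance_fraction: float = 0.80,
    seed: int = 0,
) -> tuple[FeatureTable, list[dict]]:
    """Remove outlying observations from a table.

    The table is imputed, log10-transformed and autoscaled internally.  With
    ``policy="robust_only"`` the ROBPCA bad-leverage observations are
    removed; ``"robust_plus_classical"`` additionally removes observations
    whose classical-PCA score distance exceeds sqrt(chi2(k, .975)) and that
    are extreme (|score| > 3·sd) on at least one of the first k components.

    When ``k`` is None it is chosen by the scree rule on the robust
    eigenvalue spectrum (fitted once at ``k_max``).  Removed observations
    are reported by ``obs_id`` with their distances.
    """
    if policy not in {"robust_only", "robust_plus_classical"}:
        raise ValueError(f"unknown policy {policy!r}")
    complete = impute_missing(table, "linear") if table.missing.any() else table
    logged = log10_transform(complete)
    X, _ = autoscale(logged.intensities, logged.feature_names)
    n = X.shape[0]

    if k is None:
        k_probe = min(k_max, n - 2, X.shape[1])
        probe_model, _ = fit_robpca(X, k_probe, alpha=alpha, seed=seed)
        k = choose_k_scree(probe_model.eigenvalues, variance_fraction, k_max)

    _, omap = fit_robpca(X, k, alpha=alpha, seed=seed)
    remove = omap.category == "bad_leverage"
    removed: list[dict] = []
    ids = table.obs_ids
    for i in np.flatnonzero(remove):
        removed.append(
            {
                "obs_id": str(ids[i]),
                "reason": "robpca_bad_leverage",
                "score_distance": float(omap.score_distance[i]),
                "orthogonal_distance": float(omap.orthogonal_distance[i]),
            }
        )

    if policy == "robust_plus_classical":
        cpca = fit_classical_pca(X, k)
        sd_classic = np.sqrt(
            np.sum(cpca.scores**2 / np.maximum(cpca.eigenvalues, 1e-30), axis=1)
        )
        cut = float(np.sqrt(stats.chi2.ppf(0.975, df=k)))
        comp_sd = cpca.scores.std(axis=0, ddof=1)
        extreme = (np.abs(cpca.scores) > 3.0 * comp_sd).any(axis=1)
        classic_flag = (sd_classic > cut) & extreme & ~remove
        for i in np.flatnonzero(classic_flag):
            removed.append(
                {
                    "obs_id": str(ids[i]),
                    "reason": "classical_pca",
                    "score_distance": float(sd_classic[i]),
                    "orthogonal_distance": float(omap.orthogonal_distance[i]),
                }
            )
        remove = remove | classic_flag

    kept = table.select_obs(~remove)
    for cls in ("SCH", "BD"):
        if (table.obs_meta["class_label"] == cls).any() and not (
            kept.obs_meta["class_label"] == cls
        ).any():
            raise ValueError(f"outlier removal would empty class {cls}")
    return kept, removed
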