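"""Orthogonal PLS discriminant analysis for a two-class response.

A single binary response admits exactly one predictive component; "3 latent
variables" in this pipeline therefore means 1 predictive + 2
response-orthogonal components.  The algorithm is the standard single-y
O-PLS: each orthogonal round computes the PLS weight ``w ∝ X'y``, the
loading ``p`` of the corresponding score, strips the part of ``p`` collinear
with ``w`` to obtain an orthogonal weight, and deflates X by the resulting
orthogonal component.  The predictive component is fitted on the fully
deflated X, making its score uncorrelated with every orthogonal score.

Class coding is SCH = 1 (positive class), BD = 0.  VIP scores are computed
from the predictive component, under which ``VIP_j = sqrt(p)·|w_j|/‖w‖`` and
``Σ_j VIP_j² = p`` (number of features).  Continuous cross-validated
predictions are converted to labels by Bayesian class thresholds: Gaussian
class-conditional densities with empirical priors, the decision boundary
being the posterior-0.5 point between the class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_datamodel import ScalingParams

Y_CODING = {"SCH": 1.0, "BD": 0.0}


class OplsError(ValueError):
    pass


def code_labels(labels) -> np.ndarray:
    """Map SCH/BD labels to the 1/0 coding."""
    arr = np.asarray(labels)
    try:
        return np.array([Y_CODING[str(v)] for v in arr], dtype=float)
    except KeyError as exc:  # pragma: no cover - defensive
        raise OplsError(f"unknown class label {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_core(X: np.ndarray, yc: np.ndarray, n_orth: int):
    """O-PLS on a centred/scaled X and centred y; returns raw arrays.

    Kept free of dataclass overhead because the resampling ensembles call it
    hundreds of thousands of times.
    """
    Xd = X.copy()
    p = X.shape[1]
    W_orth = np.empty((p, n_orth))
    P_orth = np.empty((p, n_orth))
    T_orth = np.empty((X.shape[0], n_orth))
    sstot = float(np.sum(X * X))
    var_pct = []
    for a in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise OplsError("degenerate response: X'y vanished during deflation")
        w /= nw
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nwo = np.linalg.norm(w_o)
        if nwo < 1e-10:
            raise OplsError(
                f"no orthogonal variation left for component {a + 1}; reduce n_orth"
            )
        w_o /= nwo
        t_o = Xd @ w_o
        tt = t_o @ t_o
        if tt < 1e-24:
            raise OplsError(f"orthogonal score {a + 1} collapsed; reduce n_orth")
        p_o = Xd.T @ t_o / tt
        Xd -= np.outer(t_o, p_o)
        W_orth[:, a] = w_o
        P_orth[:, a] = p_o
        T_orth[:, a] = t_o
        var_pct.append(100.0 * tt * (p_o @ p_o) / sstot)

    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise OplsError("degenerate response: predictive weight vanished")
    w /= nw
    t = Xd @ w
    tt = t @ t
    p_load = Xd.T @ t / tt
    q = (yc @ t) / tt
    var_pct.insert(0, 100.0 * tt * (p_load @ p_load) / sstot)
    return w, t, p_load, q, W_orth, P_orth, T_orth, np.array(var_pct)


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (1 predictive + ``n_orth`` orthogonal components)."""

    w_pred: np.ndarray
    p_pred: np.ndarray
    t_pred: np.ndarray
    q: float
    W_orth: np.ndarray
    P_orth: np.ndarray
    T_orth: np.ndarray
    y_mean: float
    n_orth: int
    variance_captured_pct: np.ndarray
    scaling: ScalingParams | None = None
    vip_mode: str = "predictive"
    n_pred: int = 1
    y_coding: dict = field(default_factory=lambda: dict(Y_CODING))

    @property
    def vip(self) -> np.ndarray:
        return vip(self)

    def fitted(self) -> np.ndarray:
        """Fitted ŷ on the 0–1 coding scale."""
        return self.t_pred * self.q + self.y_mean


def fit_opls_da(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int = 2,
    scaling: ScalingParams | None = None,
) -> OplsModel:
    """Fit OPLS-DA on an autoscaled matrix and a 0/1-coded response.

    ``y`` is centred internally; both classes must be present.  ``scaling``
    may carry the autoscaling parameters used on X so that new data can be
    brought to the training scale at prediction time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise OplsError("X and y length mismatch")
    if np.unique(y).size < 2:
        raise OplsError("both classes must be present in y")
    if n_orth < 0:
        raise OplsError("n_orth must be >= 0")
    y_mean = float(y.mean())
    yc = y - y_mean
    w, t, p_load, q, W_o, P_o, T_o, var_pct = _fit_core(X, yc, n_orth)
    return OplsModel(
        w_pred=w, p_pred=p_load, t_pred=t, q=float(q),
        W_orth=W_o, P_orth=P_o, T_orth=T_o,
        y_mean=y_mean, n_orth=n_orth, variance_captured_pct=var_pct,
        scaling=scaling,
    )


def predict_opls(model: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous ŷ for new data already on the training (autoscaled) scale.

    Orthogonal variation is removed component-by-component before the
    predictive component is applied; adding the stored y mean returns ŷ on
    the 0–1 coding scale.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.w_pred.shape[0]:
        raise OplsError(
            f"feature count mismatch: model has {model.w_pred.shape[0]}, "
            f"data has {X_new.shape[1]}"
        )
    Xd = X_new.copy()
    for a in range(model.n_orth):
        t_o = Xd @ model.W_orth[:, a]
        Xd -= np.outer(t_o, model.P_orth[:, a])
    t = Xd @ model.w_pred
    return t * model.q + model.y_mean


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection.

    ``"predictive"`` mode (default) scores features by the single predictive
    component, giving ``VIP_j = sqrt(p)·|w_j|/‖w‖``; ``"total"`` applies the
    SSY-weighted multi-component formula over predictive plus orthogonal
    components (orthogonal components explain essentially no y-variance, so
    both modes agree up to numerical noise).
    """
    p = model.w_pred.shape[0]
    if model.vip_mode == "predictive":
        w = model.w_pred
        return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)
    # SSY-weighted over all components
    weights = [model.w_pred] + [model.W_orth[:, a] for a in range(model.n_orth)]
    scores = [model.t_pred] + [model.T_orth[:, a] for a in range(model.n_orth)]
    ssy = []
    # y-variance explained by each component's regression on y
    yc = model.t_pred * model.q  # predictive contribution (centred scale)
    for t in scores:
        tt = float(t @ t)
        qa = float((yc @ t) / tt) if tt > 0 else 0.0
        ssy.append(qa**2 * tt)
    num = np.zeros(p)
    for w_a, s_a in zip(weights, ssy):
        num += s_a * (w_a / np.linalg.norm(w_a)) ** 2
    total = sum(ssy)
    if total <= 0:
        return np.ones(p)
    return np.sqrt(p * num / total)


# ---------------------------------------------------------------------------
# Bayesian class thresholds
# ---------------------------------------------------------------------------

@dataclass
class ClassThresholds:
    threshold_sch: float
    threshold_bd: float
    class_densities: dict  # class -> (mean, sd, prior)

    def classify(self, yhat: np.ndarray) -> np.ndarray:
        """Argmax-posterior class labels for continuous predictions."""
        yhat = np.asarray(yhat, dtype=float)
        m1, s1, pi1 = self.class_densities["SCH"]
        m0, s0, pi0 = self.class_densities["BD"]
        log_post1 = np.log(pi1) - np.log(s1) - 0.5 * ((yhat - m1) / s1) ** 2
        log_post0 = np.log(pi0) - np.log(s0) - 0.5 * ((yhat - m0) / s0) ** 2
        return np.where(log_post1 >= log_post0, "SCH", "BD")


def bayes_thresholds(yhat_cv: np.ndarray, labels) -> ClassThresholds:
    """Gaussian class-conditional decision boundary for continuous ŷ.

    Fits per-class normal densities with empirical priors to the
    cross-validated predictions and locates the ŷ value where the two
    posteriors are equal (the root between the class means when the
    discriminant quadratic has two).  Reported per class on each class's own
    coding scale, so for symmetric data the two thresholds sum to 1.
    """
    yhat_cv = np.asarray(yhat_cv, dtype=float)
    labels = np.asarray(labels)
    dens = {}
    n = len(labels)
    for cls in ("SCH", "BD"):
        vals = yhat_cv[labels == cls]
        if vals.size < 2:
            raise OplsError(f"class {cls} has fewer than 2 predictions; sd undefined")
        dens[cls] = (float(vals.mean()), float(vals.std(ddof=1)), vals.size / n)
    m1, s1, pi1 = dens["SCH"]
    m0, s0, pi0 = dens["BD"]

    # roots of the quadratic log pi1 N(m1,s1) = log pi0 N(m0,s0)
    a = 0.5 * (1.0 / s0**2 - 1.0 / s1**2)
    b = m1 / s1**2 - m0 / s0**2
    c = 0.5 * (m0**2 / s0**2 - m1**2 / s1**2) + np.log((pi1 * s0) / (pi0 * s1))
    if abs(a) < 1e-12:
        boundary = -c / b
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            boundary = (m0 + m1) / 2.0  # densities never cross between means
        else:
            roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
            mid = (m0 + m1) / 2.0
            boundary = float(roots[np.argmin(np.abs(roots - mid))])
    return ClassThresholds(
        threshold_sch=float(boundary),
        threshold_bd=float(1.0 - boundary),
        class_densities=dens,
    )
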