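"""Synthetic serum-lipidomics cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two patient classes (SCH and BD) measured in technical triplicate,
multiplicative (log-normal) intensity noise, a small set of planted
class-discriminative lipid features (optionally gender-specific), planted
outlier individuals, completely-at-random missingness, and a multi-batch
acquisition structure with pooled QC injections.

Intensity model, on the log10 scale, for individual *i*, replicate *r*,
feature *f* in batch *b*::

    log10 x = base_f + batch_{b,f} + effect_f * 1[class(i) = SCH, gender match]
              + bio_{i,f} + tech_{i,r,f} (+ outlier_{i,f} if i is planted)

with ``base_f ~ U(3, 7)``, ``batch ~ N(0, batch_shift_sd_log10^2)``,
``bio ~ N(0, noise_sd_log10^2)`` shared by an individual's replicates,
``tech ~ N(0, replicate_sd_log10^2)`` per row, and
``outlier ~ N(0, outlier_shift_sd^2)`` per planted individual.  Everything
planted is recorded in a :class:`GroundTruth`.

Default sizes mirror the study design this package targets: 31 BD + 30 SCH
individuals in triplicate (183 rows) over 183 features and 4 batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_datamodel import FeatureTable


@dataclass
class Biomarker:
    """A planted class-discriminative feature.

    ``effect_log10`` is the SCH-minus-BD mean shift on the log10 scale;
    ``gender_specificity`` restricts the shift to one gender ("M"/"F") or
    applies it to everyone ("both").
    """

    feature_index: int
    effect_log10: float
    gender_specificity: str = "both"


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Noise defaults: biological between-individual spread of 0.2 log10 units
    and technical replicate spread of 0.05 log10 units (a raw-scale CV of
    roughly ``ln(10) * 0.05 = 12%``, inside the usual QC acceptance band),
    with a mild 0.02 log10 batch effect.
    """

    n_bd: int = 31
    n_sch: int = 30
    n_replicates: int = 3
    n_features: int = 183
    n_batches: int = 4
    female_fraction: float = 0.5
    biomarkers: list[Biomarker] = field(default_factory=list)
    noise_sd_log10: float = 0.2
    replicate_sd_log10: float = 0.05
    missing_rate: float = 0.0
    n_outlier_individuals: int = 0
    outlier_shift_sd: float = 1.0
    batch_shift_sd_log10: float = 0.02
    base_log10_range: tuple[float, float] = (3.0, 7.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_bd, self.n_sch, self.n_replicates, self.n_features, self.n_batches) < 1:
            raise ValueError("cohort counts must be positive")
        if self.n_outlier_individuals < 0:
            raise ValueError("n_outlier_individuals must be >= 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must lie in [0, 1]")
        for bm in self.biomarkers:
            if not (0 <= bm.feature_index < self.n_features):
                raise ValueError(f"biomarker index {bm.feature_index} out of range")
            if bm.gender_specificity not in {"both", "M", "F"}:
                raise ValueError("gender_specificity must be 'both', 'M' or 'F'")
        if self.n_outlier_individuals > self.n_bd + self.n_sch:
            raise ValueError("more outlier individuals than individuals")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    biomarker_indices: set[int]
    outlier_individual_ids: set[str]
    outlier_obs_ids: set[str]
    true_effect_log10: np.ndarray  # per feature, SCH-minus-BD shift ("both" scope)
    effects_by_gender: dict[str, np.ndarray]  # per-gender realized shift vectors


def _feature_metadata(n_features: int, rng: np.random.Generator) -> pd.DataFrame:
    # ~183 features mapping onto ~129 annotated metabolites: assign adduct
    # suffixes so several features can share one metabolite id.
    n_metab = max(1, int(round(n_features * 129 / 183)))
    metab_of_feature = np.sort(rng.integers(0, n_metab, size=n_features))
    mz = np.sort(rng.uniform(250.0, 1000.0, size=n_features))
    rt = rng.uniform(0.5, 25.0, size=n_features)
    rows = []
    seen: dict[int, int] = {}
    for j in range(n_features):
        m = int(metab_of_feature[j])
        adduct = seen.get(m, 0)
        seen[m] = adduct + 1
        suffix = f" A{adduct + 1}" if seen[m] > 1 or adduct > 0 else ""
        rows.append(
            {
                "feature_id": j,
                "name": f"LIPID{m:03d}{suffix}",
                "mz": round(float(mz[j]), 4),
                "rt": round(float(rt[j]), 2),
                "metabolite_id": f"MET{m:03d}",
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(cfg: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a synthetic cohort table and its ground truth.

    Deterministic: the same config (including seed) yields a bit-identical
    table.  Rows are ordered by individual (BD first, then SCH), replicates
    adjacent; batches are contiguous blocks of rows in acquisition order.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_bd + cfg.n_sch
    n_obs = n_ind * cfg.n_replicates
    p = cfg.n_features

    classes = np.array(["BD"] * cfg.n_bd + ["SCH"] * cfg.n_sch)
    genders = np.where(rng.random(n_ind) < cfg.female_fraction, "F", "M")
    individual_ids = np.array([f"{classes[i]}{i + 1:03d}" for i in range(n_ind)])

    base = rng.uniform(*cfg.base_log10_range, size=p)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd_log10, size=(cfg.n_batches, p))
    bio = rng.normal(0.0, cfg.noise_sd_log10, size=(n_ind, p))
    tech = rng.normal(0.0, cfg.replicate_sd_log10, size=(n_obs, p))

    # planted class effects, possibly gender-specific
    effect_both = np.zeros(p)
    effect_by_gender = {"M": np.zeros(p), "F": np.zeros(p)}
    for bm in cfg.biomarkers:
        if bm.gender_specificity == "both":
            effect_both[bm.feature_index] += bm.effect_log10
            effect_by_gender["M"][bm.feature_index] += bm.effect_log10
            effect_by_gender["F"][bm.feature_index] += bm.effect_log10
        else:
            effect_by_gender[bm.gender_specificity][bm.feature_index] += bm.effect_log10

    outlier_inds = rng.choice(n_ind, size=cfg.n_outlier_individuals, replace=False)
    outlier_shift = np.zeros((n_ind, p))
    for i in outlier_inds:
        outlier_shift[i] = rng.normal(0.0, cfg.outlier_shift_sd, size=p)

    # assemble per-row log10 intensities; batches are contiguous blocks of a
    # randomized acquisition order (triplicates run back-to-back), so batch
    # membership is not confounded with class
    ind_of_row = np.repeat(np.arange(n_ind), cfg.n_replicates)
    acq_order_ind = rng.permutation(n_ind)
    acq_rank_of_ind = np.empty(n_ind, dtype=int)
    acq_rank_of_ind[acq_order_ind] = np.arange(n_ind)
    acq_rank_of_row = acq_rank_of_ind[ind_of_row] * cfg.n_replicates + np.tile(
        np.arange(cfg.n_replicates), n_ind
    )
    batch_of_row = np.minimum(
        (acq_rank_of_row * cfg.n_batches) // n_obs, cfg.n_batches - 1
    ) + 1
    log_x = (
        base[None, :]
        + batch_shift[batch_of_row - 1]
        + bio[ind_of_row]
        + tech
        + outlier_shift[ind_of_row]
    )
    is_sch_row = classes[ind_of_row] == "SCH"
    gender_row = genders[ind_of_row]
    log_x[is_sch_row & (gender_row == "M")] += effect_by_gender["M"]
    log_x[is_sch_row & (gender_row == "F")] += effect_by_gender["F"]

    values = 10.0 ** log_x
    missing = rng.random((n_obs, p)) < cfg.missing_rate
    values = values.copy()
    values[missing] = np.nan

    replicate = np.tile(np.arange(1, cfg.n_replicates + 1), n_ind)
    obs_ids = np.array(
        [f"{individual_ids[ind_of_row[i]]}_r{replicate[i]}" for i in range(n_obs)]
    )
    obs_meta = pd.DataFrame(
        {
            "obs_id": obs_ids,
            "individual_id": individual_ids[ind_of_row],
            "replicate": replicate,
            "class_label": classes[ind_of_row],
            "gender": gender_row,
            "batch": batch_of_row,
        }
    )
    feat_meta = _feature_metadata(p, np.random.default_rng(cfg.seed + 1))
    table = FeatureTable(values, missing, obs_meta, feat_meta)

    outlier_ids = {individual_ids[i] for i in outlier_inds}
    truth = GroundTruth(
        biomarker_indices={bm.feature_index for bm in cfg.biomarkers},
        outlier_individual_ids=outlier_ids,
        outlier_obs_ids={
            obs_ids[i] for i in range(n_obs) if individual_ids[ind_of_row[i]] in outlier_ids
        },
        true_effect_log10=effect_both,
        effects_by_gender=effect_by_gender,
    )
    return table, truth


def generate_latent_cohort(
    seed: int = 0,
    n_per_class: int = 30,
    n_features: int = 30,
    n_replicates: int = 3,
    delta: float = 2.0,
    orth_sd: tuple[float, float] = (8.0, 3.0),
    overlap: float = 0.7,
    noise_sd: float = 0.3,
    replicate_latent_sd: float = 0.2,
) -> FeatureTable:
    """Cohort whose covariance has one predictive + two structured
    orthogonal-to-class directions, for model-complexity studies.

    The class signal lives on a single latent direction ``w1`` (individual
    scores separated by ``delta``); two further latent directions carry
    class-independent structured variance at the two *distinct* scales in
    ``orth_sd`` and each overlaps ``w1`` with cosine ``overlap``.  Distinct
    variance scales matter: equal scales form a single eigenvalue cluster
    that one extra PLS component absorbs, whereas two separated clusters
    overlapping the predictive direction require two orthogonal components —
    a total model complexity of three latent variables (1 predictive + 2
    orthogonal) for a single-response OPLS.

    Intensities are ``10^(5 + 0.1·signal)`` so the table behaves like raw
    LC-MS abundances under the standard log10/autoscale pretreatment.
    """
    rng = np.random.default_rng(seed)
    n_ind = 2 * n_per_class
    reps = n_replicates
    n = n_ind * reps
    p = n_features
    y = np.array([0] * n_per_class + [1] * n_per_class)
    u1 = delta * (y - 0.5) + rng.normal(0, 1, n_ind)
    u2 = rng.normal(0, orth_sd[0], n_ind)
    u3 = rng.normal(0, orth_sd[1], n_ind)
    Q = np.linalg.qr(rng.normal(size=(p, 3)))[0]
    w1 = Q[:, 0]
    mix_c = np.sqrt(1 - overlap**2)
    W = np.stack([w1, overlap * w1 + mix_c * Q[:, 1], overlap * w1 + mix_c * Q[:, 2]], axis=1)
    ind_of_row = np.repeat(np.arange(n_ind), reps)
    lat = np.stack([u1, u2, u3], axis=1)[ind_of_row]
    lat = lat + rng.normal(0, replicate_latent_sd, size=(n, 3))
    M = lat @ W.T + rng.normal(0, noise_sd, size=(n, p))
    values = 10.0 ** (5.0 + 0.1 * M)

    cls = np.where(y == 1, "SCH", "BD")[ind_of_row]
    ids = np.array([f"I{i:03d}" for i in range(n_ind)])
    obs_meta = pd.DataFrame(
        {
            "obs_id": [f"I{ind_of_row[i]:03d}_r{i % reps + 1}" for i in range(n)],
            "individual_id": ids[ind_of_row],
            "replicate": np.tile(np.arange(1, reps + 1), n_ind),
            "class_label": cls,
            "gender": "M",
            "batch": 1,
        }
    )
    feat_meta = pd.DataFrame(
        {
            "feature_id": range(p),
            "name": [f"F{j:03d}" for j in range(p)],
            "mz": np.arange(p) + 300.0,
            "rt": np.arange(p) * 0.1 + 1.0,
            "metabolite_id": "",
        }
    )
    return FeatureTable(values, np.zeros((n, p), dtype=bool), obs_meta, feat_meta)


def make_qc_samples(cfg: CohortConfig, n_per_batch: int) -> FeatureTable:
    """Pooled quality-control injections: a fixed profile plus technical noise.

    QC observations carry class label ``"QC"`` and are assigned to batches
    round-robin.  Their spread over replicates reflects only
    ``replicate_sd_log10`` (within batch) and ``batch_shift_sd_log10``
    (between batches), which is what a CV filter should see.
    """
    cfg.validate()
    if n_per_batch < 2:
        raise ValueError("need at least 2 QC observations per batch (CV undefined otherwise)")
    rng = np.random.default_rng(cfg.seed + 7919)
    p = cfg.n_features
    n_obs = n_per_batch * cfg.n_batches

    base = rng.uniform(*cfg.base_log10_range, size=p)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd_log10, size=(cfg.n_batches, p))
    batch_of_row = (np.arange(n_obs) % cfg.n_batches) + 1
    tech = rng.normal(0.0, cfg.replicate_sd_log10, size=(n_obs, p))
    log_x = base[None, :] + batch_shift[batch_of_row - 1] + tech
    values = 10.0 ** log_x

    rep_within = np.zeros(n_obs, dtype=int)
    counter: dict[int, int] = {}
    for i, b in enumerate(batch_of_row):
        counter[b] = counter.get(b, 0) + 1
        rep_within[i] = counter[b]
    obs_meta = pd.DataFrame(
        {
            "obs_id": [f"QC_b{b}_{r}" for b, r in zip(batch_of_row, rep_within)],
            "individual_id": [f"QCPOOL_b{b}" for b in batch_of_row],
            "replicate": rep_within,
            "class_label": "QC",
            "gender": "F",
            "batch": batch_of_row,
        }
    )
    feat_meta = _feature_metadata(p, np.random.default_rng(cfg.seed + 1))
    return FeatureTable(values, np.zeros((n_obs, p), dtype=bool), obs_meta, feat_meta)
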