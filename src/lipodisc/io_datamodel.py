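"""Core data types and the delimited-text exchange format for feature tables.

A *feature table* is the unit every stage of the pipeline consumes: an
observations × features intensity matrix (raw ion abundances) plus
per-observation metadata (individual, replicate, class, gender, batch) and
per-feature metadata (m/z, retention time, annotation name).  The unit of
statistical independence is the *individual*; each individual contributes
several technical replicate rows (triplicates in the study design this
package targets).

Missing intensities are carried as an explicit boolean mask; masked cells in
the value matrix hold NaN so they can never silently enter arithmetic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Class labels a table may carry.  ``QC`` rows are pooled quality-control
#: injections and are excluded from any discriminant modelling.
VALID_CLASSES = ("SCH", "BD", "QC")
VALID_GENDERS = ("M", "F")

#: Default mapping from logical metadata names to file column names.
DEFAULT_SCHEMA = {
    "obs_id": "obs_id",
    "individual_id": "individual_id",
    "replicate": "replicate",
    "class_label": "class_label",
    "gender": "gender",
    "batch": "batch",
}

#: Tokens treated as missing on read (the empty string always is).
DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")

OBS_META_COLUMNS = ["obs_id", "individual_id", "replicate", "class_label", "gender", "batch"]
FEAT_META_COLUMNS = ["feature_id", "name", "mz", "rt", "metabolite_id"]


class FeatureTableError(ValueError):
    """Raised when a feature table violates its structural invariants."""


@dataclass
class FeatureTable:
    """Observations × features intensity matrix with metadata.

    Parameters
    ----------
    intensities : ndarray, shape (n_obs, n_feat)
        Raw ion abundances (arbitrary units).  Cells flagged in ``missing``
        hold NaN.
    missing : ndarray of bool, shape (n_obs, n_feat)
        True where the intensity is absent.
    obs_meta : DataFrame
        One row per observation with columns ``obs_id``, ``individual_id``,
        ``replicate``, ``class_label``, ``gender``, ``batch``.
    feat_meta : DataFrame
        One row per feature with columns ``feature_id``, ``name``, ``mz``,
        ``rt``, ``metabolite_id``.
    """

    intensities: np.ndarray
    missing: np.ndarray
    obs_meta: pd.DataFrame
    feat_meta: pd.DataFrame
    #: True once the values are on a transformed (e.g. log10) scale, which
    #: lifts the raw-abundance non-negativity invariant
    transformed: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.obs_meta = self.obs_meta.reset_index(drop=True)
        self.feat_meta = self.feat_meta.reset_index(drop=True)
        self.validate()

    # -- basic shape accessors ------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_feat(self) -> int:
        return self.intensities.shape[1]

    @property
    def obs_ids(self) -> np.ndarray:
        return self.obs_meta["obs_id"].to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.feat_meta["name"])

    def validate(self) -> None:
        """Check every structural invariant; raise FeatureTableError on failure."""
        n_obs, n_feat = self.intensities.shape
        if self.missing.shape != (n_obs, n_feat):
            raise FeatureTableError("missing mask shape does not match intensities")
        if len(self.obs_meta) != n_obs:
            raise FeatureTableError("obs_meta length does not match n_obs")
        if len(self.feat_meta) != n_feat:
            raise FeatureTableError("feat_meta length does not match n_feat")
        for col in OBS_META_COLUMNS:
            if col not in self.obs_meta.columns:
                raise FeatureTableError(f"obs_meta missing column {col!r}")
        for col in FEAT_META_COLUMNS:
            if col not in self.feat_meta.columns:
                raise FeatureTableError(f"feat_meta missing column {col!r}")

        ids = self.obs_meta["obs_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FeatureTableError(f"duplicate obs_id {dup!r}")

        bad_class = ~self.obs_meta["class_label"].isin(VALID_CLASSES)
        if bad_class.any():
            raise FeatureTableError(
                f"invalid class_label {self.obs_meta['class_label'][bad_class].iloc[0]!r}"
            )
        bad_gender = ~self.obs_meta["gender"].isin(VALID_GENDERS)
        if bad_gender.any():
            raise FeatureTableError(
                f"invalid gender {self.obs_meta['gender'][bad_gender].iloc[0]!r}"
            )

        # each individual has one class, one gender, distinct replicates
        for ind, grp in self.obs_meta.groupby("individual_id", sort=False):
            if grp["class_label"].nunique() > 1:
                raise FeatureTableError(
                    f"individual {ind!r} has inconsistent class labels "
                    f"{sorted(grp['class_label'].unique())}"
                )
            if grp["gender"].nunique() > 1:
                raise FeatureTableError(f"individual {ind!r} has inconsistent genders")
            if grp["replicate"].duplicated().any():
                raise FeatureTableError(f"individual {ind!r} has duplicate replicate indices")

        observed = self.intensities[~self.missing]
        if observed.size and (np.isnan(observed).any()):
            raise FeatureTableError("non-missing cell holds NaN")
        if not self.transformed and observed.size and (observed < 0).any():
            raise FeatureTableError("negative intensity value")
        if not np.isnan(self.intensities[self.missing]).all():
            raise FeatureTableError("masked cells must hold NaN in the value matrix")

    # -- convenience ----------------------------------------------------------
    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.missing.copy(),
            self.obs_meta.copy(),
            self.feat_meta.copy(),
            self.transformed,
        )

    def with_values(
        self,
        values: np.ndarray,
        missing: np.ndarray | None = None,
        transformed: bool | None = None,
    ) -> "FeatureTable":
        """Return a new table sharing this table's metadata with new values."""
        if missing is None:
            missing = np.isnan(np.asarray(values, dtype=float))
        return FeatureTable(
            values,
            missing,
            self.obs_meta.copy(),
            self.feat_meta.copy(),
            self.transformed if transformed is None else transformed,
        )

    def select_obs(self, row_index: np.ndarray) -> "FeatureTable":
        """Subset observations (boolean or integer index), preserving order."""
        return FeatureTable(
            self.intensities[row_index],
            self.missing[row_index],
            self.obs_meta.iloc[np.arange(self.n_obs)[row_index]],
            self.feat_meta.copy(),
            self.transformed,
        )

    def select_features(self, col_index) -> "FeatureTable":
        col_index = np.asarray(col_index)
        return FeatureTable(
            self.intensities[:, col_index],
            self.missing[:, col_index],
            self.obs_meta.copy(),
            self.feat_meta.iloc[col_index],
            self.transformed,
        )

    def individuals(self) -> pd.DataFrame:
        """One row per individual with its class, gender and row positions."""
        rows = []
        for ind, grp in self.obs_meta.groupby("individual_id", sort=False):
            rows.append(
                {
                    "individual_id": ind,
                    "class_label": grp["class_label"].iloc[0],
                    "gender": grp["gender"].iloc[0],
                    "row_positions": list(grp.index),
                }
            )
        return pd.DataFrame(rows)

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        same_vals = (
            self.intensities.shape == other.intensities.shape
            and np.array_equal(self.missing, other.missing)
            and np.allclose(
                np.nan_to_num(self.intensities), np.nan_to_num(other.intensities), rtol=0, atol=0
            )
        )
        return (
            same_vals
            and self.obs_meta.equals(other.obs_meta)
            and self.feat_meta.equals(other.feat_meta)
        )


@dataclass
class ScalingParams:
    """Per-feature centering/scaling parameters removed by autoscaling."""

    means: np.ndarray
    sds: np.ndarray
    log10_applied: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if (self.sds <= 0).any():
            raise ValueError("scaling sds must be strictly positive")

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Scale a matrix on the training scale (optionally log10 first)."""
        X = np.asarray(X, dtype=float)
        if self.log10_applied:
            X = np.log10(X)
        return (X - self.means) / self.sds


# ---------------------------------------------------------------------------
# Exchange format: delimited text, metadata columns first, then features.
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_feature_table(
    path,
    schema: dict | None = None,
    na_tokens=DEFAULT_NA_TOKENS,
    delimiter: str | None = None,
) -> FeatureTable:
    """Read a feature table from delimited text.

    ``schema`` maps logical metadata names (see :data:`DEFAULT_SCHEMA`) to the
    column names used in the file; all remaining columns are features.  Empty
    cells and any token in ``na_tokens`` become missing-mask entries.
    Feature metadata (m/z, RT) is parsed from header names of the form
    ``"name | mz | rt | metabolite_id"`` when present; otherwise placeholder
    metadata is synthesised from the column order.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    meta_cols = {logical: schema[logical] for logical in DEFAULT_SCHEMA}
    for logical, col in meta_cols.items():
        if col not in df.columns:
            raise FeatureTableError(f"metadata column {col!r} (for {logical!r}) not in file")
    feature_cols = [c for c in df.columns if c not in set(meta_cols.values())]
    if not feature_cols:
        raise FeatureTableError("file contains no feature columns")

    obs_meta = pd.DataFrame(
        {logical: df[col] for logical, col in meta_cols.items()}
    )
    obs_meta["replicate"] = obs_meta["replicate"].astype(int)
    obs_meta["batch"] = obs_meta["batch"].astype(int)

    n_obs, n_feat = len(df), len(feature_cols)
    values = np.full((n_obs, n_feat), np.nan)
    missing = np.zeros((n_obs, n_feat), dtype=bool)
    na_set = set(na_tokens) | {""}
    for j, col in enumerate(feature_cols):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell in na_set:
                missing[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FeatureTableError(
                    f"non-numeric intensity {cell!r} at row {df.index[i] + 1}, column {col!r}"
                ) from None

    feat_meta = _parse_feature_headers(feature_cols)
    return FeatureTable(values, missing, obs_meta, feat_meta)


def _parse_feature_headers(headers: list[str]) -> pd.DataFrame:
    rows = []
    for j, h in enumerate(headers):
        parts = [p.strip() for p in h.split("|")]
        if len(parts) == 4:
            name, mz, rt, met = parts
            rows.append(
                {"feature_id": j, "name": name, "mz": float(mz), "rt": float(rt),
                 "metabolite_id": met}
            )
        else:
            rows.append(
                {"feature_id": j, "name": h, "mz": np.nan, "rt": np.nan, "metabolite_id": ""}
            )
    return pd.DataFrame(rows)


def _feature_header(row: pd.Series) -> str:
    if np.isnan(row["mz"]) and np.isnan(row["rt"]) and not row["metabolite_id"]:
        return str(row["name"])
    return (
        f"{row['name']} | {float(row['mz'])!r} | {float(row['rt'])!r} | {row['metabolite_id']}"
    )


def write_feature_table(table: FeatureTable, path, delimiter: str | None = None) -> None:
    """Write a table as delimited text: metadata columns first, features after.

    Missing cells are written as empty fields.  Intensities use repr-faithful
    formatting so a read/write round trip is the identity.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    headers = OBS_META_COLUMNS + [_feature_header(r) for _, r in table.feat_meta.iterrows()]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(headers)
        for i in range(table.n_obs):
            meta = [table.obs_meta.iloc[i][c] for c in OBS_META_COLUMNS]
            row = []
            for j in range(table.n_feat):
                if table.missing[i, j]:
                    row.append("")
                else:
                    row.append(repr(float(table.intensities[i, j])))
            writer.writerow(list(map(str, meta)) + row)
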