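"""Subject-by-region feature tables.

The central data container: one row per subject (patient or healthy
control) with demographic covariates, an optional Tinnitus Handicap
Inventory (THI) score, and one gray-matter volume column (mm^3) per
brain region.  Every statistic in the package — F-score ranking, SFFS
wrapper selection, SVM training, THI correlations — runs on this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"

#: canonical non-region columns, in serialization order
META_COLUMNS = ("subject_id", "group", "age", "sex", "thi")


class TableSchemaError(ValueError):
    """Raised when a feature table violates its schema invariants."""


@dataclass
class FeatureTable:
    """Subjects x regions volume table with labels and covariates.

    Parameters
    ----------
    data
        DataFrame with the columns of :data:`META_COLUMNS` followed by one
        numeric column per region (volumes in mm^3, no missing entries).
    region_names
        Region column names in canonical order.
    provenance
        One of ``"synthetic"``, ``"extracted"``, ``"loaded"``.
    """

    data: pd.DataFrame
    region_names: list[str] = field(default_factory=list)
    provenance: str = "loaded"

    def __post_init__(self) -> None:
        if not self.region_names:
            self.region_names = [
                c for c in self.data.columns if c not in META_COLUMNS
            ]
        self.data = self.data[list(META_COLUMNS) + list(self.region_names)]
        _validate(self.data, self.region_names)

    # -- accessors ---------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_patients(self) -> int:
        return int((self.data["group"] == GROUP_PATIENT).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["group"] == GROUP_CONTROL).sum())

    @property
    def labels(self) -> np.ndarray:
        """Class labels: 1 = patient (positive), 0 = control (negative)."""
        return (self.data["group"] == GROUP_PATIENT).to_numpy(dtype=np.int64)

    @property
    def volumes(self) -> np.ndarray:
        """(n_subjects, n_regions) float64 matrix in region order."""
        return self.data[self.region_names].to_numpy(dtype=np.float64)

    def patients(self) -> pd.DataFrame:
        return self.data[self.data["group"] == GROUP_PATIENT]

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.region_names == other.region_names
            and self.data.reset_index(drop=True).equals(
                other.data.reset_index(drop=True)
            )
        )


def _validate(df: pd.DataFrame, region_names: list[str]) -> None:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing required columns: {missing}")
    if len(region_names) == 0:
        raise TableSchemaError("table has no region columns")
    if len(set(region_names)) != len(region_names):
        dupes = sorted({r for r in region_names if region_names.count(r) > 1})
        raise TableSchemaError(f"duplicate region names: {dupes}")
    dup_ids = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup_ids):
        raise TableSchemaError(
            f"duplicate subject_id: {sorted(dup_ids.unique().tolist())}"
        )
    bad_groups = sorted(
        set(df["group"].unique()) - {GROUP_PATIENT, GROUP_CONTROL}
    )
    if bad_groups:
        raise TableSchemaError(f"unknown group labels: {bad_groups}")
    for g in (GROUP_PATIENT, GROUP_CONTROL):
        if not (df["group"] == g).any():
            raise TableSchemaError(f"table has no {g} subjects")
    vols = df[region_names]
    non_numeric = [
        c for c in region_names if not pd.api.types.is_numeric_dtype(vols[c])
    ]
    if non_numeric:
        raise TableSchemaError(f"non-numeric volume columns: {non_numeric}")
    arr = vols.to_numpy(dtype=np.float64)
    if np.isnan(arr).any():
        rows = df["subject_id"][np.isnan(arr).any(axis=1)].tolist()
        raise TableSchemaError(f"missing volume entries for subjects: {rows}")
    if not np.isfinite(arr).all():
        raise TableSchemaError("non-finite volume entries")
    thi_controls = df.loc[df["group"] == GROUP_CONTROL, "thi"]
    if thi_controls.notna().any():
        raise TableSchemaError("controls must not carry a THI score")


def write_table(table: FeatureTable, path) -> None:
    """Serialize to UTF-8 CSV at full float precision (round-trip exact)."""
    table.data.to_csv(path, index=False)


def read_table(path, provenance: str = "loaded") -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing required columns: {missing}")
    region_names = [c for c in df.columns if c not in META_COLUMNS]
    return FeatureTable(df, region_names, provenance=provenance)
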