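"""Tabular I/O and validation for cohort-level spatial single-cell data.

The framework consumes four plain CSV artefacts:

* a cell table (one row per segmented cell: id, image, patient, centroid
  coordinates in microns, cell-type label),
* a cell x marker expression matrix aligned to the cell table by cell id,
* an optional clinical table (patient id, survival/censoring time, event
  indicator), and
* an optional marker classification (cell-type-specific vs cell-state
  markers, used as internal controls for spillover evaluation).

Coordinates are interpreted in a per-image Cartesian frame with arbitrary
origin; only intra-image distances are ever computed, so no registration
between images is attempted. Expression values are consumed exactly as
provided by the upstream quantification — no normalisation is applied unless
the caller explicitly requests the arcsinh transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_COLUMNS = ["cell_id", "image_id", "patient_id", "x", "y", "cell_type"]

#: canonical column order of long-format result tables
RESULT_COLUMNS = [
    "cell_type_A",
    "cell_type_B",
    "marker",
    "metric",
    "mean_coef",
    "t_stat",
    "p_value",
    "p_adjusted",
    "n_patients",
]


class SchemaError(ValueError):
    """A required column is missing or misnamed."""


class IntegrityError(ValueError):
    """A dataset invariant (uniqueness, alignment, finiteness) is violated."""


@dataclass
class CellDataset:
    """A segmented-cell cohort: per-cell metadata plus a marker matrix.

    Attributes
    ----------
    cells
        DataFrame with columns ``cell_id, image_id, patient_id, x, y,
        cell_type``. ``cell_id`` is unique across the cohort and every image
        belongs to exactly one patient.
    expression
        DataFrame of non-negative marker intensities, indexed by ``cell_id``
        in the same row order as ``cells``; columns are marker names.
    """

    cells: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def markers(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cells["cell_type"].unique())

    @property
    def image_ids(self) -> list[str]:
        return list(pd.unique(self.cells["image_id"]))

    def image_view(self, image_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (cells, expression) restricted to one image, aligned."""
        mask = (self.cells["image_id"] == image_id).to_numpy()
        return self.cells.loc[mask], self.expression.loc[mask]

    def image_patient_map(self) -> pd.Series:
        return self.cells.drop_duplicates("image_id").set_index("image_id")[
            "patient_id"
        ]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"cell table missing columns: {missing}")
        dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate cell_id values: {sorted(set(dup))[:5]}")
        if len(self.expression) != len(self.cells):
            raise IntegrityError(
                f"expression has {len(self.expression)} rows for "
                f"{len(self.cells)} cells"
            )
        if not np.array_equal(
            self.expression.index.to_numpy(), self.cells["cell_id"].to_numpy()
        ):
            raise IntegrityError("expression rows not aligned to cell table by cell_id")
        if self.expression.columns.duplicated().any():
            raise IntegrityError("duplicate marker names in expression matrix")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = self.cells.loc[~np.isfinite(xy).all(axis=1), "cell_id"]
            raise IntegrityError(f"non-finite coordinates for cells {list(bad[:5])}")
        if self.cells["cell_type"].isna().any():
            bad = self.cells.loc[self.cells["cell_type"].isna(), "cell_id"]
            raise IntegrityError(f"missing cell_type for cells {list(bad[:5])}")
        img_pat = self.cells.groupby("image_id")["patient_id"].nunique()
        multi = img_pat[img_pat > 1]
        if len(multi):
            raise IntegrityError(
                f"images mapped to multiple patients: {list(multi.index[:5])}"
            )

    def transformed(self, how: str = "arcsinh", cofactor: float = 5.0) -> "CellDataset":
        """Return a copy with transformed expression (off by default everywhere)."""
        if how == "arcsinh":
            expr = np.arcsinh(self.expression / cofactor)
        elif how == "log1p":
            expr = np.log1p(self.expression)
        else:
            raise ValueError(f"unknown transform {how!r}")
        return CellDataset(self.cells.copy(), expr)


@dataclass
class ClinicalTable:
    """Patient-level survival data: time-to-event and a binary event flag."""

    table: pd.DataFrame  # columns patient_id, time, event

    def __post_init__(self) -> None:
        t = self.table
        for col in ("patient_id", "time", "event"):
            if col not in t.columns:
                raise SchemaError(f"clinical table missing column {col!r}")
        if t["patient_id"].duplicated().any():
            raise IntegrityError("duplicate patient_id in clinical table")
        if (t["time"] <= 0).any():
            bad = t.loc[t["time"] <= 0, "patient_id"]
            raise ValueError(f"non-positive survival time for patients {list(bad)}")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def patients(self) -> list[str]:
        return list(self.table["patient_id"])


@dataclass
class MarkerClassification:
    """Partition of markers into cell-type-specific and cell-state roles.

    Cell-type-specific markers are expected only in their owning cell
    type(s); found elsewhere as a proximity association they are treated as
    spillover false positives. ``owner_types`` may be empty for cell-state
    markers.
    """

    roles: dict[str, str] = field(default_factory=dict)
    owner_types: dict[str, frozenset[str]] = field(default_factory=dict)

    VALID_ROLES = ("cell_type_specific", "cell_state")

    def __post_init__(self) -> None:
        bad = {m: r for m, r in self.roles.items() if r not in self.VALID_ROLES}
        if bad:
            raise ValueError(f"invalid marker roles: {bad}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerClassification":
        if df["marker"].duplicated().any():
            raise IntegrityError("marker classified more than once")
        roles = dict(zip(df["marker"], df["role"]))
        owners = {}
        for _, row in df.iterrows():
            raw = row.get("owner_types", "")
            if pd.isna(raw):
                raw = ""
            owners[row["marker"]] = frozenset(
                t for t in str(raw).split(";") if t
            )
        return cls(roles, owners)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.roles),
                "role": [self.roles[m] for m in self.roles],
                "owner_types": [
                    ";".join(sorted(self.owner_types.get(m, ()))) for m in self.roles
                ],
            }
        )


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def load_cell_table(
    cells_path, expression_path, schema: dict[str, str] | None = None
) -> CellDataset:
    """Load a cell table and an expression matrix into a validated dataset.

    Parameters
    ----------
    schema
        Optional mapping from canonical role names (``cell_id``, ``image_id``,
        ``patient_id``, ``x``, ``y``, ``cell_type``) to the column names used
        in the file, so arbitrarily named inputs can be ingested.
    """
    cells = pd.read_csv(cells_path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        cells = cells.rename(columns=rename)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    cells = cells[CELL_COLUMNS].copy()
    cells["cell_id"] = cells["cell_id"].astype(str)
    cells["image_id"] = cells["image_id"].astype(str)
    cells["patient_id"] = cells["patient_id"].astype(str)
    cells = cells.reset_index(drop=True)

    expr = pd.read_csv(expression_path, index_col=0)
    expr.index = expr.index.astype(str)
    if len(expr) != len(cells):
        raise IntegrityError(
            f"expression has {len(expr)} rows for {len(cells)} cells"
        )
    if set(expr.index) != set(cells["cell_id"]):
        raise IntegrityError("expression cell ids do not match the cell table")
    expr = expr.loc[cells["cell_id"]]
    return CellDataset(cells, expr)


def write_cell_table(dataset: CellDataset, cells_path, expression_path) -> None:
    dataset.cells.to_csv(cells_path, index=False)
    dataset.expression.to_csv(expression_path, index_label="cell_id")


def load_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path)
    df["patient_id"] = df["patient_id"].astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, index=False)


def load_marker_classification(path) -> MarkerClassification:
    return MarkerClassification.from_frame(pd.read_csv(path))


def write_marker_classification(mc: MarkerClassification, path) -> None:
    mc.to_frame().to_csv(path, index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write a long-format result table with a deterministic row order.

    Rows sort by ascending adjusted p-value (missing last), then by cell
    type A, cell type B, and marker lexicographically, so repeated runs on
    identical inputs produce byte-identical files.
    """
    df = results.copy()
    sort_cols = [c for c in ("p_adjusted", "cell_type_A", "cell_type_B", "marker")
                 if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, na_position="last", kind="mergesort")
    df.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
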