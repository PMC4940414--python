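"""Shared data containers for replicated trait panels.

The pipeline moves through three in-memory representations:

``ReplicateProfileTable``
    Long-format raw observations (one row per line x replicate x feature)
    together with a feature annotation table. Metabolite rows carry the
    per-chromatogram internal-standard (control) intensity; enzyme rows
    carry an assay-plate identifier.
``NormalizedMatrix``
    Wide (line, replicate) x feature matrix after normalization, with a
    per-cell provenance flag distinguishing observed from imputed values.
``BlupMatrix``
    Line x feature matrix of best linear unbiased predictions of the random
    line effect, plus the per-feature grand mean needed to move back to the
    measurement scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METABOLITE = "metabolite"
ENZYME = "enzyme"

#: provenance codes used in NormalizedMatrix.provenance
OBSERVED = "observed"
IMPUTED = "imputed"

TABLE_COLUMNS = [
    "line_id",
    "replicate_id",
    "plate_id",
    "feature_id",
    "value",
    "control_value",
]


@dataclass
class ReplicateProfileTable:
    """Raw long-format trait observations plus feature annotations.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``line_id, replicate_id, plate_id, feature_id, value,
        control_value``. Missing measurements are NaN in ``value``.
    annotations : pandas.DataFrame
        Indexed by ``feature_id`` with columns ``molecular_class``
        (``metabolite`` | ``enzyme``) and ``compound_class``.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"trait table lacks columns: {missing_cols}")
        if self.annotations.index.name != "feature_id":
            if "feature_id" in self.annotations.columns:
                self.annotations = self.annotations.set_index("feature_id")
            else:
                raise ValueError("annotations must be indexed by feature_id")

    def validate(self) -> None:
        """Check the structural invariants of the table; raise ValueError."""
        dup = self.data.duplicated(["line_id", "replicate_id", "feature_id"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (line, replicate, feature) keys"
            )
        if self.data["line_id"].nunique() < 2:
            raise ValueError("need at least 2 lines")
        unknown = set(self.data["feature_id"]) - set(self.annotations.index)
        if unknown:
            raise ValueError(f"features without annotation: {sorted(unknown)}")
        classes = set(self.annotations["molecular_class"])
        if not classes <= {METABOLITE, ENZYME}:
            raise ValueError(f"unknown molecular classes: {classes}")
        met = self.features_of_class(METABOLITE)
        met_rows = self.data[self.data["feature_id"].isin(met)]
        if met_rows["control_value"].isna().any():
            bad = met_rows[met_rows["control_value"].isna()]
            raise ValueError(
                "metabolite records without control value, e.g. "
                + _describe_samples(bad)
            )
        enz = self.features_of_class(ENZYME)
        enz_rows = self.data[self.data["feature_id"].isin(enz)]
        if len(enz_rows) and enz_rows["plate_id"].isna().any():
            bad = enz_rows[enz_rows["plate_id"].isna()]
            raise ValueError(
                "enzyme records without plate id, e.g. " + _describe_samples(bad)
            )

    def features_of_class(self, molecular_class: str) -> list[str]:
        mask = self.annotations["molecular_class"] == molecular_class
        return list(self.annotations.index[mask])

    @property
    def features(self) -> list[str]:
        return list(self.annotations.index)

    def to_wide(self) -> pd.DataFrame:
        """Pivot raw values to a (line, replicate) x feature matrix."""
        wide = self.data.pivot_table(
            index=["line_id", "replicate_id"],
            columns="feature_id",
            values="value",
            aggfunc="first",
            dropna=False,
        )
        return wide.reindex(columns=self.features)

    def control_series(self) -> pd.Series:
        """Per-(line, replicate) internal-standard intensity."""
        met = self.features_of_class(METABOLITE)
        rows = self.data[self.data["feature_id"].isin(met)]
        ctl = rows.groupby(["line_id", "replicate_id"])["control_value"].first()
        return ctl


def _describe_samples(rows: pd.DataFrame, limit: int = 5) -> str:
    keys = rows[["line_id", "replicate_id", "feature_id"]].head(limit)
    return "; ".join(
        f"(line={r.line_id}, rep={r.replicate_id}, feature={r.feature_id})"
        for r in keys.itertuples()
    )


@dataclass
class NormalizedMatrix:
    """Wide normalized data with per-cell provenance.

    ``values`` is indexed by (line_id, replicate_id); ``provenance`` has the
    same shape and holds ``"observed"`` or ``"imputed"`` (missing cells carry
    ``"observed"`` until imputation fills them).
    """

    values: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                OBSERVED, index=self.values.index, columns=self.values.columns
            )

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def line_index(self) -> pd.Index:
        return self.values.index.get_level_values("line_id")

    def copy(self) -> "NormalizedMatrix":
        return NormalizedMatrix(
            self.values.copy(), self.provenance.copy(), self.annotations
        )


@dataclass
class BlupMatrix:
    """Per-line BLUPs of the random line effect, one column per feature.

    ``values`` rows are lines, columns features; ``grand_means`` holds the
    per-feature fixed intercept so ``values + grand_means`` recovers the
    measurement scale.
    """

    values: pd.DataFrame
    grand_means: pd.Series
    annotations: pd.DataFrame | None = None

    @property
    def lines(self) -> list:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def on_measurement_scale(self) -> pd.DataFrame:
        return self.values + self.grand_means


def annotation_frame(
    metabolites: list[str],
    enzymes: list[str],
    compound_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build a feature annotation table from id lists."""
    records = []
    for f in metabolites:
        records.append(
            {
                "feature_id": f,
                "molecular_class": METABOLITE,
                "compound_class": (compound_classes or {}).get(f, "unassigned"),
            }
        )
    for f in enzymes:
        records.append(
            {
                "feature_id": f,
                "molecular_class": ENZYME,
                "compound_class": (compound_classes or {}).get(f, ENZYME),
            }
        )
    return pd.DataFrame.from_records(records).set_index("feature_id")


def as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
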