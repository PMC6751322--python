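"""Shared containers and errors for the measurement layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical timepoint labels
BASELINE = "baseline"
WEEK12 = "week12"
TIMEPOINTS = (BASELINE, WEEK12)

#: outcome categories in classification-precedence order
OUTCOME_CATEGORIES = ("remitter", "responder", "partial_responder", "failure")

MEASUREMENT_COLUMNS = [
    "sample_id",
    "metabolite_id",
    "plate_id",
    "value",
    "below_lod",
    "is_qc_pool",
]
LOD_COLUMNS = ["metabolite_id", "plate_id", "lod_value"]
SAMPLE_MAP_COLUMNS = ["sample_id", "subject_id", "timepoint"]


class ConfigError(ValueError):
    """Invalid or infeasible configuration."""


class DataError(ValueError):
    """Malformed or degenerate input data."""


@dataclass
class PlateDataset:
    """Raw (or corrected) plate measurements plus the LOD table and sample map.

    ``measurements`` is a long table with one row per (sample, metabolite):
    columns ``sample_id, metabolite_id, plate_id, value, below_lod,
    is_qc_pool``. Below-LOD entries carry ``value = NaN`` (the censored
    placeholder). ``lod`` maps (metabolite, plate) to the detection limit in
    the same units as ``value``. ``sample_map`` links subject samples to
    (subject, timepoint); QC-pool aliquots do not appear in it.
    """

    measurements: pd.DataFrame
    lod: pd.DataFrame
    sample_map: pd.DataFrame

    def validate(self) -> None:
        for col in MEASUREMENT_COLUMNS:
            if col not in self.measurements.columns:
                raise DataError(f"measurements missing column {col!r}")
        for col in LOD_COLUMNS:
            if col not in self.lod.columns:
                raise DataError(f"lod table missing column {col!r}")
        for col in SAMPLE_MAP_COLUMNS:
            if col not in self.sample_map.columns:
                raise DataError(f"sample map missing column {col!r}")
        dup = self.measurements.duplicated(["sample_id", "metabolite_id"])
        if dup.any():
            row = self.measurements.index[dup][0]
            raise DataError(
                f"duplicate (sample, metabolite) pair at row {row}: "
                f"{self.measurements.loc[row, 'sample_id']}/"
                f"{self.measurements.loc[row, 'metabolite_id']}"
            )
        bad = self.measurements["below_lod"] & self.measurements["value"].notna()
        if bad.any():
            raise DataError("below-LOD rows must carry the NaN placeholder value")

    @property
    def subject_measurements(self) -> pd.DataFrame:
        """Rows from cohort samples only (QC-pool aliquots excluded)."""
        return self.measurements[~self.measurements["is_qc_pool"]]

    @property
    def metabolites(self) -> list:
        return sorted(self.measurements["metabolite_id"].unique())

    @property
    def plates(self) -> list:
        return sorted(self.measurements["plate_id"].unique())

    def copy(self) -> "PlateDataset":
        return PlateDataset(
            self.measurements.copy(), self.lod.copy(), self.sample_map.copy()
        )
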