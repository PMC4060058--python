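"""Packaged study data: juvenile alligator section measurements.

The toolkit ships the full measurement tables from a three-individual
*Alligator mississippiensis* intraskeletal histology study (left/right
limb, scapula and coracoid cross-sections plus a hatchling neonate
baseline), together with the published per-element paired-test results and
annual apposition-rate tables used as reference values in the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_measurement_table, records_from_table

__all__ = [
    "load_alligator_measurements",
    "load_alligator_records",
    "load_expected_paired_results",
    "load_expected_growth_results",
]


def _data_path(name: str):
    return resources.files("skeletochron").joinpath("data", name)


def load_alligator_measurements() -> pd.DataFrame:
    """Per-level section measurements for all three juveniles (long format)."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return read_measurement_table(p)


def load_alligator_records():
    """Element records + shared hatchling baseline from the packaged table."""
    return records_from_table(load_alligator_measurements())


def load_expected_paired_results() -> pd.DataFrame:
    """Published per-element paired t-test summaries (reference values)."""
    with resources.as_file(_data_path("table2_expected.csv")) as p:
        return pd.read_csv(p, dtype={"reject": "boolean"})


def load_expected_growth_results() -> pd.DataFrame:
    """Published cumulative/annual thickness and apposition-rate table."""
    with resources.as_file(_data_path("table3_expected.csv")) as p:
        return pd.read_csv(p, dtype={"partial_year": "boolean"})
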