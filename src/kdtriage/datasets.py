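"""Loaders for the packaged published-count fixtures.

These are transcriptions of the printed count tables from the Taiwan
single-center validation of the two-step classifier: the 2x3 confusion
counts, the sign-frequency contingency tables by criteria-count stratum, the
coronary-outcome calls, and the per-age / per-criteria call counts. They let
the evaluation formulas be exercised against published numbers without any
patient-level data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluate import ConfusionSummary

__all__ = [
    "load_taiwan_confusion",
    "load_sign_tables",
    "load_coronary_outcomes",
    "load_age_outcomes",
    "load_criteria_outcomes",
    "load_enrollment_flow",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("kdtriage.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_taiwan_confusion() -> ConfusionSummary:
    """The published 2x3 confusion counts as a :class:`ConfusionSummary`."""
    df = _read("taiwan_confusion.csv")
    return ConfusionSummary({(r["true"], r["call"]): int(r["count"])
                             for _, r in df.iterrows()})


def load_sign_tables() -> pd.DataFrame:
    """Sign-frequency contingency rows per criteria stratum with printed p."""
    return _read("sign_tables.csv")


def load_coronary_outcomes() -> pd.DataFrame:
    return _read("coronary_outcomes.csv")


def load_age_outcomes() -> pd.DataFrame:
    return _read("age_outcomes.csv")


def load_criteria_outcomes() -> pd.DataFrame:
    return _read("criteria_outcomes.csv")


def load_enrollment_flow() -> pd.DataFrame:
    return _read("enrollment_flow.csv")
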