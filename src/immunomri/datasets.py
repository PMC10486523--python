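"""Bundled example tables and default configuration data."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["load_example_demographics", "default_signature_sets", "default_shift_constants"]


def _data_path(name: str):
    return resources.files("immunomri.data").joinpath(name)


def load_example_demographics() -> pd.DataFrame:
    """Demographics of an example 14-patient HER2+ window-of-opportunity cohort.

    Columns: patient_id, age_years, er_status, allred_score (blank for
    ER-negative patients), Nottingham combined histologic grade, and days
    from the single trastuzumab dose to the post-treatment MRI.
    """
    with _data_path("example_demographics.csv").open() as fh:
        return pd.read_csv(fh)


def _load_signature_json() -> dict:
    with _data_path("signature_sets.json").open() as fh:
        return json.load(fh)


def default_signature_sets() -> dict[str, list[str]]:
    """Toy immune signature gene sets (editable JSON shipped with the package)."""
    return {k: list(v) for k, v in _load_signature_json()["gene_sets"].items()}


def default_shift_constants() -> dict[str, float]:
    """Per-signature constants used to align score ranges (default all zero)."""
    return dict(_load_signature_json()["shift_constants"])
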