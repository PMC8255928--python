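"""Bundled reference data.

The package ships the published per-patient clinical table of a
12-patient SAPHO syndrome cohort (ESR, hsCRP, osteocalcin, VAS pain
score, white-blood-cell and neutrophil counts) together with the
reported healthy-control group summaries, so the cohort feature table
can be recomputed without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .clinical import GroupSummary
from .io import read_clinical

#: healthy-control arm summaries (n, mean, sd) as published; raw control
#: values were not released, so t-tests use the summary form.
CONTROL_SUMMARIES: dict[str, GroupSummary] = {
    "wbc": GroupSummary(12, 6.30, 1.25),
    "neutrophil": GroupSummary(12, 3.29, 0.81),
}


def sapho_clinical_path() -> str:
    return str(resources.files("lncnet").joinpath("data/sapho_clinical.tsv"))


def load_sapho_clinical() -> pd.DataFrame:
    """Per-patient clinical table of the SAPHO cohort (12 rows)."""
    return read_clinical(sapho_clinical_path())


__all__ = ["CONTROL_SUMMARIES", "load_sapho_clinical", "sapho_clinical_path"]
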