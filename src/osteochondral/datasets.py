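"""Packaged study data.

The published patient-characteristics table of the 20-patient knee
arthroplasty cohort: age, sex, BMI, inflammatory comorbidity, the mean
OARSI score over each patient's three osteochondral samples, and the
operated knee.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_patient_table", "patient_summary"]


def load_patient_table() -> pd.DataFrame:
    """The per-patient characteristics table of the cohort."""
    ref = resources.files("osteochondral.data") / "patient_characteristics.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def patient_summary(table: pd.DataFrame | None = None) -> dict:
    """Cohort-level summaries: age statistics and mean of per-patient OARSI.

    The overall OARSI figure averages the per-patient mean scores (each
    patient already being the mean over their three samples), matching how
    the cohort value is conventionally reported.
    """
    if table is None:
        table = load_patient_table()
    age = table["age_years"]
    oarsi = table["mean_oarsi"]
    return {
        "n_patients": int(len(table)),
        "mean_age_years": float(age.mean()),
        "age_min_years": float(age.min()),
        "age_max_years": float(age.max()),
        "mean_oarsi": float(oarsi.mean()),
        "sd_oarsi": float(oarsi.std()),
    }
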