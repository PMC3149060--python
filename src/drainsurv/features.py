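"""Episode-level predictor derivation from raw event streams.

For every analyte the value carried forward is the *worst* value observed
during the surveillance episode — the one most indicative of infection:
maxima for inflammatory markers (CRP, leukocytes, thrombocytes, CSF cell
counts, CSF protein), minima for haemoglobin and CSF glucose.

Culture results are corrected for skin contamination: a culture growing
coagulase-negative staphylococci (CoNS) is recoded negative unless some
antibiotic was started between one day before and three days after the
culture — untreated CoNS growth is read as contamination, not infection.

Empiric therapy for drain-related meningitis follows a two-arm protocol:
vancomycin + ceftazidime when started on day 4 of admission or later, or
ceftriaxone + flucloxacillin when started within the first four days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .episodes import SurveillanceEpisode

__all__ = [
    "worst_value",
    "correct_contamination",
    "any_positive_culture",
    "detect_empiric_therapy",
    "count_antibiotics_started",
    "crp_terms",
    "extract_features",
    "build_feature_table",
    "DIRECTIONS",
    "MODEL_PREDICTORS",
    "SCREENING_VARIABLES",
    "BINARY_FEATURES",
]

# worst-value direction per analyte
DIRECTIONS = {
    "crp": "max",
    "blood_leukocytes": "max",
    "hemoglobin": "min",
    "thrombocytes": "max",
    "csf_leukocytes": "max",
    "csf_erythrocytes": "max",
    "csf_neutrophil_pct": "max",
    "csf_neutrophils": "max",
    "csf_glucose": "min",
    "csf_protein": "max",
}

MODEL_PREDICTORS = [
    "drain_type_evd",
    "n_drains",
    "crp",
    "crp_sq",
    "crp_cu",
    "blood_leukocytes",
    "csf_leukocytes_log",
    "culture_positive",
    "empiric_abx",
    "n_abx_started",
]

SCREENING_VARIABLES = [
    "total_drain_days",
    "icu_days",
    "admission_days",
    "hemoglobin",
    "thrombocytes",
    "csf_leukocytes",
    "csf_erythrocytes",
    "csf_neutrophil_pct",
    "csf_neutrophils",
    "csf_glucose",
    "csf_protein",
    "abx_after_day4",
    "csf_leuko_binary",
]

BINARY_FEATURES = {
    "drain_type_evd",
    "culture_positive",
    "empiric_abx",
    "abx_after_day4",
    "csf_leuko_binary",
}

FEATURE_COLUMNS = ["patient_id", "admission_id"] + MODEL_PREDICTORS + SCREENING_VARIABLES + [
    "year",
    "days_at_risk",
]

EMPIRIC_LATE_PAIR = ("vancomycin", "ceftazidime")  # started on day >= 4
EMPIRIC_EARLY_PAIR = ("ceftriaxone", "flucloxacillin")  # started on day <= 4
SIMULTANEOUS_TOLERANCE = 1  # max days between the two start days of a pair

# threshold (x100 cells/uL) for the binary CSF leukocyte screening flag;
# a pragmatic configuration default, not a clinically validated cut-off
CSF_LEUKO_BINARY_THRESHOLD = 5.0

CULTURE_SITES = {"csf", "drain"}


def worst_value(series, direction: str):
    """Extremum of an in-episode measurement series; NaN when empty."""
    if direction not in ("max", "min"):
        raise ValueError(f"unknown direction {direction!r}")
    vals = np.asarray(series, dtype=float)
    if vals.size == 0:
        return np.nan
    return float(vals.max() if direction == "max" else vals.min())


def correct_contamination(cultures: pd.DataFrame, antibiotics: pd.DataFrame) -> pd.DataFrame:
    """Recode untreated CoNS growth as negative.

    A CoNS-positive culture on day d stays positive only if some antibiotic
    start falls in [d-1, d+3]. Non-CoNS results are never touched, and no
    negative result is ever flipped positive.
    """
    out = cultures.copy()
    if out.empty:
        return out
    starts = antibiotics["start_day"].to_numpy() if len(antibiotics) else np.array([])
    corrected = []
    for _, row in out.iterrows():
        pos = bool(row["positive_flag"])
        if pos and row.get("cons_flag", 0):
            d = row["day"]
            treated = bool(((starts >= d - 1) & (starts <= d + 3)).any())
            pos = treated
        corrected.append(int(pos))
    out["positive_flag"] = corrected
    return out


def any_positive_culture(cultures: pd.DataFrame, *, no_culture_as_missing: bool = True):
    """1 if any corrected-positive CSF/drain culture, 0 if all negative.

    When no culture was taken at all the result is missing under the default
    policy (the value is later imputed); the strict alternative reads absence
    of sampling as a negative result.
    """
    if cultures.empty:
        return np.nan if no_culture_as_missing else 0
    return int(cultures["positive_flag"].any())


def detect_empiric_therapy(antibiotics: pd.DataFrame, episode: SurveillanceEpisode) -> int:
    """Protocolized presumptive therapy for drain-related meningitis."""
    starts = {}
    for _, row in antibiotics.iterrows():
        agent = str(row["agent"]).strip().lower()
        starts.setdefault(agent, []).append(int(row["start_day"]))
    a, b = EMPIRIC_LATE_PAIR
    for da in starts.get(a, []):
        for db in starts.get(b, []):
            if da >= 4 and db >= 4 and abs(da - db) <= SIMULTANEOUS_TOLERANCE:
                return 1
    a, b = EMPIRIC_EARLY_PAIR
    for da in starts.get(a, []):
        for db in starts.get(b, []):
            if da <= 4 and db <= 4 and abs(da - db) <= SIMULTANEOUS_TOLERANCE:
                return 1
    return 0


def count_antibiotics_started(
    antibiotics: pd.DataFrame, episode: SurveillanceEpisode, *, mode: str = "distinct"
) -> int:
    """Number of systemic antibiotics with a start inside the episode.

    ``mode='distinct'`` counts distinct agents (default); ``'events'`` counts
    every start event.
    """
    if mode not in ("distinct", "events"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = antibiotics[
        (antibiotics["systemic_flag"] == 1)
        & antibiotics["start_day"].between(episode.start_day, episode.end_day)
    ]
    if mode == "events":
        return int(len(sub))
    return int(sub["agent"].str.strip().str.lower().nunique())


def crp_terms(crp: float) -> tuple[float, float, float]:
    """Linear, squared and cubic C-reactive-protein terms on the model scale:
    ``(crp, (crp/10)^2, (crp/100)^3)``."""
    if crp < 0:
        raise ValueError("CRP cannot be negative")
    return float(crp), (crp / 10.0) ** 2, (crp / 100.0) ** 3


def _episode_slice(df: pd.DataFrame, episode: SurveillanceEpisode, day_col: str) -> pd.DataFrame:
    return df[
        (df["patient_id"] == episode.patient_id)
        & df[day_col].between(episode.start_day, episode.end_day)
    ]


def extract_features(
    episode: SurveillanceEpisode,
    tables,
    *,
    no_culture_as_missing: bool = True,
    csf_leuko_threshold: float = CSF_LEUKO_BINARY_THRESHOLD,
    log_offset: float = 1.0,
) -> dict:
    """One predictor vector per episode; missing stays missing (NaN)."""
    labs = _episode_slice(tables.labs, episode, "day")
    feats: dict = {
        "patient_id": episode.patient_id,
        "admission_id": episode.admission_id,
        "drain_type_evd": int(episode.drain_type == "EVD"),
        "n_drains": episode.n_drains,
        "total_drain_days": episode.total_drain_days,
        "days_at_risk": episode.days_at_risk,
        "year": episode.year,
    }
    for analyte, direction in DIRECTIONS.items():
        series = labs.loc[labs["analyte"] == analyte, "value"]
        feats[analyte] = worst_value(series, direction)

    if np.isnan(feats["crp"]):
        feats["crp_sq"] = feats["crp_cu"] = np.nan
    else:
        feats["crp"], feats["crp_sq"], feats["crp_cu"] = crp_terms(feats["crp"])

    csf_leu = feats["csf_leukocytes"]
    feats["csf_leukocytes_log"] = (
        np.nan if np.isnan(csf_leu) else float(np.log(csf_leu + log_offset))
    )
    feats["csf_leuko_binary"] = (
        np.nan if np.isnan(csf_leu) else int(csf_leu > csf_leuko_threshold)
    )

    cultures = _episode_slice(tables.cultures, episode, "day")
    cultures = cultures[cultures["site"].str.lower().isin(CULTURE_SITES)]
    abx_all = tables.antibiotics[tables.antibiotics["patient_id"] == episode.patient_id]
    corrected = correct_contamination(cultures, abx_all)
    feats["culture_positive"] = any_positive_culture(
        corrected, no_culture_as_missing=no_culture_as_missing
    )

    abx = _episode_slice(tables.antibiotics, episode, "start_day")
    feats["empiric_abx"] = detect_empiric_therapy(abx, episode)
    feats["n_abx_started"] = count_antibiotics_started(abx, episode)
    feats["abx_after_day4"] = int((abx["start_day"] > 4).any()) if len(abx) else 0

    prow = (
        tables.patients[tables.patients["patient_id"] == episode.patient_id].iloc[0]
    )
    feats["icu_days"] = float(prow.get("icu_days", np.nan))
    feats["admission_days"] = float(prow["discharge_day"])
    return feats


class _PatientView:
    """Per-patient slice of the event tables (avoids rescanning full tables
    for every episode)."""

    __slots__ = ("patients", "labs", "cultures", "antibiotics")

    def __init__(self, patients, labs, cultures, antibiotics):
        self.patients = patients
        self.labs = labs
        self.cultures = cultures
        self.antibiotics = antibiotics


def build_feature_table(episodes, tables, **kwargs) -> pd.DataFrame:
    """Feature matrix for a list of episodes, columns in documented order."""
    groups = {
        name: dict(tuple(getattr(tables, name).groupby("patient_id", sort=False)))
        for name in ("patients", "labs", "cultures", "antibiotics")
    }
    empties = {name: getattr(tables, name).iloc[0:0] for name in groups}
    rows = []
    for ep in episodes:
        view = _PatientView(
            *(groups[name].get(ep.patient_id, empties[name])
              for name in ("patients", "labs", "cultures", "antibiotics"))
        )
        rows.append(extract_features(ep, view, **kwargs))
    df = pd.DataFrame(rows)
    return df[[c for c in FEATURE_COLUMNS if c in df.columns]]
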