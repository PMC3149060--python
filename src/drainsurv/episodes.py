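"""Surveillance episodes: windowing, readmission merging, exclusion rules.

A surveillance episode runs from the day the first external CSF drain is
placed until seven days after removal of the last drain, or until discharge,
whichever comes first.  All day arithmetic uses integer day offsets from
admission (day 0 = admission day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SurveillanceEpisode",
    "build_episodes",
    "merge_readmissions",
    "apply_exclusions",
    "POST_REMOVAL_WINDOW",
]

POST_REMOVAL_WINDOW = 7  # days of surveillance after last drain removal
READMISSION_WINDOW = 30  # days within which a readmission is folded in


@dataclass
class SurveillanceEpisode:
    patient_id: int
    admission_id: int
    start_day: int
    end_day: int
    drains: list = field(default_factory=list)  # (type, insertion, removal) sorted
    n_drains: int = 0
    drain_type: str = "ELD"  # "EVD" if any drain is ventricular
    total_drain_days: int = 0
    days_at_risk: int = 0
    year: int | None = None
    included: bool = True
    exclusion_reasons: list = field(default_factory=list)
    merged_admissions: list = field(default_factory=list)
    readmission_gap: float | None = None  # days since prior discharge, if any

    @property
    def episode_days(self) -> int:
        return self.end_day - self.start_day


def build_episodes(tables) -> list[SurveillanceEpisode]:
    """One episode per admission with at least one drain.

    ``end_day = min(last removal + 7, discharge_day)``; drains sorted by
    insertion day.  Raises on a drain removed before it was inserted.
    """
    patients = tables.patients
    adm_col = "admission_id" if "admission_id" in patients.columns else None
    drains = tables.drains
    bad = drains[drains["removal_day"] < drains["insertion_day"]]
    if len(bad):
        raise ValueError(
            f"drain removed before insertion for patient(s) "
            f"{sorted(bad['patient_id'].unique())}"
        )

    keys = ["patient_id"] + (["admission_id"] if adm_col and "admission_id" in drains.columns else [])
    episodes = []
    pat_idx = patients.set_index(
        ["patient_id"] + ([adm_col] if adm_col else [])
    )
    for key, grp in drains.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        pid = key[0]
        adm = key[1] if len(key) > 1 else 0
        prow = pat_idx.loc[key if len(key) > 1 else pid]
        if isinstance(prow, pd.DataFrame):
            prow = prow.iloc[0]
        grp = grp.sort_values(["insertion_day", "removal_day"], kind="stable")
        start = int(grp["insertion_day"].iloc[0])
        last_removal = int(grp["removal_day"].max())
        discharge = int(prow["discharge_day"])
        end = min(last_removal + POST_REMOVAL_WINDOW, discharge)
        total = int((grp["removal_day"] - grp["insertion_day"]).sum())
        episodes.append(
            SurveillanceEpisode(
                patient_id=pid,
                admission_id=int(adm),
                start_day=start,
                end_day=end,
                drains=list(
                    grp[["drain_type", "insertion_day", "removal_day"]].itertuples(
                        index=False, name=None
                    )
                ),
                n_drains=len(grp),
                drain_type="EVD" if (grp["drain_type"] == "EVD").any() else "ELD",
                total_drain_days=total,
                days_at_risk=total,
                year=int(prow["year"]) if "year" in prow.index else None,
                readmission_gap=(
                    float(prow["gap_days"]) if "gap_days" in prow.index and pd.notna(prow["gap_days"]) else None
                ),
            )
        )
    return episodes


def merge_readmissions(
    episodes: list[SurveillanceEpisode], window_days: int = READMISSION_WINDOW
) -> list[SurveillanceEpisode]:
    """Fold a readmission starting within ``window_days`` of the prior
    discharge into the prior episode's surveillance record.

    The merged record accumulates drain counts and days at risk; readmissions
    beyond the window remain separate and carry their gap so the exclusion
    stage can flag them.
    """
    by_patient: dict[int, list[SurveillanceEpisode]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(ep)
    out = []
    for pid, eps in by_patient.items():
        eps = sorted(eps, key=lambda e: e.admission_id)
        current = eps[0]
        for nxt in eps[1:]:
            if nxt.readmission_gap is not None and nxt.readmission_gap <= window_days:
                current.n_drains += nxt.n_drains
                current.total_drain_days += nxt.total_drain_days
                current.days_at_risk += nxt.days_at_risk
                current.drains.extend(nxt.drains)
                if nxt.drain_type == "EVD":
                    current.drain_type = "EVD"
                current.merged_admissions.append(nxt.admission_id)
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return sorted(out, key=lambda e: (e.patient_id, e.admission_id))


def _simultaneous_drains(drains) -> bool:
    """True if any two drain intervals [insertion, removal) overlap."""
    ivs = sorted((ins, rem) for _, ins, rem in drains)
    for (_, rem_a), (ins_b, _) in zip(ivs, ivs[1:]):
        if ins_b < rem_a:  # half-open: same-day exchange is not simultaneous
            return True
    return False


def apply_exclusions(
    episodes: list[SurveillanceEpisode], patients: pd.DataFrame
) -> tuple[list[SurveillanceEpisode], pd.DataFrame]:
    """Evaluate every episode against the eight exclusion criteria.

    All triggered reasons are recorded (an episode can fail several);
    idempotent: re-running on the included set changes nothing.
    Returns (included episodes, exclusion log).
    """
    pat = patients.drop_duplicates("patient_id").set_index("patient_id")
    log_rows = []
    included = []
    for ep in episodes:
        prow = pat.loc[ep.patient_id]
        reasons = []
        death_day = prow.get("death_day", -1)
        if death_day is not None and death_day >= 0 and death_day - ep.start_day <= 1:
            reasons.append("death<=1d_after_placement")
        if prow.get("age", 99) < 18:
            reasons.append("age<18")
        if prow.get("preexisting_cns_infection", 0):
            reasons.append("preexisting_cns_infection")
        if _simultaneous_drains(ep.drains):
            reasons.append("simultaneous_drains")
        if prow.get("placed_other_centre", 0):
            reasons.append("placed_other_centre")
        if prow["discharge_day"] < 1:
            reasons.append("admission<1d")
        if ep.readmission_gap is not None and ep.readmission_gap > READMISSION_WINDOW:
            reasons.append("readmission>30d")
        if prow.get("external_site", 0):
            reasons.append("external_site")
        ep.exclusion_reasons = reasons
        ep.included = not reasons
        if ep.included:
            included.append(ep)
        else:
            log_rows.append(
                {
                    "patient_id": ep.patient_id,
                    "admission_id": ep.admission_id,
                    "reasons": ";".join(reasons),
                }
            )
    log = pd.DataFrame(log_rows, columns=["patient_id", "admission_id", "reasons"])
    return included, log


def episodes_to_frame(episodes: list[SurveillanceEpisode]) -> pd.DataFrame:
    """Flat table of episode attributes (drain records elided)."""
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "admission_id": e.admission_id,
                "start_day": e.start_day,
                "end_day": e.end_day,
                "n_drains": e.n_drains,
                "drain_type": e.drain_type,
                "total_drain_days": e.total_drain_days,
                "days_at_risk": e.days_at_risk,
                "year": e.year,
                "included": e.included,
                "exclusion_reasons": ";".join(e.exclusion_reasons),
            }
            for e in episodes
        ]
    )
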