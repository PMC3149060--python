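"""Seeded synthetic cohorts of raw hospital event data.

Generates patient admissions, external-CSF-drain placements, time-stamped
laboratory results, microbiology cultures and antibiotic start events whose
*episode-level* summaries (the per-episode worst value of each marker, culture
positivity, antibiotic counts) reproduce the published per-group
median/IQR structure of a drain-related-meningitis (DRM) surveillance cohort:
82/537 infected episodes (15.3 % prevalence), strongly shifted inflammatory
markers in the infected group, and culture positivity of 74.4 % (DRM) versus
9.9 % (no DRM).

The generator works backwards from the quantity the downstream model consumes:
for each episode it first draws the *extremum* (worst value) of every lab
series from the configured group distribution, then scatters the remaining
measurements strictly on the non-extreme side, so that worst-value extraction
recovers the configured distribution exactly.

Correlation between predictors is induced only through the latent infection
flag; conditional on that flag, predictors are independent (a documented
limitation — the published tables report marginal group distributions only).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "GeneratorConfig",
    "RawEventTables",
    "generate_cohort",
    "inject_missingness",
    "generate_model_cohort",
    "lognormal_params",
    "DEFAULT_LAB_TARGETS",
    "DEFAULT_MISSINGNESS",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

# ---------------------------------------------------------------------------
# Calibration targets: (direction, family, (median, q1, q3) non-DRM, ... DRM)
# Worst-value distributions per group; lognormal for strictly-positive skewed
# analytes, normal (clipped) for the neutrophil percentage.
# ---------------------------------------------------------------------------
DEFAULT_LAB_TARGETS: dict[str, tuple[str, str, tuple, tuple]] = {
    "crp": ("max", "lognormal", (85.0, 32.0, 165.0), (141.0, 95.0, 190.0)),
    "blood_leukocytes": ("max", "lognormal", (14.8, 11.3, 19.0), (20.1, 16.3, 23.6)),
    "hemoglobin": ("min", "lognormal", (6.8, 5.8, 7.6), (6.0, 5.2, 6.8)),
    "thrombocytes": ("max", "lognormal", (329.0, 252.0, 452.0), (540.0, 381.0, 714.0)),
    "csf_leukocytes": ("max", "lognormal", (1.4, 0.2, 4.3), (10.4, 2.5, 53.1)),
    "csf_erythrocytes": ("max", "lognormal", (1.2, 0.2, 6.9), (2.4, 0.8, 10.6)),
    "csf_neutrophil_pct": ("max", "normal", (47.8, 31.3, 66.0), (85.0, 70.0, 91.5)),
    # published q1 is 0.0; a small positive stand-in keeps the lognormal solvable
    "csf_neutrophils": ("max", "lognormal", (0.4, 0.05, 2.3), (6.3, 0.6, 38.0)),
    "csf_glucose": ("min", "lognormal", (3.5, 2.9, 4.2), (2.3, 1.1, 3.3)),
    "csf_protein": ("max", "lognormal", (1.7, 0.8, 2.7), (1.8, 1.1, 3.3)),
}

LAB_UNITS = {
    "crp": "mg/L",
    "blood_leukocytes": "1e9/L",
    "hemoglobin": "mmol/L",
    "thrombocytes": "1e9/L",
    "csf_leukocytes": "1e2/uL",
    "csf_erythrocytes": "1e4/uL",
    "csf_neutrophil_pct": "%",
    "csf_neutrophils": "1e2/uL",
    "csf_glucose": "mmol/L",
    "csf_protein": "g/L",
}

# (non-DRM rate, DRM rate) for binary episode attributes
DEFAULT_BINARY_RATES: dict[str, tuple[float, float]] = {
    "sex_female": (247 / 455, 43 / 82),
    "drain_type_evd": (266 / 455, 71 / 82),
    "culture_positive": (45 / 455, 61 / 82),
    "empiric_abx": (61 / 455, 62 / 82),
    "abx_after_day4": (193 / 455, 78 / 82),
    "icu_any": (253 / 455, 59 / 82),
    "in_hospital_death": (79 / 455, 11 / 82),
}

# Per-group median/IQR duration targets (days)
DEFAULT_DURATION_TARGETS = {
    "total_drain_days": ((8.0, 5.0, 13.0), (20.0, 15.0, 29.8)),
    "admission_days": ((19.0, 11.0, 30.0), (40.0, 28.5, 59.3)),
    "age": ((59.3, 46.8, 69.4), (56.0, 47.5, 65.6)),
}

# Number-of-systemic-antibiotics-started: median (IQR) 1 (0–2) / 4 (3–6)
DEFAULT_ABX_COUNT_TARGETS = ((1.0, 0.0, 2.0), (4.0, 3.0, 6.0))

# Whole-episode "never measured" rates per analyte
DEFAULT_MISSINGNESS: dict[str, float] = {
    "crp": 0.112,
    "blood_leukocytes": 0.084,
    "hemoglobin": 0.061,
    "thrombocytes": 0.112,
    "csf_leukocytes": 0.292,
    "csf_erythrocytes": 0.291,
    "csf_glucose": 0.307,
    "csf_protein": 0.292,
}

# First-drain indication distribution (non-DRM, DRM)
INDICATIONS = ["sah_ivh", "infarction", "csf_leakage", "perioperative", "trauma", "tumor", "other"]
_INDICATION_P = {
    0: np.array([205, 14, 77, 84, 11, 30, 48], dtype=float),
    1: np.array([58, 0.5, 8, 2, 3, 7, 4], dtype=float),
}
for _g in _INDICATION_P:
    _INDICATION_P[_g] /= _INDICATION_P[_g].sum()

CONS_LABEL = "coagulase-negative staphylococci"
ORGANISMS = [
    "Staphylococcus aureus",
    "Escherichia coli",
    "Klebsiella pneumoniae",
    "Enterococcus faecalis",
    "Pseudomonas aeruginosa",
]
CONS_FRACTION = 0.338  # of positive cultures

# agents used for non-empiric systemic therapy; deliberately excludes
# ceftazidime and flucloxacillin so the empiric-pair flag stays identifiable
AGENT_POOL = [
    "meropenem",
    "cefotaxime",
    "ciprofloxacin",
    "metronidazole",
    "amoxicillin",
    "gentamicin",
    "rifampicin",
    "clindamycin",
    "cotrimoxazole",
    "piperacillin-tazobactam",
    "vancomycin",
    "ceftriaxone",
]


def lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and interquartile range.

    mu reproduces the median exactly; sigma is the average of the two
    quartile-implied values (one-sided when q1 is not strictly positive).
    """
    if median <= 0 or q3 <= 0:
        raise ValueError("lognormal targets must be positive")
    mu = np.log(median)
    if q1 > 0:
        sigma = (np.log(q3) - np.log(q1)) / (2 * _Z75)
    else:
        sigma = (np.log(q3) - mu) / _Z75
    return mu, max(sigma, 1e-6)


@lru_cache(maxsize=None)
def _nb_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Negative-binomial (n, p) whose median/IQR best match the targets.

    Coarse deterministic grid search; called once per target triple.
    """
    best, best_score = (1.0, 0.5), np.inf
    for r in np.arange(0.4, 8.01, 0.2):
        for mean in np.arange(0.2, 10.01, 0.1):
            p = r / (r + mean)
            med = stats.nbinom.ppf(0.5, r, p)
            lo = stats.nbinom.ppf(0.25, r, p)
            hi = stats.nbinom.ppf(0.75, r, p)
            score = 2 * abs(med - median) + abs(lo - q1) + abs(hi - q3)
            if score < best_score:
                best_score, best = score, (r, p)
    return best


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the published study conditions: 15.3 % prevalence,
    the per-group worst-value distributions, the per-analyte whole-episode
    missingness rates, and six calendar years of accrual.
    """

    n_patients: int = 537
    prevalence: float = 0.153
    seed: int = 0
    lab_targets: dict = field(default_factory=lambda: dict(DEFAULT_LAB_TARGETS))
    binary_rates: dict = field(default_factory=lambda: dict(DEFAULT_BINARY_RATES))
    duration_targets: dict = field(default_factory=lambda: dict(DEFAULT_DURATION_TARGETS))
    abx_count_targets: tuple = DEFAULT_ABX_COUNT_TARGETS
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    missingness_mechanism: str = "MCAR"  # or "MAR-on-outcome"
    mar_odds_ratio: float = 0.3  # CSF-deletion odds DRM vs non-DRM under MAR
    culture_missing_rate: float = 0.199  # episodes with no CSF/drain culture taken
    contaminant_rate: float = 0.08  # CoNS contaminant among culture-negative episodes
    extra_drain_rate: tuple = (0.15, 0.8)  # Poisson mean of drains beyond the first
    study_years: dict = field(
        default_factory=lambda: {y: None for y in range(2004, 2010)}
    )
    measurements_per_analyte: tuple = (1, 5)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
            if name not in self.lab_targets:
                raise ValueError(f"unknown analyte in missingness_rates: {name!r}")
        for name, (direction, family, g0, g1) in self.lab_targets.items():
            if direction not in ("max", "min"):
                raise ValueError(f"{name}: direction must be 'max' or 'min'")
            for med, q1, q3 in (g0, g1):
                if q3 <= 0 or med <= 0:
                    raise ValueError(f"{name}: scale parameters must be positive")
        if self.missingness_mechanism not in ("MCAR", "MAR-on-outcome"):
            raise ValueError("missingness_mechanism must be MCAR or MAR-on-outcome")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RawEventTables:
    """The five event tables plus the latent/reference outcome table."""

    patients: pd.DataFrame
    drains: pd.DataFrame
    labs: pd.DataFrame
    cultures: pd.DataFrame
    antibiotics: pd.DataFrame
    outcomes: pd.DataFrame

    def copy(self) -> "RawEventTables":
        return RawEventTables(**{k: getattr(self, k).copy() for k in TABLE_NAMES})

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawEventTables):
            return NotImplemented
        return all(
            getattr(self, k).reset_index(drop=True).equals(
                getattr(other, k).reset_index(drop=True)
            )
            for k in TABLE_NAMES
        )


TABLE_NAMES = ["patients", "drains", "labs", "cultures", "antibiotics", "outcomes"]


def _draw_lognormal(rng, params_by_group, drm: np.ndarray) -> np.ndarray:
    out = np.empty(drm.shape[0])
    for g in (0, 1):
        mask = drm == g
        mu, sigma = lognormal_params(*params_by_group[g])
        out[mask] = rng.lognormal(mu, sigma, mask.sum())
    return out


def _draw_binary(rng, rates: tuple[float, float], drm: np.ndarray) -> np.ndarray:
    p = np.where(drm == 1, rates[1], rates[0])
    return (rng.random(drm.shape[0]) < p).astype(int)


def generate_cohort(config: GeneratorConfig) -> RawEventTables:
    """Draw a complete (no missing values) synthetic cohort.

    Identical config (including seed) yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    drm = (rng.random(n) < config.prevalence).astype(int)
    pid = np.arange(n)

    # --- demographics -----------------------------------------------------
    age = np.empty(n)
    for g in (0, 1):
        med, q1, q3 = config.duration_targets["age"][g]
        mask = drm == g
        age[mask] = rng.normal(med, (q3 - q1) / (2 * _Z75), mask.sum())
    age = np.clip(np.round(age, 1), 18.0, 95.0)
    sex_female = _draw_binary(rng, config.binary_rates["sex_female"], drm)

    # --- drains -----------------------------------------------------------
    n_drains = 1 + rng.poisson(np.where(drm == 1, *config.extra_drain_rate[::-1]), n)
    evd = _draw_binary(rng, config.binary_rates["drain_type_evd"], drm)
    total_drain_days = np.maximum(
        np.round(_draw_lognormal(rng, config.duration_targets["total_drain_days"], drm)),
        n_drains,
    ).astype(int)
    first_insertion = rng.integers(0, 4, n)

    indication = np.empty(n, dtype=object)
    for g in (0, 1):
        mask = drm == g
        indication[mask] = rng.choice(INDICATIONS, size=mask.sum(), p=_INDICATION_P[g])

    drain_rows = []
    last_removal = np.empty(n, dtype=int)
    for i in range(n):
        k = n_drains[i]
        # split total drainage days into k positive integer durations
        if k == 1:
            durations = [total_drain_days[i]]
        else:
            cuts = np.sort(rng.choice(np.arange(1, total_drain_days[i]), size=k - 1,
                                      replace=False)) if total_drain_days[i] > k else None
            if cuts is None:
                durations = [1] * k
            else:
                bounds = np.concatenate([[0], cuts, [total_drain_days[i]]])
                durations = np.diff(bounds).tolist()
        day = int(first_insertion[i])
        dtype = "EVD" if evd[i] else "ELD"
        for j, dur in enumerate(durations):
            removal = day + int(dur)
            drain_rows.append((pid[i], dtype, day, removal, indication[i]))
            day = removal + int(rng.integers(1, 3))  # gap before any next drain
        last_removal[i] = removal
    drains = pd.DataFrame(
        drain_rows,
        columns=["patient_id", "drain_type", "insertion_day", "removal_day", "indication"],
    )

    # --- admission timeline ----------------------------------------------
    admission_days = np.round(
        _draw_lognormal(rng, config.duration_targets["admission_days"], drm)
    ).astype(int)
    discharge_day = np.maximum(admission_days, last_removal + 1)
    episode_end = np.minimum(last_removal + 7, discharge_day)

    icu_any = _draw_binary(rng, config.binary_rates["icu_any"], drm)
    icu_days = np.where(
        icu_any == 1,
        np.minimum(
            np.round(rng.lognormal(np.where(drm == 1, np.log(7.1), np.log(6.3)), 0.9, n)),
            discharge_day,
        ),
        0,
    ).astype(int)

    death = _draw_binary(rng, config.binary_rates["in_hospital_death"], drm)
    death_day = np.where(
        (death == 1) & (discharge_day - first_insertion >= 2), discharge_day, -1
    )

    years = np.array(sorted(config.study_years))
    counts = [config.study_years[y] for y in years]
    if any(c is not None for c in counts):
        weights = np.array([0 if c is None else c for c in counts], dtype=float)
        weights /= weights.sum()
        year = rng.choice(years, size=n, p=weights)
    else:
        year = rng.choice(years, size=n)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "age": age,
            "sex_female": sex_female,
            "admission_day": 0,
            "discharge_day": discharge_day,
            "icu_days": icu_days,
            "death_day": death_day,
            "preexisting_cns_infection": 0,
            "placed_other_centre": 0,
            "external_site": 0,
            "year": year,
        }
    )

    # --- laboratory time series ------------------------------------------
    lo_k, hi_k = config.measurements_per_analyte
    lab_frames = []
    for analyte, (direction, family, g0, g1) in config.lab_targets.items():
        if family == "lognormal":
            worst = _draw_lognormal(rng, (g0, g1), drm)
        elif family == "normal":
            worst = np.empty(n)
            for g, (med, q1, q3) in enumerate((g0, g1)):
                mask = drm == g
                worst[mask] = rng.normal(med, (q3 - q1) / (2 * _Z75), mask.sum())
            worst = np.clip(worst, 0.1, 100.0)
        else:
            raise ValueError(f"unknown family {family!r} for {analyte!r}")
        k = rng.integers(lo_k, hi_k + 1, n)
        total = int(k.sum())
        patient_rep = np.repeat(pid, k)
        start_rep = np.repeat(first_insertion, k)
        end_rep = np.repeat(episode_end, k)
        days = start_rep + (rng.random(total) * (end_rep - start_rep + 1)).astype(int)
        values = np.repeat(worst, k)
        # non-extremum measurements sit strictly on the non-extreme side
        u = rng.uniform(0.35, 0.98, total)
        if direction == "max":
            scattered = values * u
        else:
            scattered = values * (2.0 - u)
        first_of_patient = np.zeros(total, dtype=bool)
        first_of_patient[np.concatenate([[0], np.cumsum(k)[:-1]])] = True
        values = np.where(first_of_patient, values, scattered)
        if analyte == "csf_neutrophil_pct":
            values = np.clip(values, 0.0, 100.0)
        lab_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_rep,
                    "day": days,
                    "analyte": analyte,
                    "value": np.round(values, 3),
                    "unit": LAB_UNITS.get(analyte, ""),
                }
            )
        )
    labs = (
        pd.concat(lab_frames, ignore_index=True)
        .sort_values(["patient_id", "analyte", "day"], kind="stable")
        .reset_index(drop=True)
    )

    # --- antibiotics ------------------------------------------------------
    empiric = _draw_binary(rng, config.binary_rates["empiric_abx"], drm)
    after4 = _draw_binary(rng, config.binary_rates["abx_after_day4"], drm)
    r_nb = [_nb_params(*config.abx_count_targets[g]) for g in (0, 1)]
    n_abx = np.where(
        drm == 1,
        rng.negative_binomial(r_nb[1][0], r_nb[1][1], n),
        rng.negative_binomial(r_nb[0][0], r_nb[0][1], n),
    )
    n_abx = np.where(empiric == 1, np.maximum(n_abx, 2), n_abx)

    abx_rows = []
    abx_days_by_patient: list[list[int]] = []
    for i in range(n):
        start, end = int(first_insertion[i]), int(episode_end[i])
        agents: list[tuple[str, int]] = []
        if empiric[i]:
            if end >= 4:
                d = max(4, start)
                agents += [("vancomycin", d), ("ceftazidime", d)]
            else:
                d = min(4, end)
                agents += [("ceftriaxone", d), ("flucloxacillin", d)]
        remaining = int(n_abx[i]) - len(agents)
        if remaining > 0:
            pool = [a for a in AGENT_POOL if a not in {a0 for a0, _ in agents}]
            names = rng.choice(pool, size=min(remaining, len(pool)), replace=False)
            for name in names:
                agents.append((str(name), int(rng.integers(start, end + 1))))
        if after4[i] and agents and not any(d > 4 for _, d in agents) and end > 4:
            name, _ = agents[-1]
            if name not in ("vancomycin", "ceftazidime", "ceftriaxone", "flucloxacillin"):
                agents[-1] = (name, int(rng.integers(5, end + 1)))
        for name, d in agents:
            abx_rows.append((pid[i], name, d, 1))
        abx_days_by_patient.append([d for _, d in agents])
    antibiotics = pd.DataFrame(
        abx_rows, columns=["patient_id", "agent", "start_day", "systemic_flag"]
    )

    # --- cultures ---------------------------------------------------------
    intended_pos = _draw_binary(rng, config.binary_rates["culture_positive"], drm)
    overall_pos = (
        config.prevalence * config.binary_rates["culture_positive"][1]
        + (1 - config.prevalence) * config.binary_rates["culture_positive"][0]
    )
    # realise the overall no-culture-taken rate among intended-negative episodes
    q_not_taken = min(config.culture_missing_rate / (1 - overall_pos), 1.0)

    cult_rows = []
    for i in range(n):
        start, end = int(first_insertion[i]), int(episode_end[i])
        starts = abx_days_by_patient[i]
        if intended_pos[i]:
            day = int(rng.integers(start, end + 1))
            if rng.random() < CONS_FRACTION:
                if not any(day - 1 <= d <= day + 3 for d in starts):
                    anchored = [d for d in starts if start <= d <= end]
                    if anchored:
                        day = int(anchored[0])  # culture drawn when therapy begins
                        organism, cons = CONS_LABEL, 1
                    else:
                        organism, cons = str(rng.choice(ORGANISMS)), 0
                else:
                    organism, cons = CONS_LABEL, 1
            else:
                organism, cons = str(rng.choice(ORGANISMS)), 0
            site = "csf" if rng.random() < 0.7 else "drain"
            cult_rows.append((pid[i], day, site, organism, cons, 1))
            for _ in range(int(rng.integers(0, 2))):
                cult_rows.append(
                    (pid[i], int(rng.integers(start, end + 1)), "csf", "no growth", 0, 0)
                )
        else:
            if rng.random() < q_not_taken:
                continue  # infection never suspected: no sample sent
            for _ in range(int(rng.integers(1, 3))):
                cult_rows.append(
                    (pid[i], int(rng.integers(start, end + 1)), "csf", "no growth", 0, 0)
                )
            if rng.random() < config.contaminant_rate:
                # a skin contaminant only counts if untreated; find such a day
                for _ in range(6):
                    day = int(rng.integers(start, end + 1))
                    if not any(day - 1 <= d <= day + 3 for d in starts):
                        cult_rows.append((pid[i], day, "drain", CONS_LABEL, 1, 1))
                        break
    cultures = pd.DataFrame(
        cult_rows,
        columns=["patient_id", "day", "site", "organism", "cons_flag", "positive_flag"],
    )

    infection_day = np.where(
        drm == 1,
        first_insertion + ((episode_end - first_insertion) * rng.random(n) * 0.8).astype(int) + 1,
        -1,
    )
    outcomes = pd.DataFrame(
        {"patient_id": pid, "drm_flag": drm, "infection_day": infection_day}
    )

    return RawEventTables(patients, drains, labs, cultures, antibiotics, outcomes)


def _mar_group_rates(rate: float, prevalence: float, odds_ratio: float) -> tuple[float, float]:
    """Per-group deletion rates with odds(DRM)/odds(non-DRM)=odds_ratio and the
    configured marginal rate."""
    if rate in (0.0, 1.0) or odds_ratio == 1.0:
        return rate, rate

    def marginal(r0: float) -> float:
        odds1 = odds_ratio * r0 / (1 - r0)
        r1 = odds1 / (1 + odds1)
        return (1 - prevalence) * r0 + prevalence * r1 - rate

    r0 = brentq(marginal, 1e-9, 1 - 1e-9)
    odds1 = odds_ratio * r0 / (1 - r0)
    return r0, odds1 / (1 + odds1)


def inject_missingness(tables: RawEventTables, config: GeneratorConfig) -> RawEventTables:
    """Delete whole per-episode lab measurement sets ("never measured").

    Under MCAR every episode loses an analyte with the configured rate.
    Under MAR-on-outcome, deletion odds for CSF analytes differ between DRM
    and non-DRM episodes by ``config.mar_odds_ratio`` while keeping the
    configured marginal rate. Observed values are never altered.
    """
    rng = np.random.default_rng(np.uint32(config.seed) ^ np.uint32(0x5EED))
    labs = tables.labs
    drm = tables.outcomes.set_index("patient_id")["drm_flag"]
    drop = pd.Series(False, index=labs.index)
    for analyte, rate in config.missingness_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"rate outside [0,1] for {analyte!r}")
        patients = labs.loc[labs["analyte"] == analyte, "patient_id"].unique()
        if len(patients) == 0:
            continue
        if (
            config.missingness_mechanism == "MAR-on-outcome"
            and analyte.startswith("csf_")
        ):
            r0, r1 = _mar_group_rates(rate, config.prevalence, config.mar_odds_ratio)
            p = np.where(drm.loc[patients].to_numpy() == 1, r1, r0)
        else:
            p = rate
        doomed = patients[rng.random(len(patients)) < p]
        drop |= labs["analyte"].eq(analyte) & labs["patient_id"].isin(doomed)
    out = tables.copy()
    out.labs = labs.loc[~drop].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Cohorts drawn from a known prediction rule (for parameter-recovery and
# summed-probability concordance checks, and for model-based simulation).
# ---------------------------------------------------------------------------

_OVERALL_MARGINALS = {
    "crp": (96.0, 39.0, 173.0),
    "blood_leukocytes": (15.7, 11.8, 20.1),
    "csf_leukocytes": (1.9, 0.3, 5.7),
}


def generate_model_cohort(rule, n: int, seed: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Predictor matrix from overall population marginals with outcomes drawn
    from ``rule``'s logistic model.

    Returns ``(X, y, p)`` where ``X`` has exactly the rule's predictor columns
    (plus any extra columns the rule ignores are NOT added here), ``p`` the
    true event probabilities and ``y`` Bernoulli(p) draws.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    crp = rng.lognormal(*lognormal_params(*_OVERALL_MARGINALS["crp"]), n)
    cols["crp"] = crp
    cols["crp_sq"] = (crp / 10.0) ** 2
    cols["crp_cu"] = (crp / 100.0) ** 3
    cols["blood_leukocytes"] = rng.lognormal(
        *lognormal_params(*_OVERALL_MARGINALS["blood_leukocytes"]), n
    )
    csf_leu = rng.lognormal(*lognormal_params(*_OVERALL_MARGINALS["csf_leukocytes"]), n)
    cols["csf_leukocytes_log"] = np.log(csf_leu + 1.0)
    cols["drain_type_evd"] = (rng.random(n) < 337 / 537).astype(float)
    cols["n_drains"] = 1.0 + rng.poisson(0.25, n)
    cols["culture_positive"] = (rng.random(n) < 106 / 537).astype(float)
    cols["empiric_abx"] = (rng.random(n) < 123 / 537).astype(float)
    cols["n_abx_started"] = rng.negative_binomial(*_nb_params(1.0, 0.0, 3.0), n).astype(float)
    X = pd.DataFrame(cols)
    missing = [c for c in rule.coefficients if c not in X.columns]
    if missing:
        raise ValueError(f"no marginal sampler for predictors {missing}")
    p = rule.predict(X)
    y = (rng.random(n) < p).astype(int)
    return X, y, p
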