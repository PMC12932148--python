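"""Synthetic FAERS-like quarter generator with known ground truth.

Emulates the structure of a spontaneous-report quarter — multi-table case
reports keyed by PRIMARYID/CASEID, duplicate case versions, a deleted-cases
list, per-case demographics with explicit missingness, suspect/concomitant
drug rows, MedDRA-PT reaction rows, and therapy/event dates yielding
time-to-onset intervals — so that every downstream stage (deduplication,
coding, disproportionality, onset modelling) can be tested against planted
truth without any FAERS download.

The reporting model: each case is assigned one primary-suspect drug; each
configured event PT occurs independently with probability
``clip(background_prob * rr[drug][pt], 0, 1)``. With ``rr == 1`` everywhere
the corpus is null-calibrated (every drug shares the background reporting
rates); an ``rr > 1`` entry plants a disproportionality signal of that
strength for one drug-event pair. Cases that sample no configured event
receive a single filler PT (common to all drugs, hence signal-neutral) so
every case keeps at least one reaction row.

Default parameter values mirror the demographic and reporting mix of a
bile-acid-sequestrant safety corpus: mostly female, mostly consumer-reported,
mostly US reports with high age missingness, and an early-dominated Weibull
time-to-onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .faers_io import TABLE_SCHEMAS, QuarterBundle, write_table

_PROB_TOL = 1e-9


def _default_events() -> Dict[str, str]:
    return {
        "Constipation": "Gastrointestinal disorders",
        "Diarrhoea": "Gastrointestinal disorders",
        "Nausea": "Gastrointestinal disorders",
        "Abdominal discomfort": "Gastrointestinal disorders",
        "Product taste abnormal": "Product issues",
        "Product solubility abnormal": "Product issues",
        "Throat irritation": "Respiratory, thoracic and mediastinal disorders",
        "Cough": "Respiratory, thoracic and mediastinal disorders",
        "Headache": "Nervous system disorders",
        "Dizziness": "Nervous system disorders",
        "Rash": "Skin and subcutaneous tissue disorders",
        "Blood glucose increased": "Investigations",
    }


def _default_background() -> Dict[str, float]:
    return {pt: 0.06 for pt in _default_events()}


class SynthConfig(BaseModel):
    """Configuration of one synthetic quarter.

    Categorical distributions must sum to 1 (within 1e-9) and carry an
    explicit ``missing`` category; missing values are emitted as empty
    strings, matching FAERS practice.
    """

    n_cases: int = Field(default=5000, ge=0)
    drugs: List[str] = Field(
        default_factory=lambda: [
            "CHOLESTYRAMINE", "ATORVASTATIN", "OMEPRAZOLE",
            "METFORMIN", "LISINOPRIL",
        ]
    )
    target_drug: str = "CHOLESTYRAMINE"
    drug_probs: Optional[List[float]] = None  # uniform when None
    events: Dict[str, str] = Field(default_factory=_default_events)
    rr_matrix: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    background_event_probs: Dict[str, float] = Field(
        default_factory=_default_background)
    filler_pt: str = "Drug ineffective"
    filler_soc: str = "General disorders and administration site conditions"
    duplicate_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    deletion_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    concomitant_rate: float = Field(default=0.30, ge=0.0, le=1.0)
    sex_probs: Dict[str, float] = Field(
        default_factory=lambda: {"M": 0.2411, "F": 0.6209, "missing": 0.1380})
    age_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "<18": 0.0050, "18-65": 0.1825, ">65": 0.2405, "missing": 0.5720})
    country_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "United States of America": 0.8989, "France": 0.0050,
            "Germany": 0.0050, "Great Britain": 0.0035, "Denmark": 0.0021,
            "missing": 0.0855})
    reporter_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "CN": 0.6987, "MD": 0.1294, "PH": 0.0870, "HP": 0.0255,
            "OT": 0.0297, "missing": 0.0297})
    outcome_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "LT": 0.0071, "HO": 0.0403, "DS": 0.0085, "DE": 0.0035,
            "RI": 0.0057, "CA": 0.0071, "OT": 0.1068, "missing": 0.8210})
    onset_shape: float = Field(default=0.6, gt=0.0)
    onset_scale: float = Field(default=3.0, gt=0.0)  # days
    onset_missing_rate: float = Field(default=0.30, ge=0.0, le=1.0)
    partial_date_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    negative_onset_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    quarter: str = "24Q1"
    seed: int = 0

    @field_validator(
        "sex_probs", "age_probs", "country_probs", "reporter_probs",
        "outcome_probs")
    @classmethod
    def _check_categorical(cls, v: Dict[str, float], info):
        for key, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"{info.field_name}[{key!r}] = {p} outside [0, 1]")
        total = sum(v.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"{info.field_name} sums to {total!r}, expected 1 ± {_PROB_TOL}")
        return v

    @field_validator("background_event_probs")
    @classmethod
    def _check_background(cls, v: Dict[str, float], info):
        for key, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"background_event_probs[{key!r}] = {p} outside [0, 1]")
        if sum(v.values()) > 1.0 + _PROB_TOL:
            raise ValueError(
                f"background_event_probs sums to {sum(v.values())} > 1")
        return v

    @field_validator("rr_matrix")
    @classmethod
    def _check_rr(cls, v):
        for drug, row in v.items():
            for pt, rr in row.items():
                if not np.isfinite(rr) or rr < 0:
                    raise ValueError(
                        f"rr_matrix[{drug!r}][{pt!r}] = {rr} must be finite and >= 0")
        return v

    @model_validator(mode="after")
    def _check_consistency(self):
        if self.target_drug not in self.drugs:
            raise ValueError(
                f"target_drug {self.target_drug!r} not in drugs list")
        if self.drug_probs is not None:
            if len(self.drug_probs) != len(self.drugs):
                raise ValueError("drug_probs length != drugs length")
            if abs(sum(self.drug_probs) - 1.0) > _PROB_TOL:
                raise ValueError("drug_probs must sum to 1")
        unknown = set(self.background_event_probs) - set(self.events)
        if unknown:
            raise ValueError(
                f"background_event_probs has PTs not in events: {sorted(unknown)}")
        missing_bg = set(self.events) - set(self.background_event_probs)
        if missing_bg:
            raise ValueError(
                f"events lack background_event_probs entries: {sorted(missing_bg)}")
        return self


@dataclass
class SynthTruth:
    """Ground truth attached to a generated bundle."""

    config: SynthConfig
    retained_primaryids: Dict[str, str]        # caseid -> designated latest pid
    deleted_caseids: frozenset
    case_drug: pd.Series                        # caseid -> PS drug
    event_matrix: pd.DataFrame                  # caseid x PT booleans
    onset_days: pd.Series                       # caseid -> drawn onset (days)
    onset_usable: pd.Series                     # caseid -> bool (dates complete)


def _quarter_start(label: str):
    yy, q = label.split("Q")
    year = 2000 + int(yy)
    month = {1: 1, 2: 4, 3: 7, 4: 10}[int(q)]
    return np.datetime64(f"{year:04d}-{month:02d}-01", "D")


def _fmt_dates(days: np.ndarray) -> np.ndarray:
    """Vector of numpy datetime64[D] -> yyyymmdd strings."""
    s = np.datetime_as_string(days, unit="D")
    return np.char.replace(s, "-", "")


def generate_quarter(config: SynthConfig) -> QuarterBundle:
    """Generate one synthetic quarter, deterministically from the seed.

    The returned bundle carries a :class:`SynthTruth` in ``.truth``:
    designated retained report versions per case, the deletion list, the
    per-case suspect drug, the sampled event matrix and the drawn onset
    days (with the usable-dates mask). Event counts for each drug follow
    the planted rate-ratio matrix in expectation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    events = list(config.events)
    n_ev = len(events)
    drugs = config.drugs

    caseids = np.array([f"{10000000 + i}" for i in range(n)], dtype=str)

    # primary-suspect drug per case
    p_drug = (np.full(len(drugs), 1.0 / len(drugs))
              if config.drug_probs is None else np.asarray(config.drug_probs))
    drug_idx = rng.choice(len(drugs), size=n, p=p_drug)

    # event occurrence: per-drug Bernoulli probability matrix
    bg = np.array([config.background_event_probs[e] for e in events])
    prob = np.tile(bg, (len(drugs), 1))
    for di, d in enumerate(drugs):
        row = config.rr_matrix.get(d, {})
        for ei, e in enumerate(events):
            prob[di, ei] = min(1.0, bg[ei] * row.get(e, 1.0))
    u = rng.random((n, n_ev)) if n else np.zeros((0, n_ev))
    event_mat = u < prob[drug_idx] if n else u.astype(bool)

    # demographics
    def _cat(dist: Dict[str, float]) -> np.ndarray:
        keys = np.array(list(dist))
        p = np.array(list(dist.values()))
        return keys[rng.choice(len(keys), size=n, p=p)]

    sex = _cat(config.sex_probs)
    age_grp = _cat(config.age_probs)
    country = _cat(config.country_probs)
    reporter = _cat(config.reporter_probs)
    outcome = _cat(config.outcome_probs)

    age_val = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    lo = {"<18": 1, "18-65": 18, ">65": 66}
    hi = {"<18": 17, "18-65": 65, ">65": 95}
    for grp in ("<18", "18-65", ">65"):
        m = age_grp == grp
        k = int(m.sum())
        if k:
            age_val[m] = rng.integers(lo[grp], hi[grp] + 1, size=k).astype(str)
            age_cod[m] = "YR"

    # dates: therapy start -> (onset) -> event -> (reporting lag) -> FDA receipt
    qstart = _quarter_start(config.quarter)
    fda = qstart + rng.integers(0, 90, size=n)
    onset = np.floor(
        config.onset_scale
        * rng.weibull(config.onset_shape, size=n)).astype(np.int64)
    lag = rng.integers(3, 61, size=n)
    event_dt = fda - lag
    start_dt = event_dt - onset

    ev_str = _fmt_dates(event_dt) if n else np.array([], dtype=str)
    st_str = _fmt_dates(start_dt) if n else np.array([], dtype=str)
    st_str = st_str.astype(object)
    ev_str = ev_str.astype(object)

    usable = np.ones(n, dtype=bool)
    # planted negative intervals (event precedes therapy start)
    m_neg = rng.random(n) < config.negative_onset_rate
    if m_neg.any():
        st_str[m_neg] = _fmt_dates(event_dt[m_neg] + 5 + onset[m_neg])
        usable[m_neg] = False
    # month-precision starts
    m_part = (rng.random(n) < config.partial_date_rate) & ~m_neg
    if m_part.any():
        st_str[m_part] = np.array([s[:6] for s in st_str[m_part]], dtype=object)
        usable[m_part] = False
    # missing event dates / therapy rows
    m_miss = rng.random(n) < config.onset_missing_rate
    drop_ev = m_miss & (rng.random(n) < 0.5)
    drop_start = m_miss & ~drop_ev
    ev_str[drop_ev] = ""
    st_str[drop_start] = ""
    usable &= ~m_miss

    fda_str = _fmt_dates(fda).astype(object) if n else np.array([], dtype=object)

    # duplicate versions: designated retained = version 02
    n_dup = int(np.floor(config.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    pid = np.char.add(caseids, "02").astype(object) if n else np.array([], dtype=object)

    n_del = int(np.floor(config.deletion_rate * n))
    del_idx = rng.choice(n, size=n_del, replace=False) if n_del else np.array([], dtype=int)
    deleted = frozenset(caseids[del_idx].tolist())

    demo_rows = {
        "PRIMARYID": list(pid), "CASEID": list(caseids),
        "FDA_DT": list(fda_str), "EVENT_DT": list(ev_str),
        "SEX": ["" if s == "missing" else s for s in sex],
        "AGE": list(age_val), "AGE_COD": list(age_cod),
        "OCCP_COD": ["" if r == "missing" else r for r in reporter],
        "REPORTER_COUNTRY": ["" if c == "missing" else c for c in country],
    }
    demo = pd.DataFrame(demo_rows, dtype=str)

    # duplicate (older) DEMO versions: half earlier FDA_DT, half same-date
    # smaller PRIMARYID — both resolve to version 02 under the keep-latest rule
    if n_dup:
        old = demo.iloc[dup_idx].copy()
        old["PRIMARYID"] = [c + "01" for c in caseids[dup_idx]]
        older_dt = rng.random(n_dup) < 0.5
        shift = rng.integers(10, 61, size=n_dup)
        old_fda = fda[dup_idx] - np.where(older_dt, shift, 0)
        old["FDA_DT"] = list(_fmt_dates(old_fda))
        demo = pd.concat([demo, old], ignore_index=True)

    # child tables (duplicate versions repeat the retained version's rows)
    def _with_dups(frame: pd.DataFrame) -> pd.DataFrame:
        if not n_dup or frame.empty:
            return frame.reset_index(drop=True)
        extra = frame[frame["CASEID"].isin(set(caseids[dup_idx]))].copy()
        extra["PRIMARYID"] = extra["CASEID"] + "01"
        return pd.concat([frame, extra], ignore_index=True)

    drug_name = np.array(drugs, dtype=object)[drug_idx]
    m_con = rng.random(n) < config.concomitant_rate
    con_choice = rng.integers(0, max(len(drugs) - 1, 1), size=n)
    con_idx = np.flatnonzero(m_con)
    con_names = np.array(
        [[d for d in drugs if d != drug_name[i]][con_choice[i] % (len(drugs) - 1)]
         for i in con_idx] if len(drugs) > 1 else [],
        dtype=object)
    if len(drugs) <= 1:
        con_idx = np.array([], dtype=int)
    drug_df = pd.DataFrame({
        "PRIMARYID": np.concatenate([pid, pid[con_idx]]),
        "CASEID": np.concatenate([caseids, caseids[con_idx]]),
        "DRUG_SEQ": ["1"] * n + ["2"] * len(con_idx),
        "ROLE_COD": ["PS"] * n + ["C"] * len(con_idx),
        "DRUGNAME": np.concatenate([drug_name, con_names]),
    }, dtype=str)[TABLE_SCHEMAS["DRUG"]] if n else pd.DataFrame(
        columns=TABLE_SCHEMAS["DRUG"], dtype=str)

    ci, ei = np.nonzero(event_mat)
    filler_idx = np.flatnonzero(~event_mat.any(axis=1))
    ev_names = np.array(events, dtype=object)
    reac_df = pd.DataFrame({
        "PRIMARYID": np.concatenate([pid[ci], pid[filler_idx]]),
        "CASEID": np.concatenate([caseids[ci], caseids[filler_idx]]),
        "PT": np.concatenate(
            [ev_names[ei], np.full(len(filler_idx), config.filler_pt, dtype=object)]),
    }, dtype=str) if n else pd.DataFrame(columns=TABLE_SCHEMAS["REAC"], dtype=str)
    reac_df = reac_df.sort_values("CASEID", kind="mergesort").reset_index(drop=True) \
        if n else reac_df
    reac_df = reac_df[TABLE_SCHEMAS["REAC"]] if n else reac_df

    m_outc = outcome != "missing" if n else np.array([], dtype=bool)
    outc_df = pd.DataFrame({
        "PRIMARYID": pid[m_outc], "CASEID": caseids[m_outc],
        "OUTC_COD": outcome[m_outc],
    }, dtype=str)[TABLE_SCHEMAS["OUTC"]] if n else pd.DataFrame(
        columns=TABLE_SCHEMAS["OUTC"], dtype=str)

    m_ther = np.array([s != "" for s in st_str], dtype=bool) if n else np.array([], dtype=bool)
    ther_df = pd.DataFrame({
        "PRIMARYID": pid[m_ther], "CASEID": caseids[m_ther],
        "DSG_DRUG_SEQ": "1", "START_DT": st_str[m_ther],
    }, dtype=str)[TABLE_SCHEMAS["THER"]] if n else pd.DataFrame(
        columns=TABLE_SCHEMAS["THER"], dtype=str)

    truth = SynthTruth(
        config=config,
        retained_primaryids={c: c + "02" for c in caseids},
        deleted_caseids=deleted,
        case_drug=pd.Series(drug_name, index=caseids),
        event_matrix=pd.DataFrame(event_mat, index=caseids, columns=events),
        onset_days=pd.Series(onset, index=caseids),
        onset_usable=pd.Series(usable, index=caseids),
    )
    return QuarterBundle(
        label=config.quarter,
        demo=demo.reset_index(drop=True),
        drug=_with_dups(drug_df),
        reac=_with_dups(reac_df),
        outc=_with_dups(outc_df),
        ther=_with_dups(ther_df),
        deleted=deleted,
        truth=truth,
    )


def write_ascii(bundle: QuarterBundle, directory: str | Path) -> list[Path]:
    """Write a bundle as '$'-delimited FAERS-style text files.

    Emits ``DEMO<label>.txt`` ... ``THER<label>.txt`` plus
    ``DELETED<label>.txt`` (one CASEID per line, no header). Values
    containing the delimiter are rejected.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for table, frame in bundle.tables().items():
        path = directory / f"{table}{bundle.label}.txt"
        write_table(frame, path, table)
        written.append(path)
    del_path = directory / f"DELETED{bundle.label}.txt"
    del_path.write_text(
        "".join(f"{c}\n" for c in sorted(bundle.deleted)), encoding="utf-8")
    written.append(del_path)
    return written
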