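"""Case-level curation of raw quarterly bundles.

Three cleaning stages, applied in order:

1. hierarchical deduplication — per CASEID keep the report version with the
   most recent FDA receipt date (FDA_DT), breaking exact ties by the larger
   PRIMARYID, then remove cases named on the deleted-cases list;
2. drug-of-interest selection — retain cases with at least one
   primary-suspect (role PS) drug row whose normalised name matches a
   user pattern;
3. medical coding — map each reaction PT to its primary System Organ Class
   through a user-supplied two-column dictionary (a packaged toy dictionary
   covers the PTs used in tests and demos; real MedDRA is licensed and must
   be supplied by the user).

The curated corpus is held as a :class:`CaseCorpus` (one row per retained
case plus child drug/reaction/outcome frames); :func:`iter_cases` yields
per-case :class:`ReportCase` records from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from . import faers_io
from .faers_io import MISSING, QuarterBundle

UNMAPPED = "UNMAPPED"


@dataclass
class ReportCase:
    """One deduplicated safety report."""

    caseid: str
    primaryid: str
    fda_dt: str
    sex: str
    age_group: str
    reporter: str
    country: str
    event_year: str
    drugs: list  # (drugname, role_cod) pairs
    reactions: list  # PT strings
    reaction_socs: list
    outcomes: list
    onset_days: int | None = None


@dataclass
class CaseCorpus:
    """Curated corpus: one row per retained case plus child tables."""

    cases: pd.DataFrame      # caseid, primaryid, fda_dt, sex, age_group,
    #                          reporter, country, event_year, event_dt, start_dt
    drugs: pd.DataFrame      # caseid, role_cod, drugname
    reactions: pd.DataFrame  # caseid, pt [, soc]
    outcomes: pd.DataFrame   # caseid, outc_cod
    meddra_version: str | None = None

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def subset(self, caseids: set) -> "CaseCorpus":
        keep = self.cases["caseid"].isin(caseids)
        return CaseCorpus(
            cases=self.cases[keep].reset_index(drop=True),
            drugs=self.drugs[self.drugs["caseid"].isin(caseids)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["caseid"].isin(caseids)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["caseid"].isin(caseids)].reset_index(drop=True),
            meddra_version=self.meddra_version,
        )


@dataclass
class CurationReport:
    n_input_versions: int = 0
    n_cases: int = 0
    n_deleted: int = 0
    unmapped_pts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: deduplication

def deduplicate(demo: pd.DataFrame, deletion_list: Iterable[str] = ()) -> list[str]:
    """Return the retained PRIMARYID per case, sorted by CASEID.

    Keep-latest rule: per CASEID the maximal FDA_DT wins; exact FDA_DT ties
    go to the larger PRIMARYID (numeric comparison when the ids parse as
    integers, else lexicographic). Cases on the deletion list are then
    dropped. Missing/unparseable FDA_DT sorts oldest.
    """
    if demo.empty:
        return []
    deletion = set(deletion_list)
    df = demo[["PRIMARYID", "CASEID", "FDA_DT"]].copy()
    df["_dt"] = pd.to_numeric(df["FDA_DT"], errors="coerce").fillna(-1)
    pid_num = pd.to_numeric(df["PRIMARYID"], errors="coerce")
    # numeric ids dominate when present; string order decides otherwise
    df["_pidn"] = pid_num.fillna(float("-inf"))
    df = df.sort_values(
        ["CASEID", "_dt", "_pidn", "PRIMARYID"], kind="mergesort")
    kept = df.groupby("CASEID", sort=True).tail(1)
    kept = kept[~kept["CASEID"].isin(deletion)]
    return kept.sort_values("CASEID")["PRIMARYID"].tolist()


# ---------------------------------------------------------------------------
# stage 2: corpus assembly + drug selection

def _earliest_ps_start(bundle: QuarterBundle, retained: pd.Series) -> pd.Series:
    """Earliest therapy START_DT of a primary-suspect drug, per PRIMARYID."""
    drug = bundle.drug
    ps = drug[drug["ROLE_COD"].str.upper() == "PS"][["PRIMARYID", "DRUG_SEQ"]]
    ther = bundle.ther
    if ther.empty or ps.empty:
        return pd.Series(dtype=str)
    j = ther.merge(
        ps, left_on=["PRIMARYID", "DSG_DRUG_SEQ"],
        right_on=["PRIMARYID", "DRUG_SEQ"], how="inner")
    j = j[j["START_DT"] != ""]
    if j.empty:
        return pd.Series(dtype=str)
    # order partial dates as their earliest covered day
    j["_key"] = j["START_DT"].str.pad(8, side="right", fillchar="0")
    j = j.sort_values(["PRIMARYID", "_key"], kind="mergesort")
    first = j.groupby("PRIMARYID", sort=False).head(1)
    return first.set_index("PRIMARYID")["START_DT"]


def build_corpus(bundle: QuarterBundle) -> tuple[CaseCorpus, CurationReport]:
    """Deduplicate a bundle and assemble the typed case corpus."""
    report = CurationReport(n_input_versions=len(bundle.demo))
    retained = deduplicate(bundle.demo, bundle.deleted)
    report.n_deleted = len(
        set(bundle.demo["CASEID"]) & set(bundle.deleted))
    pid_set = set(retained)

    demo = bundle.demo[bundle.demo["PRIMARYID"].isin(pid_set)].copy()
    demo = demo.sort_values("CASEID", kind="mergesort").reset_index(drop=True)

    start = _earliest_ps_start(bundle, demo["PRIMARYID"])
    cases = pd.DataFrame({
        "caseid": demo["CASEID"],
        "primaryid": demo["PRIMARYID"],
        "fda_dt": demo["FDA_DT"],
        "sex": demo["SEX"].map(faers_io.decode_sex),
        "age_group": [
            faers_io.age_to_group(a if a != "" else None, u)
            for a, u in zip(demo["AGE"], demo["AGE_COD"])
        ],
        "reporter": demo["OCCP_COD"].map(faers_io.decode_reporter),
        "country": demo["REPORTER_COUNTRY"].replace("", MISSING),
        "event_year": [
            s[:4] if len(s) >= 4 and s[:4].isdigit() else MISSING
            for s in demo["FDA_DT"]
        ],
        "event_dt": demo["EVENT_DT"],
        "start_dt": demo["PRIMARYID"].map(start).fillna(""),
    })

    def _children(frame: pd.DataFrame, cols: dict) -> pd.DataFrame:
        sub = frame[frame["PRIMARYID"].isin(pid_set)]
        out = sub[["CASEID", *cols]].rename(
            columns={"CASEID": "caseid", **cols})
        return out.reset_index(drop=True)

    drugs = _children(bundle.drug, {"ROLE_COD": "role_cod", "DRUGNAME": "drugname"})
    reactions = _children(bundle.reac, {"PT": "pt"})
    reactions = reactions[reactions["pt"].str.strip() != ""].reset_index(drop=True)
    outcomes = _children(bundle.outc, {"OUTC_COD": "outc_cod"})

    report.n_cases = len(cases)
    corpus = CaseCorpus(
        cases=cases, drugs=drugs, reactions=reactions, outcomes=outcomes)
    return corpus, report


_NORM_RE = re.compile(r"[^A-Z0-9]+")


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim and collapse punctuation/whitespace runs to a space."""
    return _NORM_RE.sub(" ", (name or "").upper()).strip()


def primary_suspect_caseids(corpus: CaseCorpus, name_patterns: list[str]) -> set:
    """Cases with >=1 role-PS drug row matching any normalised pattern."""
    if not name_patterns:
        raise ValueError("name_patterns must be non-empty")
    pats = [normalize_drug_name(p) for p in name_patterns]
    d = corpus.drugs
    ps = d[d["role_cod"].str.upper() == "PS"]
    if ps.empty:
        return set()
    norm = ps["drugname"].map(normalize_drug_name)
    hit = pd.Series(False, index=ps.index)
    for p in pats:
        hit |= norm.str.contains(re.escape(p), regex=True)
    return set(ps.loc[hit, "caseid"])


def select_primary_suspect(corpus: CaseCorpus, name_patterns: list[str]) -> CaseCorpus:
    """Retain only cases whose primary-suspect drug matches a pattern."""
    return corpus.subset(primary_suspect_caseids(corpus, name_patterns))


# ---------------------------------------------------------------------------
# stage 3: MedDRA PT -> SOC coding

@dataclass
class MeddraMap:
    """PT -> primary SOC dictionary (case-insensitive on lookup)."""

    pt_to_soc: dict
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self._fold = {k.strip().casefold(): v for k, v in self.pt_to_soc.items()}

    def soc(self, pt: str) -> str | None:
        return self._fold.get((pt or "").strip().casefold())

    @classmethod
    def from_file(cls, path: str | Path, version: str | None = None) -> "MeddraMap":
        """Load a two-column delimited (PT, SOC) file with a header line."""
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ValueError(f"{path}: empty mapping file")
        delim = "\t" if "\t" in lines[0] else ","
        mapping = {}
        for ln in lines[1:]:
            if not ln.strip():
                continue
            parts = ln.split(delim)
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed mapping line {ln!r}")
            mapping[parts[0].strip()] = parts[1].strip()
        return cls(pt_to_soc=mapping, version=version or path.stem)


def load_toy_meddra() -> MeddraMap:
    """Packaged toy PT->SOC dictionary (synthetic stand-in for MedDRA)."""
    ref = resources.files("pvsignal") / "data" / "toy_meddra.tsv"
    with resources.as_file(ref) as path:
        return MeddraMap.from_file(path, version="toy")


def code_events(corpus: CaseCorpus, mmap: MeddraMap) -> tuple[CaseCorpus, dict]:
    """Annotate every reaction with its primary SOC.

    PTs absent from the dictionary keep SOC='UNMAPPED' and are returned in
    the report as ``{pt: count}`` rather than being dropped.
    """
    reactions = corpus.reactions.copy()
    socs = reactions["pt"].map(lambda p: mmap.soc(p) or UNMAPPED)
    reactions["soc"] = socs
    unmapped = (
        reactions.loc[socs == UNMAPPED, "pt"].value_counts().to_dict())
    coded = CaseCorpus(
        cases=corpus.cases, drugs=corpus.drugs, reactions=reactions,
        outcomes=corpus.outcomes, meddra_version=mmap.version)
    return coded, unmapped


def iter_cases(corpus: CaseCorpus) -> Iterator[ReportCase]:
    """Yield per-case records from a corpus (onset_days left unset)."""
    drugs = {k: list(zip(g["drugname"], g["role_cod"]))
             for k, g in corpus.drugs.groupby("caseid")}
    reac = {
        k: (list(g["pt"]), list(g["soc"]) if "soc" in g else [])
        for k, g in corpus.reactions.groupby("caseid")
    }
    outc = {k: list(g["outc_cod"]) for k, g in corpus.outcomes.groupby("caseid")}
    for row in corpus.cases.itertuples(index=False):
        pts, socs = reac.get(row.caseid, ([], []))
        yield ReportCase(
            caseid=row.caseid, primaryid=row.primaryid, fda_dt=row.fda_dt,
            sex=row.sex, age_group=row.age_group, reporter=row.reporter,
            country=row.country, event_year=row.event_year,
            drugs=drugs.get(row.caseid, []), reactions=pts,
            reaction_socs=socs, outcomes=outc.get(row.caseid, []),
        )
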