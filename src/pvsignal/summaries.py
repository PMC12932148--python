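"""Descriptive characterisation of a curated, drug-filtered corpus.

Reproduces the standard "clinical characteristics" report layout: sex, age
group, reporter occupation, reporting year and top-5 reporter countries as
fractions of all cases (missing shown as "Not specified"), and outcome
codes as fractions of all outcome codes reported — a case can carry several
outcome codes, each counted once per case, so the outcome denominator is
the code total, not the case count. Percentages are rounded half-up to two
decimals, matching report-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import percent
from .curation import CaseCorpus
from .faers_io import MISSING

NOT_SPECIFIED = "Not specified"

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization—initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention to prevent permanent impairment/damage",
    "OT": "Other",
}


@dataclass
class FrequencyTable:
    """One descriptive dimension: (category, count, percent) rows."""

    dimension: str
    rows: pd.DataFrame  # columns: category, count, percent
    denominator: int
    denominator_policy: str  # 'cases' or 'outcome_codes'

    def percent_of(self, category: str) -> float:
        hit = self.rows[self.rows["category"] == category]
        if hit.empty:
            raise KeyError(f"{self.dimension}: no category {category!r}")
        return float(hit["percent"].iloc[0])


def _freq(
    dimension: str,
    series: pd.Series,
    denominator: int,
    policy: str,
    order: list[str] | None = None,
    top: int | None = None,
) -> FrequencyTable:
    counts = series.value_counts()
    if order is not None:
        cats = [c for c in order if c in counts.index]
        cats += [c for c in counts.index if c not in cats]
    else:
        cats = list(counts.index)
    if top is not None:
        cats = [c for c in cats if c != NOT_SPECIFIED][:top]
    rows = pd.DataFrame({
        "category": cats,
        "count": [int(counts[c]) for c in cats],
        "percent": [percent(int(counts[c]), denominator) for c in cats],
    })
    return FrequencyTable(dimension, rows, denominator, policy)


def characteristics_table(corpus: CaseCorpus) -> dict[str, FrequencyTable]:
    """All descriptive tables for a curated, drug-filtered corpus.

    Keys: sex, age, reporter, year, country (top-5), outcome.
    """
    if corpus.n_cases == 0:
        raise ValueError("empty corpus: nothing to describe")
    n = corpus.n_cases
    cases = corpus.cases
    relabel = lambda s: s.replace(MISSING, NOT_SPECIFIED)  # noqa: E731

    tables = {
        "sex": _freq(
            "Sex", relabel(cases["sex"]).replace({"M": "Male", "F": "Female"}),
            n, "cases", order=["Male", "Female", NOT_SPECIFIED]),
        "age": _freq(
            "Age", relabel(cases["age_group"]), n, "cases",
            order=["<18", "18-65", ">65", NOT_SPECIFIED]),
        "reporter": _freq(
            "Reporter", relabel(cases["reporter"]), n, "cases"),
        "year": _freq(
            "Reporting year", relabel(cases["event_year"]), n, "cases",
            order=sorted(c for c in cases["event_year"].unique() if c != MISSING)),
        "country": _freq(
            "Top 5 reporting countries", relabel(cases["country"]), n,
            "cases", top=5),
    }

    # outcome: denominator is the number of outcome codes reported
    # (one count per case per distinct code)
    oc = corpus.outcomes[["caseid", "outc_cod"]].drop_duplicates()
    oc = oc[oc["outc_cod"].isin(OUTCOME_LABELS)]
    denom = len(oc)
    if denom:
        labeled = oc["outc_cod"].map(OUTCOME_LABELS)
        tables["outcome"] = _freq(
            "Outcome", labeled, denom, "outcome_codes",
            order=list(OUTCOME_LABELS.values()))
    else:
        tables["outcome"] = FrequencyTable(
            "Outcome",
            pd.DataFrame(columns=["category", "count", "percent"]),
            0, "outcome_codes")
    return tables


def format_characteristics(tables: dict[str, FrequencyTable]) -> str:
    """Render the descriptive tables as one delimited text block."""
    blocks = []
    for key in ("sex", "age", "reporter", "year", "country", "outcome"):
        if key not in tables:
            continue
        t = tables[key]
        lines = [f"{t.dimension}\tNumber of cases\tProportion of cases (%)"]
        for row in t.rows.itertuples(index=False):
            lines.append(f"{row.category}\t{row.count}\t{row.percent:.2f}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
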