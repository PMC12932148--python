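"""2x2 disproportionality tables for one target drug against the corpus.

For each adverse-event term (MedDRA PT, or its SOC grouping) the table is

    =============  =========  ============
                   event       no event
    target drug        a           b
    other drugs        c           d
    =============  =========  ============

Counting unit is the *case* (presence/absence): a case reporting the same
term several times contributes once, so ``a + b`` equals the number of
target-drug cases for every term and ``a + b + c + d`` equals the corpus
size. The comparator is the whole ingested corpus (no drug-class
restriction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .curation import CaseCorpus

LEVEL_PT = "PT"
LEVEL_SOC = "SOC"


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name}={v} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under row/column independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_tables(
    corpus: CaseCorpus,
    target_caseids: Iterable[str],
    level: str = LEVEL_PT,
) -> list[ContingencyTable]:
    """One table per term observed in the corpus, ordered by descending a.

    ``target_caseids`` flags the target-drug cases inside ``corpus`` (the
    corpus itself is the full comparator population). SOC level requires a
    coded corpus (reactions carry a ``soc`` column).
    """
    if corpus.n_cases == 0:
        raise ValueError("corpus has zero cases")
    target = set(target_caseids)
    if not target:
        raise ValueError("target case set is empty")
    if level not in (LEVEL_PT, LEVEL_SOC):
        raise ValueError(f"level must be {LEVEL_PT!r} or {LEVEL_SOC!r}")
    col = "pt" if level == LEVEL_PT else "soc"
    if col not in corpus.reactions.columns:
        raise ValueError("corpus reactions are not coded to SOC; run code_events")

    n_total = corpus.n_cases
    n_target = int(corpus.cases["caseid"].isin(target).sum())

    pairs = corpus.reactions[["caseid", col]].drop_duplicates()
    is_target = pairs["caseid"].isin(target)
    a_counts = pairs.loc[is_target, col].value_counts()
    all_counts = pairs[col].value_counts()

    tables = []
    for term, total in all_counts.items():
        a = int(a_counts.get(term, 0))
        c = int(total) - a
        tables.append(ContingencyTable(
            term=str(term), level=level, a=a, b=n_target - a,
            c=c, d=n_total - n_target - c))
    tables.sort(key=lambda t: (-t.a, t.term))
    return tables
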