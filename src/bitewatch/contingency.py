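"""Four-grid (2x2) contingency tables for drug-event pairs.

For a target drug and target event over a universe of N deduplicated
reports the four-grid is::

                    target event   other events
    target drug          a              b          a+b
    other drugs          c              d          c+d
                        a+c            b+d          N

The counting unit is the report: a report contributes at most one to each
cell, a report with the drug and at least one matching event counts once
in ``a``, and the four cells partition the universe (a+b+c+d = N).
Event selectors may address a single preferred term (PT level) or a whole
system organ class (SOC level, any PT mapping to the SOC matches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        """Swap the drug/event roles (a and d fixed, b and c swapped)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass
class MappedUniverse:
    """A deduplicated, vocabulary-mapped report universe.

    ``drug_sets``/``pt_sets``/``soc_sets`` map each canonical drug, PT key
    and SOC to the set of report ids mentioning it; ``n_total`` is the
    number of deduplicated reports.  Catalogued drugs or events without a
    single mention are legal (their sets are empty), so zero-margin tables
    are representable.
    """

    n_total: int
    drug_sets: dict[str, frozenset] = field(default_factory=dict)
    pt_sets: dict[str, frozenset] = field(default_factory=dict)
    soc_sets: dict[str, frozenset] = field(default_factory=dict)
    pt_display: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        report_ids: Iterable,
        drug_pairs: pd.DataFrame,
        event_pairs: pd.DataFrame,
        extra_drugs: Iterable[str] = (),
        extra_pts: Iterable[str] = (),
        extra_socs: Iterable[str] = (),
    ) -> "MappedUniverse":
        """Build from long-format (primary_id, drug) and
        (primary_id, pt[, soc]) pair frames restricted to retained ids."""
        ids = set(str(i) for i in report_ids)
        drug_sets: dict[str, set] = {str(d): set() for d in extra_drugs}
        for pid, drug in zip(drug_pairs["primary_id"], drug_pairs["drug"]):
            pid = str(pid)
            if pid in ids:
                drug_sets.setdefault(str(drug), set()).add(pid)
        pt_sets: dict[str, set] = {str(p).casefold(): set() for p in extra_pts}
        soc_sets: dict[str, set] = {str(s): set() for s in extra_socs}
        pt_display: dict[str, str] = {}
        socs = event_pairs["soc"] if "soc" in event_pairs.columns else [None] * len(event_pairs)
        for pid, pt, soc in zip(event_pairs["primary_id"], event_pairs["pt"], socs):
            pid = str(pid)
            if pid not in ids:
                continue
            key = str(pt).strip().casefold()
            pt_sets.setdefault(key, set()).add(pid)
            pt_display.setdefault(key, str(pt).strip())
            if soc is not None and not pd.isna(soc):
                soc_sets.setdefault(str(soc), set()).add(pid)
        return cls(
            n_total=len(ids),
            drug_sets={k: frozenset(v) for k, v in drug_sets.items()},
            pt_sets={k: frozenset(v) for k, v in pt_sets.items()},
            soc_sets={k: frozenset(v) for k, v in soc_sets.items()},
            pt_display=pt_display,
        )

    def event_set(self, event: str, level: str) -> frozenset:
        if level == "pt":
            key = event.strip().casefold()
            if key not in self.pt_sets:
                raise KeyError(f"unknown PT selector {event!r}")
            return self.pt_sets[key]
        if level == "soc":
            if event not in self.soc_sets:
                raise KeyError(f"unknown SOC selector {event!r}")
            return self.soc_sets[event]
        raise ValueError(f"level must be 'pt' or 'soc', got {level!r}")


def build_table(
    drug: str, event: str, universe: MappedUniverse, level: str = "pt"
) -> ContingencyTable:
    """Four-grid counts for one (drug, event) pair over the universe."""
    if drug not in universe.drug_sets:
        raise KeyError(f"unknown drug selector {drug!r}")
    drug_ids = universe.drug_sets[drug]
    event_ids = universe.event_set(event, level)
    a = len(drug_ids & event_ids)
    b = len(drug_ids) - a
    c = len(event_ids) - a
    d = universe.n_total - a - b - c
    return ContingencyTable(a, b, c, d)


def build_all_tables(
    drugs: Sequence[str],
    events: Sequence[str],
    universe: MappedUniverse,
    level: str = "pt",
) -> list[tuple[str, str, ContingencyTable]]:
    """One table per requested (drug, event) pair; a=0 pairs are retained
    (downstream statistics mark them non-evaluable)."""
    return [
        (drug, event, build_table(drug, event, universe, level))
        for drug in drugs
        for event in events
    ]


def tables_to_frame(
    tables: Iterable[tuple[str, str, ContingencyTable]], level: str = "pt"
) -> pd.DataFrame:
    """Long-format export: (drug, event_level, event, a, b, c, d, n_total)."""
    rows = [
        {
            "drug": drug,
            "event_level": level,
            "event": event,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "n_total": t.n_total,
        }
        for drug, event, t in tables
    ]
    return pd.DataFrame(
        rows, columns=["drug", "event_level", "event", "a", "b", "c", "d", "n_total"]
    )
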