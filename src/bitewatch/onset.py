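"""Time to onset (TTO): therapy start to adverse-event onset, in days.

TTO is the whole-day difference between the event date and the start of
the earliest therapy episode for the implicated drug within the same
report.  Same-day onsets are mapped to 1 day (spontaneous-report
convention: reported minima are one day, not zero); negative intervals
and partial or absent dates are excluded and counted, never imputed.
Because spontaneous-report TTO is heavy-tailed, the mean-with-range
headline is always accompanied by the median and quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from bitewatch.model import TherapyEpisode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OnsetRecord:
    case_id: str
    drug: str
    tto_days: int

    def __post_init__(self) -> None:
        if self.tto_days < 1:
            raise ValueError("tto_days must be >= 1")


@dataclass(frozen=True)
class OnsetSummary:
    drug: str
    n: int
    mean_days: float
    min_days: int
    max_days: int
    median_days: float
    q1: float
    q3: float


def compute_tto(therapy: TherapyEpisode, event_date: date | None) -> int | None:
    """Days from therapy start to event onset, or ``None`` if excluded.

    Same-day onset maps to 1; a negative interval or a missing/partial
    date on either side excludes the record.
    """
    if therapy.start_date is None or event_date is None:
        return None
    days = (event_date - therapy.start_date).days
    if days < 0:
        return None
    return max(days, 1)


def summarize_tto(
    records: Iterable[OnsetRecord], drugs: Sequence[str] | None = None
) -> list[OnsetSummary]:
    """Per-drug TTO summaries (mean, range, median, quartiles).

    When ``drugs`` is given, drugs without any record are omitted with a
    warning; otherwise every drug present in ``records`` is summarized.
    Summaries are invariant to record order.
    """
    frame = records_to_frame(records)
    wanted = list(drugs) if drugs is not None else sorted(frame["drug"].unique())
    out: list[OnsetSummary] = []
    for drug in wanted:
        days = frame.loc[frame["drug"] == drug, "tto_days"]
        if days.empty:
            logger.warning("no onset records for %s; omitted from summary", drug)
            continue
        out.append(
            OnsetSummary(
                drug=drug,
                n=int(days.size),
                mean_days=float(days.mean()),
                min_days=int(days.min()),
                max_days=int(days.max()),
                median_days=float(days.median()),
                q1=float(days.quantile(0.25)),
                q3=float(days.quantile(0.75)),
            )
        )
    return out


def records_to_frame(records: Iterable[OnsetRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "drug": [r.drug for r in records],
            "tto_days": pd.Series([r.tto_days for r in records], dtype=int),
        }
    )


def summaries_to_frame(summaries: Iterable[OnsetSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": s.drug,
                "n": s.n,
                "mean_days": s.mean_days,
                "min_days": s.min_days,
                "max_days": s.max_days,
                "median_days": s.median_days,
                "q1": s.q1,
                "q3": s.q3,
            }
            for s in summaries
        ],
        columns=["drug", "n", "mean_days", "min_days", "max_days", "median_days", "q1", "q3"],
    )
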