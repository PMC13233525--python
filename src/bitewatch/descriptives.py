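"""Demographic and clinical summaries of the analysed case set.

Produces the conventional pharmacovigilance cohort table: per-drug and
total case counts; mean +/- SD age and weight over present values; count
(percent) blocks for sex, reporter occupation, country (with an "Other
countries" bin outside a configurable named list), seriousness outcome
and reporting year.  Percentages use the per-drug n as denominator and
half-up rounding to two decimals; outcome *shares* (a drug's share of
all deaths, say) use the outcome total as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

#: Countries reported individually by default; everything else is binned.
DEFAULT_NAMED_COUNTRIES = (
    "Brazil",
    "China",
    "France",
    "Italy",
    "Japan",
    "Spain",
    "United Kingdom",
    "United States",
)

#: Outcome categories from most to least serious; a case with several
#: outcome codes is tabulated once, under the most serious one.
OUTCOME_SEVERITY = (
    "death",
    "life-threatening",
    "disability",
    "required-intervention",
    "hospitalization",
    "other-serious",
    "unknown",
)

CATEGORICAL_BLOCKS = ("sex", "reporter", "country", "outcome", "year")


def percentage(numerator: int, denominator: int) -> float | None:
    """100*numerator/denominator, half-up to 2 decimals; ``None`` when the
    denominator is zero."""
    if denominator == 0:
        return None
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Tidy and wide views of the cohort table.

    ``long`` has one row per (drug, block, category) with count and
    percent on the per-drug denominator; ``wide`` mirrors the
    variables-by-drugs layout with "count(pct)" cells; ``stats`` holds n
    and the age/weight mean +/- SD per drug; ``outcome_shares`` gives
    each drug's share of every outcome's total.
    """

    stats: pd.DataFrame
    long: pd.DataFrame
    wide: pd.DataFrame
    outcome_shares: pd.DataFrame

    @property
    def n_total(self) -> int:
        return int(self.stats.loc["Total", "n"])


def _primary_outcome(raw: str) -> str:
    cats = [c for c in str(raw).split(";") if c] if raw else []
    for level in OUTCOME_SEVERITY:
        if level in cats:
            return level
    return "unknown"


def summarize_cohort(
    cases: pd.DataFrame,
    named_countries: tuple[str, ...] = DEFAULT_NAMED_COUNTRIES,
) -> CohortSummary:
    """Summarize a cohort of (case, drug) assignments.

    ``cases`` carries one row per case-drug assignment with columns
    ``drug, age_years, weight_kg, sex, reporter, country, outcomes,
    year`` (``outcomes`` ``;``-joined).  A case assigned to two drugs
    appears under both drug columns, so the Total column is the sum of
    the drug columns.  An empty cohort yields an empty summary.
    """
    cols = ["drug", "age_years", "weight_kg", "sex", "reporter", "country",
            "outcomes", "year"]
    if cases.empty:
        empty = pd.DataFrame()
        return CohortSummary(stats=empty, long=empty, wide=empty, outcome_shares=empty)
    work = cases.copy()
    for col in cols:
        if col not in work.columns:
            work[col] = pd.NA
    named = {c.casefold(): c for c in named_countries}
    work["country_bin"] = [
        named.get(str(c).strip().casefold(), "Other countries")
        if pd.notna(c) and str(c).strip() and str(c).strip().lower() != "unknown"
        else "Unknown"
        for c in work["country"]
    ]
    work["outcome"] = [_primary_outcome(o) for o in work["outcomes"].fillna("")]
    drugs = sorted(work["drug"].unique())

    stats_rows = {}
    for label, grp in [("Total", work)] + [(d, work[work["drug"] == d]) for d in drugs]:
        age = pd.to_numeric(grp["age_years"], errors="coerce").dropna()
        wt = pd.to_numeric(grp["weight_kg"], errors="coerce").dropna()
        stats_rows[label] = {
            "n": len(grp),
            "age_mean": age.mean() if len(age) else float("nan"),
            "age_sd": age.std(ddof=1) if len(age) > 1 else (0.0 if len(age) == 1 else float("nan")),
            "weight_mean": wt.mean() if len(wt) else float("nan"),
            "weight_sd": wt.std(ddof=1) if len(wt) > 1 else (0.0 if len(wt) == 1 else float("nan")),
        }
    stats = pd.DataFrame(stats_rows).T
    stats["n"] = stats["n"].astype(int)

    block_cols = {
        "sex": "sex",
        "reporter": "reporter",
        "country": "country_bin",
        "outcome": "outcome",
        "year": "year",
    }
    long_rows = []
    for block, col in block_cols.items():
        values = work[col].fillna("unknown").astype(str)
        categories = sorted(values.unique())
        for label, grp_idx in [("Total", work.index)] + [
            (d, work.index[work["drug"] == d]) for d in drugs
        ]:
            n_label = len(grp_idx)
            counts = values.loc[grp_idx].value_counts()
            for cat in categories:
                cnt = int(counts.get(cat, 0))
                long_rows.append(
                    {
                        "drug": label,
                        "block": block,
                        "category": cat,
                        "count": cnt,
                        "pct": percentage(cnt, n_label),
                    }
                )
    long = pd.DataFrame(long_rows)

    wide_rows = []
    for block in block_cols:
        sub = long[long["block"] == block]
        for cat in sub["category"].unique():
            row = {"variable": f"{block}: {cat}"}
            for label in ["Total"] + drugs:
                cell = sub[(sub["drug"] == label) & (sub["category"] == cat)]
                cnt = int(cell["count"].iloc[0])
                pct = cell["pct"].iloc[0]
                row[label] = f"{cnt}({pct:.2f})" if pct is not None else f"{cnt}(NA)"
            wide_rows.append(row)
    wide = pd.DataFrame(wide_rows).set_index("variable")

    # Share-of-outcome: each drug's count over that outcome's total.
    outc = long[(long["block"] == "outcome") & (long["drug"] != "Total")]
    totals = (
        long[(long["block"] == "outcome") & (long["drug"] == "Total")]
        .set_index("category")["count"]
    )
    share_rows = [
        {
            "drug": r["drug"],
            "outcome": r["category"],
            "count": r["count"],
            "share_pct": percentage(r["count"], int(totals.get(r["category"], 0))),
        }
        for _, r in outc.iterrows()
    ]
    outcome_shares = pd.DataFrame(share_rows)

    return CohortSummary(stats=stats, long=long, wide=wide, outcome_shares=outcome_shares)
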