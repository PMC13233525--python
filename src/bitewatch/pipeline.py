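"""End-to-end orchestration: read -> dedup -> map -> count -> signal.

The pipeline consumes either a directory of FAERS-dialect files or the
in-memory tables produced by :mod:`bitewatch.simulate`, and produces the
standard analysis artifacts: PT- and SOC-level signal tables, the cohort
descriptives, per-drug time-to-onset summaries, a drugs-by-events
heatmap matrix, and a run log with dedup counts, mapping hit rates and
exclusion tallies.  All artifact files are written atomically
(write-then-rename) with fixed column orders.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from bitewatch import descriptives as desc
from bitewatch import model, onset, signals
from bitewatch.contingency import MappedUniverse, build_all_tables, tables_to_frame
from bitewatch.vocab import BITE_DRUGS, DrugDictionary, TermSet

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "drug", "event_level", "event", "a", "b", "c", "d", "n_total",
    "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi", "chi2",
    "ic", "ic025", "ebgm", "ebgm05",
    "ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "combined_pos",
    "ic_grade", "evaluable",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI surface)."""

    input_dir: str | Path | None = None
    simulate: bool = False
    n_cases: int = 20_000
    out_dir: str | Path = "bitewatch_out"
    drug_dict_path: str | Path | None = None
    pt_soc_path: str | Path | None = None
    nst_path: str | Path | None = None
    level: str = "both"  # pt | soc | both
    min_a: int = 3
    role_filter: tuple[str, ...] | None = None  # e.g. ("PS", "SS")
    universe_scope: str = "all"  # all | bite
    yates: bool = False
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if bool(self.input_dir) == bool(self.simulate):
            raise ValueError("exactly one input source: --input-dir or --simulate")
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")
        if self.level not in ("pt", "soc", "both"):
            raise ValueError("level must be pt, soc or both")
        if self.universe_scope not in ("all", "bite"):
            raise ValueError("universe_scope must be 'all' or 'bite'")


@dataclass
class MappedData:
    """Deduplicated and vocabulary-mapped dataset."""

    universe: MappedUniverse
    demo: pd.DataFrame            # retained DEMO rows
    drug_pairs: pd.DataFrame      # (primary_id, drug) unique
    matched_mentions: pd.DataFrame  # (primary_id, drug_seq, drug)
    event_pairs: pd.DataFrame     # (primary_id, pt, soc, is_nst) unique
    outc: pd.DataFrame
    ther: pd.DataFrame
    nst_ids: frozenset
    log: dict = field(default_factory=dict)


@dataclass
class AnalysisResult:
    mapped: MappedData
    signal_pt: pd.DataFrame
    signal_soc: pd.DataFrame
    cohort: desc.CohortSummary
    onset_summaries: list
    onset_records: list
    log: dict


def _match_unique_names(names: pd.Series, dictionary: DrugDictionary) -> dict[str, tuple]:
    """Map each unique lower-cased haystack to its canonical drug hits."""
    unique = names.dropna().unique()
    out: dict[str, tuple] = {}
    for hay in unique:
        hits = tuple(
            sorted(
                canon
                for canon, pats in dictionary.entries.items()
                if any(p in hay for p in pats)
            )
        )
        if hits:
            out[hay] = hits
    return out


def map_tables(
    tables: dict[str, pd.DataFrame],
    dictionary: DrugDictionary | None = None,
    terms: TermSet | None = None,
    role_filter: tuple[str, ...] | None = None,
    universe_scope: str = "all",
    extra_drugs: tuple[str, ...] = (),
    extra_pts: tuple[str, ...] = (),
) -> MappedData:
    """Deduplicate and apply the drug/event vocabularies.

    Returns the mapped universe plus the per-stage counts needed for the
    run log.  ``role_filter`` restricts drug mentions to the given FAERS
    role codes (PS/SS/C/I); ``universe_scope='bite'`` restricts the
    comparison universe to reports mentioning a dictionary drug.
    """
    dictionary = dictionary or DrugDictionary.load()
    terms = terms or TermSet.load()
    demo_raw = tables.get("DEMO", pd.DataFrame())
    n_raw = len(demo_raw)
    demo = model.dedup_demo_frame(demo_raw)
    retained = set(demo["primaryid"].astype(str)) if not demo.empty else set()

    drug_raw = tables.get("DRUG", pd.DataFrame())
    drug_frame = drug_raw[drug_raw["primaryid"].astype(str).isin(retained)].copy() \
        if not drug_raw.empty else pd.DataFrame(columns=["primaryid", "drugname"])
    if role_filter and "role_cod" in drug_frame.columns:
        drug_frame = drug_frame[
            drug_frame["role_cod"].astype(str).str.upper().isin(role_filter)
        ]
    name = drug_frame.get("drugname", pd.Series(dtype=str)).fillna("").astype(str)
    ai = drug_frame.get("prod_ai", pd.Series("", index=drug_frame.index)).fillna("").astype(str)
    haystack = (name + "\x1f" + ai).str.lower()
    hit_map = _match_unique_names(haystack, dictionary)
    hits = haystack.map(hit_map)
    matched = drug_frame[hits.notna()].copy()
    matched["_hits"] = hits[hits.notna()]
    mention_rows = []
    for pid, seq, hit in zip(
        matched["primaryid"].astype(str),
        matched.get("drug_seq", pd.Series("0", index=matched.index)).astype(str),
        matched["_hits"],
    ):
        for canon in hit:
            mention_rows.append((pid, seq, canon))
    matched_mentions = pd.DataFrame(
        mention_rows, columns=["primary_id", "drug_seq", "drug"]
    ).drop_duplicates()
    drug_pairs = matched_mentions[["primary_id", "drug"]].drop_duplicates()

    reac_raw = tables.get("REAC", pd.DataFrame())
    reac = reac_raw[reac_raw["primaryid"].astype(str).isin(retained)] \
        if not reac_raw.empty else pd.DataFrame(columns=["primaryid", "pt"])
    pts = reac["pt"].fillna("").astype(str).str.strip()
    keys = pts.str.casefold()
    soc = keys.map(terms.pt_to_soc)
    is_nst = keys.isin(terms.nst_terms)
    event_pairs = pd.DataFrame(
        {
            "primary_id": reac["primaryid"].astype(str),
            "pt": pts,
            "soc": soc,
            "is_nst": is_nst,
        }
    )
    event_pairs = event_pairs[event_pairs["pt"] != ""].drop_duplicates(
        subset=["primary_id", "pt"]
    )
    nst_ids = frozenset(event_pairs.loc[event_pairs["is_nst"], "primary_id"])

    universe_ids = retained
    if universe_scope == "bite":
        universe_ids = set(drug_pairs["primary_id"])
        demo = demo[demo["primaryid"].astype(str).isin(universe_ids)]

    universe = MappedUniverse.from_pairs(
        universe_ids,
        drug_pairs,
        event_pairs,
        extra_drugs=tuple(dictionary.entries) + tuple(extra_drugs),
        extra_pts=tuple(terms.pt_to_soc) + tuple(p.casefold() for p in extra_pts),
        extra_socs=tuple(terms.socs),
    )

    outc_raw = tables.get("OUTC", pd.DataFrame())
    outc = outc_raw[outc_raw["primaryid"].astype(str).isin(universe_ids)] \
        if not outc_raw.empty else pd.DataFrame(columns=["primaryid", "outc_cod"])
    ther_raw = tables.get("THER", pd.DataFrame())
    ther = ther_raw[ther_raw["primaryid"].astype(str).isin(universe_ids)] \
        if not ther_raw.empty else pd.DataFrame(columns=["primaryid", "dsg_drug_seq", "start_dt"])

    log = {
        "reports_raw": int(n_raw),
        "reports_deduplicated": int(len(demo)),
        "duplicates_removed": int(n_raw - len(demo)),
        "drug_rows": int(len(drug_frame)),
        "drug_rows_matched": int(len(matched)),
        "drug_match_rate": float(len(matched) / len(drug_frame)) if len(drug_frame) else 0.0,
        "event_rows": int(len(event_pairs)),
        "nst_reports": int(len(nst_ids)),
        "universe_scope": universe_scope,
        "universe_size": int(universe.n_total),
    }
    return MappedData(
        universe=universe,
        demo=demo,
        drug_pairs=drug_pairs,
        matched_mentions=matched_mentions,
        event_pairs=event_pairs,
        outc=outc,
        ther=ther,
        nst_ids=nst_ids,
        log=log,
    )


def signal_table(
    mapped: MappedData,
    drugs: list[str],
    events: list[str],
    level: str = "pt",
    priors: signals.BcpnnPriors = signals.DEFAULT_PRIORS,
    yates: bool = False,
    min_a: int = 3,
) -> pd.DataFrame:
    """Contingency counts plus all four estimators for every pair."""
    tables = build_all_tables(drugs, events, mapped.universe, level=level)
    base = tables_to_frame(tables, level=level)
    est_rows = []
    for _, _, t in tables:
        est = signals.estimate_signals(t, priors=priors, yates=yates, min_a=min_a)
        est_rows.append(
            {
                "ror": est.ror, "ror_lo": est.ror_ci[0], "ror_hi": est.ror_ci[1],
                "prr": est.prr, "prr_lo": est.prr_ci[0], "prr_hi": est.prr_ci[1],
                "chi2": est.chi2, "ic": est.ic, "ic025": est.ic025,
                "ebgm": est.ebgm, "ebgm05": est.ebgm05,
                "ror_pos": est.ror_pos, "prr_pos": est.prr_pos,
                "bcpnn_pos": est.bcpnn_pos, "mgps_pos": est.mgps_pos,
                "combined_pos": est.combined_pos, "ic_grade": est.ic_grade,
                "evaluable": est.evaluable,
            }
        )
    return pd.concat([base, pd.DataFrame(est_rows)], axis=1)[SIGNAL_COLUMNS]


def _demo_to_cohort(mapped: MappedData) -> pd.DataFrame:
    """One row per (NST case, matched drug) with normalized demographics."""
    demo = mapped.demo
    if demo.empty:
        return pd.DataFrame()
    pid = demo["primaryid"].astype(str)
    keep = pid.isin(mapped.nst_ids)
    demo = demo[keep]
    pid = pid[keep]
    ages = [
        model.normalize_age(
            float(a) if str(a).strip() else None, str(u) if pd.notna(u) else ""
        )
        if str(a).strip().replace(".", "", 1).isdigit()
        else None
        for a, u in zip(demo.get("age", ""), demo.get("age_cod", ""))
    ]
    outc_map = (
        mapped.outc.assign(
            primaryid=mapped.outc["primaryid"].astype(str),
            outcome=mapped.outc["outc_cod"]
            .astype(str).str.upper()
            .map(lambda c: model.OUTCOME_CODES.get(c, model.Outcome.UNKNOWN).value),
        )
        .groupby("primaryid")["outcome"]
        .apply(lambda s: ";".join(sorted(set(s))))
        if not mapped.outc.empty
        else pd.Series(dtype=str)
    )
    base = pd.DataFrame(
        {
            "primary_id": pid.to_numpy(),
            "case_id": demo.get("caseid", pid).astype(str).to_numpy(),
            "age_years": ages,
            "weight_kg": pd.to_numeric(demo.get("wt", ""), errors="coerce").to_numpy(),
            "sex": [
                model.SEX_CODES.get(str(s).strip().upper(), model.Sex.UNKNOWN).value
                for s in demo.get("sex", "")
            ],
            "reporter": [
                model.REPORTER_CODES.get(str(o).strip().upper(), model.Reporter.UNKNOWN).value
                for o in demo.get("occp_cod", "")
            ],
            "country": [
                str(c).strip() if str(c).strip() else "unknown"
                for c in demo.get("occr_country", "")
            ],
            "outcomes": pid.map(outc_map).fillna("").to_numpy(),
            "year": demo.get("fda_dt", "").astype(str).str[:4].to_numpy(),
        }
    )
    merged = mapped.drug_pairs.merge(base, on="primary_id", how="inner")
    return merged


def onset_records(mapped: MappedData) -> tuple[list[onset.OnsetRecord], dict]:
    """Link therapy episodes to matched drug mentions and compute TTO.

    The earliest start date per (case, drug) is used (first exposure);
    missing or partial dates and negative intervals are excluded and
    tallied in the returned log.
    """
    ther = mapped.ther
    if ther.empty or mapped.matched_mentions.empty:
        return [], {"linked_pairs": 0, "excluded": 0, "summarized": 0}
    ther = ther.assign(
        primary_id=ther["primaryid"].astype(str),
        drug_seq=ther["dsg_drug_seq"].astype(str),
    )
    linked = ther.merge(
        mapped.matched_mentions, on=["primary_id", "drug_seq"], how="inner"
    )
    demo = mapped.demo.assign(primary_id=mapped.demo["primaryid"].astype(str))
    linked = linked.merge(
        demo[["primary_id", "caseid", "event_dt"]], on="primary_id", how="left"
    )
    linked["start_date"] = [model.parse_faers_date(v) for v in linked.get("start_dt", "")]
    linked["event_date"] = [model.parse_faers_date(v) for v in linked["event_dt"]]
    # first exposure per (case, drug)
    linked = linked.sort_values(["caseid", "drug", "start_date"], key=lambda s: s.astype(str))
    with_start = linked[linked["start_date"].notna()]
    first = with_start.drop_duplicates(subset=["caseid", "drug"], keep="first")
    no_start = linked[~linked.set_index(["caseid", "drug"]).index.isin(
        first.set_index(["caseid", "drug"]).index
    )].drop_duplicates(subset=["caseid", "drug"])
    linked_pairs = len(first) + len(no_start)
    records: list[onset.OnsetRecord] = []
    excluded = len(no_start)
    for row in first.itertuples(index=False):
        episode = model.TherapyEpisode(
            primary_id=row.primary_id, drug_seq=0, start_date=row.start_date
        )
        tto = onset.compute_tto(episode, row.event_date)
        if tto is None:
            excluded += 1
        else:
            records.append(onset.OnsetRecord(case_id=str(row.caseid), drug=row.drug, tto_days=tto))
    log = {"linked_pairs": int(linked_pairs), "excluded": int(excluded),
           "summarized": int(len(records))}
    return records, log


def export_heatmap_matrix(
    signal_frame: pd.DataFrame, statistic: str = "ic"
) -> pd.DataFrame:
    """Rectangular drugs-by-events matrix of one signal statistic.

    Non-evaluable cells stay NaN (exported as an explicit ``NA`` marker,
    never 0).
    """
    work = signal_frame.copy()
    work.loc[~work["evaluable"].astype(bool), statistic] = float("nan")
    return work.pivot_table(
        index="drug", columns="event", values=statistic, aggfunc="first", dropna=False
    )


def analyze_tables(
    tables: dict[str, pd.DataFrame],
    drugs: list[str] | None = None,
    events: list[str] | None = None,
    dictionary: DrugDictionary | None = None,
    terms: TermSet | None = None,
    level: str = "both",
    role_filter: tuple[str, ...] | None = None,
    universe_scope: str = "all",
    yates: bool = False,
    min_a: int = 3,
) -> AnalysisResult:
    """Run the full analysis on in-memory tables."""
    dictionary = dictionary or DrugDictionary.load()
    terms = terms or TermSet.load()
    mapped = map_tables(
        tables,
        dictionary,
        terms,
        role_filter=role_filter,
        universe_scope=universe_scope,
        extra_pts=tuple(events or ()),
    )
    drugs = list(drugs) if drugs is not None else [
        d for d in BITE_DRUGS if d in dictionary.entries
    ] or sorted(dictionary.entries)
    if events is None:
        observed = {
            k for k, ids in mapped.universe.pt_sets.items() if len(ids) > 0
        }
        events = sorted(
            mapped.universe.pt_display.get(k, k)
            for k in observed & terms.nst_terms
        )
    signal_pt = (
        signal_table(mapped, drugs, events, level="pt", yates=yates, min_a=min_a)
        if level in ("pt", "both")
        else pd.DataFrame(columns=SIGNAL_COLUMNS)
    )
    socs = sorted(terms.socs)
    signal_soc = (
        signal_table(mapped, drugs, socs, level="soc", yates=yates, min_a=min_a)
        if level in ("soc", "both")
        else pd.DataFrame(columns=SIGNAL_COLUMNS)
    )
    cohort_frame = _demo_to_cohort(mapped)
    cohort_frame = cohort_frame[cohort_frame["drug"].isin(drugs)] \
        if not cohort_frame.empty else cohort_frame
    cohort = desc.summarize_cohort(cohort_frame.rename(columns={}))
    records, onset_log = onset_records(mapped)
    summaries = onset.summarize_tto(records, drugs=drugs) if records else []
    log = {**mapped.log, "onset": onset_log,
           "n_signal_pairs_pt": int(len(signal_pt)),
           "n_signal_pairs_soc": int(len(signal_soc))}
    return AnalysisResult(
        mapped=mapped,
        signal_pt=signal_pt,
        signal_soc=signal_soc,
        cohort=cohort,
        onset_summaries=summaries,
        onset_records=records,
        log=log,
    )


def _atomic_write(frame: pd.DataFrame, path: Path, **to_csv_kw) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, na_rep="NA", **to_csv_kw)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a configured run and write all artifacts.

    Returns the artifact paths.  Partial outputs are removed on failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        from bitewatch.simulate import SimulationConfig, generate

        sim = generate(SimulationConfig(n_cases=config.n_cases, seed=config.seed))
        tables = sim.tables
    else:
        tables = {
            kind: model.read_table_frame(config.input_dir, kind)
            for kind in ("DEMO", "DRUG", "REAC", "OUTC", "THER")
        }
    dictionary = DrugDictionary.load(config.drug_dict_path)
    terms = TermSet.load(config.pt_soc_path, config.nst_path)
    result = analyze_tables(
        tables,
        dictionary=dictionary,
        terms=terms,
        level=config.level,
        role_filter=config.role_filter,
        universe_scope=config.universe_scope,
        yates=config.yates,
        min_a=config.min_a,
    )
    artifacts: dict[str, Path] = {}
    written: list[Path] = []
    try:
        if config.level in ("pt", "both"):
            p = out_dir / "signals_pt.csv"
            _atomic_write(result.signal_pt, p, index=False)
            artifacts["signals_pt"] = p
            written.append(p)
            hp = out_dir / "heatmap_ic.csv"
            _atomic_write(export_heatmap_matrix(result.signal_pt, "ic"), hp)
            artifacts["heatmap_ic"] = hp
            written.append(hp)
        if config.level in ("soc", "both"):
            p = out_dir / "signals_soc.csv"
            _atomic_write(result.signal_soc, p, index=False)
            artifacts["signals_soc"] = p
            written.append(p)
        if not result.cohort.long.empty:
            _atomic_write(result.cohort.wide, out_dir / "descriptives_wide.csv")
            _atomic_write(result.cohort.long, out_dir / "descriptives_long.csv", index=False)
            artifacts["descriptives_wide"] = out_dir / "descriptives_wide.csv"
            artifacts["descriptives_long"] = out_dir / "descriptives_long.csv"
            written += [artifacts["descriptives_wide"], artifacts["descriptives_long"]]
        tto_frame = onset.summaries_to_frame(result.onset_summaries)
        _atomic_write(tto_frame, out_dir / "tto_summary.csv", index=False)
        artifacts["tto_summary"] = out_dir / "tto_summary.csv"
        written.append(artifacts["tto_summary"])
        log_path = out_dir / "run_log.yaml"
        tmp = log_path.with_suffix(".yaml.tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            yaml.safe_dump(result.log, fh, sort_keys=True)
        os.replace(tmp, log_path)
        artifacts["run_log"] = log_path
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return artifacts
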