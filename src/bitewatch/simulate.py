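"""Synthetic FAERS-dialect data with known ground truth.

The generator emits the same ``$``-delimited DEMO/DRUG/REAC/OUTC/THER
files the readers consume, built from a simple generative model:

* per-report drug and event mentions are independent Bernoulli draws on
  configurable marginal probabilities (every report also carries one
  non-BiTE filler drug, as real reports always list a suspect drug);
* *planted signals* make a target event's conditional probability given
  a target drug equal ``rr`` times its background probability (capped
  below 1; a hit cap is logged and flagged in the manifest);
* a configurable fraction of cases is re-emitted as a higher
  ``caseversion`` duplicate with perturbed mutable fields (weight,
  reporter), so deduplication correctness is observable;
* demographics follow per-drug age distributions and global sex,
  country and outcome mixtures patterned on published BiTE
  pharmacovigilance cohorts;
* onset times are log-normal per drug (heavy-tailed, strictly
  positive), with therapy start and event dates emitted to THER/DEMO.

Everything is reproducible under a fixed seed, and a ground-truth
manifest records every planted reporting-rate ratio and all true
marginals.  Note the planted ``rr`` is defined against the *background*
event rate: the drug's own excess reports inflate the database-wide
event margin by roughly ``1 + (rr-1) * p_drug``, so disproportionality
estimates recover ``rr`` only up to that factor — keep drug marginals
small when planting large ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bitewatch.model import write_table_frame

logger = logging.getLogger(__name__)

MAX_CONDITIONAL = 0.95

#: (canonical name, marginal report probability).  Marginals are scaled
#: up relative to the real database so that a 1e5-case universe yields
#: evaluable cell counts.
DEFAULT_DRUGS = (
    ("blinatumomab", 0.020),
    ("elranatamab", 0.003),
    ("epcoritamab", 0.004),
    ("glofitamab", 0.003),
    ("mosunetuzumab", 0.002),
    ("talquetamab", 0.003),
    ("tarlatamab", 0.002),
    ("tebentafusp", 0.001),
    ("teclistamab", 0.006),
)

NERVOUS = "Nervous system disorders"
ICANS = "Immune effector cell-associated neurotoxicity syndrome"

#: (PT, SOC, marginal probability).
DEFAULT_EVENTS = (
    ("Neurotoxicity", NERVOUS, 0.010),
    ("Tremor", NERVOUS, 0.004),
    ("Seizure", NERVOUS, 0.004),
    ("Nervous system disorder", NERVOUS, 0.003),
    (ICANS, NERVOUS, 0.010),
    ("Encephalopathy", NERVOUS, 0.003),
    ("Aphasia", NERVOUS, 0.002),
    ("Ataxia", NERVOUS, 0.002),
    ("Dysgeusia", NERVOUS, 0.003),
    ("Ageusia", NERVOUS, 0.002),
    ("Nausea", "Gastrointestinal disorders", 0.080),
    ("Diarrhoea", "Gastrointestinal disorders", 0.050),
    ("Pyrexia", "General disorders and administration site conditions", 0.060),
    ("Fatigue", "General disorders and administration site conditions", 0.070),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.040),
    ("Pneumonia", "Infections and infestations", 0.030),
    ("Hypotension", "Vascular disorders", 0.030),
    ("Cytokine release syndrome", "Immune system disorders", 0.002),
)

#: Default planted (drug, event, target reporting-rate ratio).
DEFAULT_PLANTED = (
    ("blinatumomab", "Neurotoxicity", 3.0),
    ("tarlatamab", ICANS, 50.0),
    ("blinatumomab", "Nausea", 1.0),
)

#: Per-drug age (mean, sd) and log-normal onset mean in days.
DEFAULT_DRUG_PROFILES = {
    "blinatumomab": {"age": (38.6, 23.2), "onset_mean_days": 27.1},
    "elranatamab": {"age": (65.2, 16.0), "onset_mean_days": 30.0},
    "epcoritamab": {"age": (60.3, 25.6), "onset_mean_days": 30.0},
    "glofitamab": {"age": (63.0, 14.5), "onset_mean_days": 82.0},
    "mosunetuzumab": {"age": (65.7, 13.7), "onset_mean_days": 30.0},
    "talquetamab": {"age": (62.3, 17.1), "onset_mean_days": 30.0},
    "tarlatamab": {"age": (54.1, 26.5), "onset_mean_days": 16.7},
    "tebentafusp": {"age": (68.4, 10.5), "onset_mean_days": 30.0},
    "teclistamab": {"age": (65.6, 14.9), "onset_mean_days": 81.6},
}

DEFAULT_SEX_PROBS = {"F": 0.33, "M": 0.39, "": 0.28}

DEFAULT_COUNTRY_WEIGHTS = {
    "United States": 0.51,
    "Japan": 0.13,
    "France": 0.05,
    "China": 0.045,
    "Brazil": 0.028,
    "Italy": 0.023,
    "Spain": 0.018,
    "United Kingdom": 0.017,
    "Germany": 0.08,
    "Canada": 0.05,
    "Australia": 0.049,
}

#: OUTC code probabilities; the remainder means no outcome record.
DEFAULT_OUTCOME_PROBS = {
    "DE": 0.205,
    "HO": 0.216,
    "OT": 0.326,
    "LT": 0.038,
    "DS": 0.003,
    "RI": 0.001,
}

FILLER_DRUGS = (
    "METHOTREXATE", "ASPIRIN", "IBUPROFEN", "METFORMIN",
    "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE", "PARACETAMOL",
)

VERBATIM_VARIANTS = {
    "blinatumomab": ("BLINATUMOMAB", "BLINCYTO"),
    "elranatamab": ("ELRANATAMAB", "ELREXFIO", "ELRANATAMAB-BCMM"),
    "epcoritamab": ("EPCORITAMAB", "EPKINLY"),
    "glofitamab": ("GLOFITAMAB", "COLUMVI"),
    "mosunetuzumab": ("MOSUNETUZUMAB", "LUNSUMIO"),
    "talquetamab": ("TALQUETAMAB", "TALVEY"),
    "tarlatamab": ("TARLATAMAB", "IMDELLTRA", "TARLATAMAB-DLLE"),
    "tebentafusp": ("TEBENTAFUSP", "KIMMTRAK"),
    "teclistamab": ("TECLISTAMAB", "TECVAYLI"),
}

ONSET_LOG_SD = 1.0
MISSING_START_DATE_FRACTION = 0.30


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_cases: int = 100_000
    seed: int = 0
    drug_catalogue: tuple = DEFAULT_DRUGS
    event_catalogue: tuple = DEFAULT_EVENTS
    planted_signals: tuple = DEFAULT_PLANTED
    duplicate_fraction: float = 0.10
    sex_probs: dict = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    country_weights: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    outcome_probs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    drug_profiles: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_PROFILES))
    onset_log_sd: float = ONSET_LOG_SD
    missing_start_fraction: float = MISSING_START_DATE_FRACTION

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        for _, p in self.drug_catalogue:
            if not 0 < p < 1:
                raise ValueError("drug marginals must be in (0, 1)")
        for _, _, p in self.event_catalogue:
            if not 0 < p < 1:
                raise ValueError("event marginals must be in (0, 1)")
        for _, _, rr in self.planted_signals:
            if rr <= 0:
                raise ValueError("target_rr must be > 0")


@dataclass
class SyntheticDataset:
    """In-memory view of a generated dataset plus its truth manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict


def _sample_categorical(rng, weights: dict, size: int) -> np.ndarray:
    keys = np.array(list(weights.keys()), dtype=object)
    probs = np.array(list(weights.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=size, p=probs)


def generate(config: SimulationConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate one dataset; optionally write it to ``out_dir``.

    Returns the five FAERS-dialect tables as string DataFrames and the
    ground-truth manifest.  Output is byte-identical under a fixed seed
    and config.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = [d for d, _ in config.drug_catalogue]
    drug_probs = np.array([p for _, p in config.drug_catalogue])
    event_names = [e for e, _, _ in config.event_catalogue]
    event_socs = {e: s for e, s, _ in config.event_catalogue}
    event_probs = np.array([p for _, _, p in config.event_catalogue])

    case_ids = np.arange(10_000_001, 10_000_001 + n)
    primary_ids = case_ids * 10 + 1

    # Drug presence (independent Bernoulli per BiTE).
    drug_present = rng.random((n, len(drug_names))) < drug_probs[None, :]

    # Event probabilities, with planted drug-conditional rates.
    prob_matrix = np.broadcast_to(event_probs[None, :], (n, len(event_names))).copy()
    planted_truth = []
    for drug, event, rr in config.planted_signals:
        di = drug_names.index(drug)
        ei = event_names.index(event)
        conditional = rr * event_probs[ei]
        capped = conditional > MAX_CONDITIONAL
        if capped:
            logger.warning(
                "planted rr=%.3g for (%s, %s) caps conditional %.3g at %.2f",
                rr, drug, event, conditional, MAX_CONDITIONAL,
            )
            conditional = MAX_CONDITIONAL
        mask = drug_present[:, di]
        prob_matrix[mask, ei] = conditional
        planted_truth.append(
            {
                "drug": drug,
                "event": event,
                "target_rr": float(rr),
                "conditional_prob": float(conditional),
                "capped": bool(capped),
                "expected_a": float(n * drug_probs[di] * conditional),
            }
        )
    event_present = rng.random((n, len(event_names))) < prob_matrix

    # Demographics keyed on the first BiTE in the report.
    first_drug_idx = np.where(
        drug_present.any(axis=1), drug_present.argmax(axis=1), -1
    )
    age_mean = np.full(n, 55.0)
    age_sd = np.full(n, 20.0)
    for i, name in enumerate(drug_names):
        prof = config.drug_profiles.get(name, {})
        m, s = prof.get("age", (55.0, 20.0))
        sel = first_drug_idx == i
        age_mean[sel] = m
        age_sd[sel] = s
    age = np.clip(rng.normal(age_mean, age_sd), 0.5, 100.0).round(0)
    age_missing = rng.random(n) < 0.05
    weight = np.clip(rng.normal(70.0, 15.0), 30.0, 160.0).round(1)
    weight_missing = rng.random(n) < 0.30
    sex = _sample_categorical(rng, config.sex_probs, n)
    country = _sample_categorical(rng, config.country_weights, n)
    occp = _sample_categorical(
        rng, {"MD": 0.52, "HP": 0.19, "PH": 0.15, "CN": 0.10, "OT": 0.03, "": 0.01}, n
    )
    outc_probs = dict(config.outcome_probs)
    none_p = max(0.0, 1.0 - sum(outc_probs.values()))
    outc = _sample_categorical(rng, {**outc_probs, "": none_p}, n)

    # Receipt dates uniform over 2015-2024 (coarse month/day grid keeps
    # every generated date valid).
    year = rng.integers(2015, 2025, size=n)
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    fda_dt = year * 10_000 + month * 100 + day
    start_ts = pd.to_datetime(
        pd.DataFrame({"year": year, "month": month, "day": day})
    )

    # Onset times per (report, BiTE) from per-drug log-normals; the
    # report's event date comes from its first BiTE mention.
    onset_mu = np.full(len(drug_names), np.log(30.0) - config.onset_log_sd**2 / 2)
    for i, name in enumerate(drug_names):
        mean_days = config.drug_profiles.get(name, {}).get("onset_mean_days", 30.0)
        onset_mu[i] = np.log(mean_days) - config.onset_log_sd**2 / 2
    tto_matrix = np.maximum(
        np.rint(rng.lognormal(onset_mu[None, :], config.onset_log_sd, (n, len(drug_names)))),
        1,
    ).astype(int)
    start_missing = rng.random(n) < config.missing_start_fraction

    has_bite = first_drug_idx >= 0
    first_tto = np.where(has_bite, tto_matrix[np.arange(n), first_drug_idx], 0)
    event_ts = start_ts + pd.to_timedelta(first_tto, unit="D")
    event_dt = np.where(
        has_bite, event_ts.dt.strftime("%Y%m%d"), ""
    )

    def dates_str(ts, mask_missing):
        out = ts.dt.strftime("%Y%m%d").to_numpy(dtype=object)
        out[mask_missing] = ""
        return out

    demo = pd.DataFrame(
        {
            "primaryid": primary_ids.astype(str),
            "caseid": case_ids.astype(str),
            "caseversion": np.ones(n, dtype=int).astype(str),
            "fda_dt": fda_dt.astype(str),
            "event_dt": event_dt,
            "age": np.where(age_missing, "", age.astype(int).astype(str)),
            "age_cod": np.where(age_missing, "", "YR"),
            "sex": sex,
            "wt": np.where(weight_missing, "", weight.astype(str)),
            "wt_cod": np.where(weight_missing, "", "KG"),
            "occp_cod": occp,
            "occr_country": country,
            "reporter_country": country,
        }
    )

    # DRUG and THER rows: one filler mention per report plus BiTEs.
    filler = rng.choice(np.array(FILLER_DRUGS, dtype=object), size=n)
    drug_rows = {
        "primaryid": list(demo["primaryid"]),
        "drug_seq": ["1"] * n,
        "role_cod": ["C"] * n,
        "drugname": list(filler),
        "prod_ai": list(filler),
    }
    ther_rows = {"primaryid": [], "dsg_drug_seq": [], "start_dt": [], "end_dt": []}
    rep_idx, drug_idx = np.nonzero(drug_present)
    variant_choice = rng.integers(0, 1_000_000, size=len(rep_idx))
    start_str = dates_str(start_ts, start_missing)
    mention_count: dict[int, int] = {}
    for k in range(len(rep_idx)):
        i, j = int(rep_idx[k]), int(drug_idx[k])
        name = drug_names[j]
        variants = VERBATIM_VARIANTS.get(name, (name.upper(),))
        mention_count[i] = mention_count.get(i, 0) + 1
        seq = str(1 + mention_count[i])
        drug_rows["primaryid"].append(demo["primaryid"].iat[i])
        drug_rows["drug_seq"].append(seq)
        drug_rows["role_cod"].append("PS" if j == first_drug_idx[i] else "SS")
        drug_rows["drugname"].append(variants[variant_choice[k] % len(variants)])
        drug_rows["prod_ai"].append(name.upper())
        ther_rows["primaryid"].append(demo["primaryid"].iat[i])
        ther_rows["dsg_drug_seq"].append(seq)
        if j == first_drug_idx[i]:
            ther_rows["start_dt"].append(start_str[i])
        else:
            other_start = event_ts.iat[i] - pd.Timedelta(days=int(tto_matrix[i, j]))
            ther_rows["start_dt"].append(
                "" if start_missing[i] else other_start.strftime("%Y%m%d")
            )
        ther_rows["end_dt"].append("")
    drug = pd.DataFrame(drug_rows)
    ther = pd.DataFrame(ther_rows)

    e_rep, e_evt = np.nonzero(event_present)
    reac = pd.DataFrame(
        {
            "primaryid": demo["primaryid"].to_numpy()[e_rep],
            "pt": np.array(event_names, dtype=object)[e_evt],
        }
    )
    outc_mask = outc != ""
    outc_frame = pd.DataFrame(
        {"primaryid": demo["primaryid"].to_numpy()[outc_mask], "outc_cod": outc[outc_mask]}
    )

    # Duplicate re-emission: version 2 with perturbed mutable fields;
    # child tables copied under the new primaryid.
    n_dup = int(np.floor(config.duplicate_fraction * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        dup_demo = demo.iloc[dup_idx].copy()
        old_pids = dup_demo["primaryid"].to_numpy()
        new_pids = (case_ids[dup_idx] * 10 + 2).astype(str)
        dup_demo["primaryid"] = new_pids
        dup_demo["caseversion"] = "2"
        new_wt = np.clip(
            rng.normal(70.0, 15.0, size=n_dup), 30.0, 160.0
        ).round(1).astype(str)
        dup_demo["wt"] = np.where(dup_demo["wt"].to_numpy() == "", "", new_wt)
        dup_demo["occp_cod"] = _sample_categorical(
            rng, {"MD": 0.5, "HP": 0.2, "PH": 0.15, "CN": 0.15}, n_dup
        )
        pid_map = dict(zip(old_pids, new_pids))

        def dup_children(frame):
            sub = frame[frame["primaryid"].isin(pid_map)].copy()
            sub["primaryid"] = sub["primaryid"].map(pid_map)
            return sub

        demo = pd.concat([demo, dup_demo], ignore_index=True)
        drug = pd.concat([drug, dup_children(drug)], ignore_index=True)
        reac = pd.concat([reac, dup_children(reac)], ignore_index=True)
        outc_frame = pd.concat([outc_frame, dup_children(outc_frame)], ignore_index=True)
        ther = pd.concat([ther, dup_children(ther)], ignore_index=True)

    manifest = {
        "n_cases": int(n),
        "seed": int(config.seed),
        "duplicate_fraction": float(config.duplicate_fraction),
        "n_duplicates": int(n_dup),
        "drug_marginals": {d: float(p) for d, p in config.drug_catalogue},
        "event_marginals": {e: float(p) for e, _, p in config.event_catalogue},
        "event_socs": dict(event_socs),
        "planted_signals": planted_truth,
        "onset_log_sd": float(config.onset_log_sd),
        "onset_mean_days": {
            d: float(config.drug_profiles.get(d, {}).get("onset_mean_days", 30.0))
            for d in drug_names
        },
    }
    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc_frame, "THER": ther}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for kind, frame in tables.items():
            write_table_frame(frame, out_dir / f"{kind}.txt")
        with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return SyntheticDataset(tables=tables, manifest=manifest)


def parameter_recovery(config: SimulationConfig, dataset: SyntheticDataset | None = None) -> dict:
    """Generate (unless given) a dataset, run the full signal pipeline
    and compare estimates with the planted truth.

    For each planted pair the report carries the EBGM point estimate,
    its relative error against ``target_rr`` and the combined-positivity
    flag; for all unplanted catalogue pairs it carries the fraction
    flagged combined-positive (the empirical false-positive rate).
    """
    from bitewatch.pipeline import analyze_tables

    if dataset is None:
        dataset = generate(config)
    event_names = [e for e, _, _ in config.event_catalogue]
    drug_names = [d for d, _ in config.drug_catalogue]
    result = analyze_tables(dataset.tables, drugs=drug_names, events=event_names)
    signal = result.signal_pt.set_index(["drug", "event"])

    planted_keys = set()
    planted_report = []
    for truth in dataset.manifest["planted_signals"]:
        key = (truth["drug"], truth["event"])
        if truth["target_rr"] != 1.0:
            planted_keys.add(key)
        row = signal.loc[key]
        ebgm = float(row["ebgm"])
        planted_report.append(
            {
                **truth,
                "observed_a": int(row["a"]),
                "ebgm": ebgm,
                "ebgm_rel_err": ebgm / truth["target_rr"] - 1.0
                if np.isfinite(ebgm)
                else float("nan"),
                "combined_pos": bool(row["combined_pos"]),
            }
        )
    null_rows = signal.loc[[k for k in signal.index if k not in planted_keys]]
    null_frac = float(null_rows["combined_pos"].mean()) if len(null_rows) else 0.0
    return {
        "planted": planted_report,
        "n_null_pairs": int(len(null_rows)),
        "null_combined_fraction": null_frac,
    }
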