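"""Synthetic-data generator: determinism, structure, known truth."""

import numpy as np
import pandas as pd
import pytest

from bitewatch.model import dedup_demo_frame
from bitewatch.simulate import (
    DEFAULT_EVENTS,
    SimulationConfig,
    generate,
)


class TestStructure:
    def test_row_counts_and_distinct_cases(self, small_dataset):
        demo = small_dataset.tables["DEMO"]
        n = small_dataset.manifest["n_cases"]
        n_dup = small_dataset.manifest["n_duplicates"]
        assert len(demo) == n + n_dup
        assert demo["caseid"].nunique() == n

    def test_dedup_recovers_exactly_n_cases(self, small_dataset):
        kept = dedup_demo_frame(small_dataset.tables["DEMO"])
        assert len(kept) == small_dataset.manifest["n_cases"]
        # retained rows are the version-2 re-emissions where they exist
        dup_cases = small_dataset.tables["DEMO"].loc[
            small_dataset.tables["DEMO"]["caseversion"] == "2", "caseid"
        ]
        kept_versions = kept.set_index("caseid")["caseversion"]
        assert (kept_versions.loc[dup_cases] == "2").all()

    def test_duplicates_have_child_rows(self, small_dataset):
        demo = small_dataset.tables["DEMO"]
        v2 = set(demo.loc[demo["caseversion"] == "2", "primaryid"])
        drug_pids = set(small_dataset.tables["DRUG"]["primaryid"])
        assert v2 <= drug_pids

    def test_every_report_has_a_drug_row(self, small_dataset):
        demo_pids = set(small_dataset.tables["DEMO"]["primaryid"])
        drug_pids = set(small_dataset.tables["DRUG"]["primaryid"])
        assert demo_pids == drug_pids


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_cases=800, seed=42)
        generate(cfg, out_dir=tmp_path / "a")
        generate(cfg, out_dir=tmp_path / "b")
        for name in ("DEMO.txt", "DRUG.txt", "REAC.txt", "OUTC.txt", "THER.txt",
                     "manifest.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seed_differs(self):
        a = generate(SimulationConfig(n_cases=500, seed=1))
        b = generate(SimulationConfig(n_cases=500, seed=2))
        assert not a.tables["DEMO"].equals(b.tables["DEMO"])


class TestGroundTruth:
    def test_manifest_marginals_match_empirical(self, small_dataset):
        """Unplanted event marginals agree with the manifest within three
        binomial standard deviations (original cases only)."""
        demo = small_dataset.tables["DEMO"]
        originals = set(demo.loc[demo["caseversion"] == "1", "primaryid"])
        reac = small_dataset.tables["REAC"]
        reac = reac[reac["primaryid"].isin(originals)]
        n = small_dataset.manifest["n_cases"]
        planted_events = {
            p["event"] for p in small_dataset.manifest["planted_signals"]
        }
        counts = reac.groupby("pt")["primaryid"].nunique()
        for event, p in small_dataset.manifest["event_marginals"].items():
            if event in planted_events:
                continue
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(event, 0) - n * p) <= 3 * sd, event

    def test_planted_conditional_rate(self, small_dataset):
        """Among reports mentioning the planted drug, the planted event's
        frequency matches the manifest conditional probability."""
        truth = next(
            t
            for t in small_dataset.manifest["planted_signals"]
            if t["target_rr"] == 50.0
        )
        drug = small_dataset.tables["DRUG"]
        demo = small_dataset.tables["DEMO"]
        originals = set(demo.loc[demo["caseversion"] == "1", "primaryid"])
        with_drug = set(
            drug.loc[
                drug["prod_ai"].str.lower() == truth["drug"], "primaryid"
            ]
        ) & originals
        reac = small_dataset.tables["REAC"]
        with_event = set(reac.loc[reac["pt"] == truth["event"], "primaryid"])
        k, m = len(with_drug & with_event), len(with_drug)
        p = truth["conditional_prob"]
        assert abs(k - m * p) <= 3 * np.sqrt(m * p * (1 - p))

    def test_infeasible_rr_is_capped_and_flagged(self):
        cfg = SimulationConfig(
            n_cases=200,
            seed=0,
            planted_signals=(("blinatumomab", "Nausea", 50.0),),
        )
        ds = generate(cfg)
        truth = ds.manifest["planted_signals"][0]
        assert truth["capped"] and truth["conditional_prob"] == 0.95

    def test_event_socs_recorded(self, small_dataset):
        socs = small_dataset.manifest["event_socs"]
        assert socs["Neurotoxicity"] == "Nervous system disorders"
        assert len(socs) == len(DEFAULT_EVENTS)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cases": 0},
            {"duplicate_fraction": 1.0},
            {"planted_signals": (("blinatumomab", "Nausea", -1.0),)},
            {"drug_catalogue": (("blinatumomab", 1.5),)},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
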