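import pandas as pd
import pytest

from bitewatch.simulate import SimulationConfig, generate


@pytest.fixture
def demo_dir(tmp_path):
    """Hand-built FAERS-dialect fixture directory (two versions of one
    case plus an independent case)."""
    (tmp_path / "DEMO.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$event_dt$age$age_cod$sex$wt$occp_cod$occr_country\n"
        "1001$100$1$20230101$20221220$45$YR$F$70$MD$United States\n"
        "1002$100$2$20230601$20221220$45$YR$F$71$MD$United States\n"
        "2001$200$1$20230301$$6$DEC$UNK$$CN$Japan\n"
    )
    (tmp_path / "DRUG.txt").write_text(
        "primaryid$drug_seq$role_cod$drugname$prod_ai\n"
        "1001$1$PS$BLINCYTO$BLINATUMOMAB\n"
        "1002$1$PS$BLINCYTO$BLINATUMOMAB\n"
        "1002$2$C$ASPIRIN$ASPIRIN\n"
        "2001$1$PS$TARLATAMAB-DLLE$TARLATAMAB\n"
    )
    (tmp_path / "REAC.txt").write_text(
        "primaryid$pt\n"
        "1001$Neurotoxicity\n"
        "1002$Neurotoxicity\n"
        "1002$Tremor\n"
        "2001$Immune effector cell-associated neurotoxicity syndrome\n"
    )
    (tmp_path / "OUTC.txt").write_text(
        "primaryid$outc_cod\n1002$HO\n1002$DE\n2001$OT\n"
    )
    (tmp_path / "THER.txt").write_text(
        "primaryid$dsg_drug_seq$start_dt$end_dt\n"
        "1002$1$20221201$\n"
        "2001$1$20230210$\n"
    )
    return tmp_path


@pytest.fixture(scope="session")
def small_dataset():
    """A 5,000-case synthetic dataset shared across tests."""
    return generate(SimulationConfig(n_cases=5_000, seed=11))


def tables_equal(a: dict[str, pd.DataFrame], b: dict[str, pd.DataFrame]) -> bool:
    return set(a) == set(b) and all(a[k].equals(b[k]) for k in a)
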