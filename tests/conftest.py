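from __future__ import annotations

import pandas as pd
import pytest

from faersig.contingency import ContingencyTable
from faersig.io import parse_quarter
from faersig.synthetic import DrugSpec, PtSpec, SignalPair, SynthConfig


def write_quarter_files(tmp_path, demo_rows, drug_rows, reac_rows, outc_rows=(), ther_rows=(),
                        demo_header="PRIMARYID$CASEID$FDA_DT$EVENT_DT$SEX$AGE$AGE_COD$OCCP_COD$REPORTER_COUNTRY",
                        drug_header="PRIMARYID$DRUG_SEQ$ROLE_COD$DRUGNAME$PROD_AI"):
    paths = {}
    spec = {
        "DEMO": (demo_header, demo_rows),
        "DRUG": (drug_header, drug_rows),
        "REAC": ("PRIMARYID$PT", reac_rows),
        "OUTC": ("PRIMARYID$OUTC_COD", outc_rows),
        "THER": ("PRIMARYID$DSG_DRUG_SEQ$START_DT", ther_rows),
    }
    for kind, (header, rows) in spec.items():
        p = tmp_path / f"{kind}.txt"
        p.write_text("\n".join([header, *rows]) + "\n")
        paths[kind.lower()] = p
    return paths


@pytest.fixture
def quarter_paths(tmp_path):
    """A 5-report fixture: 3 cohort-eligible reports on VILAZODONE."""
    return write_quarter_files(
        tmp_path,
        demo_rows=[
            "101$1$20200115$20200110$F$34$YR$CN$US",
            "102$2$20200116$$M$204$MON$MD$US",
            "103$3$20200117$20200112$F$$$$",
            "104$4$20200118$20200113$UNK$70$YR$PH$CA",
            "105$5$20200119$20200114$M$80$YR$OT$US",
        ],
        drug_rows=[
            "101$1$PS$VILAZODONE HYDROCHLORIDE$VILAZODONE",
            "101$2$C$ASPIRIN$ASPIRIN",
            "102$1$PS$VIIBRYD 20MG$VILAZODONE",
            "103$1$SS$VILAZODONE$VILAZODONE",
            "104$1$PS$SERTRALINE$SERTRALINE",
            "105$1$C$VIIBRYD$VILAZODONE",
        ],
        reac_rows=[
            "101$Nausea", "101$Insomnia", "101$Nausea",
            "102$Diarrhoea", "103$Insomnia", "104$Nausea", "105$Headache",
        ],
        outc_rows=["101$HO", "102$DE", "101$HO"],
        ther_rows=["101$1$20200101", "102$1$20200201"],
    )


@pytest.fixture
def quarter_bundle(quarter_paths):
    p = quarter_paths
    return parse_quarter(p["demo"], p["drug"], p["reac"], p["outc"], p["ther"], "2020Q1")


@pytest.fixture
def vocab_csv(tmp_path):
    p = tmp_path / "pt_soc.csv"
    pd.DataFrame(
        [
            ("Insomnia", "Psychiatric disorders", 10037175),
            ("Nausea", "Gastrointestinal disorders", 10017947),
            ("Diarrhoea", "Gastrointestinal disorders", 10017947),
            ("Headache", "Nervous system disorders", 10029205),
        ],
        columns=["pt", "soc_name", "soc_code"],
    ).to_csv(p, index=False)
    return p


@pytest.fixture
def table_example():
    """The worked 2x2 example: a=3, b=7, c=30, d=960 (N=1000)."""
    return ContingencyTable(3, 7, 30, 960)


def small_synth_config(n=2000, lam=20.0, seed=0, **kw):
    """A config whose signal pair passes all four thresholds w.h.p.

    Expected signal cells at n=2000: a ~ 40, EBGM ~ 7.6 (the finite
    background discounts the design lam of 20).
    """
    drugs = [DrugSpec("TARGETOL", 0.05), DrugSpec("ALPHADONE", 0.475), DrugSpec("BETAMAB", 0.475)]
    pts = [PtSpec(f"EVENT {i:02d}", f"SOC {i % 4}", 0.05) for i in range(20)]
    pts.append(PtSpec("SIGNAL EVENT", "SOC S", 0.02))
    pairs = [SignalPair("TARGETOL", "SIGNAL EVENT", lam)] if lam else []
    return SynthConfig(n_reports=n, drugs=drugs, pts=pts, signal_pairs=pairs, seed=seed, **kw)
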