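"""Shared fixtures: a tiny hand-written quarter, a generated medium quarter,
and a ReportCase factory for statistics-level tests."""

from __future__ import annotations

import dataclasses

import pytest

from faerspv.cohort import ReportCase
from faerspv.dates import parse_date
from faerspv.io import deduplicate, parse_quarter, quarter_paths
from faerspv.synthetic import GeneratorConfig, generate


TINY_TABLES = {
    "DEMO.txt": """\
primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$reporter_country$occp_cod
1001$C1$20230110$20230105$F$8$MON$7.2$KG$US$MD
1002$C2$20230215$202302$M$1.2$YR$$$JP$CN
1003$C3$20230301$$$$$9.1$KG$DE$
1004$C4$$20230110$F$3$MON$$$US$MD
""",
    "DRUG.txt": """\
primaryid$drug_seq$role_cod$drugname$prod_ai
1001$1$PS$ZOLGENSMA$ONASEMNOGENE ABEPARVOVEC
1001$2$C$PREDNISOLONE$
1002$1$PS$zolgensma 2e13 vg/ml$ONASEMNOGENE ABEPARVOVEC
1002$2$C$NUSINERSEN$
1003$1$PS$OTHER DRUG$
1003$2$C$AVXS-101$
""",
    "REAC.txt": """\
primaryid$pt
1001$Pyrexia
1001$Vomiting
1001$Vomiting
1002$Thrombocytopenia
1003$Pyrexia
""",
    "THER.txt": """\
primaryid$drug_seq$start_dt$end_dt
1001$1$20230101$
1002$1$202301$
1003$1$20230220$20230210
""",
    "OUTC.txt": """\
primaryid$outc_cod
1001$HO
1002$DE
1003$XX
""",
    "INDI.txt": """\
primaryid$indi_drug_seq$indi_pt
1001$1$Spinal muscular atrophy
1002$1$Spinal muscular atrophy
""",
}

TINY_SOC_MAP = {"Pyrexia": "General disorders",
                "Vomiting": "Gastrointestinal disorders",
                "Thrombocytopenia": "Blood and lymphatic system disorders"}
TINY_IME = frozenset({"Thrombocytopenia"})


@pytest.fixture()
def tiny_quarter_dir(tmp_path):
    for name, text in TINY_TABLES.items():
        (tmp_path / name).write_text(text)
    return tmp_path


@pytest.fixture()
def tiny_quarter(tiny_quarter_dir):
    return parse_quarter(quarter_paths(tiny_quarter_dir))


SMALL_CONFIG = GeneratorConfig(n_reports=8000, seed=7)


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """One generated 8,000-report quarter shared across the session."""
    outdir = tmp_path_factory.mktemp("synthq")
    paths, truth = generate(SMALL_CONFIG, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def small_synth_parsed(small_synth):
    outdir, truth = small_synth
    quarter = parse_quarter(quarter_paths(outdir))
    dedup = deduplicate(quarter.demo.records)
    return quarter, dedup, truth


def make_case(primaryid="1", pts=("Pyrexia",), sex="F", age_months=10.0,
              weight_kg=8.0, role="PS", outcomes=(), conmeds=(),
              event_dt=None, start_dt=None, country="US", occupation="MD"):
    """Minimal ReportCase for statistics-level tests."""
    return ReportCase(
        primaryid=str(primaryid), caseid=f"C{primaryid}", sex=sex,
        age_months=age_months, weight_kg=weight_kg,
        reporter_country=country, occupation=occupation,
        fda_dt=parse_date("20230301"),
        event_dt=parse_date(event_dt) if event_dt else None,
        target_role=role, reaction_pts=frozenset(pts),
        outcomes=frozenset(outcomes),
        therapy_start=parse_date(start_dt) if start_dt else None,
        multiple_therapy=False, concomitant_drugnames=frozenset(conmeds))
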