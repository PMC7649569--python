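import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_hgnc():
    """Small HGNC-style table used across modules."""
    return pd.DataFrame(
        [
            {"symbol": "MAPK1", "alias_symbol": "ERK2|p42", "prev_symbol": "PRKM1", "entrez_id": 5594},
            {"symbol": "MAPK3", "alias_symbol": "ERK1|p44", "prev_symbol": "PRKM3", "entrez_id": 5595},
            {"symbol": "AKT1", "alias_symbol": "AKT|PKB", "prev_symbol": "", "entrez_id": 207},
            {"symbol": "TP53", "alias_symbol": "p53", "prev_symbol": "", "entrez_id": 7157},
            {"symbol": "CDK1", "alias_symbol": "CDC2", "prev_symbol": "", "entrez_id": 983},
            {"symbol": "NFKB1", "alias_symbol": "", "prev_symbol": "", "entrez_id": 4790},
            {"symbol": "TYR", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7299},
            {"symbol": "WNT1", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7471},
            {"symbol": "WNT2", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7472},
            {"symbol": "WNT3", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7473},
            {"symbol": "WNT4", "alias_symbol": "", "prev_symbol": "", "entrez_id": 54361},
            {"symbol": "WNT5A", "alias_symbol": "WNT5", "prev_symbol": "", "entrez_id": 7474},
            {"symbol": "LATS1", "alias_symbol": "", "prev_symbol": "", "entrez_id": 9113},
            {"symbol": "LATS2", "alias_symbol": "", "prev_symbol": "", "entrez_id": 26524},
            {"symbol": "TEAD1", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7003},
            {"symbol": "TEAD2", "alias_symbol": "", "prev_symbol": "", "entrez_id": 8463},
            {"symbol": "TEAD3", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7005},
            {"symbol": "TEAD4", "alias_symbol": "", "prev_symbol": "", "entrez_id": 7004},
        ]
    )


@pytest.fixture(scope="session")
def toy_bioentities():
    return pd.DataFrame([["NF-κB", "NFKB1"], ["ERK", "MAPK1", "MAPK3"]])


@pytest.fixture(scope="session")
def toy_lexicon(toy_hgnc, toy_bioentities):
    from pathfig.lexicon import build_lexicon

    return build_lexicon(toy_hgnc, toy_bioentities)
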