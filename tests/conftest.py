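import numpy as np
import pandas as pd
import pytest

from mortcord import SyntheticConfig, generate_cohort

# the study's matched-cohort 8-category death-status table (N = 904,581)
TABLE1 = {
    "ABS": 209, "AB": 2682, "AS": 1071, "BS": 43,
    "A_only": 10697, "B_only": 1017, "S_only": 3972, "none": 884890,
}

# a 100-subject cohort with the same category structure, for fast roundtrips
SMALL_COUNTS = {
    "ABS": 2, "AB": 3, "AS": 1, "BS": 1,
    "A_only": 5, "B_only": 2, "S_only": 4, "none": 82,
}


@pytest.fixture(scope="session")
def table1_counts():
    return dict(TABLE1)


@pytest.fixture(scope="session")
def small_exact_cohort():
    cfg = SyntheticConfig(
        n_matched=100, category_counts=dict(SMALL_COUNTS),
        death_rate_a=0.0, death_rate_b=0.0, death_rate_s=0.0, seed=7,
    )
    return generate_cohort(cfg)


def truth_assignment(members: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Attach the true person_uid to every clustered record."""
    lookup = {}
    for col, source in (
        ("record_id_a", "SYSTEM_A"),
        ("record_id_b", "SYSTEM_B"),
        ("record_id_s", "SSADMF"),
    ):
        sub = truth[truth[col] != ""]
        lookup.update(dict(zip(zip([source] * len(sub), sub[col]), sub["person_uid"])))
    out = members.copy()
    out["person_uid"] = [
        lookup[(s, r)] for s, r in zip(out["source"], out["record_id"])
    ]
    return out


def cluster_of_person(members: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """person_uid -> cluster_id via the system-A record (matched persons)."""
    amap = members[members["source"] == "SYSTEM_A"].set_index("record_id")[
        "cluster_id"
    ]
    t = truth[truth["record_id_a"] != ""]
    return pd.Series(
        t["record_id_a"].map(amap).to_numpy(), index=t["person_uid"].to_numpy()
    )
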