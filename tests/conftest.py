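import pandas as pd
import pytest

from tokenlink.synth import SimConfig, generate_population
from tokenlink.tokens import KeyRing, encrypt_stage, tokenize_records, transform_to_cc


def pipeline_to_cc(pop, ring):
    """Run every site's PII through tokenize -> transit -> cc."""
    out = {}
    for dmid, records in pop.pii.items():
        site = tokenize_records(records, dmid, ring)
        transit = [encrypt_stage(ts, ring.transit_keys[(dmid, "CC")]) for ts in site]
        out[dmid] = [transform_to_cc(ts, ring, dmid) for ts in transit]
    return out


@pytest.fixture(scope="session")
def keyring():
    return KeyRing.generate(["S1", "S2", "S3", "S4"], seed=20240117)


@pytest.fixture(scope="session")
def small_population():
    """Two sites, planted overlap and duplicates, clean PII."""
    cfg = SimConfig(
        sites={"S1": 200, "S2": 250},
        overlaps={("S1", "S2"): 0.1},
        duplicate_rate=0.01,
        ssn_availability={"S1": 0.9, "S2": 0.3},
        seed=5,
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_cc_tokensets(small_population, keyring):
    return pipeline_to_cc(small_population, keyring)


def demographics_frame(pop) -> pd.DataFrame:
    df = pd.concat(list(pop.demographics.values()), ignore_index=True)
    df["DMID_PATID"] = df["DMID"] + "_" + df["PATID"]
    return df
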