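import pandas as pd
import pytest
from hypothesis import settings

import twinvar as tv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# AE truth used by several fitting tests: total 5.6, standardized A 0.82
AE_SPEC = tv.ComponentSpec(var_a=0.82 * 5.6, var_e=0.18 * 5.6, mean=21.0)


@pytest.fixture(scope="session")
def twin_ae_pairs() -> pd.DataFrame:
    """20k MZ + 20k DZ pairs simulated under the AE truth."""
    mz = tv.simulate_pairs("MZ", 20_000, AE_SPEC, seed=11, id_prefix="M")
    dz = tv.simulate_pairs("DZ", 20_000, AE_SPEC, seed=12, id_prefix="D")
    return pd.concat([mz, dz], ignore_index=True)


@pytest.fixture(scope="session")
def small_twin_pairs() -> pd.DataFrame:
    """200 MZ + 200 DZ pairs, small enough for brute-force oracles."""
    mz = tv.simulate_pairs("MZ", 200, AE_SPEC, seed=21, id_prefix="m")
    dz = tv.simulate_pairs("DZ", 200, AE_SPEC, seed=22, id_prefix="d")
    return pd.concat([mz, dz], ignore_index=True)


def individuals_frame(rows):
    """Build a canonical individuals table from (id, father, mother, year, bmi,
    zygosity) tuples."""
    df = pd.DataFrame(rows, columns=[
        "person_id", "father_id", "mother_id", "birth_year", "bmi", "zygosity",
    ])
    df["sex"] = "male"
    return df[["person_id", "father_id", "mother_id", "birth_year", "sex", "bmi", "zygosity"]]
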