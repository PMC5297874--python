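import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import heightmeta as hm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_effects_frame(zr, var_zr, western=None, year=None, author=None, country=None):
    """Hand-assembled effects table for model-level tests."""
    k = len(zr)
    return pd.DataFrame(
        {
            "record_id": [f"R{i}" for i in range(k)],
            "zr": np.asarray(zr, dtype=float),
            "var_zr": np.asarray(var_zr, dtype=float),
            "western": western if western is not None else [False] * k,
            "year_centered": year if year is not None else np.zeros(k),
            "author_group_id": author if author is not None else [f"A{i}" for i in range(k)],
            "country_name": country if country is not None else [f"C{i}" for i in range(k)],
            "year_published": 2000 + (np.asarray(year) if year is not None else np.zeros(k)),
        }
    )


TOY_CSV = """record_id,source_label,author_group_id,country_name,un_region_code,year_published,r_observed,n_couples,n_provenance,p_category,se_reported
R1,Alpha 1950,A1,France,250,1950,0.25,120,reported,,
R2,Beta 1970,A2,Japan,392,1970,0.18,68,median_imputed,,
R3,Gamma 1990,A1,Brazil,76,1990,-0.05,45,reported,,
"""


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture(scope="session")
def small_sim():
    """Moderate simulated dataset reused across model tests."""
    ds, truth = hm.simulate_studies(hm.SimConfig(n_studies=40, n_authors=20, n_countries=10, seed=7))
    return ds, truth


@pytest.fixture(scope="session")
def small_effects(small_sim):
    ds, _ = small_sim
    return hm.compute_effects(ds)


@pytest.fixture(scope="session")
def reference_report():
    """Full pipeline run on the synthetic stand-in study table."""
    ds, truth = hm.synthetic_reference_dataset(seed=0)
    report, artifacts = hm.run_full_analysis(ds)
    return report, artifacts, truth


@pytest.fixture(scope="session")
def recovery_result():
    """Parameter recovery at the meta-analysis' own design size.

    200 replicates of 154 studies / 91 author groups / 43 countries
    with truth equal to the generator defaults.
    """
    return hm.recovery_experiment(hm.SimConfig(seed=11), n_replicates=200)
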