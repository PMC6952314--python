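import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hrmwas.feature_table import FeatureTable
from hrmwas.synthetic_data import SimConfig, generate_two_studies


def make_table(mz, rt, intensities, sample_ids=None, batches=None, ids=None):
    """Small hand-built FeatureTable from plain lists/arrays."""
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_samp = intensities.shape
    ids = ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samp)]
    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(ids, name="feature_id"))
    inten = pd.DataFrame(intensities, index=features.index, columns=sample_ids)
    b = None
    if batches is not None:
        b = pd.Series(batches, index=inten.columns)
    return FeatureTable(features, inten, b)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured two-study dataset with ground truth."""
    cfg = SimConfig(seed=42, n_features=120, n_per_group=30, frac_affected=0.05,
                    effect_size=0.5, n_adduct_clusters=3)
    return cfg, *generate_two_studies(cfg)


@pytest.fixture()
def sample_info_small():
    rng = np.random.default_rng(0)
    n = 24
    return pd.DataFrame(
        {
            "study_id": "study1",
            "diagnosis": ["NC", "AD"] * (n // 2),
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(55, 85, n).round(1),
            "batch": "b1",
        },
        index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
    )
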