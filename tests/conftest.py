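import numpy as np
import pandas as pd
import pytest

from dielmeta.meta import RandomEffect


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def balanced_tree_newick():
    # hand-built ultrametric 4-tip tree of height 1:
    # (A,B) split at depth 0.5, (C,D) split at depth 0.75, root at 0
    return "((A:0.5,B:0.5):0.5,(C:0.25,D:0.25):0.75);"


@pytest.fixture
def arm_table():
    """Two complete study x species x metric groups (all four arms / two arms)."""
    rows = []
    for trt, m in [("day", 10.0), ("night", 12.0), ("open", 14.0), ("closed", 6.0)]:
        rows.append(dict(study_id="s1", species="Aa bb", metric="seed_set",
                         treatment=trt, n=12, mean=m, sd=2.0))
    for trt, m in [("day", 5.0), ("night", 4.0)]:
        rows.append(dict(study_id="s2", species="Cc dd", metric="fruit_mass",
                         treatment=trt, n=8, mean=m, sd=1.0))
    return pd.DataFrame(rows)


def toy_meta_data(rng, k=60, n_study=10, sigma_study=0.3, sigma_obs=0.4, mu=0.25):
    study = np.repeat(np.arange(n_study), k // n_study)
    vi = rng.uniform(0.05, 0.25, k)
    y = (mu + np.sqrt(sigma_study) * rng.standard_normal(n_study)[study]
         + np.sqrt(sigma_obs) * rng.standard_normal(k)
         + rng.normal(0, np.sqrt(vi)))
    random = [RandomEffect("study", study), RandomEffect("obs", np.arange(k))]
    return y, vi, study, random
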