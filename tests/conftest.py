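import numpy as np
import pandas as pd
import pytest

from adrenosig.cohort import CohortMatrix
from adrenosig.preprocess import run_qc
from adrenosig.synthdata import SynthConfig, generate_cohort


def make_cohort(abund, osmolality=None, group=None, sex=None, state=None, **met_meta):
    """Assemble a small CohortMatrix from a 2-D array of abundances."""
    abund = np.asarray(abund, dtype=float)
    n, p = abund.shape
    sids = [f"S{i}" for i in range(n)]
    mids = [f"M{j}" for j in range(p)]
    sm = pd.DataFrame(
        {
            "osmolality": np.ones(n) if osmolality is None else np.asarray(osmolality, float),
            "sex": np.zeros(n, dtype=int) if sex is None else np.asarray(sex, int),
            "age": np.full(n, 10.0),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    if group is not None:
        sm["group"] = group
    mm = pd.DataFrame(index=pd.Index(mids, name="metabolite_id"))
    mm["name"] = mids
    for key, val in met_meta.items():
        mm[key] = val
    return CohortMatrix(
        abundances=pd.DataFrame(abund, index=sm.index, columns=mm.index),
        sample_meta=sm,
        metabolite_meta=mm,
        state=state or [],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 40-metabolite synthetic cohort with planted effects."""
    cfg = SynthConfig(
        n_samples=60,
        n_metabolites=40,
        minority_fraction=0.2,
        n_effect_down=5,
        n_effect_up=2,
        effect_size=2.0,
        block_specs=[(8, 0.7)],
        missing_rate=0.05,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    processed, _ = run_qc(small_cohort.matrix, min_present=0.5)
    return processed
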