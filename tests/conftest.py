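import numpy as np
import pandas as pd
import pytest

import stressvirome as sv


@pytest.fixture(scope="session")
def evidence_bundle():
    """The standard planted-truth evidence bundle (200 contigs, seed 7)."""
    return sv.simulate_evidence_bundle(n_contigs=200, viral_fraction=0.3, seed=7)


@pytest.fixture(scope="session")
def count_study():
    """Cross-sectional count study at the study's group sizes."""
    return sv.simulate_count_study(
        n_features=300, n_per_group=(10, 10, 9), n_restored=30,
        effect_size=1.5, seed=1,
    )


@pytest.fixture
def small_design():
    """Balanced 3-group design, 4 subjects each, one timepoint."""
    rows = []
    for g in ("Ctr", "CtrStress", "FVTStress"):
        for k in range(4):
            rows.append(
                dict(sample_id=f"{g}{k}", group=g, subject_id=f"{g}_s{k}",
                     timepoint="T1", total_mapped_reads=1000)
            )
    return sv.validate_design(pd.DataFrame(rows))


def group_values(design, means, sd=0.0, seed=0):
    """Per-sample values from group means plus optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    return np.array(
        [means[g] + (rng.normal(0, sd) if sd else 0.0) for g in design["group"]]
    )
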