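import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import vstscan as vs

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

# Study-condition group sizes: four geographic cattle groups, 157 samples.
STUDY_GROUPS = (("North", 35), ("Northwest", 17), ("Southwest", 63), ("South", 42))


def make_group_assignment(groups=STUDY_GROUPS) -> vs.GroupAssignment:
    return vs.GroupAssignment(
        {f"{g}_{i + 1:03d}": g for g, n in groups for i in range(n)}
    )


def region_lrrs_from_matrix(values: np.ndarray, samples) -> list[vs.RegionLrr]:
    """Wrap a regions x samples value matrix as RegionLrr objects R1, R2, ..."""
    return [
        vs.RegionLrr(
            cnvr_id=f"R{i + 1}",
            values=pd.Series(values[i], index=list(samples)),
            n_probes=1,
        )
        for i in range(values.shape[0])
    ]


@pytest.fixture(scope="session")
def study_groups() -> vs.GroupAssignment:
    return make_group_assignment()


@pytest.fixture(scope="session")
def small_cohort() -> vs.SimCohort:
    """A desk-scale simulated cohort shared by read-only tests."""
    config = vs.SimConfig(
        seed=11,
        n_chrom=4,
        chrom_length_bp=2_000_000,
        probe_spacing_bp=10_000,
        truth_regions=vs.default_truth_regions(
            n_chrom=4, chrom_length_bp=2_000_000
        ),
    )
    return vs.simulate_cohort(config)
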