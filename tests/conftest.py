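import numpy as np
import pytest

import nirskinetics as nk
from nirskinetics.synthetic import QUIET


@pytest.fixture(scope="session")
def quiet_truth() -> nk.SimulationTruth:
    """Pre-bed-rest group-mean ground truth, no noise."""
    return nk.SimulationTruth(noise=QUIET)


@pytest.fixture(scope="session")
def tibia_conc(quiet_truth):
    return nk.simulate_concentrations(quiet_truth, "tibia")


@pytest.fixture(scope="session")
def tibia_raw(quiet_truth):
    return nk.simulate_device_recording(quiet_truth, "tibia", clock_offset=0.0)


@pytest.fixture(scope="session")
def gastro_raw(quiet_truth):
    return nk.simulate_device_recording(quiet_truth, "gastrocnemius", clock_offset=2.0)


@pytest.fixture(scope="session")
def segmented_pre(tibia_raw, gastro_raw):
    """Full-chain processed and segmented series for both tissues (noiseless)."""
    segs, _sync = nk.process_pair(tibia_raw, gastro_raw)
    return segs


def make_metric_table(rng, n_subjects, means, sds, subject_sd=0.0, metric="m"):
    """Long-format 2x2 metric table with per-subject random intercepts.

    ``means``/``sds``: dict[(tissue, timepoint)] -> population mean / SD.
    """
    import pandas as pd

    rows = []
    for i in range(n_subjects):
        intercept = rng.normal(0.0, subject_sd)
        for (tissue, timepoint), mu in means.items():
            rows.append(
                dict(
                    subject=f"s{i:02d}", timepoint=timepoint, tissue=tissue,
                    channel="TSI", metric=metric,
                    value=intercept + rng.normal(mu, sds[(tissue, timepoint)]),
                )
            )
    return pd.DataFrame(rows)
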