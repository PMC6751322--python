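import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from metacoex import SynthConfig, generate_cohort, preprocess


@pytest.fixture(scope="session")
def small_cohort():
    """A 26-subject cohort with the default planted structure."""
    cfg = SynthConfig(seed=7)
    dataset, metadata, truth = generate_cohort(cfg)
    return cfg, dataset, metadata, truth


@pytest.fixture(scope="session")
def small_changes(small_cohort):
    """Change matrix preprocessed from the small cohort."""
    _, dataset, metadata, truth = small_cohort
    ds, _ = preprocess.filter_by_lod(dataset)
    ds, _ = preprocess.batch_correct(ds)
    log_matrix = preprocess.impute_and_log(ds)
    changes = preprocess.compute_changes(log_matrix, ds.sample_map)
    return changes, metadata, truth


def make_plate_dataset(values, plates, qc_values=None, lod=1.0):
    """Build a minimal single-metabolite PlateDataset from raw numbers.

    ``values``: dict sample_id -> value for cohort samples;
    ``plates``: dict sample_id -> plate; ``qc_values``: dict qc_id -> (plate, value).
    """
    from metacoex.types import PlateDataset

    rows = []
    for sid, v in values.items():
        rows.append(
            dict(sample_id=sid, metabolite_id="met_A", plate_id=plates[sid],
                 value=(np.nan if v is None else v), below_lod=v is None,
                 is_qc_pool=False)
        )
    for qid, (plate, v) in (qc_values or {}).items():
        rows.append(
            dict(sample_id=qid, metabolite_id="met_A", plate_id=plate,
                 value=v, below_lod=False, is_qc_pool=True)
        )
    measurements = pd.DataFrame(rows)
    all_plates = sorted(measurements["plate_id"].unique())
    lod_table = pd.DataFrame(
        [dict(metabolite_id="met_A", plate_id=p, lod_value=lod) for p in all_plates]
    )
    sample_map = pd.DataFrame(
        {
            "sample_id": list(values),
            "subject_id": [s.rsplit("_", 1)[0] for s in values],
            "timepoint": [s.rsplit("_", 1)[1] for s in values],
        }
    )
    return PlateDataset(measurements, lod_table, sample_map)
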