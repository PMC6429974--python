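import numpy as np
import pytest

import pulsestage as ps


@pytest.fixture(scope="session")
def tiny_synth_cfg() -> ps.SyntheticConfig:
    """Small, fast cohort: 4 presyncope + 1 tolerated subject, short phases."""
    return ps.SyntheticConfig(
        n_subjects=5,
        presyncope_fraction=0.8,
        baseline_duration_s=120.0,
        max_lbnp_duration_s=600.0,
        ramp_duration_s=(360.0, 60.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_synth_cfg):
    return ps.generate_cohort(tiny_synth_cfg)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort) -> ps.BeatMatrix:
    return ps.build_beat_matrix([rec for rec, _ in tiny_cohort])


def make_features(scores, labels) -> ps.FeatureMatrix:
    """Wrap raw arrays as a FeatureMatrix for classifier-level tests."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = scores.shape[0]
    return ps.FeatureMatrix(
        scores=scores,
        labels=labels,
        subject_ids=np.array(["T"] * n, dtype=object),
        onsets_s=np.arange(n, dtype=float),
        fitted_on="toy",
    )
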