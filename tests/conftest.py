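import numpy as np
import pandas as pd
import pytest

import neurodyad as nd


@pytest.fixture(scope="session")
def small_config():
    return nd.SyntheticConfig(
        n_subjects=20, n_cohort=60, n_rois=10, n_timepoints=150, seed=7
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return nd.simulate_study(small_config)


@pytest.fixture(scope="session")
def dyad_table(small_study):
    sim = nd.dyadic_roi_correlations(small_study.timeseries)
    sim = nd.impute_missing(sim)
    sim = nd.normalize_per_roi(sim)
    sim = nd.weighted_composite(sim, small_study.volumes)
    return nd.build_dyad_table(
        sim, small_study.distances, small_study.demographics,
        small_study.scanned_ids,
    )


@pytest.fixture
def toy_nominations():
    """A nominates B, B nominates A and C (3 subjects)."""
    m = np.zeros((3, 3), dtype=int)
    m[0, 1] = 1  # A -> B
    m[1, 0] = 1  # B -> A
    m[1, 2] = 1  # B -> C
    return nd.NominationMatrix(entries=m, subject_ids=("A", "B", "C"))


def make_timeseries(series, present=None, roi_names=None):
    series = np.asarray(series, dtype=float)
    n, r, _ = series.shape
    if present is None:
        present = np.ones((n, r), dtype=bool)
    if roi_names is None:
        roi_names = tuple(f"roi{k}" for k in range(r))
    return nd.RoiTimeSeriesSet(
        series=series,
        present_mask=present,
        roi_names=roi_names,
        subject_ids=tuple(f"s{k}" for k in range(n)),
    )


@pytest.fixture
def simulate_ordered_logit():
    """Draw from the proportional-odds model logit P(Y<=k) = tau_k - x'b."""

    def _draw(beta, tau, x, rng):
        # y <= k  iff  x'b + u < tau_k, i.e. logit P(Y<=k) = tau_k - x'b
        beta = np.atleast_1d(beta)
        latent = x @ beta + rng.logistic(size=x.shape[0])
        return np.digitize(latent, np.atleast_1d(tau)) + 1

    return _draw


def dyad_demo(ids, **overrides):
    base = pd.DataFrame(
        {
            "subject_id": list(ids),
            "gender": ["F"] * len(ids),
            "ethnicity": ["e"] * len(ids),
            "nationality": ["n"] * len(ids),
            "age": [27] * len(ids),
            "handedness": ["R"] * len(ids),
        }
    ).set_index("subject_id")
    for col, vals in overrides.items():
        base[col] = vals
    return base
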