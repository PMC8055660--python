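"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from falff_prognosis import CohortConfig, make_cohort, run_group_ica


@pytest.fixture(scope="session")
def clean_cohort():
    """10 subjects, 5 planted sources, noiseless: ground truth is exact."""
    return make_cohort(CohortConfig(n_subjects=10, n_sources=5, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def clean_decomposition(clean_cohort):
    return run_group_ica(clean_cohort.scans, n_components=5, seed=1)


@pytest.fixture(scope="session")
def recovery_cohort():
    """30 subjects in the planted-linear-outcome regime (noise sd 0.03)."""
    return make_cohort(CohortConfig(n_subjects=30, n_sources=5, seed=11))


def matched_correlations(truth_maps: np.ndarray, est_maps: np.ndarray) -> np.ndarray:
    """Optimal one-to-one |correlation| matching of estimated to true maps."""
    from scipy.optimize import linear_sum_assignment

    k = truth_maps.shape[0]
    corr = np.abs(np.corrcoef(truth_maps, est_maps)[:k, k:])
    rows, cols = linear_sum_assignment(-corr)
    return corr[rows, cols]


@pytest.fixture(scope="session")
def match_maps():
    return matched_correlations
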