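import numpy as np
import pytest

from siltriage import reference


@pytest.fixture
def study_strata():
    """The published per-SIL-value stratum table."""
    return reference.stratum_table()


@pytest.fixture
def study_records(study_strata):
    """Per-patient (scores, outcomes) arrays expanded from the stratum table."""
    return study_strata.expand()


def random_cohort(rng: np.random.Generator, n_max: int = 50, k_scores: int = 7):
    """Small random discrete-score cohort with both outcome classes."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        scores = rng.integers(0, k_scores, size=n)
        outcomes = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
        if 0 < outcomes.sum() < n:
            return scores.astype(float), outcomes


def brute_force_auc(scores, outcomes) -> float:
    """O(n^2) pair-counting oracle: concordant + half ties over all pairs."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    total = 0.0
    for x in cases:
        for y in controls:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(cases) * len(controls))
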