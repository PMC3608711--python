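import numpy as np
import pytest

from darklung import (
    PhantomParams,
    RunConfig,
    analyze_cohort,
    forward_project,
    make_lung_phantom,
)


@pytest.fixture(scope="session")
def small_params():
    """Reduced cohort for fast unit tests."""
    return PhantomParams(
        image_shape=(64, 64), n_projections=2, n_per_group=2, seed=7
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return make_lung_phantom(small_params, "E1", 0)


@pytest.fixture(scope="session")
def small_scan_pair(small_params, small_truth):
    rng = np.random.default_rng(11)
    return forward_project(small_truth, small_params, rng=rng)


@pytest.fixture(scope="session")
def default_analysis():
    """Full default-condition run shared by the acceptance checks."""
    return analyze_cohort(RunConfig())


def sinusoid_fit(frames, fractions):
    """Independent least-squares oracle for the stepping-curve fit.

    I_k = A + B cos(2 pi f_k) + C sin(2 pi f_k) is linear in (A, B, C),
    so the fit is exact linear least squares; a0 = A, a1 = |(B, C)|,
    phi = atan2(-C, B).
    """
    f = np.asarray(fractions)
    design = np.column_stack(
        [np.ones_like(f), np.cos(2 * np.pi * f), np.sin(2 * np.pi * f)]
    )
    flat = frames.reshape(frames.shape[0], -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    a, b, c = (x.reshape(frames.shape[1:]) for x in coef)
    return a, np.hypot(b, c), np.arctan2(-c, b)


def pair_count_auc(scores, labels):
    """Exhaustive tie-aware Mann-Whitney oracle for the AUC."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))
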