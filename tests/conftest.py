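import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from centroquant import SimParams, segment_stack, simulate_replicate


def fast_params(seed=0, folds=None, **overrides):
    """Study-design sampling (13 nuclei x 8 foci >= 100 foci, 3 channels)
    on a reduced image geometry so simulations stay desk-fast."""
    kwargs = dict(
        image_shape_xy=(192, 192),
        n_z=5,
        condition_fold_changes=dict(folds or {"WT": 1.0}),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)


def noiseless_params(seed=0, **overrides):
    """No shot/read noise, no shading, no offset: analytic renders."""
    overrides.setdefault("shot_noise", False)
    overrides.setdefault("read_noise_sd", 0.0)
    overrides.setdefault("shading_amplitude", 0.0)
    overrides.setdefault("camera_offset", 0.0)
    return fast_params(seed=seed, **overrides)


@pytest.fixture(scope="session")
def wt_stack_truth():
    """One simulated wild-type stack with its ground truth (shared)."""
    return simulate_replicate(fast_params(seed=7), "WT", 1)


@pytest.fixture(scope="session")
def wt_segmented(wt_stack_truth):
    stack, _ = wt_stack_truth
    return segment_stack(stack)
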