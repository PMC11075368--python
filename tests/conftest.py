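import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ircut

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (48 non-IR / 45 IR men), seed 1."""
    return ircut.generate_cohort(ircut.default_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def default_panel(default_cohort):
    return ircut.index_panel(default_cohort)


@pytest.fixture(scope="session")
def matsuda_reference(default_panel):
    """(cutoff, IR labels) from the refined Matsuda reference, seed-1 cohort."""
    matsuda = default_panel["matsuda"].to_numpy()
    return ircut.refine_matsuda_cutoff(matsuda, 4.0)


def make_two_group_instance(rng, n_lo=12, n_hi=30, frac=(0.4, 0.6), separated=None):
    """Small synthetic instance emulating the study design.

    A latent severity drives both the reference x (insulin-sensitivity-like:
    low in the IR group) and the candidate y (random direction).  When
    ``separated`` is true the inter-group shift is large enough for a clean
    gap in y; group sizes are near-balanced, as in the emulated cohort.
    Returns (x, y, ir_labels).
    """
    n = int(rng.integers(n_lo, n_hi + 1))
    lo = max(3, int(np.ceil(frac[0] * n)))
    hi = min(n - 3, int(frac[1] * n))
    n_ir = int(rng.integers(lo, hi + 1))
    ir = np.zeros(n, dtype=bool)
    ir[:n_ir] = True
    if separated is None:
        separated = rng.random() < 0.5
    shift = rng.uniform(6.0, 12.0) if separated else rng.uniform(0.5, 3.0)
    severity = np.where(ir, shift, 0.0) + rng.normal(0.0, 1.0, n)
    x = -severity + rng.normal(0.0, 0.3, n)
    y = severity + rng.normal(0.0, 0.3, n)
    if rng.random() < 0.5:
        y = -y
    return x, y, ir
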