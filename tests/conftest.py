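import numpy as np
import pytest
from hypothesis import settings

from lektimap import (
    fatal_variant_demo_cohort,
    lekti_domain_table,
    spink5_transcript,
)

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def transcript():
    return spink5_transcript()


@pytest.fixture(scope="session")
def domain_table():
    return lekti_domain_table()


@pytest.fixture(scope="session")
def demo_cohort():
    return fatal_variant_demo_cohort()


def grid_logistic_mle(y, x, span=(-8.0, 8.0), stages=5, width=121):
    """Independent oracle: dense grid-search maximizer of the Bernoulli
    log-likelihood of logit(p) = b0 + b1*x, refined over several stages to
    ~1e-4 resolution. Deliberately brute force; shares no code with the
    fitting path it checks."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    lo0, hi0 = span
    b0_lo, b0_hi = lo0, hi0
    b1_lo, b1_hi = lo0, hi0
    best = (0.0, 0.0)
    for _ in range(stages):
        b0s = np.linspace(b0_lo, b0_hi, width)
        b1s = np.linspace(b1_lo, b1_hi, width)
        eta = (
            b0s[:, None, None]
            + b1s[None, :, None] * x[None, None, :]
        )
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(b0s[i]), float(b1s[j]))
        step0 = b0s[1] - b0s[0]
        step1 = b1s[1] - b1s[0]
        b0_lo, b0_hi = best[0] - 2 * step0, best[0] + 2 * step0
        b1_lo, b1_hi = best[1] - 2 * step1, best[1] + 2 * step1
    return best
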