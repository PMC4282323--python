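import numpy as np
import pytest

from dtlshrink import TrialDesign, TrialOutcome


@pytest.fixture
def design_k6():
    """The canonical design: 6 arms, unit stage errors."""
    return TrialDesign(k=6, sigma1=1.0, sigma2=1.0)


@pytest.fixture
def design_stage1_only():
    """Degenerate design with no stage-2 information (all variances equal)."""
    return TrialDesign(k=6, sigma1=1.0, sigma2=np.inf)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_outcome(x, y_s):
    """Outcome with max-selection applied to the given stage-1 vector."""
    x = np.asarray(x, dtype=float)
    s = int(np.argmax(x))
    rest = np.delete(x, s)
    r = int(np.argmax(rest))
    if r >= s:
        r += 1
    return TrialOutcome(x=x, s=s, r=r, y_s=float(y_s))
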