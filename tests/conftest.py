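import numpy as np
import pandas as pd
import pytest

from rtmeta.io_trials import TrialTable


def make_table(stimulus, response, confidence, rt, subject="s1", k_levels=0):
    """Build a validated TrialTable from parallel per-trial lists."""
    df = pd.DataFrame(
        {
            "subject": subject,
            "stimulus": list(stimulus),
            "response": list(response),
            "confidence": list(confidence),
            "rt": list(rt),
        }
    )
    return TrialTable(df, k_levels=k_levels)


def random_table(rng, n, K=4, subject="s1"):
    """A random (non-generative-model) trial table for oracle comparisons."""
    stim = rng.choice(["S1", "S2"], n)
    resp = rng.choice(["S1", "S2"], n)
    conf = rng.integers(1, K + 1, n)
    rt = rng.uniform(200, 1500, n)
    return make_table(stim, resp, conf, rt, subject=subject, k_levels=K)


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)
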