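import numpy as np
import pytest

from repsum.studies import StudyRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def discordant_records():
    """Study pairs where the two-trials rule and Edgington's method disagree.

    The first two have a marginally non-significant original but a strongly
    significant replication: the two-trials rule fails while both Edgington
    variants succeed.  The third has both p-values just under 0.025: the
    two-trials rule succeeds while unweighted Edgington does not.
    """
    return [
        StudyRecord("borderline_original_strong_replication", p_o=0.028, p_r=0.00009),
        StudyRecord("ambrus_greiner_like", p_o=0.027, p_r=0.006),
        StudyRecord("both_borderline", p_o=0.024, p_r=0.024),
    ]


@pytest.fixture
def mixed_records():
    """A small synthetic project with clear successes, failures and a
    wrong-direction replication."""
    return [
        StudyRecord("strong_both", p_o=0.001, p_r=0.002, c=1.0),
        StudyRecord("weak_both", p_o=0.2, p_r=0.4, c=1.0),
        StudyRecord("strong_orig_null_rep", p_o=0.0005, p_r=0.6, c=1.0),
        StudyRecord("borderline", p_o=0.02, p_r=0.01, c=2.0),
        StudyRecord("from_correlations", r_o=0.5, n_o=28, r_r=0.4, n_r=40),
    ]
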