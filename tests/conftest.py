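import itertools

import numpy as np
import pytest
from hypothesis import settings

from poolfit import SyntheticConfig, generate_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_signed_rank(differences, alternative="two-sided"):
    """Independent oracle: enumerate every sign assignment of the realized ranks.

    Uses the same zero-drop / midrank conventions as the implementation but
    walks all 2^n assignments directly instead of convolving.
    """
    from scipy.stats import rankdata

    d = [x for x in differences if x != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    total = 2**n
    p_ge, p_le = ge / total, le / total
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_obs, p


def brute_force_tai(counts, w, exclusions):
    """Independent oracle: direct product of w_c^n_c, then the N-th root."""
    prod = 1.0
    n = 0
    for codon, count in counts.items():
        if codon in exclusions:
            continue
        prod *= w[codon] ** count
        n += count
    return prod ** (1.0 / n)


@pytest.fixture(scope="session")
def small_panel():
    """A 6-pair panel with one satellite trio, genes strongly pool-adapted."""
    return generate_panel(
        SyntheticConfig(seed=11, n_pairs=6, n_satellites=1, gene_length_codons=120)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
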