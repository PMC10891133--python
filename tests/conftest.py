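import numpy as np
import pandas as pd
import pytest

import serumdia as sd
from serumdia.cohort import CohortDesign, generate_fragments, \
    generate_metadata, metadata_to_frame


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(n_pairs=6, n_batches=2, qc_interval=4, n_proteins=30,
                        frac_differential=0.2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    records = generate_metadata(small_design)
    frags, truth = generate_fragments(small_design, records)
    return records, metadata_to_frame(records), frags, truth


@pytest.fixture(scope="session")
def small_matrix(small_design, small_cohort):
    _, meta, frags, _ = small_cohort
    matrix, _ = sd.preprocess(frags, meta)
    return matrix, meta


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (29 pairs, 4 batches, 334 proteins), shared by the
    heavier recovery tests."""
    design = CohortDesign(seed=7)
    records = generate_metadata(design)
    frags, truth = generate_fragments(design, records)
    return design, records, metadata_to_frame(records), frags, truth


def brute_force_nw(t_eval, t_obs, x_obs, sd):
    """Direct-summation Nadaraya-Watson oracle."""
    num = den = 0.0
    for tj, xj in zip(t_obs, x_obs):
        w = np.exp(-((t_eval - tj) ** 2) / (2 * sd**2))
        num += w * xj
        den += w
    return num / den


def brute_force_bh(pvals):
    """Step-up BH over all ranks, monotonicity enforced, capped at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        adj[i] = min(prev, 1.0)
    return adj
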