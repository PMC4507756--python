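import numpy as np
import pandas as pd
import pytest

from tcna import ExpressionMatrix, GuideGeneSet
from tcna.io import CANONICAL_GUIDE_ROLES


def make_matrix(values, gene_ids=None, sample_ids=None, roles=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), roles or {})


@pytest.fixture
def small_matrix():
    return make_matrix([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])


@pytest.fixture
def full_guides():
    """A guide set covering all 15 canonical roles with synthetic gene IDs."""
    return GuideGeneSet({role: f"gene_{role}" for role in CANONICAL_GUIDE_ROLES})


@pytest.fixture
def guide_matrix_identical(full_guides):
    """All 15 guides carry one identical noisy profile (saturated network)."""
    rng = np.random.default_rng(7)
    profile = rng.lognormal(3, 1, size=13)
    values = np.tile(profile, (15, 1))
    return make_matrix(values, gene_ids=full_guides.gene_ids)
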