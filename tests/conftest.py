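import numpy as np
import pytest

from eqtlmeta.datamodel import (
    ExpressionMatrix,
    GenotypeVector,
    TissueSampleMap,
)


@pytest.fixture
def three_tissue_maps():
    """Five individuals, three tissues, three samples each (9 stacked rows)."""
    return [
        TissueSampleMap("T1", ("S1", "S2", "S3")),
        TissueSampleMap("T2", ("S1", "S2", "S4")),
        TissueSampleMap("T3", ("S3", "S4", "S5")),
    ]


@pytest.fixture
def three_tissue_genotype():
    return GenotypeVector(
        "rs1", {"S1": 0.0, "S2": 1.0, "S3": 2.0, "S4": 1.0, "S5": 0.0}
    )


@pytest.fixture
def three_tissue_expression(three_tissue_maps):
    rng = np.random.default_rng(7)
    out = []
    for m in three_tissue_maps:
        out.append(
            ExpressionMatrix(
                tissue_id=m.tissue_id,
                probe_ids=("g1", "g2"),
                sample_ids=m.sample_ids,
                values=rng.normal(size=(2, m.n_samples)),
            )
        )
    return out


def random_pd_covariance(rng, k, require_positive_weights=True, max_tries=200):
    """Random PD covariance; optionally restricted to the domain where the
    un-correlated variance construction is defined (positive inverse row
    sums), which is where sharing-induced effect covariances live."""
    for _ in range(max_tries):
        A = rng.normal(size=(k, k + 2))
        sigma = A @ A.T / (k + 2) + 0.05 * np.eye(k)
        if not require_positive_weights:
            return sigma
        w = np.linalg.solve(sigma, np.ones(k))
        if np.all(w > 0):
            return sigma
    raise RuntimeError("failed to draw a covariance with positive weights")
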