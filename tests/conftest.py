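import numpy as np
import pytest

from maprove.scoring import ScoreResult, ScoringConfig


@pytest.fixture(scope="session")
def scoring_config() -> ScoringConfig:
    return ScoringConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_result(
    score,
    protein_id="p1",
    variant="A1V",
    line_id="L1",
    gene_id="g1",
    threshold=-2.5,
    n_clusters=30,
    n_supporting=50,
    flags=(),
):
    """Construct a ScoreResult with a consistent classification."""
    flags = frozenset(flags)
    if score is None:
        flags = flags | {"unscored"}
        classification = None
    else:
        classification = "deleterious" if score < threshold else "neutral"
    return ScoreResult(
        protein_id=protein_id, variant=variant, score=score,
        classification=classification, n_clusters=n_clusters,
        n_supporting=n_supporting, flags=flags, line_id=line_id, gene_id=gene_id)
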