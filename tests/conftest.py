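import numpy as np
import pytest

from sexconflictx import generate_design, generate_expression


@pytest.fixture(scope="session")
def paper_design():
    """The source experiment's 3 treatments x 3 populations x 2 replicates."""
    return generate_design(3, 3, 2)


@pytest.fixture(scope="session")
def planted_experiment(paper_design):
    """A matrix with strong planted effects in every category (effect 10x sd)."""
    expr, truth = generate_expression(
        paper_design,
        n_transcripts=600,
        category_fractions={k: 0.03 for k in range(1, 7)},
        effect_size=3.0,
        population_sd=0.1,
        residual_sd=0.3,
        seed=11,
    )
    return expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
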