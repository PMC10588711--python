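import numpy as np
import pytest

from birt import (
    ModelSpec,
    ResponseData,
    SamplerConfig,
    draw_parameters_from_priors,
    generate_responses,
    run_chains,
)


@pytest.fixture(scope="session")
def one_pl() -> ModelSpec:
    return ModelSpec("1PL")


@pytest.fixture(scope="session")
def two_pl() -> ModelSpec:
    return ModelSpec("2PL")


@pytest.fixture(scope="session")
def tiny_data() -> ResponseData:
    """3 items x 2 takers, fully crossed."""
    return ResponseData.from_records(
        [(i, j, (i + j) % 2) for i in range(3) for j in range(2)]
    )


@pytest.fixture(scope="session")
def bone_sized_data(one_pl) -> ResponseData:
    """Synthetic data on the 60-item x 7-taker roster of the BONE study."""
    params = draw_parameters_from_priors(60, 7, one_pl, seed=42)
    return generate_responses(params, one_pl, seed=43)


@pytest.fixture(scope="session")
def bone_sized_fit(bone_sized_data, one_pl):
    """A modest but well-mixed fit reused by several tests."""
    cfg = SamplerConfig(num_chains=2, num_samples=3000, num_warmup=500, seed=1)
    return run_chains(bone_sized_data, one_pl, cfg)


def random_parameter_set(rng: np.random.Generator, n_items: int, n_takers: int,
                         two_pl: bool):
    from birt import ParameterSet

    return ParameterSet(
        theta=rng.normal(0, 1.2, n_takers),
        beta=rng.normal(0, 1.2, n_items),
        alpha=np.exp(rng.normal(0.3, 0.5, n_items)) if two_pl else None,
    )


def random_response_data(rng: np.random.Generator, n_items: int, n_takers: int):
    responses = rng.integers(0, 2, n_items * n_takers)
    return ResponseData.from_records(
        [(i, j, responses[i * n_takers + j]) for i in range(n_items) for j in range(n_takers)]
    )
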