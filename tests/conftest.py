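import numpy as np
import pytest

import pkmoo
from pkmoo.search_space import SearchSpace, TokenOption, TokenSet


@pytest.fixture(scope="session")
def tiny_space() -> SearchSpace:
    """10-bit fully enumerable benchmark space (1024 genomes)."""
    return pkmoo.make_benchmark_space("tiny")


@pytest.fixture(scope="session")
def six_set_space() -> SearchSpace:
    """Six token sets, each {no-effect, one-effect}, with effect limit 4."""
    sets = tuple(
        TokenSet(
            name=f"cov{i}",
            options=(
                TokenOption("none"),
                TokenOption("effect", n_effects=1, n_extra_params=1),
            ),
        )
        for i in range(6)
    )
    return SearchSpace(token_sets=sets, effect_limit=4)


@pytest.fixture(scope="session")
def bench_objective(tiny_space):
    """Deterministic synthetic (OFV, NEP) landscape on the tiny space."""
    return pkmoo.benchmark_objectives(tiny_space, rng_seed=42)


@pytest.fixture(scope="session")
def rich_small():
    """Rich-design 1-compartment oral dataset, 20 subjects, no covariates."""
    sc = pkmoo.rich_oral_scenario(n_subjects=20, rng_seed=3, with_covariates=False)
    ds, truth = pkmoo.generate_dataset(sc)
    return sc, ds


@pytest.fixture(scope="session")
def rich_small_fit(rich_small):
    """FOCE-I fit of the generating model on the small rich dataset."""
    sc, ds = rich_small
    return pkmoo.fit(sc.truth_spec, ds)


@pytest.fixture(scope="session")
def mini_space() -> SearchSpace:
    """4-bit space over a 1-compartment oral model for end-to-end tests."""
    from pkmoo.synthetic_data import _bsv_set, _cov_set, _ruv_set

    return SearchSpace(
        token_sets=(
            _bsv_set("CL"),
            _cov_set("CL", "WT", ("power",)),
            _ruv_set(),
        )
    )


@pytest.fixture(scope="session")
def mini_dataset():
    """Very small rich dataset for real-fit search tests (FO method)."""
    sc = pkmoo.rich_oral_scenario(n_subjects=5, rng_seed=9, with_covariates=True)
    ds, _ = pkmoo.generate_dataset(sc)
    return ds


def random_genome(rng: np.random.Generator, n: int) -> tuple[int, ...]:
    return tuple(int(b) for b in rng.integers(0, 2, n))
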