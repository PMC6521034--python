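import pytest

from nutricompile.synthetic_data import generate_food_db, generate_survey


@pytest.fixture(scope="session")
def food_bundle():
    """A small fully-specified food-database bundle (compiled lazily)."""
    return generate_food_db(n_foods=120, coverage_fraction=0.9, seed=11)


@pytest.fixture(scope="session")
def compiled_db(food_bundle):
    return food_bundle.compile()


@pytest.fixture(scope="session")
def density(compiled_db):
    return {r.food_id: r.choline for r in compiled_db if r.has_value}


@pytest.fixture(scope="session")
def survey(density):
    """A mid-sized two-day survey with known variance components."""
    return generate_survey(
        n_respondents=600, seed=7, sigma2_between=400.0,
        sigma2_within=1600.0, r_replicates=12, compiled_db=density,
    )
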