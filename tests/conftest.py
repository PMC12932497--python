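import pytest
from hypothesis import settings

from croprank import GeneratorModel, SeasonCosts, SeasonSpec, TreatmentSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_treatments() -> list[TreatmentSpec]:
    """One zero-N control and two fertilized strategies under drip."""
    return [
        TreatmentSpec("CK", 0.0, irrigation_method="drip", is_zero_n=True),
        TreatmentSpec("A", 195.0, 0.6, 0.0, 0.4, irrigation_method="drip"),
        TreatmentSpec("B", 100.0, 0.0, 0.5, 0.5, irrigation_method="drip"),
    ]


@pytest.fixture
def toy_seasons() -> list[SeasonSpec]:
    costs = SeasonCosts(
        water_price_per_m3=0.6, fertilizer_cost=2600.0,
        fertilizer_cost_zero_n=1100.0, seed_cost=750.0,
        machinery_cost=1600.0, land_rent_annual=15000.0,
    )
    return [
        SeasonSpec("w1", "wheat", "Y1", {"drip": 1950.0, "flood": 2775.0}, 2.8, costs),
        SeasonSpec("m1", "maize", "Y1", {"drip": 1125.0, "flood": 1575.0}, 2.6, costs),
    ]


@pytest.fixture
def toy_model(toy_treatments, toy_seasons) -> GeneratorModel:
    means = {
        ("CK", "w1"): 5300.0, ("CK", "m1"): 7100.0,
        ("A", "w1"): 8532.5, ("A", "m1"): 10596.95,
        ("B", "w1"): 7800.0, ("B", "m1"): 9900.0,
    }
    return GeneratorModel(mean_yield=means, seed=7)


def zero_noise(model: GeneratorModel, **overrides) -> GeneratorModel:
    """Copy of a generator model with every noise source switched off."""
    from dataclasses import replace

    return replace(model, yield_sd=0.0, yield_cv=0.0, harvest_index_sd=0.0,
                   n_noise_sd=0.0, **overrides)
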