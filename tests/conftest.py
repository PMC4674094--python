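import pytest

from ddref_lq.data_model import AnimalRecord
from ddref_lq.synthetic_data import make_paper_shaped_fixture


@pytest.fixture(scope="session")
def paper_shaped():
    """Scaled-down 16-stratum archive-like cohort (about 2.8k animals)."""
    animals, observations = make_paper_shaped_fixture(seed=42, scale=0.04)
    return animals, observations


def make_animal(
    animal_id="a0",
    group_id="g0",
    study_id="s0",
    strain="B6CF1",
    sex="F",
    age=100.0,
    lifespan=800.0,
    **kwargs,
):
    return AnimalRecord(
        animal_id=animal_id,
        group_id=group_id,
        study_id=study_id,
        strain=strain,
        sex=sex,
        age_first_exposure=age,
        lifespan=lifespan,
        **kwargs,
    )
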