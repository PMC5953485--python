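import pytest

from pedcontrib import Pedigree, PedigreeRecord, SimulationConfig, simulate_pedigree


def rec(aid, sire=None, dam=None, year=None, sex="unknown"):
    return PedigreeRecord(aid, sire, dam, year, sex)


@pytest.fixture
def trio_ped():
    """Founder sire S, founder dam D, offspring X."""
    return Pedigree([
        rec("S", sex="male", year=1990),
        rec("D", sex="female", year=1990),
        rec("X", "S", "D", year=1995),
    ])


@pytest.fixture
def fullsib_mating_ped():
    """Offspring of a full-sib mating; grandparents are founders (F=0.25)."""
    return Pedigree([
        rec("GS", sex="male"), rec("GD", sex="female"),
        rec("S", "GS", "GD", sex="male"), rec("D", "GS", "GD", sex="female"),
        rec("X", "S", "D"),
    ])


@pytest.fixture
def halfsib_mating_ped():
    """Offspring of a half-sib mating via a shared sire (F=0.125)."""
    return Pedigree([
        rec("A", sex="male"), rec("B", sex="female"), rec("C", sex="female"),
        rec("S", "A", "B", sex="male"), rec("D", "A", "C", sex="female"),
        rec("X", "S", "D"),
    ])


def small_config(seed, **overrides):
    """Desk-scale simulation config used throughout the unit tests."""
    defaults = dict(
        seed=seed,
        n_founders=30,
        years=(1970, 1999),
        matings_per_year=25,
        case_years=(1985, 1999),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def random_ped():
    """Factory: seeded multi-generation synthetic pedigree."""

    def make(seed=0, **overrides):
        return simulate_pedigree(small_config(seed, **overrides))

    return make
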