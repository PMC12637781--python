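import numpy as np
import pytest

from autozyg.pedigree import Affection, Individual, Pedigree, Sex
from autozyg.simulate import PlantSpec, SimulationScenario, simulate_cohort


def make_individual(iid, fam="F1", father=None, mother=None,
                    sex=Sex.UNKNOWN, affected=Affection.UNKNOWN):
    return Individual(id=iid, family_id=fam, father_id=father,
                      mother_id=mother, sex=sex, affected=affected)


def trio_pedigree(affected=Affection.AFFECTED):
    return Pedigree.from_individuals([
        make_individual("fa", sex=Sex.MALE, affected=Affection.UNAFFECTED),
        make_individual("mo", sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        make_individual("c1", father="fa", mother="mo", sex=Sex.MALE,
                        affected=affected),
    ])


def first_cousin_pedigree(n_affected=2, n_unaffected=1):
    from autozyg.simulate import pedigree_from_template
    return pedigree_from_template("first_cousin", "F1", n_affected,
                                  n_unaffected)


def random_layered_pedigree(rng: np.random.Generator, n_founders=4,
                            n_generations=3, children_per_gen=3) -> Pedigree:
    """Random acyclic pedigree for property tests."""
    inds = [make_individual(f"f{i}",
                            sex=Sex.MALE if i % 2 == 0 else Sex.FEMALE)
            for i in range(n_founders)]
    males = [i.id for i in inds if i.sex is Sex.MALE]
    females = [i.id for i in inds if i.sex is Sex.FEMALE]
    counter = 0
    for _ in range(n_generations):
        new_m, new_f = [], []
        for _ in range(children_per_gen):
            fa = males[rng.integers(len(males))]
            mo = females[rng.integers(len(females))]
            sex = Sex.MALE if rng.integers(2) == 0 else Sex.FEMALE
            iid = f"c{counter}"
            counter += 1
            inds.append(make_individual(iid, father=fa, mother=mo, sex=sex))
            (new_m if sex is Sex.MALE else new_f).append(iid)
        males = males + new_m
        females = females + new_f
    return Pedigree.from_individuals(inds)


@pytest.fixture(scope="session")
def recessive_sim():
    """Small noisy first-cousin cohort with planted recessive variants."""
    scenario = SimulationScenario(
        n_families=6, planted=PlantSpec(causal_model="hom_recessive_in_roh"),
        seed=0)
    return simulate_cohort(scenario)


@pytest.fixture(scope="session")
def plain_sim():
    """Cohort without planted variants, used for ROH truth scoring."""
    scenario = SimulationScenario(n_families=8, planted=None, seed=1)
    return simulate_cohort(scenario)
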