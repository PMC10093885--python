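import pytest

from mednova import (
    BrandedFood,
    NutrientPanel,
    default_lexicon,
    default_mappings,
    default_score_tables,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def tables():
    return default_score_tables()


@pytest.fixture(scope="session")
def mappings():
    return default_mappings()


@pytest.fixture
def egg_food():
    """A single ultra-processed egg product built from its printed label."""
    return BrandedFood(
        id="egg-upf",
        name="liquid egg white",
        subcategory="Fresh or Processed Egg",
        basis="solid",
        ingredient_text="pasteurised egg white, preservative: sodium benzoate",
        panel=NutrientPanel(
            energy_kcal=46,
            protein_g=11.0,
            total_fat_g=0.3,
            sfa_g=0.0,
            sugars_g=0.3,
            salt_g=0.44,
        ),
    )


def make_food(
    id="f1",
    subcategory="Vegetable",
    basis="solid",
    ingredient_text="tomatoes",
    panel=None,
    **kwargs,
):
    return BrandedFood(
        id=id,
        name=id,
        subcategory=subcategory,
        basis=basis,
        ingredient_text=ingredient_text,
        panel=panel or NutrientPanel(),
        **kwargs,
    )
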