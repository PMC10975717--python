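import pytest

from nutriprofiler.catalog import (
    Category,
    MeatClass,
    NutrientProfile,
    ProductRecord,
    TechGroup,
)
from nutriprofiler.market import default_config, generate_market


def make_record(
    product_id="p1",
    category=Category.MEAT_PRODUCT,
    group=TechGroup.SMOKED,
    meat_class=MeatClass.WHITE,
    **profile_fields,
):
    defaults = dict(
        energy_kj=500.0,
        sugars_g=0.5,
        sfa_g=2.0,
        sodium_mg=800.0,
        protein_g=15.0,
        fibre_g=0.0,
        fvl_pct=0.0,
    )
    defaults.update(profile_fields)
    return ProductRecord(
        product_id=product_id,
        name=product_id,
        category=category,
        group=group,
        meat_class=meat_class,
        profile=NutrientProfile(**defaults),
    )


@pytest.fixture(scope="session")
def synthetic_market():
    """One default 1700-product market, shared across the session."""
    return generate_market(default_config(), seed=42)


@pytest.fixture(scope="session")
def small_market():
    """A reduced market (~170 products) for quicker end-to-end checks."""
    import dataclasses

    cfg = default_config()
    groups = tuple(
        dataclasses.replace(g, n=max(3, g.n // 10)) for g in cfg.groups
    )
    cfg = dataclasses.replace(cfg, groups=groups)
    return generate_market(cfg, seed=7)
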