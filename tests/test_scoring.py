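"""Scoring engine: threshold semantics, combination rule, class bands,
variant behaviour, and the published single-product worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriprofiler.catalog import Category, MeatClass, NutrientProfile, TechGroup
from nutriprofiler.scoring import (
    AlgorithmVariant,
    ClassBands,
    ComponentScores,
    ScoreTable,
    ScoringError,
    TableError,
    assign_class,
    combine_score,
    component_points,
    default_tables,
    load_score_tables,
    nutriscore,
    score_components,
    sodium_from_salt,
)
from .conftest import make_record

TABLES = default_tables()


# --------------------------------------------------------------- conversion

@pytest.mark.parametrize("salt,sodium", [(2.0, 800.0), (0.0, 0.0), (2.5, 1000.0), (1.9, 760.0)])
def test_sodium_from_salt(salt, sodium):
    assert sodium_from_salt(salt) == pytest.approx(sodium)


def test_sodium_from_salt_rejects_negative():
    with pytest.raises(ScoringError):
        sodium_from_salt(-0.1)


# ---------------------------------------------------------- component points

def linear_scan_points(value, table):
    """Independent oracle: walk the rows, keep the last strictly exceeded."""
    points = 0
    for bound, pts in table.thresholds:
        if value > bound:
            points = pts
    return points


def _component_grid(table):
    """Dense grid: all bounds, bounds +- epsilon, midpoints, and extremes."""
    bounds = np.array(table.bounds, dtype=float)
    eps = np.maximum(1e-9, np.abs(bounds) * 1e-12)
    grid = np.concatenate(
        [bounds, bounds - eps, bounds + eps, (bounds[:-1] + bounds[1:]) / 2,
         [0.0, bounds[-1] * 2], np.linspace(0, bounds[-1] * 1.1, 211)]
    )
    return grid[grid >= 0]


@pytest.mark.parametrize(
    "name",
    ["energy", "sugars", "sfa", "sodium", "fvl", "fibre", "protein_white", "protein_red"],
)
def test_component_points_matches_linear_scan_oracle(name):
    table = getattr(TABLES, name)
    for value in _component_grid(table):
        assert component_points(value, table) == linear_scan_points(value, table), (
            name,
            value,
        )


@pytest.mark.parametrize(
    "value,table_name,expected",
    [
        (346, "energy", 1),     # published class-A smoked poultry product
        (335, "energy", 0),     # boundary takes the lower score
        (311, "energy", 0),
        (1474, "energy", 4),
        (760, "sodium", 8),
        (600, "sodium", 6),
        (80, "sodium", 0),
        (11.0, "sfa", 10),
        (0.5, "sfa", 0),
        (13.0, "protein_white", 5),
        (8.2, "protein_white", 5),
        (8.0, "protein_white", 4),  # boundary
        (20.0, "protein_red", 2),
        (2.4, "protein_red", 0),
        (0.5, "fibre", 0),
        (0.9, "fibre", 0),
        (31.5, "sugars", 7),    # the non-uniform step above 31
        (45.0, "sugars", 9),
        (100.0, "fvl", 5),
        (70.0, "fvl", 2),
    ],
)
def test_component_points_threshold_lookups(value, table_name, expected):
    assert component_points(value, getattr(TABLES, table_name)) == expected


def test_fvl_points_attainable_set_has_no_3_or_4():
    attainable = {component_points(v, TABLES.fvl) for v in np.linspace(0, 100, 2001)}
    assert attainable == {0, 1, 2, 5}


def test_component_points_rejects_negative_value():
    with pytest.raises(ScoringError):
        component_points(-1.0, TABLES.energy)


def test_invalid_tables_are_refused():
    with pytest.raises(TableError):
        ScoreTable("x", ((2.0, 1), (1.0, 2)), max_points=2)  # bounds not increasing
    with pytest.raises(TableError):
        ScoreTable("x", ((1.0, 2), (2.0, 1)), max_points=2)  # points decreasing
    with pytest.raises(TableError):
        ScoreTable("x", ((1.0, 1), (2.0, 2)), max_points=5)  # max not reached


def test_bundled_table_file_loads_and_validates():
    tables = load_score_tables()
    assert tables.energy.max_points == 10
    assert tables.protein_red.max_points == 2
    assert tables.fvl.thresholds == ((40.0, 1), (60.0, 2), (80.0, 5))


# ------------------------------------------------------------ score_components

def test_score_components_worked_example_class_a():
    profile = NutrientProfile(
        energy_kj=346, sugars_g=0.1, sfa_g=1.1, sodium_mg=80,
        protein_g=13.0, fibre_g=0.0, fvl_pct=0.0,
    )
    c = score_components(profile, MeatClass.WHITE, AlgorithmVariant.REFINED)
    assert (c.energy_pts, c.sugars_pts, c.sfa_pts, c.sodium_pts) == (1, 0, 1, 0)
    assert (c.fvl_pts, c.fibre_pts, c.protein_pts) == (0, 0, 5)
    assert c.n_total == 2 and c.p_total == 5


@pytest.mark.parametrize(
    "meat_class,variant,expected_protein",
    [
        (MeatClass.RED, AlgorithmVariant.REFINED, 2),
        (MeatClass.RED, AlgorithmVariant.ORIGINAL, 5),
        (MeatClass.WHITE, AlgorithmVariant.REFINED, 5),
        (MeatClass.WHITE, AlgorithmVariant.ORIGINAL, 5),
    ],
)
def test_protein_table_selection(meat_class, variant, expected_protein):
    profile = NutrientProfile(
        energy_kj=500, sugars_g=0.5, sfa_g=2.0, sodium_mg=800,
        protein_g=20.0, fibre_g=0.0,
    )
    assert score_components(profile, meat_class, variant).protein_pts == expected_protein


def test_missing_fvl_scored_as_zero_pct():
    profile = NutrientProfile(
        energy_kj=500, sugars_g=0.5, sfa_g=2.0, sodium_mg=800,
        protein_g=20.0, fibre_g=0.0, fvl_pct=None,
    )
    assert score_components(profile, MeatClass.WHITE).fvl_pts == 0


def test_unresolvable_sodium_raises():
    profile = NutrientProfile(
        energy_kj=500, sugars_g=0.5, sfa_g=2.0, protein_g=20.0, fibre_g=0.0
    )
    with pytest.raises(ScoringError, match="sodium"):
        score_components(profile, MeatClass.WHITE)


# -------------------------------------------------------------- combine_score

def _cs(energy=0, sugars=0, sfa=0, sodium=0, fvl=0, fibre=0, protein=0):
    return ComponentScores(energy, sugars, sfa, sodium, fvl, fibre, protein)


@pytest.mark.parametrize(
    "components,total,counted",
    [
        (_cs(energy=1, sfa=1, protein=5), -3, True),           # N=2 < 11
        (_cs(sodium=10, energy=1, protein=5), 11, False),      # N=11, fvl<5
        (_cs(sodium=10, energy=1, fvl=5, fibre=2, protein=5), -1, True),  # fvl=5 branch
        (_cs(sodium=10, energy=1, fvl=2, fibre=1, protein=5), 8, False),  # only fvl+fibre subtracted
        (_cs(), 0, True),
    ],
)
def test_combine_score_branches(components, total, counted):
    assert combine_score(components) == (total, counted)


# --------------------------------------------------------------- class bands

@pytest.mark.parametrize(
    "total,letter",
    [(-15, "A"), (-3, "A"), (-1, "A"), (0, "B"), (2, "B"), (3, "C"),
     (10, "C"), (11, "D"), (18, "D"), (19, "E"), (40, "E")],
)
def test_class_band_edges(total, letter):
    assert assign_class(total) == letter


def test_every_integer_total_maps_to_exactly_one_letter():
    letters = [assign_class(t) for t in range(-15, 41)]
    assert "".join(sorted(set(letters))) == "ABCDE"
    # bands are contiguous runs A..E
    assert letters == sorted(letters)


def test_bands_refuse_gaps():
    with pytest.raises(TableError):
        ClassBands(bands=((float("-inf"), -1, "A"), (1, 2, "B"), (3, 10, "C"),
                          (11, 18, "D"), (19, float("inf"), "E")))


# ------------------------------------------------------ full worked examples

WORKED_EXAMPLES = [
    # (profile fields, group, meat class, expected total, expected letter)
    (dict(energy_kj=346, sugars_g=0.1, sfa_g=1.1, sodium_mg=80, protein_g=13.0,
          fibre_g=0.0), TechGroup.SMOKED, MeatClass.WHITE, -3, "A"),
    (dict(energy_kj=481, sugars_g=0.0, sfa_g=0.5, sodium_mg=600, protein_g=25.0,
          fibre_g=0.0), TechGroup.SMOKED, MeatClass.WHITE, 2, "B"),
    (dict(energy_kj=311, sugars_g=0.8, sfa_g=1.4, sodium_mg=600, protein_g=8.2,
          fibre_g=0.5), TechGroup.OTHER, MeatClass.WHITE, 2, "B"),
    # median-valued red-meat profile of the class-C smoked red meats group
    (dict(energy_kj=478, sugars_g=0.6, sfa_g=1.1, sodium_mg=760, protein_g=20.0,
          fibre_g=0.0), TechGroup.SMOKED, MeatClass.RED, 8, "C"),
]


@pytest.mark.parametrize("fields,group,meat_class,total,letter", WORKED_EXAMPLES)
def test_published_single_product_scores(fields, group, meat_class, total, letter):
    record = make_record(group=group, meat_class=meat_class, fvl_pct=0.0, **fields)
    result = nutriscore(record, AlgorithmVariant.REFINED)
    assert result.total == total
    assert result.letter == letter


def test_nutriscore_error_carries_product_id():
    record = make_record(product_id="broken", fibre_g=None)
    with pytest.raises(ScoringError, match="broken"):
        nutriscore(record)


# ------------------------------------------------------------ property tests

profile_strategy = st.builds(
    NutrientProfile,
    energy_kj=st.floats(0, 4000),
    sugars_g=st.floats(0, 60),
    sfa_g=st.floats(0, 30),
    sodium_mg=st.floats(0, 2500),
    protein_g=st.floats(0, 40),
    fibre_g=st.floats(0, 8),
    fvl_pct=st.floats(0, 100),
)


def _total(profile, meat_class=MeatClass.WHITE, variant=AlgorithmVariant.REFINED):
    return combine_score(score_components(profile, meat_class, variant))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(profile=profile_strategy, bump=st.floats(0.1, 500))
def test_total_monotone_in_unfavourable_components(profile, bump):
    from dataclasses import replace

    base, _ = _total(profile)
    for f, scale in [("energy_kj", 1.0), ("sugars_g", 0.05), ("sfa_g", 0.02),
                     ("sodium_mg", 1.0)]:
        worse = replace(profile, **{f: getattr(profile, f) + bump * scale})
        assert _total(worse)[0] >= base


@settings(max_examples=300, deadline=None, derandomize=True)
@given(profile=profile_strategy, bump=st.floats(0.1, 100))
def test_total_never_increases_in_fibre_and_fvl(profile, bump):
    from dataclasses import replace

    base, _ = _total(profile)
    more_fibre = replace(profile, fibre_g=profile.fibre_g + bump * 0.05)
    more_fvl = replace(profile, fvl_pct=min(100.0, profile.fvl_pct + bump))
    assert _total(more_fibre)[0] <= base
    assert _total(more_fvl)[0] <= base


@settings(max_examples=300, deadline=None, derandomize=True)
@given(profile=profile_strategy)
def test_ranges_and_idempotence(profile):
    c = score_components(profile, MeatClass.RED, AlgorithmVariant.REFINED)
    assert 0 <= c.n_total <= 40
    assert 0 <= c.p_total <= 15
    total, _ = combine_score(c)
    assert -15 <= total <= 40
    assert assign_class(total) in "ABCDE"
    # pure function: identical on repeat
    assert score_components(profile, MeatClass.RED, AlgorithmVariant.REFINED) == c


@settings(max_examples=300, deadline=None, derandomize=True)
@given(profile=profile_strategy)
def test_variant_delta_property(profile):
    """White meat: variants identical. Red meat: refined >= original, the
    difference at most 3 and positive only when protein counts and clears
    the first white-table threshold (1.6 g), where the two tables diverge."""
    w_orig, _ = _total(profile, MeatClass.WHITE, AlgorithmVariant.ORIGINAL)
    w_refi, _ = _total(profile, MeatClass.WHITE, AlgorithmVariant.REFINED)
    assert w_orig == w_refi
    r_orig, counted_o = _total(profile, MeatClass.RED, AlgorithmVariant.ORIGINAL)
    r_refi, counted_r = _total(profile, MeatClass.RED, AlgorithmVariant.REFINED)
    assert counted_o == counted_r
    delta = r_refi - r_orig
    assert delta in {0, 1, 2, 3}
    if delta > 0:
        assert counted_r and profile.protein_g > 1.6
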