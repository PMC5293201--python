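"""GF(3) polynomials: interpolation, gate polynomials, continuity, reduction."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ferronet import (
    GF3Polynomial,
    Literal,
    Max,
    Min,
    NOT,
    STAR_IRP1_INH,
    apply_continuity,
    continuity_step,
    eval_expression,
    from_expression,
    interpolate,
    tabulate,
    transform_polynomial,
)
from ferronet.ternary import expression_species

LEVELS = (0, 1, 2)


# -- interpolation ------------------------------------------------------

def test_interpolating_not_table_gives_2_plus_2x():
    poly = interpolate({(0,): 2, (1,): 1, (2,): 0}, [0])
    assert poly == GF3Polynomial({(): 2, ((0, 1),): 2})


def test_interpolating_identity_gives_x():
    poly = interpolate({(0,): 0, (1,): 1, (2,): 2}, [0])
    assert poly == GF3Polynomial.variable(0)


def test_interpolate_rejects_incomplete_table():
    with pytest.raises(ValueError, match="incomplete"):
        interpolate({(0,): 0, (1,): 1}, [0])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 2), min_size=9, max_size=9))
def test_interpolation_matches_any_two_input_table(values):
    """Random functions {0,1,2}^2 -> {0,1,2}: the interpolated polynomial
    reproduces the table at all nine points (brute-force oracle)."""
    points = list(itertools.product(LEVELS, repeat=2))
    table = dict(zip(points, values))
    poly = interpolate(table, [0, 1])
    for c in points:
        assert poly.evaluate({0: c[0], 1: c[1]}) == table[c]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.dictionaries(
    keys=st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)),
    values=st.integers(1, 2),
    max_size=8,
))
def test_interpolate_tabulate_round_trip(monomials):
    """interpolate(tabulate(p)) returns p itself for canonical polynomials
    in up to three variables (uniqueness of the reduced representation)."""
    key_coeffs = {}
    for exps, coeff in monomials.items():
        key = tuple((v, e) for v, e in enumerate(exps) if e > 0)
        key_coeffs[key] = coeff
    poly = GF3Polynomial(key_coeffs)
    assert interpolate(tabulate(poly, [0, 1, 2]), [0, 1, 2]) == poly


def test_exponent_reduction_is_sound():
    """x^3 and x evaluate identically on the field, and x^3 reduces to x."""
    x = GF3Polynomial.variable(0)
    cubed = x * x * x
    assert cubed == x
    for v in LEVELS:
        assert cubed.evaluate({0: v}) == v


# -- expression trees -> polynomials -----------------------------------

MAX_POLY = GF3Polynomial(
    {
        ((0, 2), (1, 2)): 1,
        ((0, 2), (1, 1)): 1,
        ((0, 1), (1, 2)): 1,
        ((0, 1), (1, 1)): 2,
        ((0, 1),): 1,
        ((1, 1),): 1,
    }
)

MIN_POLY = GF3Polynomial(
    {
        ((0, 2), (1, 2)): 2,
        ((0, 2), (1, 1)): 2,
        ((0, 1), (1, 2)): 2,
        ((0, 1), (1, 1)): 1,
    }
)


def test_max_gate_polynomial():
    poly = from_expression(Max(Literal("x"), Literal("y")), {"x": 0, "y": 1})
    assert poly == MAX_POLY
    assert poly.evaluate({0: 1, 1: 2}) == 2


def test_min_gate_polynomial():
    poly = from_expression(Min(Literal("x"), Literal("y")), {"x": 0, "y": 1})
    assert poly == MIN_POLY


def test_gate_polynomials_agree_with_gate_semantics_everywhere():
    for x, y in itertools.product(LEVELS, repeat=2):
        assert MAX_POLY.evaluate({0: x, 1: y}) == max(x, y)
        assert MIN_POLY.evaluate({0: x, 1: y}) == min(x, y)


def test_partial_inhibition_transform_polynomial():
    poly = transform_polynomial(STAR_IRP1_INH, 0)
    assert poly == GF3Polynomial({(): 2, ((0, 2),): 2})  # 2 + 2x^2


def test_ferritin_rule_polynomial_and_rendering(iron_model):
    """The raw Ft rule polynomial in the bundled variable order."""
    index_of = {n: i for i, n in enumerate(iron_model.species_names)}
    poly = from_expression(iron_model.rules["Ft"], index_of)
    assert str(poly) == "x5^2*x6^2 + 2*x5^2 + 2*x6 + 2"


#: Continuity-adjusted ferritin update f4 over (x4, x5, x6) =
#: (Ft, IRP1, IRP2), 0-based variable indices 3, 4, 5.
F4 = GF3Polynomial(
    {
        (): 1,
        ((3, 2),): 1,
        ((3, 2), (4, 2)): 2,
        ((5, 1),): 2,
        ((3, 1), (5, 1)): 1,
        ((3, 2), (5, 1)): 2,
        ((5, 2),): 1,
        ((3, 1), (5, 2)): 2,
        ((3, 2), (4, 2), (5, 2)): 1,
    }
)


def test_continuity_adjusted_ferritin_polynomial(iron_model):
    index_of = {n: i for i, n in enumerate(iron_model.species_names)}
    raw = from_expression(iron_model.rules["Ft"], index_of)
    f4 = apply_continuity(raw, index_of["Ft"])
    assert f4 == F4
    # spot values: high Ft with both IRPs active steps down one level;
    # empty Ft with inactive IRPs steps up one level toward induction
    assert f4.evaluate({3: 2, 4: 2, 5: 2}) == 1
    assert f4.evaluate({3: 0, 4: 0, 5: 0}) == 1


def test_continuity_of_self_constant_rule_is_identity():
    """h(x, x) = x: a rule that already outputs the current level."""
    poly = apply_continuity(GF3Polynomial.variable(0), 0)
    assert poly == GF3Polynomial.variable(0)


def test_continuity_step_moves_one_level():
    assert continuity_step(2, 0) == 1
    assert continuity_step(0, 2) == 1
    assert continuity_step(1, 1) == 1
    assert continuity_step(1, 2) == 2


def test_zero_polynomial_evaluates_to_zero():
    assert GF3Polynomial.zero().evaluate({0: 2, 1: 1}) == 0


# -- dual-route equivalence on the bundled model ------------------------

def test_every_bundled_rule_polynomial_matches_gate_semantics(iron_model):
    """For each of the 24 rules, the interpolated/composed polynomial and
    direct gate evaluation agree on every assignment of the rule's inputs."""
    index_of = {n: i for i, n in enumerate(iron_model.species_names)}
    for name in iron_model.species_names:
        rule = iron_model.rules[name]
        inputs = sorted(expression_species(rule))
        poly = from_expression(rule, index_of)
        for combo in itertools.product(LEVELS, repeat=len(inputs)):
            named = dict(zip(inputs, combo))
            indexed = {index_of[s]: v for s, v in named.items()}
            assert poly.evaluate(indexed) == eval_expression(rule, named), name


def test_continuity_polynomials_move_at_most_one_level(iron_model):
    """|h(x_i, f) - x_i| <= 1 on every assignment, for each non-exempt rule."""
    index_of = {n: i for i, n in enumerate(iron_model.species_names)}
    for name in iron_model.species_names:
        if iron_model.continuity.is_exempt(name):
            continue
        raw = from_expression(iron_model.rules[name], index_of)
        poly = apply_continuity(raw, index_of[name])
        variables = sorted(poly.variables() | {index_of[name]})
        tpos = variables.index(index_of[name])
        for combo in itertools.product(LEVELS, repeat=len(variables)):
            out = poly.evaluate(dict(zip(variables, combo)))
            assert abs(out - combo[tpos]) <= 1, name
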