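"""Synchronous stepping, attractor discovery, basin statistics."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ferronet import (
    CompiledModel,
    ContinuityPolicy,
    FixtureSpec,
    Literal,
    Model,
    Species,
    attractors_of_states,
    basin_summary,
    decode_state,
    encode_state,
    exhaustive_attractors,
    export_pds,
    merge_attractor_sets,
    random_model,
    run_to_attractor,
    sample_attractors,
    step,
    step_poly,
    verify_closure,
)
from ferronet.dynamics import decode_batch, encode_batch
from ferronet.ternary import NOT


def _mutual_not_model() -> Model:
    """Two species inverting each other, no continuity."""
    return Model(
        species=(Species("A", 1), Species("B", 2)),
        rules={"A": Literal("B", NOT), "B": Literal("A", NOT)},
        continuity=ContinuityPolicy(frozenset({"A", "B"})),
        name="mutual_not",
    )


# -- state codes --------------------------------------------------------

@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 3**24 - 1))
def test_state_code_round_trip(code):
    assert encode_state(decode_state(code, 24)) == code


def test_first_species_is_most_significant_digit():
    assert decode_state(2 * 3**23, 24)[0] == 2
    assert decode_state(1, 24)[-1] == 1


def test_batch_codecs_match_scalar():
    codes = np.array([0, 1, 5, 3**10, 3**24 - 1], dtype=np.int64)
    states = decode_batch(codes, 24)
    for c, s in zip(codes, states):
        assert tuple(s) == decode_state(int(c), 24)
    assert np.array_equal(encode_batch(states), codes)


# -- single-step semantics ----------------------------------------------

def test_all_normal_state_is_fixed(iron_model):
    ones = (1,) * 24
    assert step(iron_model, ones) == ones


def test_heme_jumps_without_continuity(iron_model):
    """heme is a pool: with high ALAS1 and low HO-1 it goes straight to 2
    regardless of its current level."""
    heme_i = iron_model.index_of("heme")
    base = [1] * 24
    base[iron_model.index_of("ALAS1")] = 2
    base[iron_model.index_of("HO1")] = 0
    for heme_now in (0, 1, 2):
        state = list(base)
        state[heme_i] = heme_now
        assert step(iron_model, state)[heme_i] == 2


def test_ferritin_steps_down_one_level_under_full_repression(iron_model):
    """Ft=2 with both IRPs active: raw output 0, continuity gives 1."""
    state = [1] * 24
    state[iron_model.index_of("Ft")] = 2
    state[iron_model.index_of("IRP1")] = 2
    state[iron_model.index_of("IRP2")] = 2
    assert step(iron_model, state)[iron_model.index_of("Ft")] == 1


def test_compiled_engine_matches_reference_step(iron_model, iron_compiled):
    rng = random.Random(3)
    for _ in range(300):
        state = tuple(rng.randrange(3) for _ in range(24))
        assert iron_compiled.step_state(state) == step(iron_model, state)


def test_batch_step_matches_scalar_step(iron_compiled):
    rng = np.random.default_rng(4)
    states = rng.integers(0, 3, size=(500, 24)).astype(np.uint8)
    batched = iron_compiled.step_batch(states)
    for s_in, s_out in zip(states, batched):
        assert tuple(int(v) for v in s_out) == iron_compiled.step_state(tuple(int(v) for v in s_in))


def test_polynomial_dynamics_agree_with_gate_dynamics(iron_model):
    """The PDS view (continuity-adjusted GF(3) polynomials) steps exactly
    like the logic-tree semantics."""
    pds = export_pds(iron_model)
    rng = random.Random(7)
    for _ in range(100):
        state = tuple(rng.randrange(3) for _ in range(24))
        assert step_poly(iron_model, state, pds) == step(iron_model, state)


def test_polynomial_dynamics_agree_on_random_small_models():
    for seed in range(5):
        model = random_model(FixtureSpec(n_species=3, seed=seed))
        pds = export_pds(model)
        for code in range(27):
            state = decode_state(code, 3)
            assert step_poly(model, state, pds) == step(model, state)


def test_continuity_bound_along_trajectories(iron_model, iron_compiled):
    """Non-pool species move at most one level per step (10,000 random
    transitions)."""
    rng = np.random.default_rng(8)
    states = rng.integers(0, 3, size=(10_000, 24)).astype(np.uint8)
    nxt = iron_compiled.step_batch(states)
    exempt = [iron_model.index_of(n) for n in iron_model.continuity.exempt_species]
    bounded = np.delete(
        np.abs(nxt.astype(int) - states.astype(int)), exempt, axis=1
    )
    assert bounded.max() <= 1


# -- trajectories and attractors ----------------------------------------

def test_normal_model_reaches_homeostasis_from_anywhere(iron_model, iron_compiled):
    ones = (1,) * 24
    rng = random.Random(2017)
    for _ in range(1000):
        state = tuple(rng.randrange(3) for _ in range(24))
        attractor, _ = run_to_attractor(iron_compiled, state)
        assert attractor.states == (ones,)


def test_transient_length_zero_on_a_fixed_point(iron_model):
    attractor, transient = run_to_attractor(iron_model, (1,) * 24)
    assert transient == 0
    assert attractor.kind == "point"


def test_mutual_not_toy_cycles_from_the_origin():
    model = _mutual_not_model()
    attractor, transient = run_to_attractor(model, (0, 0))
    assert attractor.kind == "cycle"
    assert attractor.period == 2
    assert attractor.states == ((0, 0), (2, 2)) or attractor.states == ((0, 2), (2, 0))
    assert transient == 0


def test_mutual_not_full_transition_table():
    """All 9 states of the two-species inverter, against the hand table:
    (a,b) -> (2-b, 2-a)."""
    model = _mutual_not_model()
    cm = CompiledModel(model)
    for a, b in itertools.product((0, 1, 2), repeat=2):
        assert cm.step_state((a, b)) == (2 - b, 2 - a)


def test_exhaustive_basins_partition_the_state_space(toys):
    for toy in toys.values():
        aset = exhaustive_attractors(toy.model)
        total = sum(a.basin_count for a in aset.attractors)
        assert total == toy.model.n_states


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_exhaustive_partition_on_random_fixtures(seed):
    model = random_model(FixtureSpec(n_species=4 + seed, seed=100 + seed))
    aset = exhaustive_attractors(model)
    assert sum(a.basin_count for a in aset.attractors) == model.n_states
    for a in aset.attractors:
        assert verify_closure(model, a)


def test_chunked_enumeration_merges_to_the_monolithic_result(toys):
    """Exhaustive over [0, 3^N) equals the merge over any partition."""
    for toy in toys.values():
        full = exhaustive_attractors(toy.model)
        n = toy.model.n_states
        cuts = [0, n // 3, n // 2, n]
        parts = [
            exhaustive_attractors(toy.model, (cuts[i], cuts[i + 1]))
            for i in range(len(cuts) - 1)
        ]
        merged = merge_attractor_sets(parts)
        assert {a.key: a.basin_count for a in merged.attractors} == {
            a.key: a.basin_count for a in full.attractors
        }
        assert merged.total_states_examined == full.total_states_examined


def test_iron_model_slice_enumeration_partitions(iron_model):
    """243 initial states (five core iron species free, everything else at
    normal) partition among the reachable attractors."""
    free = ["LIP", "TfR1", "Fpn", "Ft", "IRP1"]
    idx = [iron_model.index_of(n) for n in free]
    states = []
    for combo in itertools.product((0, 1, 2), repeat=5):
        s = [1] * 24
        for i, v in zip(idx, combo):
            s[i] = v
        states.append(tuple(s))
    aset = attractors_of_states(iron_model, states)
    assert sum(a.basin_count for a in aset.attractors) == 243
    # the normal network is monostable: everything returns to homeostasis
    assert aset.n_attractors == 1
    assert aset.attractors[0].states == ((1,) * 24,)


def test_sampling_finds_the_exhaustive_attractor_set_on_toys(toys):
    """On small models, 10,000 samples find every attractor and estimate
    each basin fraction within 4 binomial standard errors of exact."""
    for toy in toys.values():
        exact = exhaustive_attractors(toy.model)
        sampled = sample_attractors(toy.model, n_samples=10_000, seed=42)
        assert {a.key for a in sampled.attractors} == {a.key for a in exact.attractors}
        exact_frac = {
            a.key: a.basin_count / toy.model.n_states for a in exact.attractors
        }
        for a in sampled.attractors:
            assert abs(a.basin_fraction - exact_frac[a.key]) <= 4 * a.basin_se + 1e-12


def test_sampling_is_deterministic_given_seed(toys):
    model = next(iter(toys.values())).model
    a = sample_attractors(model, n_samples=5000, seed=7)
    b = sample_attractors(model, n_samples=5000, seed=7)
    assert a == b


def test_sampled_fractions_sum_to_one(iron_model):
    aset = sample_attractors(iron_model, n_samples=2000, seed=1)
    assert sum(a.basin_fraction for a in aset.attractors) == pytest.approx(1.0)


def test_attractor_closure_of_sampled_cycles(iron_model):
    from ferronet import apply_perturbations, overexpress

    model = apply_perturbations(iron_model, [overexpress("Ras")])
    aset = sample_attractors(model, n_samples=2000, seed=3)
    cm = CompiledModel(model)
    for a in aset.attractors:
        assert verify_closure(cm, a)
        assert len(set(a.states)) == a.period  # all cycle states distinct
        assert a.key[0] == min(a.key)  # canonical rotation


def test_basin_summary_table(toys):
    toy = toys["mutual_activation"]
    aset = exhaustive_attractors(toy.model)
    df = basin_summary(aset)
    assert df["basin_count"].sum() == 9
    assert df["basin_fraction"].sum() == pytest.approx(1.0)
    assert set(df["kind"]) == {"point", "cycle"}


def test_exhaustive_range_validation(toys):
    model = next(iter(toys.values())).model
    with pytest.raises(ValueError):
        exhaustive_attractors(model, (0, model.n_states + 1))
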