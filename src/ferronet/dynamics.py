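"""Synchronous state-transition engine and attractor/basin analysis.

All species update simultaneously from the previous state.  Non-exempt
species move at most one level per step toward their raw rule output
(continuity); exempt species jump straight to the rule output.  Under
this deterministic scheme every trajectory ends in a point attractor
(fixed state) or a cycle attractor, and the basins of attraction
partition the 3^N state space.

Attractor discovery comes in two flavours mirroring how such systems
are analysed in practice: seeded uniform random sampling of initial
states (fast, estimates basin fractions with binomial standard errors)
and exhaustive enumeration over a contiguous range of base-3 state
codes (exact counts; ranges merge associatively so a full enumeration
can be chunked across processes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gf3 import GF3Polynomial, apply_continuity, continuity_step, from_expression
from .model import Model
from .ternary import Constant, eval_expression, expression_species

StateTuple = tuple[int, ...]


# ---------------------------------------------------------------------
# State codes (base-3 integers, species index 1 = most significant digit)
# ---------------------------------------------------------------------

def encode_state(state: Sequence[int], n_species: int | None = None) -> int:
    code = 0
    for v in state:
        code = code * 3 + int(v)
    return code


def decode_state(code: int, n_species: int) -> StateTuple:
    if not 0 <= code < 3**n_species:
        raise ValueError(f"state code {code} outside [0, 3^{n_species})")
    digits = []
    for _ in range(n_species):
        code, d = divmod(code, 3)
        digits.append(d)
    return tuple(reversed(digits))


def decode_batch(codes: np.ndarray, n_species: int) -> np.ndarray:
    """Decode an int64 array of codes into a (n, N) uint8 digit matrix."""
    out = np.empty((codes.shape[0], n_species), dtype=np.uint8)
    rem = codes.astype(np.int64).copy()
    for i in range(n_species - 1, -1, -1):
        out[:, i] = rem % 3
        rem //= 3
    return out


def encode_batch(states: np.ndarray) -> np.ndarray:
    codes = np.zeros(states.shape[0], dtype=np.int64)
    for i in range(states.shape[1]):
        codes = codes * 3 + states[:, i]
    return codes


# ---------------------------------------------------------------------
# Reference step and compiled engine
# ---------------------------------------------------------------------

def step(model: Model, state: Sequence[int]) -> StateTuple:
    """One synchronous update, straight from the expression trees.

    This is the reference semantics; :class:`CompiledModel` is the fast
    path and is tested for agreement with this function.
    """
    names = model.species_names
    if len(state) != len(names):
        raise ValueError(f"state length {len(state)} != species count {len(names)}")
    named = dict(zip(names, state))
    out = []
    for i, name in enumerate(names):
        raw = eval_expression(model.rules[name], named)
        if model.continuity.is_exempt(name):
            out.append(raw)
        else:
            out.append(continuity_step(state[i], raw))
    return tuple(out)


class CompiledModel:
    """Per-species lookup tables for fast scalar and batch stepping.

    Each species' continuity-adjusted update is tabulated over its own
    inputs (plus itself when continuity applies); tables have at most
    3^6 entries for the bundled network.  Correctness never depends on
    this compilation: tables are filled by the reference semantics.
    """

    def __init__(self, model: Model):
        self.model = model
        self.n = model.n_species
        names = model.species_names
        self._vars: list[list[int]] = []
        self._tables: list[np.ndarray] = []
        for j, name in enumerate(names):
            rule = model.rules[name]
            inputs = sorted(model.index_of(s) for s in expression_species(rule))
            exempt = model.continuity.is_exempt(name)
            vars_j = inputs if exempt else sorted(set(inputs) | {j})
            table = np.empty(3 ** len(vars_j), dtype=np.uint8)
            for combo in itertools.product((0, 1, 2), repeat=len(vars_j)):
                named = {names[v]: val for v, val in zip(vars_j, combo)}
                raw = eval_expression(rule, named)
                if not exempt:
                    raw = continuity_step(combo[vars_j.index(j)], raw)
                idx = 0
                for val in combo:
                    idx = idx * 3 + val
                table[idx] = raw
            self._vars.append(vars_j)
            self._tables.append(table)

    def step_state(self, state: Sequence[int]) -> StateTuple:
        out = []
        for vars_j, table in zip(self._vars, self._tables):
            idx = 0
            for v in vars_j:
                idx = idx * 3 + state[v]
            out.append(int(table[idx]))
        return tuple(out)

    def step_batch(self, states: np.ndarray) -> np.ndarray:
        """Synchronous update of a (n, N) uint8 state matrix."""
        out = np.empty_like(states)
        for j, (vars_j, table) in enumerate(zip(self._vars, self._tables)):
            if not vars_j:
                out[:, j] = table[0]
                continue
            idx = states[:, vars_j[0]].astype(np.int32)
            for v in vars_j[1:]:
                idx *= 3
                idx += states[:, v]
            out[:, j] = table[idx]
        return out


# ---------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A point (single state) or cycle attractor, in canonical rotation.

    The canonical form starts the cycle at the state with the smallest
    base-3 integer code, so attractor identity is comparable across
    runs and discovery modes.
    """

    states: tuple[StateTuple, ...]
    basin_count: int | None = None
    basin_fraction: float | None = None
    basin_se: float | None = None

    @property
    def kind(self) -> str:
        return "point" if len(self.states) == 1 else "cycle"

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(encode_state(s) for s in self.states)

    def value_of(self, model: Model, name: str) -> int | None:
        """The species' level if constant across the attractor, else None."""
        idx = model.index_of(name)
        vals = {s[idx] for s in self.states}
        return vals.pop() if len(vals) == 1 else None


@dataclass(frozen=True)
class AttractorSet:
    attractors: tuple[Attractor, ...]
    total_states_examined: int
    mode: str  # "sampled" | "exhaustive"
    n_species: int
    seed: int | None = None

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def find(self, key: tuple[int, ...]) -> Attractor | None:
        for a in self.attractors:
            if a.key == key:
                return a
        return None

    def points(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "point"]

    def cycles(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "cycle"]


def _canonical_cycle(states: list[StateTuple]) -> tuple[StateTuple, ...]:
    codes = [encode_state(s) for s in states]
    start = codes.index(min(codes))
    return tuple(states[start:] + states[:start])


def _cycle_from(cm: CompiledModel, state: StateTuple) -> tuple[StateTuple, ...]:
    """Enumerate the cycle containing `state` (state must lie on a cycle)."""
    states = [state]
    cur = cm.step_state(state)
    while cur != state:
        states.append(cur)
        cur = cm.step_state(cur)
    return _canonical_cycle(states)


def run_to_attractor(
    model: Model | CompiledModel, initial: Sequence[int]
) -> tuple[Attractor, int]:
    """Iterate from an initial state until a state repeats.

    Returns the canonical attractor and the transient length (steps
    taken before first entering the attractor).
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    state = tuple(int(v) for v in initial)
    visited: dict[StateTuple, int] = {}
    trajectory: list[StateTuple] = []
    while state not in visited:
        visited[state] = len(trajectory)
        trajectory.append(state)
        state = cm.step_state(state)
    entry = visited[state]
    cycle = _canonical_cycle(trajectory[entry:])
    return Attractor(states=cycle), entry


def _sort_attractors(attractors: Iterable[Attractor]) -> tuple[Attractor, ...]:
    return tuple(
        sorted(
            attractors,
            key=lambda a: (
                -(a.basin_count if a.basin_count is not None else 0),
                a.key,
            ),
        )
    )


def sample_attractors(model: Model, n_samples: int, seed: int) -> AttractorSet:
    """Attractor discovery by seeded uniform sampling of initial states.

    Draws ``n_samples`` initial states with replacement, runs each to
    its attractor (vectorised tortoise-hare cycle detection over the
    whole batch), and estimates basin fractions as hit proportions with
    binomial standard errors.  Deterministic given the seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cm = CompiledModel(model)
    rng = np.random.default_rng(seed)
    n_states = model.n_states
    if n_states <= np.iinfo(np.int64).max:
        codes = rng.integers(0, n_states, size=n_samples, dtype=np.int64)
        states = decode_batch(codes, model.n_species)
    else:  # pragma: no cover - > 39 species
        states = rng.integers(0, 3, size=(n_samples, model.n_species)).astype(np.uint8)

    # Floyd cycle detection, vectorised: advance a 1x and a 2x walker per
    # trajectory until they coincide; the meeting state lies on the cycle.
    meet = np.empty_like(states)
    active = np.arange(n_samples)
    slow = cm.step_batch(states)
    fast = cm.step_batch(slow)
    while active.size:
        done = np.all(slow == fast, axis=1)
        if done.any():
            meet[active[done]] = slow[done]
            keep = ~done
            active, slow, fast = active[keep], slow[keep], fast[keep]
            if not active.size:
                break
        slow = cm.step_batch(slow)
        fast = cm.step_batch(cm.step_batch(fast))

    meet_codes = encode_batch(meet)
    unique_codes, counts = np.unique(meet_codes, return_counts=True)
    hits: dict[tuple[int, ...], int] = {}
    for code, count in zip(unique_codes, counts):
        cycle = _cycle_from(cm, decode_state(int(code), model.n_species))
        key = tuple(encode_state(s) for s in cycle)
        if key in hits:
            hits[key] += int(count)
        else:
            hits[key] = int(count)
    attractors = []
    for key, count in hits.items():
        cycle = tuple(decode_state(c, model.n_species) for c in key)
        p = count / n_samples
        se = float(np.sqrt(p * (1.0 - p) / n_samples))
        attractors.append(
            Attractor(states=cycle, basin_count=count, basin_fraction=p, basin_se=se)
        )
    return AttractorSet(
        attractors=_sort_attractors(attractors),
        total_states_examined=n_samples,
        mode="sampled",
        n_species=model.n_species,
        seed=seed,
    )


def exhaustive_attractors(
    model: Model,
    state_range: tuple[int, int] | None = None,
) -> AttractorSet:
    """Exact basin counts over a contiguous range of state codes.

    With the default full range, basin counts partition the 3^N state
    space.  Restricted ranges count only initial states inside the
    range (trajectories may leave it); partial results over a partition
    of the full range merge to the monolithic result.
    """
    cm = CompiledModel(model)
    n = model.n_species
    full = (0, model.n_states)
    start, end = state_range if state_range is not None else full
    if not (0 <= start <= end <= model.n_states):
        raise ValueError(f"range [{start}, {end}) outside [0, {model.n_states})")
    memo: dict[int, int] = {}  # state code -> attractor id
    keys: list[tuple[int, ...]] = []
    key_to_id: dict[tuple[int, ...], int] = {}
    basin: dict[int, int] = {}
    for code in range(start, end):
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = code
        state = decode_state(cur, n)
        while cur not in memo and cur not in pos:
            pos[cur] = len(path)
            path.append(cur)
            state = cm.step_state(state)
            cur = encode_state(state)
        if cur in memo:
            aid = memo[cur]
        else:
            # new cycle discovered along this path
            cycle_states = [decode_state(c, n) for c in path[pos[cur]:]]
            cycle = _canonical_cycle(cycle_states)
            key = tuple(encode_state(s) for s in cycle)
            if key in key_to_id:
                aid = key_to_id[key]
            else:
                aid = len(keys)
                key_to_id[key] = aid
                keys.append(key)
        for c in path:
            memo[c] = aid
        basin[memo[code]] = basin.get(memo[code], 0) + 1
    attractors = []
    for aid, key in enumerate(keys):
        if aid not in basin:
            continue  # attractor never reached from this range
        cycle = tuple(decode_state(c, n) for c in key)
        attractors.append(Attractor(states=cycle, basin_count=basin[aid]))
    return AttractorSet(
        attractors=_sort_attractors(attractors),
        total_states_examined=end - start,
        mode="exhaustive",
        n_species=n,
    )


def attractors_of_states(
    model: Model, initial_states: Iterable[Sequence[int]]
) -> AttractorSet:
    """Exact basin counts over an explicit (possibly non-contiguous) set
    of initial states, e.g. a slice with most species held fixed."""
    cm = CompiledModel(model)
    basin: dict[tuple[int, ...], int] = {}
    total = 0
    for s in initial_states:
        att, _ = run_to_attractor(cm, s)
        basin[att.key] = basin.get(att.key, 0) + 1
        total += 1
    attractors = [
        Attractor(
            states=tuple(decode_state(c, model.n_species) for c in key),
            basin_count=count,
        )
        for key, count in basin.items()
    ]
    return AttractorSet(
        attractors=_sort_attractors(attractors),
        total_states_examined=total,
        mode="exhaustive",
        n_species=model.n_species,
    )


def merge_attractor_sets(sets: Sequence[AttractorSet]) -> AttractorSet:
    """Merge exhaustive partial results from a partition of state codes.

    Associative and order-independent: basin counts for identical
    canonical attractors add, totals add.
    """
    if not sets:
        raise ValueError("nothing to merge")
    if any(s.mode != "exhaustive" for s in sets):
        raise ValueError("only exhaustive attractor sets can be merged")
    n_species = sets[0].n_species
    if any(s.n_species != n_species for s in sets):
        raise ValueError("attractor sets come from models of different size")
    basin: dict[tuple[int, ...], int] = {}
    total = 0
    for s in sets:
        total += s.total_states_examined
        for a in s.attractors:
            basin[a.key] = basin.get(a.key, 0) + (a.basin_count or 0)
    attractors = [
        Attractor(
            states=tuple(decode_state(c, n_species) for c in key),
            basin_count=count,
        )
        for key, count in basin.items()
    ]
    return AttractorSet(
        attractors=_sort_attractors(attractors),
        total_states_examined=total,
        mode="exhaustive",
        n_species=n_species,
    )


def verify_closure(model: Model | CompiledModel, attractor: Attractor) -> bool:
    """Check that stepping each attractor state yields the next one."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    k = attractor.period
    for i, s in enumerate(attractor.states):
        if cm.step_state(s) != attractor.states[(i + 1) % k]:
            return False
    return True


def basin_summary(attractor_set: AttractorSet, total: int | None = None) -> pd.DataFrame:
    """Tabulate attractors: kind, period, basin count/fraction (and SE).

    ``total`` overrides the denominator for fractions (e.g. 3^N when
    summarising a full exhaustive enumeration assembled from chunks).
    """
    denom = total if total is not None else attractor_set.total_states_examined
    rows = []
    for i, a in enumerate(attractor_set.attractors):
        frac = a.basin_fraction
        if frac is None and a.basin_count is not None and denom:
            frac = a.basin_count / denom
        rows.append(
            {
                "attractor": i,
                "kind": a.kind,
                "period": a.period,
                "basin_count": a.basin_count,
                "basin_fraction": frac,
                "basin_se": a.basin_se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Polynomial dynamical system view
# ---------------------------------------------------------------------

def export_pds(model: Model) -> dict[str, GF3Polynomial]:
    """The model as a polynomial dynamical system over GF(3).

    Each species' update is its rule polynomial, wrapped in the
    continuity adjustment unless the species is exempt.  Stepping these
    polynomials (all modulo 3) agrees state-for-state with the gate
    semantics in :func:`step`.
    """
    index_of = {name: i for i, name in enumerate(model.species_names)}
    pds = {}
    for name in model.species_names:
        poly = from_expression(model.rules[name], index_of)
        if not model.continuity.is_exempt(name):
            poly = apply_continuity(poly, index_of[name])
        pds[name] = poly
    return pds


def step_poly(
    model: Model,
    state: Sequence[int],
    pds: Mapping[str, GF3Polynomial] | None = None,
) -> StateTuple:
    """One synchronous update evaluated through the PDS polynomials."""
    if pds is None:
        pds = export_pds(model)
    state = tuple(int(v) for v in state)
    return tuple(pds[name].evaluate(state) for name in model.species_names)
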