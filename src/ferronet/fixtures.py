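"""Random small ternary networks and hand-verified toy models.

These exist so every dynamics and polynomial operation can be tested
against brute-force oracles (exhaustive enumeration over 3^n states,
pointwise truth-table evaluation) without any external data.  The
random fixtures make no claim to biological plausibility.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .dynamics import Attractor
from .gf3 import GF3Polynomial
from .model import ContinuityPolicy, Model, Species
from .ternary import (
    Constant,
    Gate,
    IDENTITY,
    Literal,
    LiteralTransform,
    LogicExpression,
    NOT,
    STAR_IRP1_ACT,
    STAR_IRP1_INH,
    STAR_NRF2,
)

DEFAULT_TRANSFORM_POOL = (IDENTITY, NOT, STAR_IRP1_ACT, STAR_IRP1_INH, STAR_NRF2)


@dataclass(frozen=True)
class FixtureSpec:
    n_species: int
    seed: int
    max_inputs_per_rule: int = 3
    transform_pool: tuple[LiteralTransform, ...] = DEFAULT_TRANSFORM_POOL
    continuity_probability: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.n_species <= 8:
            raise ValueError("fixture models are capped at 8 species")
        if not 1 <= self.max_inputs_per_rule <= 3:
            raise ValueError("max_inputs_per_rule must be in 1..3")


def random_model(spec: FixtureSpec) -> Model:
    """Deterministic random model: depth <= 2 expression per species.

    Uses a private Random instance seeded from the spec; never touches
    the global RNG.
    """
    rng = random.Random(spec.seed)
    names = [f"S{i + 1}" for i in range(spec.n_species)]

    def random_literal() -> Literal:
        return Literal(rng.choice(names), rng.choice(spec.transform_pool))

    def random_rule() -> LogicExpression:
        shape = rng.random()
        if shape < 0.15:
            return Constant(rng.randrange(3))
        if shape < 0.45 or spec.n_species == 1:
            return random_literal()
        kind = rng.choice(("MAX", "MIN"))
        k = rng.randint(2, max(2, spec.max_inputs_per_rule))
        children: list[LogicExpression] = []
        for _ in range(k):
            if rng.random() < 0.2:
                inner_kind = rng.choice(("MAX", "MIN"))
                children.append(
                    Gate(inner_kind, (random_literal(), random_literal()))
                )
            else:
                children.append(random_literal())
        return Gate(kind, tuple(children))

    rules = {name: random_rule() for name in names}
    exempt = frozenset(
        name for name in names if rng.random() < spec.continuity_probability
    )
    species = tuple(Species(name=n, index=i + 1) for i, n in enumerate(names))
    return Model(
        species=species,
        rules=rules,
        continuity=ContinuityPolicy(exempt),
        name=f"random_seed{spec.seed}_n{spec.n_species}",
    )


@dataclass(frozen=True)
class ToyModel:
    """A model with hand-derived ground truth for oracle tests."""

    name: str
    model: Model
    #: full attractor set with exact basin counts, derived by hand from
    #: the complete 3^n transition table; None when the ground truth is
    #: a polynomial rather than a landscape.
    attractors: tuple[Attractor, ...] | None = None
    #: expected continuity-adjusted update polynomials by species name
    expected_polynomials: dict[str, GF3Polynomial] = field(default_factory=dict)


def _model(names, rules, exempt=(), name="toy") -> Model:
    species = tuple(Species(name=n, index=i + 1) for i, n in enumerate(names))
    return Model(
        species=species,
        rules=rules,
        continuity=ContinuityPolicy(frozenset(exempt)),
        name=name,
    )


def toy_catalog() -> list[ToyModel]:
    """Hand-verified toys with known attractor landscapes.

    * ``self_not``: one species inverting itself, continuity-exempt.
      Transition table: 0 -> 2 -> 0, 1 -> 1; so one fixed point {1}
      (basin 1) and one 2-cycle {0, 2} (basin 2).
    * ``mutual_activation``: A = B, B = A with continuity.  Each
      coordinate moves one level toward the other, so the diagonal
      states are fixed ((1,1) also absorbs (0,2) and (2,0)), and the
      off-by-one pairs swap forever: cycles {(0,1),(1,0)} and
      {(1,2),(2,1)}, each with basin 2.
    * ``ferritin_subsystem``: the three-variable ferritin repression
      module (Ft inhibited partially by IRP1 and fully by IRP2, inert
      self-maintaining IRPs), whose continuity-adjusted Ft polynomial
      is known in closed form.
    """
    catalog: list[ToyModel] = []

    self_not = _model(("A",), {"A": Literal("A", NOT)}, exempt=("A",), name="self_not")
    catalog.append(
        ToyModel(
            name="self_not",
            model=self_not,
            attractors=(
                Attractor(states=((0,), (2,)), basin_count=2),
                Attractor(states=((1,),), basin_count=1),
            ),
        )
    )

    mutual = _model(
        ("A", "B"),
        {"A": Literal("B", IDENTITY), "B": Literal("A", IDENTITY)},
        name="mutual_activation",
    )
    catalog.append(
        ToyModel(
            name="mutual_activation",
            model=mutual,
            attractors=(
                Attractor(states=((0, 0),), basin_count=1),
                Attractor(states=((1, 1),), basin_count=3),
                Attractor(states=((2, 2),), basin_count=1),
                Attractor(states=((0, 1), (1, 0)), basin_count=2),
                Attractor(states=((1, 2), (2, 1)), basin_count=2),
            ),
        )
    )

    ft = _model(
        ("Ft", "IRP1", "IRP2"),
        {
            "Ft": Gate("MIN", (Literal("IRP1", STAR_IRP1_INH), Literal("IRP2", NOT))),
            "IRP1": Literal("IRP1", IDENTITY),
            "IRP2": Literal("IRP2", IDENTITY),
        },
        name="ferritin_subsystem",
    )
    # Continuity-adjusted Ft update, variables (x1, x2, x3) = (Ft, IRP1, IRP2):
    # 1 + x1^2 + 2*x1^2*x2^2 + 2*x3 + x1*x3 + 2*x1^2*x3 + x3^2 + 2*x1*x3^2
    #   + x1^2*x2^2*x3^2
    ft_poly = GF3Polynomial(
        {
            (): 1,
            ((0, 2),): 1,
            ((0, 2), (1, 2)): 2,
            ((2, 1),): 2,
            ((0, 1), (2, 1)): 1,
            ((0, 2), (2, 1)): 2,
            ((2, 2),): 1,
            ((0, 1), (2, 2)): 2,
            ((0, 2), (1, 2), (2, 2)): 1,
        }
    )
    catalog.append(
        ToyModel(
            name="ferritin_subsystem",
            model=ft,
            expected_polynomials={"Ft": ft_poly},
        )
    )
    return catalog
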