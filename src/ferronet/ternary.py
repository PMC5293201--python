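"""Three-valued gate algebra for logical network models.

Each molecular species takes one of three levels: 0 (low/inactive),
1 (normal/intermediate), 2 (high/active).  Update rules are built from
n-ary Max (OR-like) and Min (AND-like) gates over *literals*.  A literal
is a species reference filtered through a transition table
(:class:`LiteralTransform`): identity, logical NOT (0 and 2 swapped,
1 fixed), or an adjusted-regulation table that weakens or shifts the
effect of a regulator (e.g. active IRP1 inhibits ferritin only down to
the intermediate level, not all the way to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

TERNARY_LEVELS = (0, 1, 2)


def _check_value(x: int) -> int:
    if x not in (0, 1, 2):
        raise ValueError(f"ternary value must be 0, 1 or 2, got {x!r}")
    return x


def eval_not(x: int) -> int:
    """Ternary NOT: swap 0 and 2, leave the intermediate level fixed."""
    return 2 - _check_value(x)


def eval_max(xs: Sequence[int]) -> int:
    """n-ary Max gate (ternary OR). Associative fold of the binary gate."""
    if not xs:
        raise ValueError("Max gate needs at least one input")
    return max(_check_value(x) for x in xs)


def eval_min(xs: Sequence[int]) -> int:
    """n-ary Min gate (ternary AND)."""
    if not xs:
        raise ValueError("Min gate needs at least one input")
    return min(_check_value(x) for x in xs)


@dataclass(frozen=True)
class LiteralTransform:
    """A total transition table {0,1,2} -> {0,1,2} applied at a leaf.

    Adjusted-regulation tables modify the strength of a single
    regulator; NOT is itself a transform, so every leaf of an
    expression tree is a single (species, transform) pair.
    """

    name: str
    table: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.table) != 3 or any(v not in (0, 1, 2) for v in self.table):
            raise ValueError(f"transform table must map {{0,1,2}} into {{0,1,2}}: {self.table!r}")

    def __call__(self, x: int) -> int:
        return self.table[_check_value(x)]

    def compose(self, inner: "LiteralTransform", name: str | None = None) -> "LiteralTransform":
        """Return self∘inner as a single precomposed table."""
        tbl = tuple(self.table[inner.table[v]] for v in TERNARY_LEVELS)
        return LiteralTransform(name or f"{self.name}({inner.name})", tbl)  # type: ignore[arg-type]


IDENTITY = LiteralTransform("IDENTITY", (0, 1, 2))
NOT = LiteralTransform("NOT", (2, 1, 0))
# Active IRP1 stabilises TfR1 mRNA only partially: level 2 acts as 1.
STAR_IRP1_ACT = LiteralTransform("STAR_IRP1_ACT", (0, 1, 1))
# Active IRP1 represses Ft/Fpn translation only down to the
# intermediate level (combined star-and-invert table).
STAR_IRP1_INH = LiteralTransform("STAR_IRP1_INH", (2, 1, 1))
# Basal Keap1 is present even without Nrf2: level 0 acts as 1.
STAR_NRF2 = LiteralTransform("STAR_NRF2", (1, 1, 2))

BUILTIN_TRANSFORMS: dict[str, LiteralTransform] = {
    t.name: t for t in (IDENTITY, NOT, STAR_IRP1_ACT, STAR_IRP1_INH, STAR_NRF2)
}


@dataclass(frozen=True)
class Literal:
    """A species reference filtered through a transform."""

    species: str
    transform: LiteralTransform = IDENTITY


@dataclass(frozen=True)
class Constant:
    value: int

    def __post_init__(self) -> None:
        _check_value(self.value)


@dataclass(frozen=True)
class Gate:
    """An n-ary Max or Min node (kind in {"MAX", "MIN"}), >= 2 children."""

    kind: str
    children: tuple["LogicExpression", ...]

    def __post_init__(self) -> None:
        if self.kind not in ("MAX", "MIN"):
            raise ValueError(f"gate kind must be MAX or MIN, got {self.kind!r}")
        if len(self.children) < 2:
            raise ValueError(f"{self.kind} gate needs at least 2 children")


LogicExpression = Union[Literal, Constant, Gate]


def Max(*children: LogicExpression) -> Gate:
    return Gate("MAX", tuple(children))


def Min(*children: LogicExpression) -> Gate:
    return Gate("MIN", tuple(children))


def expression_species(expr: LogicExpression) -> set[str]:
    """Set of species names referenced by the expression's literals."""
    if isinstance(expr, Literal):
        return {expr.species}
    if isinstance(expr, Constant):
        return set()
    out: set[str] = set()
    for child in expr.children:
        out |= expression_species(child)
    return out


def eval_expression(expr: LogicExpression, state: Mapping[str, int]) -> int:
    """Evaluate an expression tree on a named state.

    Literal transforms are applied at the leaves; Min/Max fold the
    internal nodes.  Gate semantics never involve modular arithmetic.
    """
    if isinstance(expr, Constant):
        return expr.value
    if isinstance(expr, Literal):
        try:
            raw = state[expr.species]
        except KeyError:
            raise KeyError(f"expression references unknown species {expr.species!r}") from None
        return expr.transform(raw)
    vals = [eval_expression(c, state) for c in expr.children]
    return eval_max(vals) if expr.kind == "MAX" else eval_min(vals)


def substitute_literal(expr: LogicExpression, target: str, value: int) -> LogicExpression:
    """Replace every literal of `target` with the constant its transform maps `value` to.

    Used to model reduced bioactivity of one regulator inside a single
    rule (e.g. zeroing the antioxidant-enzyme group inside the ROS
    rule) without clamping the regulator globally.
    """
    _check_value(value)
    if isinstance(expr, Literal):
        if expr.species == target:
            return Constant(expr.transform(value))
        return expr
    if isinstance(expr, Constant):
        return expr
    return Gate(expr.kind, tuple(substitute_literal(c, target, value) for c in expr.children))
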