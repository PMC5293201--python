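"""Reduced multivariate polynomials over the field with three elements.

Every ternary logical rule has a unique representation as a polynomial
over GF(3) once exponents are reduced with x^3 = x (so each variable
appears with exponent at most 2).  This module provides that canonical
representation, Lagrange-style interpolation of arbitrary truth tables,
translation of gate expression trees into polynomials, and the
continuity adjustment that limits each species to one-level moves per
time step.

Variables are identified by 0-based species indices; the pretty-printer
uses the conventional 1-based labels (index 3 prints as ``x4``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ternary import (
    Constant,
    Gate,
    Literal,
    LiteralTransform,
    LogicExpression,
)

# A monomial key is a tuple of (variable_index, exponent) pairs, sorted
# by variable index, with exponents in {1, 2}.  The empty tuple is the
# constant monomial.  Coefficients are stored in {1, 2}.
MonomialKey = tuple[tuple[int, int], ...]


def _reduce_exponent(e: int) -> int:
    """Reduce x^e with the field identity x^3 = x (for e >= 1)."""
    if e <= 0:
        raise ValueError("exponent must be positive for a stored variable")
    return ((e - 1) % 2) + 1


class GF3Polynomial:
    """Canonical reduced polynomial over GF(3).

    Immutable value object: two polynomials are equal iff they agree as
    functions on every assignment, because the reduced representation
    is unique.
    """

    __slots__ = ("_monomials",)

    def __init__(self, monomials: Mapping[MonomialKey, int] | None = None):
        clean: dict[MonomialKey, int] = {}
        if monomials:
            for key, coeff in monomials.items():
                c = coeff % 3
                if c == 0:
                    continue
                norm = tuple(sorted((v, _reduce_exponent(e)) for v, e in key))
                clean[norm] = (clean.get(norm, 0) + c) % 3
                if clean[norm] == 0:
                    del clean[norm]
        self._monomials = clean

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "GF3Polynomial":
        return cls()

    @classmethod
    def constant(cls, c: int) -> "GF3Polynomial":
        return cls({(): c})

    @classmethod
    def variable(cls, index: int) -> "GF3Polynomial":
        return cls({((index, 1),): 1})

    # -- accessors ----------------------------------------------------
    @property
    def monomials(self) -> dict[MonomialKey, int]:
        return dict(self._monomials)

    def variables(self) -> set[int]:
        return {v for key in self._monomials for v, _ in key}

    def is_zero(self) -> bool:
        return not self._monomials

    # -- field arithmetic ---------------------------------------------
    def __add__(self, other: "GF3Polynomial") -> "GF3Polynomial":
        out = dict(self._monomials)
        for key, c in other._monomials.items():
            out[key] = out.get(key, 0) + c
        return GF3Polynomial(out)

    def __neg__(self) -> "GF3Polynomial":
        return GF3Polynomial({k: (-c) % 3 for k, c in self._monomials.items()})

    def __sub__(self, other: "GF3Polynomial") -> "GF3Polynomial":
        return self + (-other)

    def __mul__(self, other: "GF3Polynomial") -> "GF3Polynomial":
        out: dict[MonomialKey, int] = {}
        for k1, c1 in self._monomials.items():
            for k2, c2 in other._monomials.items():
                exps: dict[int, int] = dict(k1)
                for v, e in k2:
                    exps[v] = _reduce_exponent(exps.get(v, 0) + e)
                key = tuple(sorted(exps.items()))
                out[key] = out.get(key, 0) + c1 * c2
        return GF3Polynomial(out)

    def scale(self, c: int) -> "GF3Polynomial":
        return GF3Polynomial({k: v * c for k, v in self._monomials.items()})

    def __pow__(self, n: int) -> "GF3Polynomial":
        if n < 0:
            raise ValueError("negative powers are undefined")
        result = GF3Polynomial.constant(1)
        for _ in range(n):
            result = result * self
        return result

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GF3Polynomial):
            return NotImplemented
        return self._monomials == other._monomials

    def __hash__(self) -> int:
        return hash(frozenset(self._monomials.items()))

    # -- evaluation ---------------------------------------------------
    def evaluate(self, assignment: Mapping[int, int] | Sequence[int]) -> int:
        """Evaluate modulo 3 at an assignment (dict by index, or full vector)."""
        total = 0
        for key, coeff in self._monomials.items():
            term = coeff
            for v, e in key:
                x = assignment[v]
                term *= x**e
            total += term
        return total % 3

    # -- printing -----------------------------------------------------
    def _sort_key(self, key: MonomialKey):
        degree = sum(e for _, e in key)
        return (-degree, tuple((v, -e) for v, e in key))

    def __str__(self) -> str:
        if not self._monomials:
            return "0"
        parts = []
        for key in sorted(self._monomials, key=self._sort_key):
            coeff = self._monomials[key]
            factors = [f"x{v + 1}" + (f"^{e}" if e > 1 else "") for v, e in key]
            if not factors:
                parts.append(str(coeff))
            elif coeff == 1:
                parts.append("*".join(factors))
            else:
                parts.append("*".join([str(coeff)] + factors))
        return " + ".join(parts)

    def __repr__(self) -> str:
        return f"GF3Polynomial({self})"


# ---------------------------------------------------------------------
# Interpolation (finite-field Lagrange formula)
# ---------------------------------------------------------------------

def interpolate(
    truth_table: Mapping[tuple[int, ...], int],
    variables: Sequence[int],
) -> GF3Polynomial:
    """Interpolate a total function {0,1,2}^n -> {0,1,2} into a polynomial.

    Uses g(x) = sum_c f(c) * prod_j (1 - (x_j - c_j)^2) over GF(3): the
    product is the indicator of x = c, so g matches the table at every
    point, and the reduced result is the unique canonical polynomial.
    """
    n = len(variables)
    points = list(itertools.product((0, 1, 2), repeat=n))
    missing = [c for c in points if c not in truth_table]
    if missing:
        raise ValueError(
            f"incomplete truth table: missing {len(missing)} of {len(points)} tuples, "
            f"first missing {missing[0]!r}"
        )
    one = GF3Polynomial.constant(1)
    result = GF3Polynomial.zero()
    for c in points:
        fc = truth_table[c] % 3
        if fc == 0:
            continue
        term = GF3Polynomial.constant(fc)
        for var, cj in zip(variables, c):
            xj = GF3Polynomial.variable(var)
            diff = xj - GF3Polynomial.constant(cj)
            term = term * (one - diff * diff)
        result = result + term
    return result


def tabulate(poly: GF3Polynomial, variables: Sequence[int]) -> dict[tuple[int, ...], int]:
    """Full truth table of a polynomial over the given variables."""
    table = {}
    for c in itertools.product((0, 1, 2), repeat=len(variables)):
        table[c] = poly.evaluate(dict(zip(variables, c)))
    return table


def transform_polynomial(transform: LiteralTransform, variable: int) -> GF3Polynomial:
    """Univariate polynomial of a literal transition table."""
    table = {(v,): transform.table[v] for v in (0, 1, 2)}
    return interpolate(table, [variable])


# ---------------------------------------------------------------------
# Expression trees -> polynomials
# ---------------------------------------------------------------------

def _gate_apply(kind: str, p: GF3Polynomial, q: GF3Polynomial) -> GF3Polynomial:
    """Substitute polynomials into the binary Max/Min gate polynomials.

    Max(x,y) = x^2y^2 + x^2y + xy^2 + 2xy + x + y
    Min(x,y) = 2x^2y^2 + 2x^2y + 2xy^2 + xy
    """
    p2, q2 = p * p, q * q
    if kind == "MAX":
        return p2 * q2 + p2 * q + p * q2 + (p * q).scale(2) + p + q
    return (p2 * q2).scale(2) + (p2 * q).scale(2) + (p * q2).scale(2) + p * q


def from_expression(
    expr: LogicExpression, index_of: Mapping[str, int]
) -> GF3Polynomial:
    """Translate a gate expression tree into its canonical polynomial.

    Leaf transforms become univariate interpolated polynomials; Min/Max
    nodes substitute child polynomials into the gate polynomials and
    reduce modulo 3 with x^3 = x.  The result agrees with direct gate
    evaluation on every assignment.
    """
    if isinstance(expr, Constant):
        return GF3Polynomial.constant(expr.value)
    if isinstance(expr, Literal):
        try:
            idx = index_of[expr.species]
        except KeyError:
            raise KeyError(f"expression references unknown species {expr.species!r}") from None
        return transform_polynomial(expr.transform, idx)
    children = [from_expression(c, index_of) for c in expr.children]
    result = children[0]
    for child in children[1:]:
        result = _gate_apply(expr.kind, result, child)
    return result


# ---------------------------------------------------------------------
# Continuity adjustment
# ---------------------------------------------------------------------

def continuity_step(current: int, raw: int) -> int:
    """h(x, f): move the current level one unit toward the raw rule output."""
    if raw > current:
        return current + 1
    if raw < current:
        return current - 1
    return current


def apply_continuity(rule_poly: GF3Polynomial, target: int) -> GF3Polynomial:
    """Polynomial of h(x_target, f): the continuity-adjusted update.

    Tabulates h over all assignments of the target variable together
    with the rule's own inputs and interpolates, mirroring the way the
    adjusted update is derived pointwise; the result depends on the
    target variable itself (a self-regulation loop).
    """
    variables = sorted(rule_poly.variables() | {target})
    tpos = variables.index(target)
    table: dict[tuple[int, ...], int] = {}
    for c in itertools.product((0, 1, 2), repeat=len(variables)):
        raw = rule_poly.evaluate(dict(zip(variables, c)))
        table[c] = continuity_step(c[tpos], raw)
    return interpolate(table, variables)
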