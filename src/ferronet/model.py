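"""Network model container and a plain-text rule DSL.

A model is an ordered list of species, one update rule per species
(an expression tree over Max/Min gates and transformed literals), and
a continuity policy listing the species whose updates are *not*
smoothed to one-level moves (pools that can be produced or consumed in
bulk within one time step).

DSL format (UTF-8, LF, one statement per line, ``#`` comments)::

    species: LIP, TfR1, Fpn, ...
    pathway: iron_homeostasis = LIP, TfR1, ...
    continuity_exempt: LIP, heme, ROS
    transform: MYTABLE 0->1 1->1 2->0        # optional user tables
    Ft = MIN(STAR_IRP1_INH(IRP1), NOT(IRP2))
    Hep = IL6

Literals are a bare species name, ``TRANSFORM(name)`` with a named
transform, or the shorthands ``*name`` (partial activation,
STAR_IRP1_ACT) and ``*NOT(name)`` (partial inhibition, STAR_IRP1_INH).
Constants 0/1/2 may appear anywhere an expression may.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .ternary import (
    BUILTIN_TRANSFORMS,
    Constant,
    Gate,
    IDENTITY,
    Literal,
    LiteralTransform,
    LogicExpression,
    NOT,
    STAR_IRP1_ACT,
    STAR_IRP1_INH,
    expression_species,
)


class ModelError(ValueError):
    """Invalid model structure (unknown species, missing/duplicate rules)."""


class DSLSyntaxError(ValueError):
    """Malformed model text; carries a 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Species:
    """A network node. `index` is the 1-based position in canonical order."""

    name: str
    index: int
    pathway: str = "unassigned"
    display_name: str | None = None

    @property
    def label(self) -> str:
        return self.display_name or self.name


@dataclass(frozen=True)
class ContinuityPolicy:
    """Species exempt from the one-level-per-step continuity adjustment."""

    exempt_species: frozenset[str] = frozenset()

    def is_exempt(self, name: str) -> bool:
        return name in self.exempt_species


@dataclass(frozen=True)
class Model:
    species: tuple[Species, ...]
    rules: Mapping[str, LogicExpression]
    continuity: ContinuityPolicy = ContinuityPolicy()
    transforms: Mapping[str, LiteralTransform] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species names")
        missing = set(names) - set(self.rules)
        if missing:
            raise ModelError(f"species without an update rule: {sorted(missing)}")
        extra = set(self.rules) - set(names)
        if extra:
            raise ModelError(f"rules for undeclared species: {sorted(extra)}")
        for name, rule in self.rules.items():
            unknown = expression_species(rule) - set(names)
            if unknown:
                raise ModelError(f"rule for {name} references unknown species {sorted(unknown)}")
        bad_exempt = self.continuity.exempt_species - set(names)
        if bad_exempt:
            raise ModelError(f"continuity exemptions for unknown species: {sorted(bad_exempt)}")

    # -- conveniences --------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_states(self) -> int:
        """Size of the synchronous state space, 3^N."""
        return 3**self.n_species

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def index_of(self, name: str) -> int:
        """0-based index of a species in canonical order."""
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ModelError(f"unknown species {name!r}") from None

    def rule(self, name: str) -> LogicExpression:
        if name not in self.rules:
            raise ModelError(f"unknown species {name!r}")
        return self.rules[name]

    def with_rules(
        self,
        new_rules: Mapping[str, LogicExpression],
        extra_exempt: Iterable[str] = (),
        name: str | None = None,
    ) -> "Model":
        rules = dict(self.rules)
        rules.update(new_rules)
        policy = ContinuityPolicy(self.continuity.exempt_species | frozenset(extra_exempt))
        return Model(
            species=self.species,
            rules=rules,
            continuity=policy,
            transforms=self.transforms,
            name=name or self.name,
        )


# ---------------------------------------------------------------------
# Expression text round-trip
# ---------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\*NOT\(|\*|[A-Za-z_][A-Za-z0-9_\-]*|\d|[(),])")


def _tokenize(text: str, line: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise DSLSyntaxError(f"unexpected character {text[pos]!r}", line)
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_expression(
    text: str,
    transforms: Mapping[str, LiteralTransform] | None = None,
    line: int = 0,
) -> LogicExpression:
    """Parse one rule expression. Raises DSLSyntaxError on bad input."""
    registry = dict(BUILTIN_TRANSFORMS)
    if transforms:
        registry.update(transforms)
    tokens = _tokenize(text, line)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise DSLSyntaxError("unexpected end of expression", line)
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise DSLSyntaxError(f"expected {expected!r}, got {tok!r}", line)
        pos += 1
        return tok

    def parse_node() -> LogicExpression:
        tok = take()
        if tok in ("0", "1", "2"):
            return Constant(int(tok))
        if tok == "*NOT(":
            name = take()
            take(")")
            return Literal(name, STAR_IRP1_INH)
        if tok == "*":
            return Literal(take(), STAR_IRP1_ACT)
        upper = tok.upper()
        if upper in ("MAX", "MIN"):
            take("(")
            children = [parse_node()]
            while peek() == ",":
                take(",")
                children.append(parse_node())
            take(")")
            if len(children) < 2:
                raise DSLSyntaxError(f"{upper} needs at least 2 arguments", line)
            return Gate(upper, tuple(children))
        if peek() == "(":
            if tok not in registry:
                raise DSLSyntaxError(f"unknown transform {tok!r}", line)
            take("(")
            name = take()
            take(")")
            return Literal(name, registry[tok])
        return Literal(tok, IDENTITY)

    node = parse_node()
    if pos != len(tokens):
        raise DSLSyntaxError(f"trailing tokens starting at {tokens[pos]!r}", line)
    return node


def format_expression(expr: LogicExpression) -> str:
    """Canonical text of an expression (inverse of parse_expression)."""
    if isinstance(expr, Constant):
        return str(expr.value)
    if isinstance(expr, Literal):
        if expr.transform is IDENTITY or expr.transform.name == "IDENTITY":
            return expr.species
        return f"{expr.transform.name}({expr.species})"
    inner = ", ".join(format_expression(c) for c in expr.children)
    return f"{expr.kind}({inner})"


# ---------------------------------------------------------------------
# Model documents
# ---------------------------------------------------------------------

def parse_model(text: str, name: str = "model") -> Model:
    """Parse a rule-DSL document into a validated Model."""
    species_order: list[str] = []
    pathways: dict[str, str] = {}
    display: dict[str, str] = {}
    exempt: set[str] = set()
    transforms: dict[str, LiteralTransform] = {}
    rules: dict[str, LogicExpression] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species:"):
            names = [t.strip() for t in line[len("species:"):].replace(",", " ").split()]
            species_order.extend(names)
            continue
        if line.startswith("pathway:"):
            body = line[len("pathway:"):]
            if "=" not in body:
                raise DSLSyntaxError("pathway line needs 'name = species...'", lineno)
            pname, members = body.split("=", 1)
            for sp in members.replace(",", " ").split():
                pathways[sp] = pname.strip()
            continue
        if line.startswith("display:"):
            body = line[len("display:"):]
            if "=" not in body:
                raise DSLSyntaxError("display line needs 'name = label'", lineno)
            sp, label = body.split("=", 1)
            display[sp.strip()] = label.strip()
            continue
        if line.startswith("continuity_exempt:"):
            exempt |= set(line[len("continuity_exempt:"):].replace(",", " ").split())
            continue
        if line.startswith("transform:"):
            parts = line[len("transform:"):].split()
            if len(parts) != 4:
                raise DSLSyntaxError("transform line needs a name and three a->b maps", lineno)
            tname = parts[0]
            table = [None, None, None]
            for entry in parts[1:]:
                m = re.fullmatch(r"([012])->([012])", entry)
                if not m:
                    raise DSLSyntaxError(f"bad transform entry {entry!r}", lineno)
                table[int(m.group(1))] = int(m.group(2))
            if any(v is None for v in table):
                raise DSLSyntaxError(f"transform {tname} is not total on {{0,1,2}}", lineno)
            transforms[tname] = LiteralTransform(tname, tuple(table))  # type: ignore[arg-type]
            continue
        if "=" in line:
            lhs, rhs = line.split("=", 1)
            target = lhs.strip()
            if target in rules:
                raise DSLSyntaxError(f"duplicate rule for {target}", lineno)
            rules[target] = parse_expression(rhs.strip(), transforms, lineno)
            continue
        raise DSLSyntaxError(f"unrecognized statement {line!r}", lineno)

    if not species_order:
        species_order = list(rules)
    species = tuple(
        Species(
            name=n,
            index=i + 1,
            pathway=pathways.get(n, "unassigned"),
            display_name=display.get(n),
        )
        for i, n in enumerate(species_order)
    )
    try:
        return Model(
            species=species,
            rules=rules,
            continuity=ContinuityPolicy(frozenset(exempt)),
            transforms=transforms,
            name=name,
        )
    except ModelError as exc:
        raise ModelError(f"invalid model document: {exc}") from exc


def write_model(model: Model) -> str:
    """Serialize a model to canonical DSL text (parse_model inverse)."""
    lines = [f"# ferronet model: {model.name}"]
    if model.species:
        lines.append("species: " + ", ".join(model.species_names))
    by_pathway: dict[str, list[str]] = {}
    for sp in model.species:
        if sp.pathway != "unassigned":
            by_pathway.setdefault(sp.pathway, []).append(sp.name)
    for pname, members in by_pathway.items():
        lines.append(f"pathway: {pname} = " + ", ".join(members))
    for sp in model.species:
        if sp.display_name:
            lines.append(f"display: {sp.name} = {sp.display_name}")
    if model.continuity.exempt_species:
        ordered = [n for n in model.species_names if n in model.continuity.exempt_species]
        lines.append("continuity_exempt: " + ", ".join(ordered))
    for tname, t in sorted(model.transforms.items()):
        entries = " ".join(f"{v}->{t.table[v]}" for v in (0, 1, 2))
        lines.append(f"transform: {tname} {entries}")
    for sp in model.species:
        lines.append(f"{sp.name} = {format_expression(model.rules[sp.name])}")
    return "\n".join(lines) + "\n"


def _expression_to_json(expr: LogicExpression) -> dict:
    if isinstance(expr, Constant):
        return {"kind": "CONSTANT", "value": expr.value}
    if isinstance(expr, Literal):
        return {"kind": "LITERAL", "species": expr.species, "transform": expr.transform.name}
    return {"kind": expr.kind, "children": [_expression_to_json(c) for c in expr.children]}


def model_to_json(model: Model) -> str:
    """JSON export: species (with pathway), rule trees, continuity list."""
    doc = {
        "name": model.name,
        "species": [
            {"name": s.name, "index": s.index, "pathway": s.pathway, "label": s.label}
            for s in model.species
        ],
        "rules": {name: _expression_to_json(model.rules[name]) for name in model.species_names},
        "continuity_exempt": sorted(model.continuity.exempt_species),
        "transforms": {
            name: list(t.table)
            for name, t in sorted({**BUILTIN_TRANSFORMS, **model.transforms}.items())
        },
        "n_states": model.n_states,
    }
    return json.dumps(doc, indent=2)
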