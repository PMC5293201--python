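"""In-silico knockout/overexpression clamps and rule-local substitutions.

A knockout sets a species' update rule to the constant 0 and an
overexpression to the constant 2; the clamped species then sits at that
level from the first update onward, regardless of its regulators (the
clamp bypasses the continuity adjustment).  A rule substitution models
reduced bioactivity of one regulator inside a single target rule —
e.g. low catalase bioactivity is modelled by zeroing the grouped
antioxidant-enzyme node only inside the ROS update rule — leaving every
other rule untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import Model, ModelError
from .ternary import Constant, LogicExpression, substitute_literal

KNOCKOUT = "KNOCKOUT"
OVEREXPRESS = "OVEREXPRESS"
RULE_SUBSTITUTE = "RULE_SUBSTITUTE"


@dataclass(frozen=True)
class Perturbation:
    """A node clamp or a rule-local constant substitution.

    - ``KNOCKOUT(target)``: target's rule becomes the constant 0.
    - ``OVEREXPRESS(target)``: target's rule becomes the constant 2.
    - ``RULE_SUBSTITUTE(target, host_rule, replacement)``: every literal
      of ``target`` inside ``host_rule``'s expression is replaced by the
      constant the literal's transform maps ``replacement`` to.
    """

    kind: str
    target: str
    host_rule: str | None = None
    replacement: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (KNOCKOUT, OVEREXPRESS, RULE_SUBSTITUTE):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == RULE_SUBSTITUTE:
            if self.host_rule is None or self.replacement not in (0, 1, 2):
                raise ValueError("RULE_SUBSTITUTE needs a host rule and a replacement in {0,1,2}")
        elif self.host_rule is not None or self.replacement is not None:
            raise ValueError(f"{self.kind} takes only a target species")

    @property
    def clamp_value(self) -> int | None:
        if self.kind == KNOCKOUT:
            return 0
        if self.kind == OVEREXPRESS:
            return 2
        return None


def knockout(target: str) -> Perturbation:
    return Perturbation(KNOCKOUT, target)


def overexpress(target: str) -> Perturbation:
    return Perturbation(OVEREXPRESS, target)


def rule_substitute(target: str, host_rule: str, replacement: int) -> Perturbation:
    return Perturbation(RULE_SUBSTITUTE, target, host_rule, replacement)


def apply_perturbations(model: Model, perturbations: Sequence[Perturbation]) -> Model:
    """Return a new model with the perturbations applied.

    Clamped species get constant rules and are exempted from the
    continuity adjustment, so they jump to the clamp level in one step
    from any initial value (all 3^N states remain legal initial
    states).  The input model is not modified.
    """
    names = set(model.species_names)
    new_rules: dict[str, LogicExpression] = {}
    clamped: dict[str, int] = {}
    for p in perturbations:
        if p.target not in names:
            raise ModelError(f"perturbation target {p.target!r} not in model")
        if p.kind == RULE_SUBSTITUTE:
            if p.host_rule not in names:
                raise ModelError(f"rule-substitution host {p.host_rule!r} not in model")
            host = new_rules.get(p.host_rule, model.rules[p.host_rule])
            new_rules[p.host_rule] = substitute_literal(host, p.target, p.replacement)
        else:
            if p.target in clamped and clamped[p.target] != p.clamp_value:
                raise ModelError(f"conflicting clamps on {p.target!r}")
            clamped[p.target] = p.clamp_value  # type: ignore[assignment]
    for target, value in clamped.items():
        new_rules[target] = Constant(value)
    if not perturbations:
        return model
    suffix = "+".join(_describe(p) for p in perturbations)
    return model.with_rules(new_rules, extra_exempt=clamped, name=f"{model.name}[{suffix}]")


def _describe(p: Perturbation) -> str:
    if p.kind == KNOCKOUT:
        return f"{p.target}_ko"
    if p.kind == OVEREXPRESS:
        return f"{p.target}_oe"
    return f"{p.host_rule}:{p.target}={p.replacement}"


# ---------------------------------------------------------------------
# Scenario presets: the standard knockout/overexpression panel for the
# bundled iron network.
# ---------------------------------------------------------------------

SCENARIO_PRESETS: dict[str, tuple[Perturbation, ...]] = {
    "normal": (),
    "IRP2_oe": (overexpress("IRP2"),),
    "Ftmt_oe": (overexpress("Ftmt"),),
    "Ras_oe": (overexpress("Ras"),),
    # low catalase bioactivity: zero the AE group inside the ROS rule
    "Ras_oe+CAT_ko": (
        overexpress("Ras"),
        rule_substitute(target="AE", host_rule="ROS", replacement=0),
    ),
    "Mfrn_ko": (knockout("Mfrn"),),
    "Ras_oe+CAT_ko+Mfrn_ko": (
        overexpress("Ras"),
        rule_substitute(target="AE", host_rule="ROS", replacement=0),
        knockout("Mfrn"),
    ),
}

#: Preset order used in reports (normal first, single perturbations,
#: then the combined cancer scenario).
SCENARIO_ORDER = tuple(SCENARIO_PRESETS)


def scenario_perturbations(name: str) -> tuple[Perturbation, ...]:
    try:
        return SCENARIO_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known scenarios: {', '.join(SCENARIO_PRESETS)}"
        ) from None


def parse_scenario_config(config: Mapping[str, object]) -> tuple[Perturbation, ...]:
    """Build perturbations from a key-value scenario config.

    Recognised keys: ``oe`` (list of species to overexpress), ``ko``
    (list to knock out), ``rule_zero`` (list of {host, target} pairs
    whose target literal is zeroed inside the host rule).
    """
    out: list[Perturbation] = []
    for name in config.get("oe", []):  # type: ignore[union-attr]
        out.append(overexpress(str(name)))
    for name in config.get("ko", []):  # type: ignore[union-attr]
        out.append(knockout(str(name)))
    for entry in config.get("rule_zero", []):  # type: ignore[union-attr]
        out.append(rule_substitute(str(entry["target"]), str(entry["host"]), 0))
    return tuple(out)
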