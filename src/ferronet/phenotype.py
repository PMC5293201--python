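"""Phenotype concordance scoring for attractors.

An attractor is compared against a target vector over a subset of
species (a phenotype).  A species matches only if it is constant across
the attractor at exactly the target level; an oscillating species never
matches.  The bundled target is the cancer phenotype of the iron
homeostasis pathway (CP-IHP): relative to all-normal levels, malignant
breast epithelial lines show low Fpn and Ft and high Hep, TfR1, IRP2,
IRP1 and LIP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .dynamics import Attractor
from .iron import CP_IHP
from .model import Model


@dataclass(frozen=True)
class SpeciesScore:
    species: str
    target: int
    value: int | None  # None if the species oscillates across a cycle
    match: bool


@dataclass(frozen=True)
class PhenotypeScore:
    rows: tuple[SpeciesScore, ...]

    @property
    def matches(self) -> int:
        return sum(r.match for r in self.rows)

    @property
    def total(self) -> int:
        return len(self.rows)

    def matches_excluding(self, excluded: Sequence[str]) -> tuple[int, int]:
        rows = [r for r in self.rows if r.species not in excluded]
        return sum(r.match for r in rows), len(rows)

    def as_dict(self) -> dict:
        return {
            "matches": self.matches,
            "total": self.total,
            "per_species": [
                {
                    "species": r.species,
                    "target": r.target,
                    "value": r.value,
                    "match": r.match,
                }
                for r in self.rows
            ],
        }


def score_phenotype(
    model: Model,
    attractor: Attractor,
    target: Mapping[str, int] | None = None,
) -> PhenotypeScore:
    """Count target species whose attractor level equals the target.

    For cycle attractors a species counts as matching only when it is
    constant at the target level over the whole cycle.
    """
    if target is None:
        target = CP_IHP
    rows = []
    for name, want in target.items():
        value = attractor.value_of(model, name)
        rows.append(
            SpeciesScore(species=name, target=want, value=value, match=value == want)
        )
    return PhenotypeScore(rows=tuple(rows))
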