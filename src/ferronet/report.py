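"""Scenario runner and heatmap-style tabular reports.

Runs a panel of perturbation scenarios on a model, discovers attractors
(by sampling, optionally exhaustively for small models), scores each
attractor against the iron cancer phenotype, and serialises everything
as JSON and as a TSV heatmap matrix (one row per attractor, one column
per species; oscillating species print the sorted set of levels they
visit, e.g. ``0/1``).

Reports are deterministic: identical model, scenarios and seed produce
byte-identical output.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

from . import __version__
from .dynamics import (
    Attractor,
    AttractorSet,
    CompiledModel,
    exhaustive_attractors,
    sample_attractors,
    verify_closure,
)
from .iron import CP_IHP
from .model import Model
from .perturb import Perturbation, apply_perturbations, _describe
from .phenotype import score_phenotype


def attractor_levels(model: Model, attractor: Attractor) -> dict[str, str]:
    """Heatmap cell per species: the constant level, or 'a/b' if oscillating."""
    out = {}
    for i, name in enumerate(model.species_names):
        vals = sorted({s[i] for s in attractor.states})
        out[name] = "/".join(str(v) for v in vals)
    return out


def _attractor_record(model: Model, a: Attractor) -> dict:
    score = score_phenotype(model, a, CP_IHP)
    non_lip, non_lip_total = score.matches_excluding(["LIP"])
    return {
        "kind": a.kind,
        "period": a.period,
        "basin_count": a.basin_count,
        "basin_fraction": a.basin_fraction,
        "basin_se": a.basin_se,
        "states": [list(s) for s in a.states],
        "levels": attractor_levels(model, a),
        "cp_ihp": {
            **score.as_dict(),
            "matches_excluding_LIP": non_lip,
            "total_excluding_LIP": non_lip_total,
        },
    }


def run_scenarios(
    model: Model,
    scenarios: Sequence[tuple[str, Sequence[Perturbation]]],
    n_samples: int = 100_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """Run each scenario's perturbed model to its attractor landscape.

    Returns a JSON-serialisable report bundle.  Every reported
    attractor is re-verified for closure (stepping each cycle state
    yields the next) before it enters the report.
    """
    blocks = []
    for name, perturbations in scenarios:
        perturbed = apply_perturbations(model, list(perturbations))
        if exhaustive:
            aset: AttractorSet = exhaustive_attractors(perturbed)
        else:
            aset = sample_attractors(perturbed, n_samples=n_samples, seed=seed)
        cm = CompiledModel(perturbed)
        for a in aset.attractors:
            if not verify_closure(cm, a):  # pragma: no cover - engine invariant
                raise RuntimeError(f"attractor failed closure check in scenario {name!r}")
        blocks.append(
            {
                "scenario": name,
                "perturbations": [_describe(p) for p in perturbations],
                "mode": aset.mode,
                "total_states_examined": aset.total_states_examined,
                "n_attractors": aset.n_attractors,
                "attractors": [_attractor_record(perturbed, a) for a in aset.attractors],
            }
        )
    return {
        "engine": "ferronet",
        "version": __version__,
        "model": model.name,
        "n_species": model.n_species,
        "n_states": model.n_states,
        "species": list(model.species_names),
        "seed": seed,
        "n_samples": None if exhaustive else n_samples,
        "scenarios": blocks,
    }


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=False) + "\n"


def report_to_tsv(report: Mapping) -> str:
    """Heatmap-shaped TSV: one row per attractor, species as columns."""
    species = report["species"]
    header = ["scenario", "attractor", "kind", "period", "basin_fraction"] + list(species)
    lines = ["\t".join(header)]
    for block in report["scenarios"]:
        for i, a in enumerate(block["attractors"]):
            frac = a["basin_fraction"]
            row = [
                block["scenario"],
                str(i),
                a["kind"],
                str(a["period"]),
                "" if frac is None else f"{frac:.6f}",
            ]
            row.extend(a["levels"][name] for name in species)
            lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
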