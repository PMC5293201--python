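"""The bundled 24-node intracellular iron network.

The network couples four pathways around the cytosolic labile iron
pool (LIP): iron homeostasis (import via TfR1, export via Fpn,
sequestration in Ft, post-transcriptional control by IRP1/IRP2,
hepcidin), mitochondrial iron utilization (Mfrn import, LIPmt, Ftmt
storage, heme synthesis via ALAS1 and degradation via HO-1), the
oxidative stress response (ROS, Keap1/Nrf2, a grouped antioxidant
enzyme node AE = SOD+CAT+GPx), an EGFR/Ras/ERK/c-Myc oncogenic arm,
and IL-6 as the single inflammatory cytokine.

Three adjusted regulations depart from plain NOT/identity tables:
active IRP1 (level 2) stabilises TfR1 mRNA and represses Ft/Fpn only
partially (it acts as level 1), and Keap1 retains a basal level 1 even
when Nrf2 is absent.  The labile iron pools (LIP, LIPmt), heme and ROS
are pools without self-degradation/self-regulation loops, so the
one-level-per-step continuity adjustment is not applied to them; their
levels track their inputs directly.
"""

from __future__ import annotations

from .model import ContinuityPolicy, Model, Species
from .ternary import (
    IDENTITY,
    Literal,
    Max,
    Min,
    NOT,
    STAR_IRP1_ACT,
    STAR_IRP1_INH,
    STAR_NRF2,
)

#: Canonical species order (1-based indices follow list position, so
#: Ft is x4, IRP1 is x5, IRP2 is x6).
IRON_SPECIES_ORDER = (
    "LIP", "TfR1", "Fpn", "Ft", "IRP1", "IRP2", "Hep",
    "Mfrn", "LIPmt", "Ftmt", "ALAS1", "heme", "HO1",
    "ROS", "Keap1", "Nrf2", "AE",
    "EGFR", "SOS", "GAPs", "Ras", "ERK", "cMyc",
    "IL6",
)

_PATHWAYS = {
    "iron_homeostasis": ("LIP", "TfR1", "Fpn", "Ft", "IRP1", "IRP2", "Hep"),
    "iron_utilization": ("Mfrn", "LIPmt", "Ftmt", "ALAS1", "heme", "HO1"),
    "oxidative_stress": ("ROS", "Keap1", "Nrf2", "AE"),
    "oncogenic": ("EGFR", "SOS", "GAPs", "Ras", "ERK", "cMyc"),
    "inflammatory": ("IL6",),
}

_DISPLAY = {"HO1": "HO-1", "cMyc": "c-Myc", "IL6": "IL-6"}

#: Species whose updates skip the continuity adjustment: the two labile
#: iron pools, heme and the ROS group are not self-regulating stores and
#: can be filled or drained in bulk within one time step.
CONTINUITY_EXEMPT = frozenset({"LIP", "LIPmt", "heme", "ROS"})

#: The cancer phenotype of the iron homeostasis pathway: target levels
#: of the seven iron-homeostasis species in malignant vs non-malignant
#: breast epithelial cell lines.
CP_IHP = {
    "Fpn": 0, "Ft": 0, "Hep": 2, "TfR1": 2, "IRP2": 2, "IRP1": 2, "LIP": 2,
}


def _lit(name: str) -> Literal:
    return Literal(name, IDENTITY)


def _not(name: str) -> Literal:
    return Literal(name, NOT)


def build_iron_model() -> Model:
    """Construct the bundled 24-species iron network model."""
    rules = {
        # -- iron homeostasis ------------------------------------------
        "LIP": Min(Max(_lit("TfR1"), _lit("HO1")),
                   Min(_not("Fpn"), _not("Ft"), _not("Mfrn"))),
        "TfR1": Max(Literal("IRP1", STAR_IRP1_ACT), _lit("IRP2"), _lit("cMyc")),
        "Fpn": Min(Literal("IRP1", STAR_IRP1_INH), _not("IRP2"), _not("Hep")),
        "Ft": Min(Literal("IRP1", STAR_IRP1_INH), _not("IRP2")),
        "IRP1": _not("LIP"),
        "IRP2": Max(_not("LIP"), _lit("cMyc")),
        "Hep": _lit("IL6"),
        # -- iron utilization ------------------------------------------
        "Mfrn": _not("LIPmt"),
        "LIPmt": Min(_lit("Mfrn"), _not("Ftmt"), _not("heme")),
        "Ftmt": _lit("LIPmt"),
        "ALAS1": Min(_not("heme"), _lit("LIPmt")),
        "heme": Min(_lit("ALAS1"), _not("HO1")),
        "HO1": Max(_lit("heme"), _lit("Nrf2")),
        # -- oxidative stress response ---------------------------------
        "ROS": Min(Max(_lit("LIP"), _lit("Ras"), _lit("EGFR")), _not("AE")),
        "Keap1": Min(_not("ROS"), Literal("Nrf2", STAR_NRF2)),
        "Nrf2": Max(_not("Keap1"), _lit("Ras"), _lit("ERK")),
        "AE": _lit("Nrf2"),
        # -- oncogenic pathway -----------------------------------------
        "EGFR": _lit("ROS"),
        "SOS": Max(_lit("EGFR"), _not("ERK")),
        "GAPs": _lit("EGFR"),
        "Ras": Min(Max(_lit("IL6"), _lit("SOS")), _not("GAPs")),
        "ERK": _lit("Ras"),
        "cMyc": _lit("ERK"),
        # -- inflammatory cytokine -------------------------------------
        "IL6": Max(_not("HO1"), _lit("ROS")),
    }
    pathway_of = {sp: p for p, members in _PATHWAYS.items() for sp in members}
    species = tuple(
        Species(
            name=name,
            index=i + 1,
            pathway=pathway_of[name],
            display_name=_DISPLAY.get(name),
        )
        for i, name in enumerate(IRON_SPECIES_ORDER)
    )
    return Model(
        species=species,
        rules=rules,
        continuity=ContinuityPolicy(CONTINUITY_EXEMPT),
        name="iron",
    )
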