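"""Default Martini 2.2 species registry and plasma-membrane compositions.

The eight species approximate an average mammalian plasma membrane: five
phosphatidylcholine/-ethanolamine species, sphingomyelin, cholesterol, a
phosphatidylserine and a PIP2 lipid (PAP6) restricted to the inner leaflet.
Bead inventories follow the published Martini 2.2 lipid topologies (the
PIP2 lipid follows the lipid-itp-generator recipe: P2 head, G G linker,
CCCC and DDDDC tails).  The head/tail split counts headgroup plus linker
(glycerol / phospho-sphingosine) beads as "head" and acyl-chain beads as
"tail"; both the split and the surface-defining headgroup bead are
overridable through the configuration because measured curvature depends
on the bead chosen to represent the surface.
"""

from __future__ import annotations

from .core_model import Composition, CompositionEntry, LipidSpec

__all__ = [
    "default_registry",
    "plasma_membrane_composition",
    "symmetric_composition",
    "PLASMA_MEMBRANE_TABLE",
]


def _spec(name, head, beads, n_head, tails, n_unsat):
    tails = tuple(tuple(t) for t in tails)
    n_tail = sum(len(t) for t in tails)
    n_bonds = sum(max(len(t) - 1, 0) for t in tails)
    return LipidSpec(
        name=name,
        headgroup_bead=head,
        bead_names=tuple(beads),
        n_head_beads=n_head,
        n_tail_beads=n_tail,
        n_tail_bonds=n_bonds,
        n_unsaturated_bonds=n_unsat,
        tails=tails,
    )


def default_registry() -> dict[str, LipidSpec]:
    """Martini 2.2 bead inventories for the eight plasma-membrane species."""
    reg = {}
    reg["POPC"] = _spec(
        "POPC", "PO4",
        ["NC3", "PO4", "GL1", "GL2",
         "C1A", "D2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"],
        4,
        [["C1A", "D2A", "C3A", "C4A"], ["C1B", "C2B", "C3B", "C4B"]],
        1,
    )
    reg["PAPC"] = _spec(
        "PAPC", "PO4",
        ["NC3", "PO4", "GL1", "GL2",
         "D1A", "D2A", "D3A", "D4A", "C5A", "C1B", "C2B", "C3B", "C4B"],
        4,
        [["D1A", "D2A", "D3A", "D4A", "C5A"], ["C1B", "C2B", "C3B", "C4B"]],
        4,
    )
    reg["POPE"] = _spec(
        "POPE", "PO4",
        ["NH3", "PO4", "GL1", "GL2",
         "C1A", "D2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"],
        4,
        [["C1A", "D2A", "C3A", "C4A"], ["C1B", "C2B", "C3B", "C4B"]],
        1,
    )
    reg["DIPE"] = _spec(
        "DIPE", "PO4",
        ["NH3", "PO4", "GL1", "GL2",
         "C1A", "D2A", "D3A", "C4A", "C1B", "D2B", "D3B", "C4B"],
        4,
        [["C1A", "D2A", "D3A", "C4A"], ["C1B", "D2B", "D3B", "C4B"]],
        4,
    )
    reg["DPSM"] = _spec(
        "DPSM", "PO4",
        ["NC3", "PO4", "AM1", "AM2",
         "T1A", "C2A", "C3A", "C1B", "C2B", "C3B", "C4B"],
        4,
        [["T1A", "C2A", "C3A"], ["C1B", "C2B", "C3B", "C4B"]],
        0,
    )
    reg["PAPS"] = _spec(
        "PAPS", "PO4",
        ["CNO", "PO4", "GL1", "GL2",
         "D1A", "D2A", "D3A", "D4A", "C5A", "C1B", "C2B", "C3B", "C4B"],
        4,
        [["D1A", "D2A", "D3A", "D4A", "C5A"], ["C1B", "C2B", "C3B", "C4B"]],
        4,
    )
    reg["PAP6"] = _spec(
        "PAP6", "PO4",
        ["C1", "C2", "C3", "PO4", "P1", "P2", "GL1", "GL2",
         "D1A", "D2A", "D3A", "D4A", "C5A", "C1B", "C2B", "C3B", "C4B"],
        8,
        [["D1A", "D2A", "D3A", "D4A", "C5A"], ["C1B", "C2B", "C3B", "C4B"]],
        4,
    )
    reg["CHOL"] = LipidSpec(
        name="CHOL",
        headgroup_bead="ROH",
        bead_names=("ROH", "R1", "R2", "R3", "R4", "R5", "C1", "C2"),
        n_head_beads=1,
        n_tail_beads=7,
        n_tail_bonds=0,
        n_unsaturated_bonds=0,
        tails=(),
    )
    return reg


# outer / inner leaflet (fraction, count) of the reference asymmetric
# plasma-membrane model; the leaflets hold 1350 and 1348 lipids in total
PLASMA_MEMBRANE_TABLE = {
    "outer": {
        "POPC": (0.243, 328),
        "PAPC": (0.121, 163),
        "POPE": (0.020, 27),
        "DIPE": (0.061, 82),
        "DPSM": (0.242, 327),
        "PAPS": (0.000, 0),
        "PAP6": (0.000, 0),
        "CHOL": (0.313, 423),
    },
    "inner": {
        "POPC": (0.139, 187),
        "PAPC": (0.075, 101),
        "POPE": (0.054, 73),
        "DIPE": (0.161, 217),
        "DPSM": (0.108, 146),
        "PAPS": (0.161, 217),
        "PAP6": (0.022, 29),
        "CHOL": (0.280, 378),
    },
}


def _entries(table: dict[str, tuple[float, int]]) -> tuple[CompositionEntry, ...]:
    return tuple(
        CompositionEntry(species=s, fraction=f, count=c)
        for s, (f, c) in table.items()
    )


def plasma_membrane_composition() -> Composition:
    """Asymmetric reference composition (explicit counts: 1350 / 1348)."""
    return Composition(leaflets={
        "outer": _entries(PLASMA_MEMBRANE_TABLE["outer"]),
        "inner": _entries(PLASMA_MEMBRANE_TABLE["inner"]),
    })


def symmetric_composition() -> Composition:
    """Symmetric control: both leaflets carry the inner-leaflet composition."""
    inner = _entries(PLASMA_MEMBRANE_TABLE["inner"])
    return Composition(leaflets={"outer": inner, "inner": inner})
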