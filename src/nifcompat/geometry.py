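"""Inter-cofactor distances and interface salt-bridge analysis.

The central measurement is the edge-to-edge distance *R* (Å): the minimum
Euclidean distance between the designated edge atoms of the electron
carrier's cofactor and the Fe atoms of the Fe protein's [4Fe-4S] cluster.
Short R (≲10 Å) is the structural signature of a carrier that can sample
electron-transfer-competent orientations.

The salt-bridge census enumerates close-range electrostatic contacts
across the docking interface between Arg/Lys side chains on one protein
and Asp/Glu side chains on the other, and maps them onto the conserved
Fe-protein hotspot residues (R101, R140, E112, E69 in R. palustris
numbering). Histidine is excluded from the positive set (protonation
ambiguous at neutral pH) and backbone termini are not considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AtomRecord, DockedComplexModel, RedoxCofactor

__all__ = [
    "DistanceMeasurement",
    "SaltBridge",
    "HotspotContactReport",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
    "DEFAULT_HOTSPOTS",
    "POSITIVE_GROUP_ATOMS",
    "NEGATIVE_GROUP_ATOMS",
    "edge_to_edge_distance",
    "nearest_ligand_cofactor",
    "find_salt_bridges",
    "hotspot_contacts",
    "bridges_to_table",
]

logger = logging.getLogger(__name__)

#: Conventional crystallographic salt-bridge criterion between side-chain
#: charged-group heavy atoms, in Å.
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0

#: Conserved charged residues on the R. palustris Fe protein implicated in
#: carrier docking.
DEFAULT_HOTSPOTS = ("R101", "R140", "E112", "E69")

POSITIVE_GROUP_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
NEGATIVE_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

_ONE_LETTER = {"ARG": "R", "LYS": "K", "ASP": "D", "GLU": "E"}


@dataclass
class DistanceMeasurement:
    """An edge-to-edge distance R with the achieving atom pair."""

    R: float
    receptor_atom: AtomRecord
    ligand_atom: AtomRecord
    ligand_cofactor_kind: str
    model_index: int = 1


@dataclass
class SaltBridge:
    """One cross-interface charged-residue pair within the cutoff.

    ``carrier_residue`` and ``fe_protein_residue`` are (chain, number,
    name) triples; for the Fe protein the chain is the homodimer label
    ``a`` or ``b``. ``pair_distance`` is the closest distance between the
    two residues' charged-group heavy atoms.
    """

    carrier_residue: tuple[str, int, str]
    fe_protein_residue: tuple[str, int, str]
    pair_distance: float
    polarity: str  # "carrier_positive" | "carrier_negative"
    carrier_atom: str = ""
    fe_protein_atom: str = ""


@dataclass
class HotspotContactReport:
    """Salt bridges grouped by Fe-protein hotspot residue and chain label."""

    contacts: dict[tuple[str, str], list[SaltBridge]]
    not_present: set[str] = field(default_factory=set)


def edge_to_edge_distance(
    cofactor_a: RedoxCofactor, cofactor_b: RedoxCofactor, model_index: int = 1
) -> DistanceMeasurement:
    """Minimum distance over all cross pairs of edge atoms of two cofactors.

    Symmetric in its arguments (same R either way); the stored
    receptor/ligand atoms follow the argument order (first = receptor
    side by convention).
    """
    if not cofactor_a.edge_atoms or not cofactor_b.edge_atoms:
        raise ValueError("edge_to_edge_distance requires non-empty edge-atom sets")
    xa = np.array([a.xyz for a in cofactor_a.edge_atoms])
    xb = np.array([b.xyz for b in cofactor_b.edge_atoms])
    d = cdist(xa, xb)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return DistanceMeasurement(
        R=float(d[i, j]),
        receptor_atom=cofactor_a.edge_atoms[int(i)],
        ligand_atom=cofactor_b.edge_atoms[int(j)],
        ligand_cofactor_kind=cofactor_b.kind,
        model_index=model_index,
    )


def nearest_ligand_cofactor(
    model: DockedComplexModel,
) -> tuple[RedoxCofactor, DistanceMeasurement]:
    """The ligand cofactor closest to the receptor [4Fe-4S] cluster.

    Carriers with two clusters (2[4Fe-4S] ferredoxins) contribute the
    cluster nearest to the receptor. Exact ties break toward the lower
    parent residue number.
    """
    receptor = model.receptor_cluster
    best: tuple[float, int, RedoxCofactor, DistanceMeasurement] | None = None
    for cof in model.ligand_cofactors:
        meas = edge_to_edge_distance(receptor, cof, model_index=model.model_index)
        key = (meas.R, cof.parent_residue)
        if best is None or key < (best[0], best[1]):
            best = (meas.R, cof.parent_residue, cof, meas)
    assert best is not None  # guaranteed by DockedComplexModel invariant
    return best[2], best[3]


def _charged_residues(
    atoms: list[AtomRecord],
) -> dict[tuple[str, int, str], tuple[str, list[AtomRecord]]]:
    """Map (chain, resnum, resname) -> (sign, charged-group atoms)."""
    out: dict[tuple[str, int, str], tuple[str, list[AtomRecord]]] = {}
    for a in atoms:
        if a.residue_name in POSITIVE_GROUP_ATOMS:
            sign, names = "+", POSITIVE_GROUP_ATOMS[a.residue_name]
        elif a.residue_name in NEGATIVE_GROUP_ATOMS:
            sign, names = "-", NEGATIVE_GROUP_ATOMS[a.residue_name]
        else:
            continue
        if a.name not in names or a.element == "H":
            continue
        key = (a.chain_id, a.residue_number, a.residue_name)
        out.setdefault(key, (sign, []))[1].append(a)
    return out


def find_salt_bridges(
    model: DockedComplexModel, cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF
) -> list[SaltBridge]:
    """Enumerate cross-interface Arg/Lys ↔ Asp/Glu contacts within cutoff.

    One bridge is reported per residue pair (the closest atom pair is
    recorded even if several fall under the cutoff). The result is sorted
    by pair distance, ascending.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    carrier = _charged_residues(model.ligand_atoms)
    receptor = _charged_residues(model.receptor_atoms)
    bridges: list[SaltBridge] = []
    for ckey, (csign, catoms) in carrier.items():
        for rkey, (rsign, ratoms) in receptor.items():
            if csign == rsign:
                continue
            d = cdist(np.array([a.xyz for a in catoms]), np.array([a.xyz for a in ratoms]))
            i, j = np.unravel_index(np.argmin(d), d.shape)
            dist = float(d[i, j])
            if dist > cutoff:
                continue
            rchain, rnum, rname = rkey
            label = model.chain_labels.get(rchain, rchain)
            bridges.append(
                SaltBridge(
                    carrier_residue=ckey,
                    fe_protein_residue=(label, rnum, rname),
                    pair_distance=dist,
                    polarity="carrier_positive" if csign == "+" else "carrier_negative",
                    carrier_atom=catoms[int(i)].name,
                    fe_protein_atom=ratoms[int(j)].name,
                )
            )
    bridges.sort(key=lambda b: (b.pair_distance, b.carrier_residue, b.fe_protein_residue))
    return bridges


def _parse_hotspot(spec: str) -> tuple[str, int]:
    """'R101' -> ('R', 101)."""
    return spec[0].upper(), int(spec[1:])


def hotspot_contacts(
    bridges: list[SaltBridge],
    model: DockedComplexModel,
    hotspot_spec: tuple[str, ...] = DEFAULT_HOTSPOTS,
) -> HotspotContactReport:
    """Group salt bridges by the Fe-protein hotspot residue they touch.

    Bridges to non-hotspot receptor residues stay in the full census but
    do not appear in the report. A hotspot whose residue number (with the
    matching residue type) is absent from the receptor is flagged in
    ``not_present`` with a warning.
    """
    receptor_residues = {
        (a.residue_number, _ONE_LETTER.get(a.residue_name, "?")) for a in model.receptor_atoms
    }
    contacts: dict[tuple[str, str], list[SaltBridge]] = {}
    not_present: set[str] = set()
    labels = sorted(set(model.chain_labels.values()))
    for spec in hotspot_spec:
        letter, num = _parse_hotspot(spec)
        if (num, letter) not in receptor_residues:
            logger.warning("hotspot residue %s not present in receptor numbering", spec)
            not_present.add(spec)
        for lab in labels:
            contacts[(spec, lab)] = []
    for b in bridges:
        label, num, name = b.fe_protein_residue
        spec = f"{_ONE_LETTER.get(name, '?')}{num}"
        key = (spec, label)
        if key in contacts:
            contacts[key].append(b)
    return HotspotContactReport(contacts=contacts, not_present=not_present)


def bridges_to_table(bridges: list[SaltBridge]):
    """Salt-bridge census as a DataFrame (mirrors a per-pair bubble plot)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "carrier_residue": f"{b.carrier_residue[2]}{b.carrier_residue[1]}"
                f".{b.carrier_residue[0]}",
                "fe_residue": f"{b.fe_protein_residue[2]}{b.fe_protein_residue[1]}",
                "chain_label": b.fe_protein_residue[0],
                "pair_distance": round(b.pair_distance, 3),
                "polarity": b.polarity,
            }
            for b in bridges
        ],
        columns=["carrier_residue", "fe_residue", "chain_label", "pair_distance", "polarity"],
    )
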