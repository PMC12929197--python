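"""PDB structure I/O and redox-cofactor detection.

Reads and writes PDB-format text (via gemmi), identifies the
electron-carrying prosthetic groups relevant to nitrogenase electron
transfer — [4Fe-4S] (HET code SF4), [2Fe-2S] (FES), [3Fe-4S] (F3S)
clusters and flavin mononucleotide (FMN) — and splits a docked two-body
complex into its Fe-protein (receptor) and electron-carrier (ligand)
sides.

Distance measurements downstream operate on each cofactor's *edge atoms*:
the Fe atoms for iron-sulfur clusters, and the 14 heavy atoms of the
conjugated isoalloxazine ring system for FMN (the ribityl tail and
phosphate are not part of the electron conduit). Inorganic sulfurs can be
added to the FeS edge set with ``include_sulfur=True``; the default keeps
Fe only. Hydrogens are dropped on input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi

__all__ = [
    "AtomRecord",
    "RedoxCofactor",
    "DockedComplexModel",
    "PdbParseError",
    "StructureError",
    "COFACTOR_CODES",
    "FMN_RING_ATOMS",
    "parse_structure",
    "find_cofactors",
    "split_receptor_ligand",
    "write_structure",
]

logger = logging.getLogger(__name__)


class PdbParseError(ValueError):
    """Raised when PDB text cannot be parsed."""


class StructureError(ValueError):
    """Raised when a structure violates a cofactor or complex invariant."""


#: HET residue codes recognized as redox cofactors, mapped to cofactor kinds.
COFACTOR_CODES = {"SF4": "FE4S4", "FES": "FE2S2", "F3S": "FE3S4", "FMN": "FMN"}

#: Required iron stoichiometry per FeS cofactor kind.
_FE_COUNT = {"FE4S4": 4, "FE2S2": 2, "FE3S4": 3}

#: Heavy atoms of the FMN isoalloxazine ring system (carbonyl oxygens,
#: methyls, ribityl chain and phosphate excluded).
FMN_RING_ATOMS = frozenset(
    ["N1", "C2", "N3", "C4", "C4A", "N5", "C5A", "C6", "C7", "C8", "C9", "C9A", "N10", "C10"]
)

_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class AtomRecord:
    """One heavy atom from an ATOM/HETATM record."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: tuple[float, float, float]
    element: str

    def __post_init__(self) -> None:
        if not all(abs(c) < 1e6 and c == c for c in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.serial}")


@dataclass
class RedoxCofactor:
    """An electron-carrying prosthetic group with its designated edge atoms."""

    kind: str
    residue_name: str
    atoms: list[AtomRecord]
    edge_atoms: list[AtomRecord]
    parent_chain: str
    parent_residue: int

    def __post_init__(self) -> None:
        if any(e not in self.atoms for e in self.edge_atoms):
            raise ValueError("edge_atoms must be a subset of atoms")


@dataclass
class DockedComplexModel:
    """One receptor+ligand docking pose with cofactors partitioned by side.

    The Fe protein is a homodimer; its two chains are labeled ``a`` and
    ``b`` in ascending chain-id order (an arbitrary but deterministic
    convention).
    """

    model_index: int
    receptor_chains: tuple[str, ...]
    ligand_chains: tuple[str, ...]
    receptor_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    receptor_cofactors: list[RedoxCofactor]
    ligand_cofactors: list[RedoxCofactor]
    chain_labels: dict[str, str] = field(default_factory=dict)

    @property
    def receptor_cluster(self) -> RedoxCofactor:
        """The receptor's [4Fe-4S] cluster (exactly one by construction)."""
        return next(c for c in self.receptor_cofactors if c.kind == "FE4S4")


def _validate_coordinate_fields(pdb_text: str) -> None:
    # gemmi silently zero-fills malformed coordinate columns; report them.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM") and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PdbParseError(
                        f"malformed coordinate field {line[lo:hi]!r} on line {lineno}"
                    ) from None


def parse_structure(pdb_text: str) -> list[list[AtomRecord]]:
    """Parse PDB text into per-model lists of heavy-atom records.

    Multi-model files (MODEL/ENDMDL) yield one atom list per model. For
    alternate locations only the first altloc encountered per atom name is
    kept; hydrogens and waters are discarded.

    Raises
    ------
    PdbParseError
        On empty input or malformed coordinate fields (the offending line
        number is named).
    """
    if not pdb_text.strip():
        raise PdbParseError("empty PDB input")
    _validate_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PdbParseError(str(exc)) from exc

    models: list[list[AtomRecord]] = []
    for model in st:
        atoms: list[AtomRecord] = []
        for chain in model:
            for residue in chain:
                if residue.name == "HOH":
                    continue
                seen: set[str] = set()
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    if atom.name in seen:
                        continue  # later altloc of an atom already kept
                    seen.add(atom.name)
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            residue_name=residue.name,
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                            element=atom.element.name.upper(),
                        )
                    )
        if atoms:
            models.append(atoms)
    if not models:
        raise PdbParseError("no ATOM/HETATM records found")
    return models


def find_cofactors(atoms: list[AtomRecord], include_sulfur: bool = False) -> list[RedoxCofactor]:
    """Detect redox cofactors among the HET residues of one model.

    Every residue whose name is a recognized cofactor code (SF4, FES, F3S,
    FMN) yields one :class:`RedoxCofactor` with its edge atoms populated:
    Fe atoms for FeS clusters (optionally plus inorganic S), the
    isoalloxazine ring atoms for FMN. Unrecognized HET residues are
    ignored. Detection is independent of atom order within a residue.

    Raises
    ------
    StructureError
        If a recognized FeS code lacks its full iron complement, or an FMN
        is missing its ring atoms.
    """
    by_residue: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for a in atoms:
        if a.residue_name in COFACTOR_CODES:
            by_residue.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)

    cofactors: list[RedoxCofactor] = []
    for (chain_id, resnum, resname), group in sorted(
        by_residue.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        kind = COFACTOR_CODES[resname]
        if kind == "FMN":
            edge = [a for a in group if a.name in FMN_RING_ATOMS]
            if len(edge) < 10:
                raise StructureError(
                    f"FMN {chain_id}/{resnum}: only {len(edge)} isoalloxazine ring atoms found"
                )
        else:
            fe = [a for a in group if a.element == "FE"]
            if len(fe) != _FE_COUNT[kind]:
                raise StructureError(
                    f"{resname} {chain_id}/{resnum}: expected {_FE_COUNT[kind]} Fe atoms, "
                    f"found {len(fe)}"
                )
            edge = list(fe)
            if include_sulfur:
                edge += [a for a in group if a.element == "S"]
        cofactors.append(
            RedoxCofactor(
                kind=kind,
                residue_name=resname,
                atoms=group,
                edge_atoms=edge,
                parent_chain=chain_id,
                parent_residue=resnum,
            )
        )
    return cofactors


def split_receptor_ligand(
    atoms: list[AtomRecord],
    receptor_chain_ids: set[str] | list[str] | tuple[str, ...],
    model_index: int = 1,
    include_sulfur: bool = False,
) -> DockedComplexModel:
    """Partition one docked model into Fe-protein and carrier sides.

    Cofactors are assigned to the side owning their parent chain. The
    receptor must carry exactly one [4Fe-4S] cluster; the ligand must
    carry at least one cofactor of any kind.
    """
    receptor_ids = tuple(sorted(receptor_chain_ids))
    chain_ids = {a.chain_id for a in atoms}
    missing = set(receptor_ids) - chain_ids
    if missing:
        raise StructureError(f"receptor chains not in structure: {sorted(missing)}")

    rec_atoms = [a for a in atoms if a.chain_id in receptor_ids]
    lig_atoms = [a for a in atoms if a.chain_id not in receptor_ids]
    rec_cof = find_cofactors(rec_atoms, include_sulfur=include_sulfur)
    lig_cof = find_cofactors(lig_atoms, include_sulfur=include_sulfur)

    n_rec_fe4s4 = sum(1 for c in rec_cof if c.kind == "FE4S4")
    if n_rec_fe4s4 != 1:
        raise StructureError(
            f"receptor cluster missing: expected one FE4S4 on the receptor side, "
            f"found {n_rec_fe4s4}"
        )
    if not lig_cof:
        raise StructureError("ligand carries no recognized redox cofactor")

    # homodimer chains labeled a/b in ascending chain-id order
    labels = {cid: lab for cid, lab in zip(receptor_ids, "abcdefgh")}
    return DockedComplexModel(
        model_index=model_index,
        receptor_chains=receptor_ids,
        ligand_chains=tuple(sorted(chain_ids - set(receptor_ids))),
        receptor_atoms=rec_atoms,
        ligand_atoms=lig_atoms,
        receptor_cofactors=rec_cof,
        ligand_cofactors=lig_cof,
        chain_labels=labels,
    )


def write_structure(atoms: list[AtomRecord]) -> str:
    """Serialize atom records to PDB-format text.

    Residues with non-standard names are written as HETATM. The output
    round-trips through :func:`parse_structure` with coordinates preserved
    to 3 decimals.
    """
    for a in atoms:
        if any(abs(c) >= 10000 for c in a.xyz):
            raise ValueError(
                f"coordinate of atom {a.serial} overflows the fixed-width PDB field"
            )
    # group first; gemmi's add_residue/add_chain copy their argument, so
    # containers must be fully built bottom-up before insertion
    grouped: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for a in atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []
        ).append(a)

    st = gemmi.Structure()
    model = gemmi.Model(1)
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (resnum, resname), group in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "A" if resname in _STANDARD_RESIDUES else "H"
            for a in group:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.serial = a.serial
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.make_pdb_string()
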