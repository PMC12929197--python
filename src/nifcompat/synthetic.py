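"""Synthetic docked-complex and cohort generators.

Produces two-body pseudo-complexes in PDB format that stand in for
protein-protein docking output: a homodimeric receptor (two short
poly-alanine chains plus one [4Fe-4S] cluster) and a carrier ligand chain
holding the requested cofactor, built so that

* the minimum edge-to-edge cofactor distance equals ``target_R`` to
  within 1 mÅ after PDB serialization,
* exactly ``n_bridges`` Arg/Lys ↔ Glu/Asp cross-interface contacts sit at
  ``bridge_distance``, each isolated from the others by wide spacing, and
* optional decoy charged pairs sit safely beyond the census cutoff.

Geometry trick: the receptor cluster is placed near the origin and the
ligand cofactor is translated along +x so that its minimum-x edge atom
lands exactly ``target_R`` away from the maximum-x receptor Fe at
identical y/z. Every other cross pair then has an x-separation of at
least ``target_R`` plus a strictly positive y/z offset, so the planted
pair is the unique minimizer. All contractual coordinates are laid on a
3-decimal grid so fixed-width PDB output does not round them.

Protein bodies are minimal poly-alanine scaffolds with grafted charged
residues: downstream geometry needs only atoms, not plausible folds,
which keeps fixtures tiny and exactly controllable. Cofactor internal
geometries are idealized (cubane [4Fe-4S] with ~2.7 Å Fe-Fe edges, planar
[2Fe-2S], planar three-ring isoalloxazine); only the inter-cofactor
minimum distance is contractual.

Cohort generation plants the group structure of a carrier screen: short
distances for nif-linked carriers, intermediate for other bacterial
carriers, long for plant ferredoxins, with a linear distance-activity
law for regression recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import geometry, structure_io
from .structure_io import AtomRecord

__all__ = [
    "ComplexSpec",
    "CohortSpec",
    "CohortResult",
    "GenerationError",
    "make_toy_complex",
    "make_cohort",
]


class GenerationError(RuntimeError):
    """Raised when a spec is geometrically unsatisfiable or validation fails."""


@dataclass(frozen=True)
class ComplexSpec:
    """Ground-truth recipe for one synthetic docked complex."""

    target_R: float
    ligand_cofactor_kind: str = "FE4S4"
    n_extra_ligand_cofactors: int = 0
    n_bridges: int = 0
    bridge_distance: float = 3.5
    decoy_charged_pairs: int = 0
    cutoff: float = geometry.DEFAULT_SALT_BRIDGE_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_R <= 0:
            raise GenerationError("target_R must be positive")
        if self.ligand_cofactor_kind not in ("FE4S4", "FE2S2", "FMN"):
            raise GenerationError(f"unsupported cofactor kind {self.ligand_cofactor_kind!r}")
        if not 0 < self.bridge_distance < self.cutoff:
            raise GenerationError(
                "bridge_distance must be positive and below the salt-bridge cutoff"
            )
        if min(self.n_extra_ligand_cofactors, self.n_bridges, self.decoy_charged_pairs) < 0:
            raise GenerationError("counts must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic carrier cohort with planted group structure.

    Distances are per-role normal draws truncated to [4, 19.5] Å (above
    van-der-Waals contact, below the point where the activity law would
    clip at zero). Activity follows max(0, a + b·R + noise).
    """

    n_nif: int = 8
    n_non_nif: int = 8
    n_plant: int = 11
    distance_means: tuple[float, float, float] = (8.5, 12.0, 15.5)
    distance_sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    potential_means: tuple[float, float, float] = (-430.0, -400.0, -370.0)
    potential_sds: tuple[float, float, float] = (60.0, 80.0, 50.0)
    bridges_per_role: tuple[int, int, int] = (3, 1, 0)
    activity_intercept: float = 160.0
    activity_slope: float = -8.0
    activity_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.distance_sds + self.potential_sds) or (
            self.activity_noise_sd < 0
        ):
            raise GenerationError("standard deviations must be non-negative")


@dataclass
class CohortResult:
    """Carrier table, per-carrier complex PDBs, and the ground-truth manifest."""

    carriers_tsv: str
    complexes: dict[str, list[str]]
    manifest: dict


# ---------------------------------------------------------------- cofactors

_R3 = lambda v: round(v, 3)  # noqa: E731  - everything contractual sits on this grid


def _sf4_atoms(chain: str, resnum: int) -> list[AtomRecord]:
    """Idealized cubane [4Fe-4S]: Fe-Fe edges 2.701 Å, centered at origin."""
    h = 0.955
    fe = [(-h, -h, -h), (h, h, -h), (h, -h, h), (-h, h, h)]
    s = [(h, -h, -h), (-h, h, -h), (-h, -h, h), (h, h, h)]
    atoms = []
    for i, p in enumerate(fe, 1):
        atoms.append(AtomRecord(0, f"FE{i}", "SF4", chain, resnum, p, "FE"))
    for i, p in enumerate(s, 1):
        atoms.append(AtomRecord(0, f"S{i}", "SF4", chain, resnum, p, "S"))
    return atoms


def _fes_atoms(chain: str, resnum: int) -> list[AtomRecord]:
    """Idealized planar [2Fe-2S] rhombus."""
    coords = [("FE1", (-1.35, 0.0, 0.0), "FE"), ("FE2", (1.35, 0.0, 0.0), "FE"),
              ("S1", (0.0, 1.1, 0.0), "S"), ("S2", (0.0, -1.1, 0.0), "S")]
    return [AtomRecord(0, n, "FES", chain, resnum, p, e) for n, p, e in coords]


_FMN_RING_NAME_ORDER = (
    # assigned to the 14 fused-ring vertices sorted by (x, y)
    "N1", "C2", "N3", "C4", "C10", "C4A", "N10", "N5", "C9A", "C5A",
    "C9", "C6", "C8", "C7",
)


def _fmn_atoms(chain: str, resnum: int) -> list[AtomRecord]:
    """Planar three-ring isoalloxazine skeleton (plus carbonyl O and methyls)."""
    L = 1.4
    centers = [(0.0, 0.0), (L * math.sqrt(3), 0.0), (2 * L * math.sqrt(3), 0.0)]
    verts: dict[tuple[float, float], None] = {}
    for cx, cy in centers:
        for k in range(6):
            ang = math.radians(30 + 60 * k)
            verts[(_R3(cx + L * math.cos(ang)), _R3(cy + L * math.sin(ang)))] = None
    ordered = sorted(verts)  # 14 unique vertices
    atoms = [
        AtomRecord(0, name, "FMN", chain, resnum, (x, y, 0.0), name[0])
        for name, (x, y) in zip(_FMN_RING_NAME_ORDER, ordered)
    ]
    by_name = {a.name: a for a in atoms}
    for parent, child, dy in (("C2", "O2", 1.23), ("C4", "O4", 1.23),
                              ("C7", "C7M", 1.5), ("C8", "C8M", 1.5)):
        px, py, _ = by_name[parent].xyz
        off = dy if py >= 0 else -dy
        atoms.append(
            AtomRecord(0, child, "FMN", chain, resnum, (px, _R3(py + off), 0.0), child[0])
        )
    return atoms


_COFACTOR_BUILDERS = {"FE4S4": _sf4_atoms, "FE2S2": _fes_atoms, "FMN": _fmn_atoms}
_EDGE_NAMES = {
    "FE4S4": lambda a: a.element == "FE",
    "FE2S2": lambda a: a.element == "FE",
    "FMN": lambda a: a.name in structure_io.FMN_RING_ATOMS,
}


def _translate(atoms: list[AtomRecord], t: tuple[float, float, float]) -> list[AtomRecord]:
    return [
        AtomRecord(
            a.serial, a.name, a.residue_name, a.chain_id, a.residue_number,
            (_R3(a.xyz[0] + t[0]), _R3(a.xyz[1] + t[1]), _R3(a.xyz[2] + t[2])),
            a.element,
        )
        for a in atoms
    ]


def _place_ligand_cofactor(
    template: list[AtomRecord], anchor: tuple[float, float, float], offset_x: float
) -> list[AtomRecord]:
    """Translate so the template's min-x edge atom sits at anchor + (offset_x, 0, 0)."""
    kind = structure_io.COFACTOR_CODES[template[0].residue_name]
    edge = [a for a in template if _EDGE_NAMES[kind](a)]
    q = min(edge, key=lambda a: a.xyz)
    t = (
        anchor[0] + offset_x - q.xyz[0],
        anchor[1] - q.xyz[1],
        anchor[2] - q.xyz[2],
    )
    return _translate(template, t)


# ------------------------------------------------------------- protein bits

_ALA_OFFSETS = (
    ("N", (-0.5, -1.2, 0.3)), ("CA", (0.0, 0.0, 0.0)), ("C", (1.2, 0.8, 0.0)),
    ("O", (1.3, 2.0, 0.2)), ("CB", (-1.0, 0.7, 1.1)),
)


def _poly_ala(chain: str, start_res: int, n: int, origin: tuple[float, float, float],
              rng: np.random.Generator) -> list[AtomRecord]:
    atoms = []
    for i in range(n):
        base = (
            origin[0] + float(rng.normal(0, 0.25)),
            origin[1] + 3.8 * i,
            origin[2] + float(rng.normal(0, 0.25)),
        )
        for name, (dx, dy, dz) in _ALA_OFFSETS:
            atoms.append(
                AtomRecord(
                    0, name, "ALA", chain, start_res + i,
                    (_R3(base[0] + dx), _R3(base[1] + dy), _R3(base[2] + dz)), name[0],
                )
            )
    return atoms


# dx > 0 points away from the interface; direction = +1 on the carrier side
# (away is +x), -1 on the receptor side. The first listed side-chain atom is
# the primary charged atom, placed exactly at the anchor; every other atom
# retreats from the partner so the planted pair is the closest one.
_SIDECHAIN = {
    "ARG": (("NH1", (0.0, 0.0, 0.0)), ("NH2", (0.5, 1.0, 0.0)), ("NE", (1.2, -0.6, 0.4)),
            ("CZ", (0.6, 0.3, 0.2)), ("CD", (2.4, -0.9, 0.6)), ("CG", (3.6, -0.5, 0.3))),
    "LYS": (("NZ", (0.0, 0.0, 0.0)), ("CE", (1.3, 0.4, 0.2)), ("CD", (2.5, -0.3, 0.1)),
            ("CG", (3.7, 0.2, 0.4))),
    "GLU": (("OE1", (0.0, 0.0, 0.0)), ("OE2", (0.7, -1.1, 0.0)), ("CD", (1.0, 0.2, 0.3)),
            ("CG", (2.3, 0.5, 0.1))),
    "ASP": (("OD1", (0.0, 0.0, 0.0)), ("OD2", (0.7, -1.1, 0.0)), ("CB", (1.9, 0.6, 0.2))),
}
_BACKBONE = (("N", (5.0, -0.8, 0.5)), ("CA", (4.2, 0.2, 0.0)), ("C", (3.4, 1.3, 0.4)),
             ("O", (3.5, 2.5, 0.3)))


def _charged_residue(
    chain: str, resnum: int, resname: str, anchor: tuple[float, float, float], direction: int
) -> list[AtomRecord]:
    """A grafted charged residue whose primary charged atom sits exactly at anchor."""
    atoms = []
    for name, (dx, dy, dz) in _BACKBONE + _SIDECHAIN[resname]:
        atoms.append(
            AtomRecord(
                0, name, resname, chain, resnum,
                (_R3(anchor[0] + direction * dx), _R3(anchor[1] + dy), _R3(anchor[2] + dz)),
                name[0],
            )
        )
    return atoms


_HOTSPOT_CYCLE = (("A", 101, "ARG"), ("B", 112, "GLU"), ("A", 140, "ARG"), ("B", 69, "GLU"))
_PARTNER_CHOICES = {"ARG": ("GLU", "ASP"), "GLU": ("LYS", "ARG"), "ASP": ("LYS", "ARG")}


# ------------------------------------------------------------------ builder

def make_toy_complex(spec: ComplexSpec) -> tuple[str, dict]:
    """Emit one synthetic docked complex as PDB text plus its manifest.

    Deterministic: the same spec yields byte-identical output. The emitted
    structure is re-measured before return; any contract violation raises
    :class:`GenerationError`.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []

    receptor_sf4 = _sf4_atoms("A", 301)
    p = max((a for a in receptor_sf4 if a.element == "FE"), key=lambda a: a.xyz)

    # receptor scaffolds, well away from the interface
    chain_a = _poly_ala("A", 1, 8, (-9.0, -16.0, 4.0), rng)
    chain_b = _poly_ala("B", 1, 8, (-9.0, -16.0, -4.0), rng)

    # ligand cofactors
    builder = _COFACTOR_BUILDERS[spec.ligand_cofactor_kind]
    ligand_cofactors = [_place_ligand_cofactor(builder("C", 201), p.xyz, spec.target_R)]
    for i in range(spec.n_extra_ligand_cofactors):
        extra = builder("C", 202 + i)
        extra = _place_ligand_cofactor(extra, p.xyz, spec.target_R + 6.0 * (i + 1))
        extra = _translate(extra, (0.0, 4.0 * (i + 1), 0.0))
        ligand_cofactors.append(extra)

    chain_c = _poly_ala("C", 1, 8, (p.xyz[0] + spec.target_R + 9.0, -16.0, 6.0), rng)

    # salt bridges: isolated lanes 14 Å apart in y
    bridges_truth = []
    carrier_extra: list[AtomRecord] = []
    receptor_extra: list[AtomRecord] = []
    xm = _R3(p.xyz[0] + spec.target_R / 2.0 - spec.bridge_distance / 2.0)
    for i in range(spec.n_bridges):
        if i < len(_HOTSPOT_CYCLE):
            rchain, rnum, rname = _HOTSPOT_CYCLE[i]
        else:
            rchain, rnum, rname = ("A", 150 + i, "ARG" if i % 2 else "GLU")
        cname = _PARTNER_CHOICES[rname][int(rng.integers(2))]
        y = 24.0 + 14.0 * i
        receptor_extra += _charged_residue(rchain, rnum, rname, (xm, y, 0.0), -1)
        carrier_extra += _charged_residue(
            "C", 50 + i, cname, (_R3(xm + spec.bridge_distance), y, 0.0), +1
        )
        bridges_truth.append(
            {
                "fe_protein_residue": [{"A": "a", "B": "b"}[rchain], rnum, rname],
                "carrier_residue": ["C", 50 + i, cname],
                "distance": spec.bridge_distance,
            }
        )

    # decoy charged pairs: beyond the cutoff, on isolated negative-y lanes
    decoy_sep = _R3(spec.cutoff + 1.5)
    for i in range(spec.decoy_charged_pairs):
        y = -24.0 - 14.0 * i
        rname = "GLU" if i % 2 else "ARG"
        cname = _PARTNER_CHOICES[rname][int(rng.integers(2))]
        receptor_extra += _charged_residue("B", 160 + i, rname, (xm, y, 0.0), -1)
        carrier_extra += _charged_residue("C", 80 + i, cname, (_R3(xm + decoy_sep), y, 0.0), +1)

    # receptor charged residues belong to chains A/B; splice by chain
    atoms = (
        chain_a + [a for a in receptor_extra if a.chain_id == "A"] + receptor_sf4
        + chain_b + [a for a in receptor_extra if a.chain_id == "B"]
        + chain_c + carrier_extra
    )
    for cof in ligand_cofactors:
        atoms += cof
    for serial, a in enumerate(atoms, 1):
        a.serial = serial

    pdb_text = structure_io.write_structure(atoms)
    manifest = {
        "spec": asdict(spec),
        "target_R": spec.target_R,
        "ligand_cofactor_kind": spec.ligand_cofactor_kind,
        "n_ligand_cofactors": 1 + spec.n_extra_ligand_cofactors,
        "n_bridges": spec.n_bridges,
        "bridges": bridges_truth,
        "decoy_charged_pairs": spec.decoy_charged_pairs,
        "receptor_chains": ["A", "B"],
        "ligand_chain": "C",
    }
    _validate_complex(pdb_text, spec)
    return pdb_text, manifest


def _validate_complex(pdb_text: str, spec: ComplexSpec) -> None:
    """Re-measure the emitted structure against its own ground truth."""
    model = structure_io.split_receptor_ligand(
        structure_io.parse_structure(pdb_text)[0], {"A", "B"}
    )
    cof, meas = geometry.nearest_ligand_cofactor(model)
    if abs(meas.R - spec.target_R) > 1e-3:
        raise GenerationError(
            f"generated complex measures R={meas.R:.4f}, wanted {spec.target_R}"
        )
    if cof.parent_residue != 201:
        raise GenerationError("an extra ligand cofactor became the nearest cluster")
    n_found = len(geometry.find_salt_bridges(model, cutoff=spec.cutoff))
    if n_found != spec.n_bridges:
        raise GenerationError(
            f"generated complex has {n_found} salt bridges, wanted {spec.n_bridges}"
        )


# ------------------------------------------------------------------ cohorts

_ROLE_IDS = {"nif": "nifFd", "non_nif_bacterial": "bacFd", "plant": "pltFd"}
_ROLE_KINDS = {
    "nif": ("FE4S4", "FE4S4", "FMN"),
    "non_nif_bacterial": ("FE2S2", "FE4S4"),
    "plant": ("FE2S2",),
}


def make_cohort(spec: CohortSpec, emit_structures: bool = True) -> CohortResult:
    """Generate a synthetic carrier cohort with planted group structure.

    Each carrier gets three docking poses (mirroring a top-3 docking
    selection) whose distances are drawn from its role's distribution.
    With ``emit_structures=False`` only the carrier table and manifest are
    produced (regression-recovery studies do not need the PDB bodies).
    """
    rng = np.random.default_rng(spec.seed)
    roles = ("nif", "non_nif_bacterial", "plant")
    counts = (spec.n_nif, spec.n_non_nif, spec.n_plant)

    rows = []
    complexes: dict[str, list[str]] = {}
    truth: list[dict] = []
    for role_i, (role, n) in enumerate(zip(roles, counts)):
        mu, sd = spec.distance_means[role_i], spec.distance_sds[role_i]
        pmu, psd = spec.potential_means[role_i], spec.potential_sds[role_i]
        n_bridges = spec.bridges_per_role[role_i]
        for k in range(n):
            cid = f"{_ROLE_IDS[role]}{k + 1:02d}"
            kind = _ROLE_KINDS[role][k % len(_ROLE_KINDS[role])]
            dists = []
            while len(dists) < 3:
                d = float(rng.normal(mu, sd))
                if 4.0 <= d <= 19.5:
                    dists.append(round(d, 3))
            pot1 = round(float(rng.normal(pmu, psd)), 1)
            pots = [pot1]
            if kind == "FE4S4" and rng.integers(2):  # 2[4Fe-4S] carrier, distinct clusters
                pots.append(round(pot1 - float(rng.uniform(50, 250)), 1))
            mean_r = float(np.mean(dists))
            activity = max(
                0.0,
                spec.activity_intercept
                + spec.activity_slope * mean_r
                + float(rng.normal(0.0, spec.activity_noise_sd)),
            )
            rows.append(
                {
                    "carrier_id": cid,
                    "organism": f"synthetic sp. {cid}",
                    "role_class": role,
                    "potential_mv_1": max(pots),
                    "potential_mv_2": min(pots) if len(pots) == 2 else "",
                    "activity": round(activity, 3),
                }
            )
            truth.append(
                {
                    "carrier_id": cid,
                    "role_class": role,
                    "cofactor_kind": kind,
                    "planted_distances": dists,
                    "planted_mean_R": round(mean_r, 4),
                    "potentials_mV": pots,
                    "activity": round(activity, 3),
                    "n_bridges": n_bridges,
                }
            )
            if emit_structures:
                complexes[cid] = [
                    make_toy_complex(
                        ComplexSpec(
                            target_R=d,
                            ligand_cofactor_kind=kind,
                            n_extra_ligand_cofactors=1 if kind == "FE4S4" and len(pots) == 2 else 0,
                            n_bridges=n_bridges,
                            seed=int(rng.integers(2**31)),
                        )
                    )[0]
                    for d in dists
                ]

    header = "carrier_id\torganism\trole_class\tpotential_mv_1\tpotential_mv_2\tactivity"
    lines = [header] + [
        "\t".join(str(r[c]) for c in header.split("\t")) for r in rows
    ]
    manifest = {
        "spec": asdict(spec),
        "roles": {r: c for r, c in zip(roles, counts)},
        "activity_model": {
            "intercept": spec.activity_intercept,
            "slope": spec.activity_slope,
            "noise_sd": spec.activity_noise_sd,
        },
        "carriers": truth,
    }
    return CohortResult(
        carriers_tsv="\n".join(lines) + "\n",
        complexes=complexes,
        manifest=manifest,
    )


def manifest_to_json(manifest: dict) -> str:
    """Deterministic JSON form of a generator manifest."""
    return json.dumps(manifest, indent=2, sort_keys=False)
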