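"""Protein structure model, PDB input/output and deterministic toy structures.

The data model is deliberately small: heavy atoms with coordinates, van der
Waals radii and a side-chain flag, grouped into residues that keep the author
numbering of the source file (active sites in the literature are specified in
author numbering, so it is never renumbered).

Hydrogens are ignored everywhere: the accessible-surface machinery downstream
is heavy-atom based, matching how relative side-chain accessibility is
conventionally defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "BACKBONE_ATOMS",
    "STANDARD_RESIDUES",
    "load_structure",
    "write_pdb",
    "detect_disulfides",
    "generate_toy_structure",
]

# NACCESS-style single radius set; overridable via the `radii` argument of the
# SASA routines. Radius choice shifts absolute areas by a few percent but
# cancels in relative accessibilities computed with the same set.
VDW_RADII: dict[str, float] = {"C": 1.76, "N": 1.65, "O": 1.40, "S": 1.85}
DEFAULT_RADIUS: float = 1.80

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def vdw_radius(element: str, radii: dict[str, float] | None = None) -> float:
    """Van der Waals radius for an element symbol (case-insensitive)."""
    table = VDW_RADII if radii is None else radii
    return table.get(element.upper(), DEFAULT_RADIUS)


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    radius: float
    is_sidechain: bool = False
    het_flag: bool = False
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if self.radius <= 0:
            raise ValueError(f"atom {self.name!r}: radius must be positive")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_code: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_code in STANDARD_RESIDUES

    @property
    def is_het(self) -> bool:
        return any(a.het_flag for a in self.atoms)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> list[Atom]:
        """Non-backbone heavy atoms; for glycine the CA stands in, so every
        residue has a defined side-chain proxy."""
        sc = [a for a in self.atoms if a.is_sidechain]
        if not sc and self.res_code == "GLY":
            ca = self.atom("CA")
            if ca is not None:
                sc = [ca]
        return sc

    def __repr__(self) -> str:
        icode = self.insertion_code.strip() or ""
        return f"<Residue {self.res_code} {self.chain_id}:{self.seq_number}{icode}>"


@dataclass
class Structure:
    residues: list[Residue]
    model_id: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_number, insertion_code) residue keys")

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        """(N, 3) array of all heavy-atom coordinates."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.coord for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard and not r.is_het]

    def get_residue(self, chain_id: str, seq_number: int, insertion_code: str = " ") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, seq_number, insertion_code):
                return r
        valid = ", ".join(f"{r.chain_id}:{r.seq_number}{r.insertion_code.strip()}" for r in self.residues)
        raise KeyError(
            f"no residue {chain_id}:{seq_number}{insertion_code.strip()}; valid numbering: {valid}"
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            atoms = [
                Atom(a.name, a.element, rotation @ a.coord + translation, a.radius,
                     a.is_sidechain, a.het_flag, a.bfactor)
                for a in r.atoms
            ]
            new_res.append(Residue(r.chain_id, r.seq_number, r.insertion_code, r.res_code, atoms))
        return Structure(new_res, self.model_id, self.source_id)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def load_structure(
    path: str | Path,
    model_index: int = 0,
    keep_het: bool = False,
    radii: dict[str, float] | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    The selected model (first by default) is used; hydrogens and deuteriums
    are dropped; alternate locations resolve to the highest-occupancy
    conformer; water is always discarded. Non-water HETATM groups are kept
    only when ``keep_het`` is true — they act as steric bodies downstream and
    are never scored for affinity.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise ValueError(f"{path}: file contains no models")
    if model_index >= len(models):
        raise ValueError(f"{path}: model index {model_index} out of range ({len(models)} models)")
    model = models[model_index]

    residues: list[Residue] = []
    for chain in model:
        for bio_res in chain:
            hetfield, seq, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            is_het = hetfield.strip() != ""
            if resname in _WATER_NAMES or hetfield == "W":
                continue
            if is_het and not keep_het:
                continue
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                # DisorderedAtom iteration yields the highest-occupancy altloc
                # through Biopython's selected-child mechanism.
                element = (bio_atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                name = bio_atom.get_name().strip()
                atoms.append(
                    Atom(
                        name=name,
                        element=element or name[:1],
                        coord=np.array(bio_atom.get_coord(), dtype=float),
                        radius=vdw_radius(element or name[:1], radii),
                        is_sidechain=(name not in BACKBONE_ATOMS) and not is_het
                        and resname in STANDARD_RESIDUES,
                        het_flag=is_het,
                        bfactor=float(bio_atom.get_bfactor() or 0.0),
                    )
                )
            if atoms:
                residues.append(Residue(chain.id, seq, icode, resname, atoms))

    if not residues:
        raise ValueError(f"{path}: no residues after filtering")
    structure = Structure(residues, model_id=model_index, source_id=path.stem)
    if not structure.standard_residues() and not keep_het:
        raise ValueError(f"{path}: no standard residues")
    if not structure.standard_residues():
        warnings.warn(f"{path}: no standard residues (hetero groups only)", stacklevel=2)
    return structure


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure back out as fixed-width PDB ATOM/HETATM records."""
    lines = []
    serial = 1
    for res in structure.residues:
        for atom in res.atoms:
            record = "HETATM" if atom.het_flag else "ATOM  "
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"{record}{serial:>5d} {name:<4.4s} {res.res_code:<3.3s} "
                f"{res.chain_id:1.1s}{res.seq_number:>4d}{res.insertion_code:1.1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}          "
                f"{atom.element:>2.2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Disulfide detection
# ---------------------------------------------------------------------------

def detect_disulfides(structure: Structure, sg_cutoff: float = 2.5) -> list[tuple[Residue, Residue]]:
    """Pair up cysteines whose SG–SG distance is within ``sg_cutoff`` Å.

    Greedy nearest-first matching: the closest SG pair is bonded first, then
    the next closest among unpaired cysteines, so each CYS joins at most one
    bridge. Returns an empty list when there are no cysteines.
    """
    cys = [(r, r.atom("SG")) for r in structure.residues if r.res_code == "CYS"]
    cys = [(r, sg) for r, sg in cys if sg is not None]
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1].coord - cys[j][1].coord))
            if d <= sg_cutoff:
                candidates.append((d, i, j))
    candidates.sort(key=lambda t: t[0])
    paired: set[int] = set()
    pairs: list[tuple[Residue, Residue]] = []
    for _, i, j in candidates:
        if i in paired or j in paired:
            continue
        paired.update((i, j))
        a, b = cys[i][0], cys[j][0]
        pairs.append((a, b) if a.key <= b.key else (b, a))
    pairs.sort(key=lambda p: (p[0].key, p[1].key))
    return pairs


# ---------------------------------------------------------------------------
# Deterministic toy structures
# ---------------------------------------------------------------------------

# Idealized backbone geometry (lengths in Å, angles in degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d from a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(angle),
        length * math.sin(angle) * math.cos(torsion),
        length * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(torsions: Sequence[tuple[float, float]], omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with given (phi, psi) per residue."""
    n_res = len(torsions)
    frames: list[dict[str, np.ndarray]] = []
    # Seed the first three atoms in a canonical pose.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    frames.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        _, psi_prev = torsions[i - 1]
        phi_i, _ = torsions[i]
        prev = frames[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_i)
        frames.append({"N": n_i, "CA": ca_i, "C": c_i})
    # Carbonyl oxygens: in the peptide plane, trans to the next N (or to the
    # chain direction for the C-terminal residue).
    for i, frame in enumerate(frames):
        if i + 1 < len(frames):
            torsion = _dihedral(frame["N"], frame["CA"], frame["C"], frames[i + 1]["N"]) + 180.0
        else:
            torsion = 0.0
        frame["O"] = _place_atom(frame["N"], frame["CA"], frame["C"], _B_C_O, _A_CA_C_O, torsion)
    return frames


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R m + t - target||."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _template_residue(res_code: str) -> tuple[list[str], list[str], np.ndarray]:
    """Ideal heavy-atom geometry for a standard residue (names, elements, coords)."""
    import biotite.structure.info as info

    arr = info.residue(res_code)
    mask = (arr.element != "H") & (arr.atom_name != "OXT")
    arr = arr[mask]
    return list(arr.atom_name), list(arr.element), np.asarray(arr.coord, dtype=float)


def _build_peptide(
    sequence: Sequence[str],
    torsions: Sequence[tuple[float, float]],
    chain_id: str = "A",
    radii: dict[str, float] | None = None,
) -> Structure:
    frames = _build_backbone(torsions)
    residues = []
    for i, (code, frame) in enumerate(zip(sequence, frames), start=1):
        names, elements, coords = _template_residue(code)
        idx = {n: k for k, n in enumerate(names)}
        mobile = np.array([coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]]])
        target = np.array([frame["N"], frame["CA"], frame["C"]])
        rot, trans = _kabsch(mobile, target)
        atoms = []
        for name, element, xyz in zip(names, elements, coords):
            if name in ("N", "CA", "C", "O"):
                coord = frame[name]
            else:
                coord = rot @ xyz + trans
            atoms.append(
                Atom(name, element, coord, vdw_radius(element, radii),
                     is_sidechain=name not in BACKBONE_ATOMS)
            )
        residues.append(Residue(chain_id, i, " ", code, atoms))
    return Structure(residues, source_id="toy")


_EXTENDED = (180.0, 180.0)
_STRAND = (-139.0, 135.0)
_HELIX = (-57.0, -47.0)

_HAIRPIN_SEQUENCE = (
    "LYS GLY THR LYS VAL GLY GLU ALA THR LYS GLY".split()
)


def generate_toy_structure(kind: str, **params) -> Structure:
    """Deterministic fixture structures (no randomness anywhere).

    Kinds
    -----
    ``single_atom``
        One carbon at the origin (lone GLY CA).
    ``two_atoms``
        Two carbons separated by ``d`` Å along x.
    ``gxg_tripeptide``
        Extended Gly-X-Gly with ``x`` the central residue; the full-exposure
        reference geometry for relative side-chain accessibility.
    ``beta_hairpin``
        An 11-residue two-strand hairpin (strand torsions plus a tight turn),
        a compact object with two distinguishable faces.
    ``helix``
        Ideal alpha-helix, poly-ALA by default (``sequence`` overrides).
    ``extended``
        Fully extended peptide with an arbitrary ``sequence`` (list of
        residue codes) and optional ``chain_id``.
    """
    if kind == "single_atom":
        atom = Atom("CA", "C", np.zeros(3), vdw_radius("C"), is_sidechain=False)
        return Structure([Residue("A", 1, " ", "GLY", [atom])], source_id="toy")
    if kind == "two_atoms":
        d = float(params.get("d", 5.0))
        a1 = Atom("CA", "C", np.zeros(3), vdw_radius("C"))
        a2 = Atom("CA", "C", np.array([d, 0.0, 0.0]), vdw_radius("C"))
        return Structure(
            [Residue("A", 1, " ", "GLY", [a1]), Residue("A", 2, " ", "GLY", [a2])],
            source_id="toy",
        )
    if kind == "gxg_tripeptide":
        x = params.get("x", "ALA")
        x = ONE_TO_THREE.get(x, x).upper()
        if x not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue code {x!r}")
        return _build_peptide(["GLY", x, "GLY"], [_EXTENDED] * 3)
    if kind == "beta_hairpin":
        sequence = params.get("sequence", _HAIRPIN_SEQUENCE)
        n = len(sequence)
        turn = n // 2
        torsions = [_STRAND] * n
        # type I' turn, the common tight-hairpin connector
        torsions[turn - 1] = (60.0, 30.0)
        torsions[turn] = (90.0, 0.0)
        return _build_peptide(sequence, torsions)
    if kind == "helix":
        sequence = params.get("sequence", ["ALA"] * int(params.get("n", 12)))
        return _build_peptide(sequence, [_HELIX] * len(sequence))
    if kind == "extended":
        sequence = [ONE_TO_THREE.get(c, c).upper() for c in params["sequence"]]
        return _build_peptide(sequence, [_EXTENDED] * len(sequence),
                              chain_id=params.get("chain_id", "A"))
    raise ValueError(f"unknown toy structure kind {kind!r}")
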