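"""Surface prediction of the nanoparticle-binding face of a protein.

The algorithm: each surface residue is scored as

    score = alpha(residue) x relative side-chain accessibility

so a high-affinity residue only matters when its side chain is actually
solvent-exposed. A cubic grid is laid over the structure and the points that
fall in a thin solvent shell hugging the protein surface become candidate
"virtual atoms"; each carries the average score of nearby residues. Virtual
atoms below a threshold are discarded, the survivors are clustered into
connected binding patches, and — when an active site is given — the patches
are tested for steric overlap with the catalytic residues to call the
enzyme's active site exposed or occluded in the bound orientation.

Cysteines in disulfide bridges lose the covalent Au–S contribution and are
substituted per the configured policy. Non-standard residues and hetero
groups are kept as steric bodies but never scored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .sasa import SasaResult, relative_sidechain_accessibility
from .scale import AlphaScale, default_scale, get_alpha
from .structure import Residue, Structure, detect_disulfides

__all__ = [
    "ResidueAffinity",
    "VirtualAtom",
    "BindingPatch",
    "OcclusionReport",
    "residue_affinities",
    "build_surface_grid",
    "score_grid",
    "apply_threshold",
    "cluster_patches",
    "classify_active_site",
    "write_outputs",
]

logger = logging.getLogger(__name__)


@dataclass
class ResidueAffinity:
    residue: Residue
    alpha: float
    rel_access: float
    score: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class VirtualAtom:
    coord: np.ndarray
    affinity: float
    n_contributors: int
    above_threshold: bool = True


@dataclass
class BindingPatch:
    patch_id: int
    members: list[VirtualAtom]
    centroid: np.ndarray
    mean_affinity: float
    area_proxy: float          # member count x grid-cell face area
    small: bool = False        # below the minimum-size flag

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OcclusionReport:
    active_site: list[tuple[str, int, str]]
    min_patch_distance: float
    overlap_fraction: float
    call: str                   # "exposed" | "occluded"
    contact_cutoff: float
    occlusion_fraction: float

    def as_dict(self) -> dict:
        return {
            "active_site": [f"{c}:{n}{i.strip()}" for c, n, i in self.active_site],
            "min_patch_distance_A": self.min_patch_distance,
            "overlap_fraction": self.overlap_fraction,
            "call": self.call,
            "contact_cutoff_A": self.contact_cutoff,
            "occlusion_fraction_threshold": self.occlusion_fraction,
        }


# ---------------------------------------------------------------------------
# Per-residue affinity scores
# ---------------------------------------------------------------------------

def residue_affinities(
    structure: Structure,
    scale: AlphaScale | None = None,
    sasa_result: SasaResult | None = None,
    *,
    disulfide_policy: str = "serine",
    sg_cutoff: float = 2.5,
    reference: dict[str, float] | None = None,
) -> list[ResidueAffinity]:
    """Score every residue as alpha x relative side-chain accessibility.

    ``sasa_result`` must come from the same structure (atom counts are
    checked). Exclusions — non-standard/hetero residues, disulfide cysteines
    under the ``exclude`` policy, and residues with zero exposure — carry
    score 0 with a recorded reason and do not enter grid averaging.
    """
    from .sasa import compute_sasa

    scale = scale or default_scale()
    if sasa_result is None:
        sasa_result = compute_sasa(structure)
    if len(sasa_result.per_atom) != len(structure.atoms):
        raise ValueError(
            "SASA result does not match structure "
            f"({len(sasa_result.per_atom)} areas vs {len(structure.atoms)} atoms)"
        )
    rel = dict(sasa_result.relative_sidechain) or relative_sidechain_accessibility(
        sasa_result, structure, reference
    )
    bridged = {r.key for pair in detect_disulfides(structure, sg_cutoff) for r in pair}

    out: list[ResidueAffinity] = []
    for res in structure.residues:
        if not res.is_standard or res.is_het:
            out.append(ResidueAffinity(res, 0.0, 0.0, 0.0, True, "nonstandard"))
            continue
        is_bridged = res.key in bridged
        alpha = get_alpha(res.res_code, scale, disulfide=is_bridged,
                          disulfide_policy=disulfide_policy)
        if alpha is None:
            out.append(ResidueAffinity(res, 0.0, rel.get(res.key, 0.0), 0.0,
                                       True, "disulfide policy: excluded"))
            continue
        if is_bridged:
            logger.info("disulfide Cys %r: alpha substituted to %.2f (%s policy)",
                        res, alpha, disulfide_policy)
        fraction = rel.get(res.key, 0.0)
        if fraction <= 0.0:
            out.append(ResidueAffinity(res, alpha, 0.0, 0.0, True, "zero exposure"))
            continue
        out.append(ResidueAffinity(res, alpha, fraction, alpha * fraction))
    return out


# ---------------------------------------------------------------------------
# Surface grid and virtual atoms
# ---------------------------------------------------------------------------

def build_surface_grid(
    structure: Structure,
    spacing: float = 1.5,
    shell: tuple[float, float] = (1.4, 4.0),
) -> np.ndarray:
    """Candidate grid points in a solvent shell hugging the protein surface.

    A regular cubic lattice covers the bounding box plus margin; a point is
    kept when its distance to the nearest van der Waals surface (distance to
    atom center minus that atom's radius) lies within ``[inner, outer]``.
    Points closer than ``inner`` sit inside the probe-expanded spheres and
    are discarded.
    """
    inner, outer = shell
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not inner < outer:
        raise ValueError("shell inner bound must be below the outer bound")
    coords = structure.coords()
    if coords.size == 0:
        raise ValueError("empty structure")
    radii = structure.radii()
    rmax = radii.max()

    # lattice centered on the bounding box, so a symmetric molecule gets a
    # symmetric grid
    lo = coords.min(axis=0) - (rmax + outer)
    hi = coords.max(axis=0) + (rmax + outer)
    center = (lo + hi) / 2.0
    half = np.ceil((hi - lo) / (2.0 * spacing)).astype(int)
    axes = [center[k] + spacing * np.arange(-half[k], half[k] + 1) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(coords)
    # Any atom whose surface is within `outer` of the point has its centre
    # within outer + rmax; query that ball and minimize surface distance.
    neighbor_lists = tree.query_ball_point(grid, outer + rmax)
    keep = np.zeros(len(grid), dtype=bool)
    for idx, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        d = np.linalg.norm(coords[neighbors] - grid[idx], axis=1) - radii[neighbors]
        dmin = d.min()
        keep[idx] = inner <= dmin <= outer
    points = grid[keep]
    if len(points) == 0:
        warnings.warn("surface grid is empty (spacing larger than the solvent shell?)",
                      stacklevel=2)
    return points


def score_grid(
    points: np.ndarray,
    affinities: Sequence[ResidueAffinity],
    neighbor_cutoff: float = 8.0,
    weighting: str = "uniform",
) -> list[VirtualAtom]:
    """Average the residue scores near each candidate point.

    A residue contributes to a point when at least one of its side-chain
    heavy atoms lies within ``neighbor_cutoff`` (binding is side-chain
    mediated, so backbone proximity does not count). ``uniform`` averages the
    contributing scores; ``inverse-distance`` weights each residue by the
    reciprocal of its closest side-chain atom distance. Points with no
    contributor are dropped.
    """
    if neighbor_cutoff <= 0:
        raise ValueError("neighbor cutoff must be positive")
    if weighting not in ("uniform", "inverse-distance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    contributors = [a for a in affinities if not a.excluded]
    if not contributors:
        raise ValueError("no scoreable residues")
    points = np.asarray(points, dtype=float).reshape(-1, 3)

    atom_coords, atom_res = [], []
    for ridx, aff in enumerate(contributors):
        for atom in aff.residue.sidechain_atoms():
            atom_coords.append(atom.coord)
            atom_res.append(ridx)
    atom_coords = np.asarray(atom_coords)
    atom_res = np.asarray(atom_res)
    tree = cKDTree(atom_coords)

    virtual: list[VirtualAtom] = []
    for point, neighbors in zip(points, tree.query_ball_point(points, neighbor_cutoff)):
        if not neighbors:
            continue
        neighbors = np.asarray(neighbors)
        res_ids = atom_res[neighbors]
        unique = np.unique(res_ids)
        scores = np.array([contributors[r].score for r in unique])
        if weighting == "uniform":
            affinity = float(scores.mean())
        else:
            d = np.linalg.norm(atom_coords[neighbors] - point, axis=1)
            # closest side-chain atom per residue
            dmin = np.array([d[res_ids == r].min() for r in unique])
            w = 1.0 / np.maximum(dmin, 1e-6)
            affinity = float(np.sum(w * scores) / np.sum(w))
        virtual.append(VirtualAtom(point, affinity, len(unique)))
    return virtual


def apply_threshold(
    virtual_atoms: Sequence[VirtualAtom],
    *,
    absolute: float | None = None,
    percentile: float | None = 75.0,
) -> list[VirtualAtom]:
    """Retain virtual atoms with affinity at or above the threshold.

    Either an ``absolute`` affinity value or a ``percentile`` of the affinity
    distribution (default 75th). Ties at the threshold are retained.
    """
    atoms = list(virtual_atoms)
    if not atoms:
        return []
    if absolute is not None:
        cut = float(absolute)
    else:
        if percentile is None or not 0.0 < percentile < 100.0:
            raise ValueError("percentile must lie in the open interval (0, 100)")
        cut = float(np.percentile([v.affinity for v in atoms], percentile))
    retained = []
    for v in atoms:
        v.above_threshold = v.affinity >= cut
        if v.above_threshold:
            retained.append(v)
    return retained


def cluster_patches(
    virtual_atoms: Sequence[VirtualAtom],
    adjacency: float,
    min_size: int = 3,
    grid_spacing: float | None = None,
) -> list[BindingPatch]:
    """Group retained virtual atoms into connected binding patches.

    Connectivity is pairwise distance <= ``adjacency`` (use sqrt(3) x grid
    spacing for the full 26-neighbourhood of a cubic lattice). Patches are
    sorted by mean affinity, highest first; components smaller than
    ``min_size`` are kept but flagged ``small``. ``area_proxy`` is member
    count times one grid-cell face area when the spacing is known.
    """
    atoms = list(virtual_atoms)
    if not atoms:
        return []
    if adjacency <= 0:
        raise ValueError("adjacency must be positive")
    coords = np.array([v.coord for v in atoms])
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(adjacency)))
    n = len(atoms)
    if pairs.size:
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)

    face_area = grid_spacing**2 if grid_spacing else 1.0
    patches = []
    for comp in range(n_comp):
        members = [atoms[i] for i in np.flatnonzero(labels == comp)]
        member_coords = np.array([m.coord for m in members])
        patches.append(
            BindingPatch(
                patch_id=-1,
                members=members,
                centroid=member_coords.mean(axis=0),
                mean_affinity=float(np.mean([m.affinity for m in members])),
                area_proxy=len(members) * face_area,
                small=len(members) < min_size,
            )
        )
    patches.sort(key=lambda p: -p.mean_affinity)
    for i, p in enumerate(patches):
        p.patch_id = i
    return patches


# ---------------------------------------------------------------------------
# Active-site occlusion
# ---------------------------------------------------------------------------

def _resolve_active_site(structure: Structure, active_site: Iterable) -> list[Residue]:
    resolved = []
    for ref in active_site:
        if isinstance(ref, Residue):
            resolved.append(ref)
            continue
        if isinstance(ref, str):
            chain, _, num = ref.partition(":")
            if not num:
                chain, num = structure.residues[0].chain_id, chain
            num = num.strip()
            icode = " "
            if num and not num[-1].isdigit():
                num, icode = num[:-1], num[-1]
            resolved.append(structure.get_residue(chain.strip(), int(num), icode))
        else:
            chain, num, *rest = ref
            icode = rest[0] if rest else " "
            resolved.append(structure.get_residue(chain, int(num), icode))
    return resolved


def classify_active_site(
    patches: Sequence[BindingPatch],
    structure: Structure,
    active_site: Iterable,
    contact_cutoff: float = 6.0,
    occlusion_fraction: float = 0.5,
) -> OcclusionReport:
    """Decide whether the predicted binding face buries the active site.

    ``overlap_fraction`` is the fraction of active-site residues with any
    heavy atom within ``contact_cutoff`` of an above-threshold virtual atom;
    the call is ``occluded`` when that fraction reaches
    ``occlusion_fraction``. Active-site residues use author numbering
    (``"A:39"`` strings, ``(chain, number)`` tuples, or Residue objects).
    """
    residues = _resolve_active_site(structure, active_site)
    if not residues:
        raise ValueError("active site is empty")
    vatoms = [v for p in patches for v in p.members]
    if not vatoms:
        return OcclusionReport(
            [r.key for r in residues], float("inf"), 0.0, "exposed",
            contact_cutoff, occlusion_fraction,
        )
    vcoords = np.array([v.coord for v in vatoms])
    tree = cKDTree(vcoords)
    n_contact = 0
    min_dist = float("inf")
    for res in residues:
        coords = np.array([a.coord for a in res.atoms])
        d, _ = tree.query(coords)
        res_min = float(d.min())
        min_dist = min(min_dist, res_min)
        if res_min <= contact_cutoff:
            n_contact += 1
    overlap = n_contact / len(residues)
    call = "occluded" if overlap >= occlusion_fraction else "exposed"
    return OcclusionReport(
        [r.key for r in residues], min_dist, overlap, call,
        contact_cutoff, occlusion_fraction,
    )


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

_PML_TEMPLATE = """\
# Rendered binding-surface prediction: load over the input structure.
load {pdb_name}, virtual_atoms
hide everything, virtual_atoms
show spheres, virtual_atoms
set sphere_scale, 0.35, virtual_atoms
spectrum b, white_red, virtual_atoms
"""


def write_outputs(
    virtual_atoms: Sequence[VirtualAtom],
    patches: Sequence[BindingPatch],
    report: OcclusionReport | None,
    out_prefix: str | Path,
    affinities: Sequence[ResidueAffinity] | None = None,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the prediction artifacts.

    Four files: a pseudo-atom PDB (one HETATM per retained virtual atom,
    B-factor carrying the affinity), a PyMOL script reproducing the
    white-to-red colouring, a per-residue TSV (when affinities are given) and
    a JSON report. Returns the paths keyed by kind.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    retained = [v for v in virtual_atoms if v.above_threshold]
    if not retained:
        warnings.warn("no virtual atoms above threshold; writing empty model", stacklevel=2)

    stamp = ""
    if metadata:
        stamp = (f"tool_version={metadata.get('tool_version', '?')} "
                 f"config_hash={metadata.get('config_hash', '?')}")

    pdb_path = prefix.with_name(prefix.name + "_virtual_atoms.pdb")
    lines = [f"REMARK   3 {stamp}"] if stamp else []
    for i, v in enumerate(retained, start=1):
        x, y, z = v.coord
        lines.append(
            f"HETATM{i:>5d}  X   VRT V{(i - 1) % 9999 + 1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{v.affinity:6.2f}           X"
        )
    lines.append("END")
    pdb_path.write_text("\n".join(lines) + "\n")

    pml_path = prefix.with_name(prefix.name + "_view.pml")
    pml_header = f"# {stamp}\n" if stamp else ""
    pml_path.write_text(pml_header + _PML_TEMPLATE.format(pdb_name=pdb_path.name))

    paths = {"pdb": pdb_path, "pml": pml_path}

    if affinities is not None:
        tsv_path = prefix.with_name(prefix.name + "_residues.tsv")
        rows = ([f"# {stamp}"] if stamp else []) + [
            "chain\tseq\ticode\tresidue\talpha\trel_access\tscore\texcluded\treason"
        ]
        for a in affinities:
            r = a.residue
            rows.append(
                f"{r.chain_id}\t{r.seq_number}\t{r.insertion_code.strip()}\t{r.res_code}\t"
                f"{a.alpha:.4f}\t{a.rel_access:.4f}\t{a.score:.4f}\t"
                f"{int(a.excluded)}\t{a.exclusion_reason}"
            )
        tsv_path.write_text("\n".join(rows) + "\n")
        paths["tsv"] = tsv_path

    json_path = prefix.with_name(prefix.name + "_report.json")
    payload = {
        "n_virtual_atoms": len(list(virtual_atoms)),
        "n_retained": len(retained),
        "patches": [
            {
                "patch_id": p.patch_id,
                "size": p.size,
                "mean_affinity": p.mean_affinity,
                "centroid": [round(float(c), 3) for c in p.centroid],
                "area_proxy_A2": p.area_proxy,
                "small": p.small,
            }
            for p in patches
        ],
        "occlusion": report.as_dict() if report else None,
    }
    if metadata:
        payload["metadata"] = metadata
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["json"] = json_path
    return paths
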