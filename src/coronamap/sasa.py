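"""Shrake–Rupley solvent-accessible surface area and relative accessibility.

For every heavy atom a deterministic quasi-uniform point set (golden-spiral /
Fibonacci lattice) is placed on the sphere of radius r_vdw + r_probe; the
accessible area is the fraction of points falling outside every neighbour's
expanded sphere, times 4·pi·(r_vdw + r_probe)². No random numbers are used,
so results are exactly reproducible at a given point count.

Relative side-chain accessibility divides a residue's side-chain SASA by the
area of the same side chain in a fully exposed reference conformation — an
extended Gly-X-Gly tripeptide computed with the same radii and probe. The
fraction is capped at 1.0 (a residue in an unusually open local geometry can
slightly exceed its reference). Glycine has no side chain; its CA area stands
in so that every residue carries a defined fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import (
    Structure,
    generate_toy_structure,
    STANDARD_RESIDUES,
    THREE_TO_ONE,
)

__all__ = [
    "SasaResult",
    "sphere_points",
    "compute_sasa",
    "reference_sidechain_areas",
    "load_reference_sidechain_areas",
    "relative_sidechain_accessibility",
]

logger = logging.getLogger(__name__)

_REFERENCE_RESOURCE = "reference_sidechain_sasa.tsv"


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) lattice on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    return np.column_stack((np.cos(phi) * sin_theta, np.sin(phi) * sin_theta, cos_theta))


@dataclass
class SasaResult:
    per_atom: np.ndarray                       # Å², aligned with structure.atoms
    per_residue_sidechain: dict[tuple, float]  # Å², keyed by residue key
    relative_sidechain: dict[tuple, float]     # dimensionless, filled on demand
    probe_radius: float
    n_sphere_points: int

    def total(self) -> float:
        return float(self.per_atom.sum())

    def to_frame(self, structure: Structure) -> pd.DataFrame:
        rows = []
        for res in structure.residues:
            rows.append({
                "chain": res.chain_id,
                "seq": res.seq_number,
                "icode": res.insertion_code.strip(),
                "residue": res.res_code,
                "sidechain_sasa_A2": self.per_residue_sidechain.get(res.key, float("nan")),
                "relative_sidechain": self.relative_sidechain.get(res.key, float("nan")),
            })
        return pd.DataFrame(rows)


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaResult:
    """Per-atom and per-residue side-chain solvent-accessible surface area."""
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_sphere_points < 60:
        raise ValueError("need at least 60 sphere points for a usable quadrature")
    atoms = structure.atoms
    if not atoms:
        raise ValueError("empty structure")

    coords = structure.coords()
    radii = structure.radii() + probe_radius
    unit = sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * math.pi * radii[i] ** 2

    per_residue_sc: dict[tuple, float] = {}
    offset = 0
    for res in structure.residues:
        n_atoms = len(res.atoms)
        sc_ids = [
            offset + k
            for k, a in enumerate(res.atoms)
            if a.is_sidechain or (res.res_code == "GLY" and a.name == "CA")
        ]
        per_residue_sc[res.key] = float(per_atom[sc_ids].sum()) if sc_ids else 0.0
        offset += n_atoms

    return SasaResult(
        per_atom=per_atom,
        per_residue_sidechain=per_residue_sc,
        relative_sidechain={},
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def reference_sidechain_areas(
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[str, float]:
    """Fully exposed side-chain areas from extended Gly-X-Gly tripeptides.

    Computed with the same radii, probe and quadrature as the numerator of
    the relative accessibility, so the ratio is self-consistent. For GLY the
    CA area in Gly-Gly-Gly is the reference.
    """
    reference: dict[str, float] = {}
    for code in STANDARD_RESIDUES:
        tri = generate_toy_structure("gxg_tripeptide", x=code)
        sasa = compute_sasa(tri, probe_radius, n_sphere_points)
        central = tri.residues[1]
        reference[THREE_TO_ONE[code]] = sasa.per_residue_sidechain[central.key]
    return reference


def load_reference_sidechain_areas() -> dict[str, float]:
    """Frozen copy of the default-parameter reference table shipped with the
    package (probe 1.4 Å, 960 points); regenerate with
    :func:`reference_sidechain_areas` for other parameters."""
    with resources.files("coronamap.data").joinpath(_REFERENCE_RESOURCE).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["residue"], df["max_sidechain_sasa_A2"].astype(float)))


def relative_sidechain_accessibility(
    sasa: SasaResult,
    structure: Structure,
    reference: dict[str, float] | None = None,
) -> dict[tuple, float]:
    """Per-residue side-chain SASA divided by its fully exposed reference.

    Fractions above 1 are capped at 1.0 (and logged); non-standard residues
    get no fraction. The result is also stored on ``sasa.relative_sidechain``.
    """
    if reference is None:
        if (sasa.probe_radius, sasa.n_sphere_points) == (1.4, 960):
            reference = load_reference_sidechain_areas()
        else:
            reference = reference_sidechain_areas(sasa.probe_radius, sasa.n_sphere_points)
    fractions: dict[tuple, float] = {}
    for res in structure.residues:
        if not res.is_standard or res.is_het:
            continue
        one = THREE_TO_ONE[res.res_code]
        if one not in reference:
            raise KeyError(f"residue {res.res_code} missing from reference table")
        ref_area = reference[one]
        frac = sasa.per_residue_sidechain.get(res.key, 0.0) / ref_area
        if frac > 1.0:
            logger.debug("capping relative accessibility %.3f -> 1.0 for %r", frac, res)
            frac = 1.0
        fractions[res.key] = frac
    sasa.relative_sidechain.update(fractions)
    return fractions


def write_reference_table(path: str | Path) -> None:
    """Regenerate and write the frozen reference table (maintainer utility)."""
    ref = reference_sidechain_areas()
    df = pd.DataFrame(
        {"residue": list(ref), "max_sidechain_sasa_A2": [round(v, 3) for v in ref.values()]}
    )
    df.to_csv(path, sep="\t", index=False)
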