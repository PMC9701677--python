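"""The residue affinity scale for citrate-capped gold nanoparticles.

The alpha value of residue X is the competitive binding ratio of a host
protein carrying X at the probe position relative to the glycine variant:
alpha > 1 means X out-competes glycine for limited nanoparticle surface.
Cysteine is the lone alpha > 1 residue (covalent Au–S anchoring); every other
side chain binds more weakly than glycine, with affinity falling roughly
linearly with side-chain molecular volume inside chemically similar
subgroups.

This module houses the measured 20-residue scale, the standard residue
molecular volumes used for the steric analysis, and the subgroup regressions
of alpha against volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "AlphaEntry",
    "AlphaScale",
    "VolumeTable",
    "SubgroupFit",
    "default_scale",
    "default_volumes",
    "get_alpha",
    "regress_alpha_volume",
    "ALIPHATIC_SUBGROUP",
    "POLAR_AROMATIC_SUBGROUP",
]

CATEGORIES = ("Small", "Hydrophobic", "Aromatic", "Nucleophilic", "Acidic", "Amide", "Basic")

# Measured competitive-binding alphas (dimensionless) with a uniform 0.04
# 95% confidence interval. Keyed by one-letter code.
_ALPHA_DATA: dict[str, tuple[float, float, str]] = {
    "G": (0.98, 0.04, "Small"),
    "A": (0.66, 0.04, "Hydrophobic"),
    "L": (0.40, 0.04, "Hydrophobic"),
    "I": (0.40, 0.04, "Hydrophobic"),
    "V": (0.46, 0.04, "Hydrophobic"),
    "M": (0.74, 0.04, "Hydrophobic"),
    "P": (0.63, 0.04, "Hydrophobic"),
    "F": (0.46, 0.04, "Aromatic"),
    "Y": (0.47, 0.04, "Aromatic"),
    "W": (0.41, 0.04, "Aromatic"),
    "S": (0.57, 0.04, "Nucleophilic"),
    "C": (5.69, 0.04, "Nucleophilic"),
    "T": (0.50, 0.04, "Nucleophilic"),
    "E": (0.35, 0.04, "Acidic"),
    "D": (0.47, 0.04, "Acidic"),
    "N": (0.54, 0.04, "Amide"),
    "Q": (0.40, 0.04, "Amide"),
    "H": (0.79, 0.04, "Basic"),
    "K": (0.81, 0.04, "Basic"),
    "R": (0.84, 0.04, "Basic"),
}

# Standard amino-acid molecular volumes (Å³), Zamyatnin's scale.
_VOLUME_DATA: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Subgroups whose alpha-vs-volume relationships are linear. Methionine is
# excluded from the aliphatic fit as a flagged outlier (organo-sulfur/Au
# attraction inflates its alpha); glutamine breaks the polar trend and
# cysteine binds covalently, so both sit outside the polar/aromatic fit.
ALIPHATIC_SUBGROUP: tuple[str, ...] = ("G", "A", "V", "I", "L", "P")
POLAR_AROMATIC_SUBGROUP: tuple[str, ...] = ("S", "T", "Y", "W")


def normalize_residue_code(residue: str) -> str:
    """Accept 1- or 3-letter codes, return the 1-letter code or raise."""
    code = residue.strip().upper()
    if len(code) == 3 and code in THREE_TO_ONE:
        return THREE_TO_ONE[code]
    if len(code) == 1 and code in ONE_TO_THREE:
        return code
    raise KeyError(f"unknown residue code {residue!r}")


@dataclass(frozen=True)
class AlphaEntry:
    alpha: float
    ci95: float
    category: str


@dataclass
class AlphaScale:
    """Per-residue nanoparticle-binding affinities (dimensionless ratios)."""

    entries: dict[str, AlphaEntry]

    def __post_init__(self) -> None:
        if set(self.entries) != set(_VOLUME_DATA):
            missing = set(_VOLUME_DATA) - set(self.entries)
            extra = set(self.entries) - set(_VOLUME_DATA)
            raise ValueError(f"scale must cover the 20 standard residues (missing {sorted(missing)}, extra {sorted(extra)})")
        for code, entry in self.entries.items():
            if entry.alpha <= 0:
                raise ValueError(f"alpha({code}) must be positive")
            if entry.category not in CATEGORIES:
                raise ValueError(f"unknown category {entry.category!r} for {code}")

    def alpha(self, residue: str) -> float:
        return self.entries[normalize_residue_code(residue)].alpha

    def __getitem__(self, residue: str) -> AlphaEntry:
        return self.entries[normalize_residue_code(residue)]

    def to_frame(self, volumes: "VolumeTable | None" = None) -> pd.DataFrame:
        rows = []
        for code in sorted(self.entries):
            e = self.entries[code]
            row = {"residue": code, "alpha": e.alpha, "ci95": e.ci95, "category": e.category}
            if volumes is not None:
                row["volume"] = volumes.volumes[code]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, volumes: "VolumeTable | None" = None) -> None:
        self.to_frame(volumes).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlphaScale":
        df = pd.read_csv(path, sep="\t")
        required = {"residue", "alpha", "ci95", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"scale TSV must have columns {sorted(required)}")
        entries = {
            normalize_residue_code(str(r.residue)): AlphaEntry(float(r.alpha), float(r.ci95), str(r.category))
            for r in df.itertuples()
        }
        return cls(entries)


@dataclass
class VolumeTable:
    """Residue molecular volumes in Å³."""

    volumes: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.volumes) != set(_VOLUME_DATA):
            raise ValueError("volume table must cover the 20 standard residues")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("volumes must be positive")

    def volume(self, residue: str) -> float:
        return self.volumes[normalize_residue_code(residue)]


def default_scale() -> AlphaScale:
    return AlphaScale({c: AlphaEntry(*v) for c, v in _ALPHA_DATA.items()})


def default_volumes() -> VolumeTable:
    return VolumeTable(dict(_VOLUME_DATA))


# ---------------------------------------------------------------------------
# Alpha lookup with the disulfide policy
# ---------------------------------------------------------------------------

DISULFIDE_POLICIES = ("serine", "alanine", "exclude")


def get_alpha(
    residue: str,
    scale: AlphaScale | None = None,
    *,
    disulfide: bool = False,
    disulfide_policy: str = "serine",
) -> float | None:
    """Alpha for a residue, applying the disulfide substitution for cystines.

    The covalent Au–S interaction that gives free cysteine its outlier
    affinity is unavailable once the sulfur is locked in a disulfide bridge,
    so bridged cysteines must not inherit alpha(C). Policies:

    ``serine``  (default) use alpha(S), the closest isosteric residue
    ``alanine`` use alpha(A)
    ``exclude`` drop the residue from scoring entirely (returns ``None``)
    """
    scale = scale or default_scale()
    code = normalize_residue_code(residue)
    if code == "C" and disulfide:
        if disulfide_policy == "serine":
            return scale.alpha("S")
        if disulfide_policy == "alanine":
            return scale.alpha("A")
        if disulfide_policy == "exclude":
            return None
        raise ValueError(f"unknown disulfide policy {disulfide_policy!r} (choose from {DISULFIDE_POLICIES})")
    return scale.alpha(code)


# ---------------------------------------------------------------------------
# Alpha-vs-volume subgroup regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupFit:
    subgroup_id: str
    residues: tuple[str, ...]
    slope: float            # alpha per Å³
    intercept: float
    r_squared: float
    slope_stderr: float

    def as_dict(self) -> dict:
        return {
            "subgroup": self.subgroup_id,
            "residues": list(self.residues),
            "slope_per_A3": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_stderr_per_A3": self.slope_stderr,
        }


def regress_alpha_volume(
    residues: Sequence[str],
    scale: AlphaScale | None = None,
    volumes: VolumeTable | None = None,
    subgroup_id: str = "",
) -> SubgroupFit:
    """Unweighted ordinary least squares of alpha (y) on molecular volume (x).

    At least three residues are required for a meaningful subgroup fit (the
    two-point case is exact and carries no error estimate). R² is the square
    of Pearson's correlation coefficient.
    """
    scale = scale or default_scale()
    volumes = volumes or default_volumes()
    codes = [normalize_residue_code(r) for r in residues]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate residues in subgroup")
    if len(codes) < 2:
        raise ValueError("need at least 2 residues to fit a line")
    x = np.array([volumes.volumes[c] for c in codes])
    y = np.array([scale.entries[c].alpha for c in codes])
    if len(codes) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return SubgroupFit(subgroup_id, tuple(codes), float(slope),
                           float(y[0] - slope * x[0]), 1.0, 0.0)
    res = stats.linregress(x, y)
    return SubgroupFit(
        subgroup_id=subgroup_id or "+".join(codes),
        residues=tuple(codes),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        slope_stderr=float(res.stderr),
    )


def standard_subgroup_fits(
    scale: AlphaScale | None = None,
    volumes: VolumeTable | None = None,
) -> dict[str, SubgroupFit]:
    """The two canonical subgroup regressions (aliphatic and polar/aromatic).

    Their slopes differ by roughly a factor of five: steric bulk penalizes
    small aliphatic side chains steeply, while hydroxyl/polar character
    partially offsets volume in the polar/aromatic group.
    """
    return {
        "aliphatic": regress_alpha_volume(ALIPHATIC_SUBGROUP, scale, volumes, "aliphatic"),
        "polar_aromatic": regress_alpha_volume(POLAR_AROMATIC_SUBGROUP, scale, volumes, "polar_aromatic"),
    }
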