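"""End-to-end prediction pipeline: structure -> SASA -> scores -> patches."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .config import RunConfig
from .sasa import SasaResult, compute_sasa, relative_sidechain_accessibility
from .scale import AlphaScale, default_scale
from .structure import Structure, load_structure
from .surface import (
    BindingPatch,
    OcclusionReport,
    ResidueAffinity,
    VirtualAtom,
    apply_threshold,
    build_surface_grid,
    classify_active_site,
    cluster_patches,
    residue_affinities,
    score_grid,
    write_outputs,
)


@dataclass
class PredictionResult:
    structure: Structure
    sasa: SasaResult
    affinities: list[ResidueAffinity]
    virtual_atoms: list[VirtualAtom]
    retained: list[VirtualAtom]
    patches: list[BindingPatch]
    occlusion: OcclusionReport | None
    config: RunConfig

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        from . import __version__

        return write_outputs(
            self.virtual_atoms,
            self.patches,
            self.occlusion,
            out_prefix,
            affinities=self.affinities,
            metadata={"tool_version": __version__, "config_hash": self.config.config_hash(),
                      "config": self.config.to_dict(),
                      "source": self.structure.source_id},
        )


def predict_binding_surface(
    structure: Structure | str | Path,
    active_site: Iterable | None = None,
    scale: AlphaScale | None = None,
    config: RunConfig | None = None,
) -> PredictionResult:
    """Run the full nanoparticle-binding-surface prediction.

    Accepts a loaded :class:`Structure` or a PDB path. When ``active_site``
    residues are given (author numbering) the occlusion call is included.
    """
    config = config or RunConfig()
    scale = scale or default_scale()
    if not isinstance(structure, Structure):
        structure = load_structure(structure, model_index=config.model_index,
                                   keep_het=config.keep_het)

    sasa = compute_sasa(structure, config.probe_radius, config.n_sphere_points)
    relative_sidechain_accessibility(sasa, structure)
    affinities = residue_affinities(
        structure, scale, sasa,
        disulfide_policy=config.disulfide_policy, sg_cutoff=config.sg_cutoff,
    )
    grid = build_surface_grid(structure, config.grid_spacing,
                              (config.shell_inner, config.shell_outer))
    vatoms = score_grid(grid, affinities, config.neighbor_cutoff, config.weighting)
    retained = apply_threshold(
        vatoms,
        absolute=config.threshold_absolute,
        percentile=None if config.threshold_absolute is not None else config.threshold_percentile,
    )
    patches = cluster_patches(retained, config.adjacency, config.min_patch_size,
                              config.grid_spacing)
    occlusion = None
    if active_site:
        occlusion = classify_active_site(patches, structure, active_site,
                                         config.contact_cutoff, config.occlusion_fraction)
    return PredictionResult(structure, sasa, affinities, vatoms, retained,
                            patches, occlusion, config)
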