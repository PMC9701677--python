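import numpy as np
import pytest

from coronamap.structure import (
    Atom,
    Residue,
    Structure,
    generate_toy_structure,
    vdw_radius,
)


@pytest.fixture(scope="session")
def hairpin() -> Structure:
    return generate_toy_structure("beta_hairpin")


@pytest.fixture(scope="session")
def helix() -> Structure:
    return generate_toy_structure("helix", n=12)


def single_sg_cys(chain: str, seq: int, coord) -> Residue:
    sg = Atom("SG", "S", np.asarray(coord, float), vdw_radius("S"), is_sidechain=True)
    return Residue(chain, seq, " ", "CYS", [sg])


def merge_structures(*structures: Structure, chains: str = "ABCDEFGH") -> Structure:
    """Combine several toy structures into one, re-lettering the chains."""
    residues = []
    for chain, s in zip(chains, structures):
        for r in s.residues:
            residues.append(Residue(chain, r.seq_number, r.insertion_code, r.res_code,
                                    list(r.atoms)))
    return Structure(residues, source_id="merged")


@pytest.fixture(scope="session")
def two_face_structure() -> Structure:
    """Two extended 7-mers 25 Å apart: chain A pure CYS (very high affinity),
    chain B pure GLU (lowest affinity). A deterministic object with one
    strongly preferred nanoparticle-contact face."""
    cys = generate_toy_structure("extended", sequence=["CYS"] * 7, chain_id="A")
    glu = generate_toy_structure("extended", sequence=["GLU"] * 7, chain_id="B")
    glu = glu.transformed(np.eye(3), np.array([0.0, 25.0, 0.0]))
    return merge_structures(cys, glu)
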