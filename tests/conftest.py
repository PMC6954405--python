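import numpy as np
import pytest

from pepdock.cg_model import CGComplex, CGResidue, PEPTIDE_CHAIN_ID
from pepdock.fixtures import ToySystemSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_system():
    """Default bound/unbound toy complex with 3 planted native contacts."""
    return make_toy_complex(ToySystemSpec(rng_seed=7))


@pytest.fixture(scope="session")
def bound_reference(toy_system):
    return toy_system[0]


def residue(chain_id, number, aa, ca, sc=None, cb=None, cp=None):
    ca = np.asarray(ca, dtype=float)
    return CGResidue(chain_id=chain_id, residue_number=number, aa_type=aa,
                     ca=ca, cb=cb, sc=ca.copy() if sc is None else np.asarray(sc, float),
                     cp=cp)


def tiny_complex(receptor_sc_positions, peptide_sc_positions,
                 receptor_aa="L", peptide_aa="A"):
    """Hand-built complex with SC pseudo-atoms at given positions.

    Peptide is padded to the 3-residue minimum with far-away residues.
    """
    receptor = [residue("A", i + 1, receptor_aa, pos, sc=pos)
                for i, pos in enumerate(receptor_sc_positions)]
    peptide = [residue(PEPTIDE_CHAIN_ID, i + 1, peptide_aa, pos, sc=pos)
               for i, pos in enumerate(peptide_sc_positions)]
    pad = 1000.0
    while len(peptide) < 3:
        n = len(peptide) + 1
        pos = [pad, pad * n, pad]
        peptide.append(residue(PEPTIDE_CHAIN_ID, n, peptide_aa, pos, sc=pos))
    return CGComplex(receptor_chains=[receptor], peptide=peptide)
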