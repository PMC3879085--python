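import numpy as np
import pytest

from pdbkit import Atom, Chain, FixtureSpec, Model, Residue, Structure, synthetic_structure


def make_atom(serial=1, name="CA", coord=(0.0, 0.0, 0.0), **kwargs):
    kwargs.setdefault("element", "C")
    return Atom(serial=serial, name=name, coord=np.array(coord, dtype=float), **kwargs)


@pytest.fixture
def two_atom_chain():
    """Chain of one residue with atoms at (-1,0,0) and (1,0,0)."""
    return Chain(
        chain_id="A",
        residues=[
            Residue(
                res_name="GLY",
                res_seq=1,
                atoms=[
                    make_atom(serial=1, name="N", coord=(-1.0, 0.0, 0.0), element="N"),
                    make_atom(serial=2, name="CA", coord=(1.0, 0.0, 0.0)),
                ],
            )
        ],
    )


@pytest.fixture
def small_structure():
    """2 models x 1 chain x 3 residues x 4 atoms, deterministic."""
    return synthetic_structure(
        FixtureSpec(n_models=2, chains_per_model=1, residues_per_chain=3,
                    atoms_per_residue=4, seed=11)
    )


@pytest.fixture
def rich_structure():
    """Multi-chain structure with altlocs and water tails."""
    return synthetic_structure(
        FixtureSpec(n_models=2, chains_per_model=3, residues_per_chain=6,
                    atoms_per_residue=3, altloc_fraction=0.5, hetatm_tail=2, seed=23)
    )
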