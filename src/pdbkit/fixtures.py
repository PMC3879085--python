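"""Deterministic synthetic structures and PDB files for testing.

Everything every module needs to be exercised — multi-model ensembles,
multiple chains, alternate locations, water tails, deliberately malformed
lines — is generated here from a seeded RNG, so no real archive entries
are ever required.  The same :class:`FixtureSpec` and seed always produce
byte-identical output (numpy's seeded PCG64 generator; if the platform
RNG stream ever changed, frozen expectations would be regenerated).

Coordinates are quantized to 3 decimals and occupancy/B to 2 by
construction, so every synthetic structure survives the text round trip
exactly.  Geometry is a random cloud in a box: deliberately not
biophysically realistic (no bond lengths or angles) — these fixtures
exercise the format and the container machinery, not force fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .model import Atom, Chain, MetadataLine, Model, Residue, Structure
from .writer import write_file, write_structure

__all__ = ["FixtureSpec", "synthetic_structure", "synthetic_pdb_text", "write_fixture"]

_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
_ATOM_NAMES = ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "CZ", "OG")
_ELEMENTS = ("N", "C", "C", "O", "C", "C", "C", "C", "C", "O")
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure / file.

    ``altloc_fraction`` of residues receive a duplicate of their first
    atom at alternate location 'B'; ``hetatm_tail`` water residues are
    appended to each chain; ``bad_lines`` malformed lines are injected
    into the emitted text (not the structure).
    """

    n_models: int = 1
    chains_per_model: int = 1
    residues_per_chain: int = 5
    atoms_per_residue: int = 3
    altloc_fraction: float = 0.0
    hetatm_tail: int = 0
    bad_lines: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atoms_per_residue < 1:
            raise ValueError("atoms_per_residue must be >= 1")
        if not 0.0 <= self.altloc_fraction <= 1.0:
            raise ValueError("altloc_fraction must be in [0, 1]")
        if min(self.n_models, self.chains_per_model, self.residues_per_chain) < 0:
            raise ValueError("counts must be >= 0")
        if self.hetatm_tail < 0 or self.bad_lines < 0:
            raise ValueError("hetatm_tail and bad_lines must be >= 0")


def _quantized_coord(rng: np.random.Generator) -> np.ndarray:
    return np.round(rng.uniform(-99.0, 99.0, size=3), 3)


def synthetic_structure(spec: FixtureSpec) -> Structure:
    """Build a hierarchy with the spec's exact counts, deterministically."""
    rng = np.random.default_rng(spec.seed)
    models = []
    for model_index in range(spec.n_models):
        chains = []
        for chain_index in range(spec.chains_per_model):
            chain_id = _CHAIN_IDS[chain_index % len(_CHAIN_IDS)]
            residues = []
            for res_index in range(spec.residues_per_chain):
                res_name = _AMINO_ACIDS[res_index % len(_AMINO_ACIDS)]
                atoms = []
                for atom_index in range(spec.atoms_per_residue):
                    name_idx = atom_index % len(_ATOM_NAMES)
                    atoms.append(
                        Atom(
                            serial=0,  # assigned below
                            name=_ATOM_NAMES[name_idx],
                            coord=_quantized_coord(rng),
                            occupancy=1.0,
                            b_factor=round(float(rng.uniform(2.0, 80.0)), 2),
                            element=_ELEMENTS[name_idx],
                        )
                    )
                if spec.altloc_fraction > 0 and rng.random() < spec.altloc_fraction:
                    first = atoms[0]
                    atoms[0] = Atom(
                        serial=0,
                        name=first.name,
                        coord=first.coord,
                        alt_loc="A",
                        occupancy=0.6,
                        b_factor=first.b_factor,
                        element=first.element,
                    )
                    atoms.insert(
                        1,
                        Atom(
                            serial=0,
                            name=first.name,
                            coord=_quantized_coord(rng),
                            alt_loc="B",
                            occupancy=0.4,
                            b_factor=first.b_factor,
                            element=first.element,
                        ),
                    )
                residues.append(
                    Residue(res_name=res_name, res_seq=res_index + 1, atoms=atoms)
                )
            for water_index in range(spec.hetatm_tail):
                residues.append(
                    Residue(
                        res_name="HOH",
                        res_seq=spec.residues_per_chain + water_index + 1,
                        atoms=[
                            Atom(
                                serial=0,
                                name="O",
                                coord=_quantized_coord(rng),
                                element="O",
                                is_hetatm=True,
                            )
                        ],
                    )
                )
            chains.append(Chain(chain_id=chain_id, residues=residues))
        models.append(Model(model_id=model_index + 1, chains=chains))
    structure = Structure(models=models)
    from .analysis import renumber_atoms

    return renumber_atoms(structure)


def _malformed_line(rng: np.random.Generator) -> str:
    """One line guaranteed to be rejected in both lenient and strict mode."""
    choice = int(rng.integers(0, 3))
    if choice == 0:
        # unknown record name
        return "FOOBAR injected garbage line"
    if choice == 1:
        # non-numeric serial
        return "ATOM  XXXXX  N   MET A   1      11.000  22.000  33.000  1.00 10.00           N"
    # non-numeric coordinate
    return "ATOM      9  CA  GLY A   2      1x.000  22.000  33.000  1.00 10.00           C"


def synthetic_pdb_text(spec: FixtureSpec) -> str:
    """PDB text for the spec's structure, with ``bad_lines`` malformed
    lines injected at seeded positions inside the coordinate block.

    The header carries one HEADER and one REMARK metadata line; injected
    lines never land in that header (nor after END), so each one yields
    exactly one parse error in both lenient and strict mode.
    """
    structure = synthetic_structure(spec)
    structure.metadata = [
        MetadataLine("HEADER    SYNTHETIC FIXTURE                       01-JAN-20   XXXX"),
        MetadataLine(f"REMARK 999 SYNTHETIC FIXTURE SEED {spec.seed}"),
    ]
    text = write_structure(structure, renumber=True)
    if spec.bad_lines == 0:
        return text
    rng = np.random.default_rng(spec.seed + 1)
    lines = text.splitlines()
    n_header = 2
    # insertion slots within the coordinate block (before the final END)
    for _ in range(spec.bad_lines):
        slot = int(rng.integers(n_header, len(lines)))  # before END at most
        lines.insert(slot, _malformed_line(rng))
    return "\n".join(lines) + "\n"


def write_fixture(path: Union[str, Path], spec: FixtureSpec) -> Path:
    """Emit a fixture file (plain or gzip by suffix) and return its path."""
    path = Path(path)
    text = synthetic_pdb_text(spec)
    if path.suffix == ".gz":
        import gzip

        with gzip.open(path, "wb") as handle:
            handle.write(text.encode("latin-1"))
    else:
        path.write_text(text, encoding="latin-1")
    return path
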