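"""Domain types for the PDB hierarchy.

A PDB entry is represented as five nested levels::

    Structure -> Model -> Chain -> Residue -> Atom

Each level stores its children in file (document) order.  Non-coordinate
records are kept verbatim as :class:`MetadataLine` entries on the
:class:`Structure`, tagged by whether they appeared before or after the
coordinate block, so that writing a structure back reproduces them
byte-identically.

All types are plain dataclasses with value semantics at the API surface:
transformations (see :mod:`pdbkit.traverse`) return new objects and leave
their inputs untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "Structure",
    "MetadataLine",
    "RigidTransform",
    "structure_equal",
    "chain_is_polymer",
]


@dataclass
class Atom:
    """A single atom location (one ATOM or HETATM record).

    Alternate locations of the same physical atom appear as separate
    ``Atom`` entries differing in ``alt_loc``, mirroring how the file
    stores them.

    Parameters
    ----------
    serial : int
        Atom serial number, >= 0.
    name : str
        Atom name, stored stripped of padding (<= 4 chars).  Column
        justification is regenerated by the writer.
    coord : (3,) ndarray of float
        Cartesian coordinates in Angstroms; must be finite.
    alt_loc : str
        Alternate location indicator; ``' '`` means none.
    occupancy, b_factor : float
        Occupancy (not constrained to [0, 1]; real entries exceed it)
        and isotropic temperature factor in A^2.
    seg_id, element, charge : str
        Segment identifier (<= 4), element symbol (<= 2, stripped) and
        formal charge kept as the raw string (e.g. ``"2+"``).
    is_hetatm : bool
        Whether the record name is HETATM rather than ATOM.
    """

    serial: int
    name: str
    coord: np.ndarray
    alt_loc: str = " "
    occupancy: float = 1.0
    b_factor: float = 0.0
    seg_id: str = ""
    element: str = ""
    charge: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"coord must be a 3-vector, got shape {self.coord.shape}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial} {self.name!r}: non-finite coordinates")
        if self.serial < 0:
            raise ValueError(f"atom serial must be >= 0, got {self.serial}")


@dataclass
class Residue:
    """One monomer (amino-acid residue, nucleotide or hetero group).

    ``atoms`` preserves file order.  Two atoms may share a name only when
    their ``alt_loc`` differs; real archive files violate this, so it is
    checked by :func:`lint`, not enforced here.
    """

    res_name: str
    res_seq: int
    ins_code: str = " "
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    """A single polymer chain (or the blank-id chain holding waters)."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Model:
    """One model of the molecule (e.g. one member of an NMR ensemble)."""

    model_id: int
    chains: list[Chain] = field(default_factory=list)


@dataclass(frozen=True)
class MetadataLine:
    """A verbatim non-coordinate record line.

    ``position`` is ``"head"`` for lines seen before the coordinate block
    and ``"tail"`` for lines after it.
    """

    line: str
    position: str = "head"


@dataclass
class Structure:
    """A whole PDB entry: models plus verbatim metadata lines."""

    models: list[Model] = field(default_factory=list)
    metadata: list[MetadataLine] = field(default_factory=list)


@dataclass
class RigidTransform:
    """A proper rigid-body motion ``x -> rotation @ x + translation``.

    The rotation must be orthonormal with determinant +1 (no reflection),
    checked to 1e-9 on construction.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != +1 (improper rotation)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or single 3-vector) of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``inner`` first."""
        return RigidTransform(
            rotation=self.rotation @ inner.rotation,
            translation=self.rotation @ inner.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def chain_is_polymer(chain: Chain) -> bool:
    """True when the chain holds at least one non-HETATM residue.

    A residue counts as polymeric when any of its atoms was read from an
    ATOM record.  Chains of pure HETATM content (waters, ligands) do not
    receive a TER record on output and do not consume a TER serial.
    """
    return any(
        any(not atom.is_hetatm for atom in residue.atoms) for residue in chain.residues
    )


def _atoms_equal(a: Atom, b: Atom, coord_tol: float) -> bool:
    if (
        a.serial != b.serial
        or a.name != b.name
        or a.alt_loc != b.alt_loc
        or a.occupancy != b.occupancy
        or a.b_factor != b.b_factor
        or a.seg_id != b.seg_id
        or a.element != b.element
        or a.charge != b.charge
        or a.is_hetatm != b.is_hetatm
    ):
        return False
    return bool(np.all(np.abs(a.coord - b.coord) <= coord_tol))


def structure_equal(a: Structure, b: Structure, coord_tol: float = 0.0) -> bool:
    """Compare two structures for identical shape and content.

    Returns True iff the hierarchies have the same shape, every
    non-coordinate field matches exactly, and coordinates agree
    component-wise within ``coord_tol``.  At ``coord_tol=0`` this is an
    equivalence relation.
    """
    if coord_tol < 0:
        raise ValueError("coord_tol must be >= 0")
    if a.metadata != b.metadata:
        return False
    if len(a.models) != len(b.models):
        return False
    for ma, mb in zip(a.models, b.models):
        if ma.model_id != mb.model_id or len(ma.chains) != len(mb.chains):
            return False
        for ca, cb in zip(ma.chains, mb.chains):
            if ca.chain_id != cb.chain_id or len(ca.residues) != len(cb.residues):
                return False
            for ra, rb in zip(ca.residues, cb.residues):
                if (
                    ra.res_name != rb.res_name
                    or ra.res_seq != rb.res_seq
                    or ra.ins_code != rb.ins_code
                    or len(ra.atoms) != len(rb.atoms)
                ):
                    return False
                for aa, ab in zip(ra.atoms, rb.atoms):
                    if not _atoms_equal(aa, ab, coord_tol):
                        return False
    return True


def lint(structure: Structure) -> list[str]:
    """Report soft invariant violations that real archive files exhibit.

    Checks: duplicate model ids, duplicate chain ids within a model, and
    duplicate (name, alt_loc) pairs within a residue.  Returns
    human-readable warnings; an empty list means no issues found.
    """
    warnings: list[str] = []
    seen_models: set[int] = set()
    for model in structure.models:
        if model.model_id in seen_models:
            warnings.append(f"duplicate model id {model.model_id}")
        seen_models.add(model.model_id)
        seen_chains: set[str] = set()
        for chain in model.chains:
            if chain.chain_id in seen_chains:
                warnings.append(
                    f"model {model.model_id}: chain id {chain.chain_id!r} re-opened"
                )
            seen_chains.add(chain.chain_id)
            for residue in chain.residues:
                seen_atoms: set[tuple[str, str]] = set()
                for atom in residue.atoms:
                    key = (atom.name, atom.alt_loc)
                    if key in seen_atoms:
                        warnings.append(
                            f"model {model.model_id} chain {chain.chain_id!r} "
                            f"residue {residue.res_name} {residue.res_seq}: "
                            f"duplicate atom {atom.name!r} altloc {atom.alt_loc!r}"
                        )
                    seen_atoms.add(key)
    return warnings
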