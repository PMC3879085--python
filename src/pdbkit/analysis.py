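"""Worked analyses over the hierarchy.

Everything here is written against the generic traversal API: geometry
statistics are folds over atoms, coordinate edits are maps, and the
renumbering operations thread a counter through a stateful map — the same
handful of traversal primitives covering very different jobs.

Weighting: operations named after mass (center of mass, radius of
gyration) accept a :class:`WeightingScheme`.  The default is UNIFORM
(every atom weight 1), which is what bead-model geometry in small-angle
scattering uses; ELEMENT_MASS looks standard atomic weights up by element
symbol and fails loudly on an unknown or missing element.
"""

from __future__ import annotations

import enum
from dataclasses import replace
from typing import Tuple, TypeVar, Union

import numpy as np

from .model import Atom, Chain, Model, RigidTransform, Structure, chain_is_polymer
from .traverse import (
    FoldDirection,
    TraversalError,
    TraversalKind,
    TraversalRoot,
    count,
    fold_over,
    iter_nodes,
    map_over,
    map_with_state,
)


def _fold_atoms(root, fn, init):
    """Left fold over atoms, surfacing weighting failures as their own type."""
    try:
        return fold_over(root, TraversalKind.ATOM, fn, init, FoldDirection.LEFT)
    except TraversalError as exc:
        if isinstance(exc.__cause__, UnknownElementError):
            raise exc.__cause__
        raise

__all__ = [
    "WeightingScheme",
    "UnknownElementError",
    "center_of_mass",
    "recenter",
    "renumber_residues",
    "renumber_atoms",
    "radius_of_gyration",
    "canonical_axes",
    "chain_sequence",
]


class WeightingScheme(enum.Enum):
    UNIFORM = "uniform"
    ELEMENT_MASS = "element_mass"


class UnknownElementError(ValueError):
    """ELEMENT_MASS weighting met an atom with no usable element symbol."""


# Standard atomic weights (IUPAC 2021, rounded), by element symbol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "SE": 78.971, "FE": 55.845,
    "ZN": 65.38, "MG": 24.305, "CA": 40.078, "NA": 22.990, "CL": 35.45,
    "K": 39.098, "MN": 54.938, "BR": 79.904, "I": 126.904, "CU": 63.546,
    "NI": 58.693, "CO": 58.933, "MO": 95.95, "W": 183.84,
}


def _atom_weight(atom: Atom, scheme: WeightingScheme) -> float:
    if scheme is WeightingScheme.UNIFORM:
        return 1.0
    symbol = atom.element.strip().upper()
    if symbol not in ATOMIC_MASSES:
        raise UnknownElementError(
            f"atom {atom.serial} {atom.name!r}: unknown element {atom.element!r}"
        )
    return ATOMIC_MASSES[symbol]


def center_of_mass(
    root: TraversalRoot, weighting: WeightingScheme = WeightingScheme.UNIFORM
) -> np.ndarray:
    """Weighted mean atom position, in Angstroms.

    Two fold passes over the contained atoms: one accumulating the
    weighted coordinate sum, one the total weight.
    """
    n_atoms = count(root, TraversalKind.ATOM)
    if n_atoms == 0:
        raise ValueError("center_of_mass requires at least one atom")
    weighted_sum = _fold_atoms(
        root,
        lambda acc, atom: acc + _atom_weight(atom, weighting) * atom.coord,
        np.zeros(3),
    )
    total_weight = _fold_atoms(
        root, lambda acc, atom: acc + _atom_weight(atom, weighting), 0.0
    )
    return weighted_sum / total_weight


def recenter(
    root: TraversalRoot, weighting: WeightingScheme = WeightingScheme.UNIFORM
) -> TraversalRoot:
    """Translate so the (weighted) center lands at the origin."""
    center = center_of_mass(root, weighting)
    return map_over(
        root, TraversalKind.ATOM, lambda atom: replace(atom, coord=atom.coord - center)
    )


def renumber_residues(chain: Chain, start: int = 1) -> Chain:
    """Assign consecutive residue numbers ``start, start+1, ...``.

    Insertion codes are cleared (consecutive numbering makes them
    meaningless).  Numbering begins anew with each chain, so apply this
    per chain.  Implemented as a stateful map threading the counter.
    """

    def step(counter: int, residue):
        return counter + 1, replace(residue, res_seq=counter, ins_code=" ")

    new_chain, _ = map_with_state(chain, TraversalKind.RESIDUE, step, start)
    return new_chain


RootT = TypeVar("RootT", Structure, Model)


def renumber_atoms(root: RootT) -> RootT:
    """Regenerate atom serials, counting TER records along with the atoms.

    Within each model a counter starts at 1 and advances per atom in
    document order; after each polymer chain the counter advances once
    more for the TER record the writer will emit there.  The counter
    restarts for every model, matching multi-model output where each
    model's numbering is self-contained.
    """

    def renumber_model(model: Model) -> Model:
        serial = 1

        def step(counter: int, atom: Atom):
            return counter + 1, replace(atom, serial=counter)

        new_chains = []
        for chain in model.chains:
            new_chain, serial = map_with_state(chain, TraversalKind.ATOM, step, serial)
            if chain_is_polymer(chain):
                serial += 1  # the TER record's serial
            new_chains.append(new_chain)
        return replace(model, chains=new_chains)

    if isinstance(root, Model):
        return renumber_model(root)
    return map_over(root, TraversalKind.MODEL, renumber_model)


def radius_of_gyration(
    root: TraversalRoot, weighting: WeightingScheme = WeightingScheme.UNIFORM
) -> float:
    """Root-mean-square (weighted) distance of atoms from their center, A.

    Rg = sqrt( sum_i w_i |r_i - c|^2 / sum_i w_i ) with c the weighted
    center; the overall size measure reported for small-angle scattering
    shape reconstructions.
    """
    center = center_of_mass(root, weighting)
    sq_sum, w_sum = _fold_atoms(
        root,
        lambda acc, atom: (
            acc[0]
            + _atom_weight(atom, weighting) * float(np.sum((atom.coord - center) ** 2)),
            acc[1] + _atom_weight(atom, weighting),
        ),
        (0.0, 0.0),
    )
    return float(np.sqrt(sq_sum / w_sum))


def _atom_coords(root: TraversalRoot) -> np.ndarray:
    return np.array([atom.coord for atom in iter_nodes(root, TraversalKind.ATOM)])


def _max_distance_pair(coords: np.ndarray) -> Tuple[int, int]:
    """Indices (i, j), i < j, of the most distant pair; ties break to the
    lowest (i, j) in document order.  Exact O(n^2) scan."""
    n = len(coords)
    best = (-1.0, 0, 0)
    for i in range(n - 1):
        d2 = np.sum((coords[i + 1 :] - coords[i]) ** 2, axis=1)
        j_rel = int(np.argmax(d2))
        if d2[j_rel] > best[0]:
            best = (float(d2[j_rel]), i, i + 1 + j_rel)
    return best[1], best[2]


def _rotation_to_y(v: np.ndarray) -> np.ndarray:
    """Proper rotation carrying unit vector v onto +Y (Rodrigues)."""
    y = np.array([0.0, 1.0, 0.0])
    c = float(np.dot(v, y))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # v is -Y: rotate 180 degrees about X
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, y)
    s = float(np.linalg.norm(axis))
    axis = axis / s
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def canonical_axes(
    structure: Structure, weighting: WeightingScheme = WeightingScheme.UNIFORM
) -> Tuple[Structure, RigidTransform]:
    """Reorient so the longest diameter lies along Y and the widest
    cross-sectional direction along X.

    Steps: (1) translate the (weighted) center to the origin; (2) find
    the most distant atom pair and rotate their separation vector onto
    +Y; (3) project all atoms onto the XZ plane, take the principal
    direction of the projected second-moment matrix, and rotate about Y
    to bring it onto +X (skipped — identity — when the projection is
    degenerate, e.g. collinear atoms).  Signs are fixed by orienting the
    diameter vector to non-negative y and the cross-section eigenvector
    to non-negative x.

    Returns the transformed structure and the composed rigid transform;
    a rigid motion, so all pairwise distances are preserved.
    """
    coords = _atom_coords(structure)
    if len(coords) < 2:
        raise ValueError("canonical_axes requires at least two atoms")
    center = center_of_mass(structure, weighting)
    centered = coords - center

    i, j = _max_distance_pair(centered)
    diameter = centered[j] - centered[i]
    norm = float(np.linalg.norm(diameter))
    if norm < 1e-12:
        rot_y = np.eye(3)
    else:
        direction = diameter / norm
        if direction[1] < 0:
            direction = -direction
        rot_y = _rotation_to_y(direction)
    rotated = centered @ rot_y.T

    # widest direction of the XZ-projected cloud, by second moments
    projected = rotated[:, [0, 2]]
    moment = projected.T @ projected
    if float(np.trace(moment)) < 1e-18:
        rot_x = np.eye(3)
    else:
        eigvals, eigvecs = np.linalg.eigh(moment)
        u = eigvecs[:, int(np.argmax(eigvals))]
        if u[0] < 0 or (u[0] == 0 and u[1] < 0):
            u = -u
        ux, uz = float(u[0]), float(u[1])
        rot_x = np.array([[ux, 0.0, uz], [0.0, 1.0, 0.0], [-uz, 0.0, ux]])

    rotation = rot_x @ rot_y
    transform = RigidTransform(rotation=rotation, translation=-rotation @ center)
    new_structure = map_over(
        structure,
        TraversalKind.ATOM,
        lambda atom: replace(atom, coord=transform.apply(atom.coord)),
    )
    return new_structure, transform


# Standard residue-name translation: the 20 amino acids plus common
# variants, and one-letter codes for DNA/RNA bases.  Unknowns map to 'X'.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DI": "I",
    "A": "A", "C": "C", "G": "G", "U": "U", "I": "I",
}

_WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence of a chain, in residue order.

    Water residues are skipped; any residue name outside the standard
    amino-acid and nucleotide tables becomes ``'X'``.
    """
    letters = []
    for residue in chain.residues:
        name = residue.res_name.strip().upper()
        if name in _WATER_NAMES:
            continue
        letters.append(THREE_TO_ONE.get(name, "X"))
    return "".join(letters)
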