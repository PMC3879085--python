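"""Serialize a Structure back to PDB text; CleanPDB normalization.

Output layout: leading metadata verbatim, then per model — a MODEL line
(only for multi-model structures), coordinate lines, one TER after each
chain containing polymer (non-HETATM) residues, ENDMDL when MODEL was
written — then trailing metadata and a final END record.

Metadata is re-emitted verbatim in its head block before the coordinates
and its tail block after them; original interleaving of metadata *inside*
the coordinate block is not preserved (a known fidelity limit).

``renumber=True`` regenerates atom serials at write time: a fresh counter
per model, incremented per atom in document order, with each emitted TER
consuming one serial of its own, as the format mandates.
"""

from __future__ import annotations

import copy
import gzip
from pathlib import Path
from typing import Union

from .model import Atom, Chain, MetadataLine, Residue, Structure, chain_is_polymer
from .records import (
    AtomRecord,
    RecordKind,
    classify_line,
    format_coord_line,
)

__all__ = ["write_structure", "write_file", "clean"]


def _coord_line(atom: Atom, residue: Residue, chain: Chain, serial: int) -> str:
    rec = AtomRecord(
        serial=serial,
        name=atom.name,
        alt_loc=atom.alt_loc or " ",
        res_name=residue.res_name,
        chain_id=chain.chain_id or " ",
        res_seq=residue.res_seq,
        ins_code=residue.ins_code or " ",
        x=float(atom.coord[0]),
        y=float(atom.coord[1]),
        z=float(atom.coord[2]),
        occupancy=atom.occupancy,
        b_factor=atom.b_factor,
        seg_id=atom.seg_id,
        element=atom.element,
        charge=atom.charge,
        is_hetatm=atom.is_hetatm,
    )
    return format_coord_line(rec)


def _ter_line(serial: int, residue: Residue, chain: Chain) -> str:
    if not (0 <= serial <= 99999):
        from .records import FieldOverflowError

        raise FieldOverflowError(f"TER serial {serial} does not fit columns 7-11")
    line = (
        f"TER   {serial:5d}      "
        f"{residue.res_name[:3]:>3s}"
        f" {(chain.chain_id or ' ')[:1]}"
        f"{residue.res_seq:4d}"
        f"{(residue.ins_code or ' ')[:1]}"
    )
    return line.ljust(80)


def write_structure(structure: Structure, renumber: bool = False) -> str:
    """Render a Structure as PDB text (trailing newline included).

    With ``renumber=False`` the stored serials are written as-is and must
    fit their field widths; with ``renumber=True`` serials are
    regenerated per model with TER records counted along with the atoms.
    """
    lines: list[str] = [m.line for m in structure.metadata if m.position == "head"]
    emit_model_records = len(structure.models) > 1
    for model in structure.models:
        if emit_model_records:
            lines.append(f"MODEL     {model.model_id:4d}".ljust(80))
        serial_counter = 1
        for chain in model.chains:
            last_residue: Residue | None = None
            last_serial = 0
            for residue in chain.residues:
                for atom in residue.atoms:
                    serial = serial_counter if renumber else atom.serial
                    lines.append(_coord_line(atom, residue, chain, serial))
                    last_serial = serial
                    serial_counter += 1
                last_residue = residue
            if last_residue is not None and chain_is_polymer(chain):
                ter_serial = serial_counter if renumber else last_serial + 1
                lines.append(_ter_line(ter_serial, last_residue, chain))
                serial_counter += 1
        if emit_model_records:
            lines.append("ENDMDL".ljust(80))
    lines.extend(m.line for m in structure.metadata if m.position == "tail")
    lines.append("END".ljust(80))
    return "\n".join(lines) + "\n"


def write_file(
    path: Union[str, Path], structure: Structure, renumber: bool = False
) -> None:
    """Write a structure to disk; gzip output keyed on a ``.gz`` suffix."""
    path = Path(path)
    text = write_structure(structure, renumber=renumber)
    if path.suffix == ".gz":
        with gzip.open(path, "wb") as handle:
            handle.write(text.encode("latin-1"))
    else:
        path.write_text(text, encoding="latin-1")


def clean(structure: Structure, renumber_residues: bool = False) -> Structure:
    """Normalize a structure so its output passes a strict re-parse.

    Returns a copy with every field truncated/stripped to its column
    width, atom serials regenerated (TER records counted along with the
    atoms), single-character codes defaulted to ``' '`` when blank, and
    metadata lines whose record name is outside the PDB vocabulary
    dropped.  With ``renumber_residues=True``, residues are additionally
    renumbered consecutively from 1 within each chain (insertion codes
    cleared).  Idempotent: cleaning a clean structure changes nothing.
    """
    from .analysis import renumber_atoms, renumber_residues as _renumber_res

    result = copy.deepcopy(structure)
    result.metadata = [
        m for m in result.metadata if classify_line(m.line) is RecordKind.METADATA
    ]
    for model in result.models:
        for chain in model.chains:
            chain.chain_id = (chain.chain_id or " ")[:1]
            for residue in chain.residues:
                residue.res_name = residue.res_name.strip()[:3]
                residue.ins_code = (residue.ins_code or " ")[:1]
                for atom in residue.atoms:
                    atom.name = atom.name.strip()[:4]
                    atom.alt_loc = (atom.alt_loc or " ")[:1]
                    atom.seg_id = atom.seg_id.strip()[:4]
                    atom.element = atom.element.strip()[:2]
                    atom.charge = atom.charge.strip()[:2]
                    atom.occupancy = round(float(atom.occupancy), 2)
                    atom.b_factor = round(float(atom.b_factor), 2)
        if renumber_residues:
            model.chains = [_renumber_res(c, start=1) for c in model.chains]
    return renumber_atoms(result)
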