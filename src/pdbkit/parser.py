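"""Assemble a Structure from PDB text; serial and parallel parse modes.

Parsing is split into two phases so the parallel mode is trivially
equivalent to the serial one:

1. *Tokenize*: each line independently becomes an atom record, a control
   token, a metadata line or a parse error.  This is the per-line work
   that parallel mode distributes over worker processes, chunked at line
   boundaries.
2. *Assemble*: the merged, file-ordered token stream is grouped into the
   Model/Chain/Residue hierarchy serially.  Consecutive coordinate
   records form a residue until (resName, resSeq, iCode) changes or a TER
   intervenes; a chain closes on chain-id change or TER; MODEL/ENDMDL
   bracket models.  Files without MODEL records yield one model with id 1.

Parsing never raises on malformed content: every rejected line is
collected as a :class:`~pdbkit.records.ParseError` and parsing continues
("no crashes" even on a garbled archive).
"""

from __future__ import annotations

import enum
import gzip
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .model import Atom, Chain, MetadataLine, Model, Residue, Structure
from .records import (
    AtomRecord,
    ControlToken,
    ParseError,
    RecordKind,
    classify_line,
    parse_control_line,
    parse_coord_line,
)

__all__ = ["ParseMode", "ParseResult", "parse_text", "parse_file", "split_models"]


class ParseMode(enum.Enum):
    SERIAL = "serial"
    PARALLEL = "parallel"


@dataclass
class ParseResult:
    """A parsed structure plus every problem found along the way.

    ``errors`` is ordered by line number.  ``lints`` are soft warnings
    about format oddities that were still parsed (e.g. coordinates after
    ENDMDL, a chain id re-opened after an intervening chain).
    """

    structure: Structure
    errors: list[ParseError] = field(default_factory=list)
    lints: list[str] = field(default_factory=list)


_Token = Union[AtomRecord, ControlToken, ParseError, MetadataLine]


def _tokenize_chunk(
    lines: Sequence[str], first_line_no: int, strict: bool
) -> list[_Token]:
    """Per-line decoding: the embarrassingly parallel part of parsing.

    Metadata position tags are provisional here (chunks cannot know about
    earlier chunks); assembly re-tags them.
    """
    tokens: list[_Token] = []
    for offset, line in enumerate(lines):
        line_no = first_line_no + offset
        kind = classify_line(line)
        if kind is RecordKind.COORD:
            tokens.append(parse_coord_line(line, line_no, strict))
        elif kind in (RecordKind.TER, RecordKind.MODEL, RecordKind.ENDMDL, RecordKind.END):
            tokens.append(parse_control_line(line, line_no))
        elif kind is RecordKind.METADATA:
            tokens.append(MetadataLine(line=line, position="head"))
        else:
            tokens.append(
                ParseError(line_no, line, f"unknown record name {line[:6]!r}")
            )
    return tokens


def _assemble(tokens: Sequence[_Token]) -> ParseResult:
    """Group a file-ordered token stream into the hierarchy."""
    models: list[Model] = []
    metadata: list[MetadataLine] = []
    errors: list[ParseError] = []
    lints: list[str] = []

    current_model: Model | None = None
    current_chain: Chain | None = None
    current_residue: Residue | None = None
    used_model_ids: set[int] = set()
    coord_block_seen = False
    model_was_closed = False  # an ENDMDL has closed a model

    def close_chain() -> None:
        nonlocal current_chain, current_residue
        current_chain = None
        current_residue = None

    def close_model() -> None:
        nonlocal current_model
        if current_model is not None:
            models.append(current_model)
            current_model = None
        close_chain()

    def next_implicit_id() -> int:
        return max(used_model_ids) + 1 if used_model_ids else 1

    for token in tokens:
        if isinstance(token, ParseError):
            errors.append(token)
            continue
        if isinstance(token, MetadataLine):
            metadata.append(
                MetadataLine(token.line, "tail" if coord_block_seen else "head")
            )
            continue
        if isinstance(token, ControlToken):
            coord_block_seen = True
            if token.kind is RecordKind.MODEL:
                if current_model is not None:
                    lints.append(
                        f"line {token.line_no}: MODEL {token.model_id} opened "
                        f"before ENDMDL of model {current_model.model_id}"
                    )
                    close_model()
                model_id = token.model_id
                assert model_id is not None
                if model_id in used_model_ids:
                    lints.append(f"line {token.line_no}: duplicate MODEL id {model_id}")
                used_model_ids.add(model_id)
                current_model = Model(model_id=model_id)
            elif token.kind is RecordKind.ENDMDL:
                if current_model is None:
                    lints.append(f"line {token.line_no}: ENDMDL without open MODEL")
                close_model()
                model_was_closed = True
            elif token.kind is RecordKind.TER:
                close_chain()
            # END: coordinate section terminator, nothing to build
            continue

        # AtomRecord
        rec = token
        coord_block_seen = True
        if current_model is None:
            implicit_id = next_implicit_id()
            if model_was_closed:
                lints.append(
                    f"line {rec.line_no}: coordinates after ENDMDL attached to "
                    f"implicit model {implicit_id}"
                )
            used_model_ids.add(implicit_id)
            current_model = Model(model_id=implicit_id)
        if current_chain is None or current_chain.chain_id != rec.chain_id:
            if current_chain is not None and any(
                c.chain_id == rec.chain_id for c in current_model.chains
            ):
                lints.append(
                    f"line {rec.line_no}: chain id {rec.chain_id!r} re-opened"
                )
            current_chain = Chain(chain_id=rec.chain_id)
            current_model.chains.append(current_chain)
            current_residue = None
        residue_key = (rec.res_name, rec.res_seq, rec.ins_code)
        if current_residue is None or (
            current_residue.res_name,
            current_residue.res_seq,
            current_residue.ins_code,
        ) != residue_key:
            current_residue = Residue(
                res_name=rec.res_name, res_seq=rec.res_seq, ins_code=rec.ins_code
            )
            current_chain.residues.append(current_residue)
        current_residue.atoms.append(
            Atom(
                serial=rec.serial,
                name=rec.name,
                coord=np.array([rec.x, rec.y, rec.z]),
                alt_loc=rec.alt_loc,
                occupancy=rec.occupancy,
                b_factor=rec.b_factor,
                seg_id=rec.seg_id,
                element=rec.element,
                charge=rec.charge,
                is_hetatm=rec.is_hetatm,
            )
        )

    close_model()
    errors.sort(key=lambda e: e.line_no)
    return ParseResult(
        structure=Structure(models=models, metadata=metadata),
        errors=errors,
        lints=lints,
    )


def parse_text(text: str, strict: bool = False) -> ParseResult:
    """Parse PDB-format text into a Structure plus collected errors.

    Pure function of ``(text, strict)``; never raises on content.
    """
    return _assemble(_tokenize_chunk(text.splitlines(), 1, strict))


def _chunk_bounds(n_lines: int, workers: int) -> list[tuple[int, int]]:
    """Split ``n_lines`` into up to ``workers`` contiguous [start, stop) spans."""
    workers = max(1, min(workers, n_lines)) if n_lines else 1
    base, extra = divmod(n_lines, workers)
    bounds = []
    start = 0
    for i in range(workers):
        stop = start + base + (1 if i < extra else 0)
        if stop > start:
            bounds.append((start, stop))
        start = stop
    return bounds


def parse_file(
    path: Union[str, Path],
    strict: bool = False,
    mode: ParseMode = ParseMode.SERIAL,
    workers: int = 1,
) -> ParseResult:
    """Parse a PDB file (plain text or gzip, keyed on a ``.gz`` suffix).

    PARALLEL mode splits the input at line boundaries into roughly
    ``workers`` chunks, decodes lines in worker processes and assembles
    the merged stream serially, so its result is identical to SERIAL for
    any input — same structure, same error list.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as handle:  # type: ignore[operator]
        data = handle.read()
    # PDB is a single-byte format; latin-1 maps every byte to one char so
    # stray non-ASCII bytes in metadata survive verbatim.
    lines = data.decode("latin-1").splitlines()

    if mode is ParseMode.SERIAL or workers == 1 or len(lines) < 2:
        return _assemble(_tokenize_chunk(lines, 1, strict))

    bounds = _chunk_bounds(len(lines), workers)
    with ProcessPoolExecutor(max_workers=len(bounds)) as pool:
        futures = [
            pool.submit(_tokenize_chunk, lines[start:stop], start + 1, strict)
            for start, stop in bounds
        ]
        tokens: list[_Token] = []
        for future in futures:
            tokens.extend(future.result())
    return _assemble(tokens)


def split_models(structure: Structure) -> list[Structure]:
    """Split a multi-model structure into single-model structures.

    Each output carries exactly one model (id preserved) plus a copy of
    the parent metadata; the input is left untouched.  A structure with
    zero models yields an empty list.
    """
    import copy

    return [
        Structure(models=[copy.deepcopy(model)], metadata=list(structure.metadata))
        for model in structure.models
    ]
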