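"""Column-exact decoding and encoding of single PDB lines.

The PDB coordinate format is fixed-width: every field of an ATOM/HETATM
record lives at a fixed 1-based column range (v3.3 layout)::

    record name 1-6   serial 7-11   name 13-16   altLoc 17
    resName 18-20     chainID 22    resSeq 23-26 iCode 27
    x 31-38  y 39-46  z 47-54       occupancy 55-60  B 61-66
    segID 73-76       element 77-78 charge 79-80

Decoding never raises on malformed input: every failure is returned as a
:class:`ParseError` carrying the line number, the verbatim line and a
reason.  Strict mode requires lines of at least 66 columns with all
numeric fields present; lenient mode substitutes documented defaults for
absent trailing columns (occupancy 1.00, B 0.00, empty segID/element/
charge), which is what most of the archive's slightly-off lines need.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Union

__all__ = [
    "RecordKind",
    "AtomRecord",
    "ParseError",
    "ControlToken",
    "FieldOverflowError",
    "classify_line",
    "parse_coord_line",
    "format_coord_line",
    "parse_control_line",
]


class RecordKind(enum.Enum):
    """Coarse classification of a PDB line, from columns 1-6 only."""

    COORD = "COORD"
    TER = "TER"
    MODEL = "MODEL"
    ENDMDL = "ENDMDL"
    END = "END"
    METADATA = "METADATA"
    UNKNOWN = "UNKNOWN"


# PDB v3.3 record-name vocabulary, minus the coordinate/control names
# classified separately above.  ANISOU/SIGATM/SIGUIJ/CONECT are preserved
# verbatim as metadata; their contents are not interpreted.
_METADATA_RECORD_NAMES = frozenset(
    {
        "HEADER", "OBSLTE", "TITLE", "SPLIT", "CAVEAT", "COMPND", "SOURCE",
        "KEYWDS", "EXPDTA", "NUMMDL", "MDLTYP", "AUTHOR", "REVDAT", "SPRSDE",
        "JRNL", "REMARK", "DBREF", "DBREF1", "DBREF2", "SEQADV", "SEQRES",
        "MODRES", "HET", "HETNAM", "HETSYN", "FORMUL", "HELIX", "SHEET",
        "SSBOND", "LINK", "CISPEP", "SITE", "CRYST1", "ORIGX1", "ORIGX2",
        "ORIGX3", "SCALE1", "SCALE2", "SCALE3", "MTRIX1", "MTRIX2", "MTRIX3",
        "ANISOU", "SIGATM", "SIGUIJ", "CONECT", "MASTER",
    }
)


@dataclass
class AtomRecord:
    """One decoded coordinate line: atom fields plus the residue/chain
    context printed on the same line, before hierarchy assembly."""

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    ins_code: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    seg_id: str
    element: str
    charge: str
    is_hetatm: bool
    line_no: int = 0


@dataclass(frozen=True)
class ParseError:
    """A rejected input line: 1-based line number, verbatim text, reason."""

    line_no: int
    line: str
    reason: str


@dataclass(frozen=True)
class ControlToken:
    """A decoded TER / MODEL / ENDMDL / END record."""

    kind: RecordKind
    model_id: Optional[int] = None
    serial: Optional[int] = None
    line_no: int = 0


class FieldOverflowError(ValueError):
    """A numeric field does not fit its fixed column width on output."""


def classify_line(line: str) -> RecordKind:
    """Classify a line by its record name (columns 1-6).

    Total function: any line maps to a kind, unrecognised record names to
    ``UNKNOWN``.
    """
    key = line[:6].ljust(6)
    if key in ("ATOM  ", "HETATM"):
        return RecordKind.COORD
    name = key.strip()
    if name == "TER":
        return RecordKind.TER
    if name == "MODEL":
        return RecordKind.MODEL
    if name == "ENDMDL":
        return RecordKind.ENDMDL
    if name == "END":
        return RecordKind.END
    if name in _METADATA_RECORD_NAMES:
        return RecordKind.METADATA
    return RecordKind.UNKNOWN


def _slice(line: str, start: int, stop: int) -> str:
    """Columns ``start``..``stop`` (1-based, inclusive), blank-padded."""
    return line[start - 1 : stop].ljust(stop - start + 1)


def _char(line: str, col: int) -> str:
    return line[col - 1] if len(line) >= col else " "


def parse_coord_line(
    line: str, line_no: int = 0, strict: bool = False
) -> Union[AtomRecord, ParseError]:
    """Decode one ATOM/HETATM line into an :class:`AtomRecord`.

    Never raises: malformed fields come back as :class:`ParseError`.
    Trailing CR/LF and trailing whitespace are ignored for parsing; the
    verbatim line is preserved inside any error.
    """
    raw = line
    line = line.rstrip("\r\n")
    try:
        is_hetatm = line[:6].ljust(6) == "HETATM"
        if strict and len(line.rstrip()) < 66:
            return ParseError(line_no, raw, "line shorter than 66 columns (strict)")

        def num_int(lo: int, hi: int, what: str, allow_negative: bool = True):
            text = _slice(line, lo, hi).strip()
            if not text:
                raise _FieldError(f"missing {what} (columns {lo}-{hi})")
            try:
                value = int(text)
            except ValueError:
                raise _FieldError(f"non-numeric {what}: {text!r}") from None
            if not allow_negative and value < 0:
                raise _FieldError(f"negative {what}: {value}")
            return value

        def num_float(lo: int, hi: int, what: str):
            text = _slice(line, lo, hi).strip()
            if not text:
                raise _FieldError(f"missing {what} (columns {lo}-{hi})")
            try:
                return float(text)
            except ValueError:
                raise _FieldError(f"non-numeric {what}: {text!r}") from None

        serial = num_int(7, 11, "atom serial", allow_negative=False)
        name = _slice(line, 13, 16).strip()
        if not name:
            raise _FieldError("blank atom name (columns 13-16)")
        res_seq = num_int(23, 26, "residue number")
        x = num_float(31, 38, "x coordinate")
        y = num_float(39, 46, "y coordinate")
        z = num_float(47, 54, "z coordinate")

        occ_text = _slice(line, 55, 60).strip()
        b_text = _slice(line, 61, 66).strip()
        if strict:
            occupancy = num_float(55, 60, "occupancy")
            b_factor = num_float(61, 66, "temperature factor")
        else:
            occupancy = float(occ_text) if occ_text else 1.0
            b_factor = float(b_text) if b_text else 0.0

        return AtomRecord(
            serial=serial,
            name=name,
            alt_loc=_char(line, 17),
            res_name=_slice(line, 18, 20).strip(),
            chain_id=_char(line, 22),
            res_seq=res_seq,
            ins_code=_char(line, 27),
            x=x,
            y=y,
            z=z,
            occupancy=occupancy,
            b_factor=b_factor,
            seg_id=_slice(line, 73, 76).strip(),
            element=_slice(line, 77, 78).strip(),
            charge=_slice(line, 79, 80).strip(),
            is_hetatm=is_hetatm,
            line_no=line_no,
        )
    except _FieldError as exc:
        return ParseError(line_no, raw, str(exc))
    except ValueError as exc:  # lenient occupancy/B with garbage content
        return ParseError(line_no, raw, str(exc))


class _FieldError(Exception):
    pass


def _justify_atom_name(name: str, element: str) -> str:
    """Reproduce the standard atom-name column justification.

    Names whose element code is a single character start at column 14
    (`` CA ``); two-character elements start at column 13 (``FE  ``);
    four-character names fill columns 13-16 regardless.
    """
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def format_coord_line(rec: AtomRecord) -> str:
    """Encode an :class:`AtomRecord` as exactly 80 characters.

    Raises :class:`FieldOverflowError` when serial or residue number do
    not fit their column widths (serial > 99999 or resSeq outside
    -999..9999); hybrid-36 extension is deliberately not implemented.
    """
    if not (0 <= rec.serial <= 99999):
        raise FieldOverflowError(f"atom serial {rec.serial} does not fit columns 7-11")
    if not (-999 <= rec.res_seq <= 9999):
        raise FieldOverflowError(
            f"residue number {rec.res_seq} does not fit columns 23-26"
        )
    record_name = "HETATM" if rec.is_hetatm else "ATOM  "
    line = (
        f"{record_name}{rec.serial:5d} "
        f"{_justify_atom_name(rec.name, rec.element)}"
        f"{(rec.alt_loc or ' ')[:1]}"
        f"{rec.res_name[:3]:>3s}"
        f" {(rec.chain_id or ' ')[:1]}"
        f"{rec.res_seq:4d}"
        f"{(rec.ins_code or ' ')[:1]}"
        f"   "
        f"{rec.x:8.3f}{rec.y:8.3f}{rec.z:8.3f}"
        f"{rec.occupancy:6.2f}{rec.b_factor:6.2f}"
        f"      "
        f"{rec.seg_id[:4]:<4s}"
        f"{rec.element[:2]:>2s}"
        f"{rec.charge[:2]:>2s}"
    )
    if len(line) != 80:
        raise FieldOverflowError(
            f"record does not fit fixed columns (formatted length {len(line)})"
        )
    return line


def parse_control_line(
    line: str, line_no: int = 0
) -> Union[ControlToken, ParseError]:
    """Decode a TER / MODEL / ENDMDL / END line.

    The bare ``TER`` dialect (no serial or residue context) is accepted;
    a MODEL record must carry a numeric id in columns 11-14.
    """
    raw = line
    line = line.rstrip("\r\n")
    kind = classify_line(line)
    if kind is RecordKind.MODEL:
        text = _slice(line, 11, 14).strip() or line[6:].strip()
        if not text:
            return ParseError(line_no, raw, "MODEL record without a model id")
        try:
            model_id = int(text)
        except ValueError:
            return ParseError(line_no, raw, f"non-numeric MODEL id: {text!r}")
        return ControlToken(RecordKind.MODEL, model_id=model_id, line_no=line_no)
    if kind is RecordKind.TER:
        serial_text = _slice(line, 7, 11).strip()
        serial: Optional[int] = None
        if serial_text:
            try:
                serial = int(serial_text)
            except ValueError:
                serial = None  # tolerated: TER context is informational
        return ControlToken(RecordKind.TER, serial=serial, line_no=line_no)
    if kind in (RecordKind.ENDMDL, RecordKind.END):
        return ControlToken(kind, line_no=line_no)
    return ParseError(line_no, raw, f"not a control record: {line[:6]!r}")
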