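"""Readers and writers: single/multi-frame PDB, PDBQT, and the PYM container.

PDB parsing is strict fixed-column (v3.3): serial 7-11, name 13-16, altLoc 17,
resName 18-20, chainID 22, resSeq 23-26, iCode 27, x/y/z 31-38/39-46/47-54,
occupancy 55-60, tempFactor 61-66, element 77-78, charge 79-80 (1-based
inclusive). MODEL/ENDMDL blocks become trajectory frames; topology comes from
the first block and later blocks contribute coordinates only. CONECT records
are ignored — bonds come from distance perception.

PYM is a binary columnar container designed for fast block reads::

    header : magic b"PYM1" | version u8=1 | n_atoms u32 LE | n_frames u32 LE
             | column_flags u16 LE
    then   : string columns  name, alt_loc, resname, chain, insertion_code,
             record_kind [, element if flag 0x1] [, one aux column if flag 0x4],
             each as a u32 LE offsets array of length n_atoms+1 followed by the
             concatenated UTF-8 bytes
    then   : integer columns serial, resseq as i64 LE
    then   : real columns occupancy, bfactor, charge as f64 LE
    then   : coordinates, n_frames contiguous blocks of n_atoms*3 f64 LE
    then   : remark lines if flag 0x2 (u32 count, then offsets+bytes as above)

The round trip is bit-exact: floats never pass through text.
"""

from __future__ import annotations

import io
import re
import struct
from pathlib import Path
from typing import BinaryIO, TextIO, Union

import numpy as np

from .core import AtomTable, Molecule
from .elements import AUTODOCK_TYPE_TO_ELEMENT, canonicalize, infer_element_from_name
from .errors import (
    FieldOverflowError,
    PymFormatError,
    PymTruncationError,
    RecordParseError,
    TrajectoryConsistencyError,
)

PYM_MAGIC = b"PYM1"
PYM_VERSION = 1
PYM_FLAG_ELEMENT = 0x1
PYM_FLAG_REMARKS = 0x2
PYM_FLAG_AUX = 0x4

_HEADER_STRUCT = struct.Struct("<4sBIIH")

_REMARK_PREFIXES = (
    "REMARK", "HEADER", "TITLE", "COMPND", "SOURCE", "KEYWDS", "EXPDTA",
    "AUTHOR", "SEQRES", "CRYST1",
    # PDBQT torsion-tree records, preserved verbatim in order:
    "ROOT", "ENDROOT", "BRANCH", "ENDBRANCH", "TORSDOF",
)

PathOrTextIO = Union[str, Path, TextIO]
PathOrBinaryIO = Union[str, Path, BinaryIO]


def _open_text(source: PathOrTextIO, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, newline=""), True
    return source, False


def _open_binary(source: PathOrBinaryIO, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def _parse_charge(field: str, line_number: int) -> float:
    """Parse a PDB charge field like '2+', '1-', '+2', or blank."""
    s = field.strip()
    if not s:
        return 0.0
    m = re.fullmatch(r"(\d+(?:\.\d+)?)([+-])", s)
    if m:
        value = float(m.group(1))
        return value if m.group(2) == "+" else -value
    try:
        return float(s)
    except ValueError:
        raise RecordParseError(f"unparseable charge field {field!r}", line_number)


def _parse_float(field: str, what: str, line_number: int, default=None) -> float:
    s = field.strip()
    if not s:
        if default is not None:
            return default
        raise RecordParseError(f"blank {what} field", line_number)
    try:
        return float(s)
    except ValueError:
        raise RecordParseError(f"unparseable {what} field {field!r}", line_number)


def _parse_int(field: str, what: str, line_number: int, default=None) -> int:
    s = field.strip()
    if not s:
        if default is not None:
            return default
        raise RecordParseError(f"blank {what} field", line_number)
    try:
        return int(s)
    except ValueError:
        raise RecordParseError(f"unparseable {what} field {field!r}", line_number)


def _parse_atom_line(line: str, line_number: int, pdbqt: bool) -> tuple[dict, float, list[float], str]:
    """Parse one ATOM/HETATM line -> (fields, charge, xyz, aux_type)."""
    padded = line.ljust(80)
    raw_name = padded[12:16]
    xyz = [
        _parse_float(padded[30:38], "x coordinate", line_number),
        _parse_float(padded[38:46], "y coordinate", line_number),
        _parse_float(padded[46:54], "z coordinate", line_number),
    ]
    aux_type = ""
    if pdbqt:
        charge = _parse_float(padded[66:76], "partial charge", line_number, default=0.0)
        aux_type = padded[77:79].strip()
        element = AUTODOCK_TYPE_TO_ELEMENT.get(
            aux_type.upper(), ""
        ) or infer_element_from_name(raw_name)
    else:
        charge = _parse_charge(padded[78:80], line_number)
        element_field = padded[76:78].strip()
        element = (
            canonicalize(element_field)
            if element_field
            else infer_element_from_name(raw_name)
        )
    fields = {
        "record_kind": "HETATM" if padded.startswith("HETATM") else "ATOM",
        "serial": _parse_int(padded[6:11], "serial", line_number, default=0),
        "name": raw_name.strip(),
        "alt_loc": padded[16].strip(),
        "resname": padded[17:20].strip(),
        "chain": padded[21].strip(),
        "resseq": _parse_int(padded[22:26], "resseq", line_number, default=0),
        "insertion_code": padded[26].strip(),
        "occupancy": _parse_float(padded[54:60], "occupancy", line_number, default=1.0),
        "bfactor": _parse_float(padded[60:66], "bfactor", line_number, default=0.0),
        "element": element,
        "charge": charge,
    }
    return fields, charge, xyz, aux_type


def _load_pdb_like(source: PathOrTextIO, pdbqt: bool, infer_bonds: bool) -> Molecule:
    stream, close = _open_text(source, "r")
    try:
        rows: list[dict] = []
        aux_types: list[str] = []
        remarks: list[str] = []
        frames: list[list[list[float]]] = []
        current: list[list[float]] = []
        first_frame_done = False
        last_line = 0

        def finish_frame(line_number: int):
            nonlocal current, first_frame_done
            if not current:
                return
            if first_frame_done and len(current) != len(rows):
                raise TrajectoryConsistencyError(
                    f"MODEL block ending near line {line_number} has "
                    f"{len(current)} atoms, expected {len(rows)}"
                )
            frames.append(current)
            current = []
            first_frame_done = True

        for line_number, raw in enumerate(stream, start=1):
            last_line = line_number
            line = raw.rstrip("\r\n")
            tag = line[:6].strip().upper()
            if tag in ("ATOM", "HETATM"):
                fields, _charge, xyz, aux = _parse_atom_line(line, line_number, pdbqt)
                if not first_frame_done:
                    rows.append(fields)
                    aux_types.append(aux)
                current.append(xyz)
            elif tag == "MODEL":
                if current:  # tolerate a missing ENDMDL before the next MODEL
                    finish_frame(line_number)
            elif tag == "ENDMDL":
                finish_frame(line_number)
            elif tag in ("END", "TER", "CONECT"):
                continue
            elif any(line.startswith(p) for p in _REMARK_PREFIXES):
                remarks.append(line)
        finish_frame(last_line)
        if not frames:
            frames = [[]]
        atoms = AtomTable.from_rows(rows)
        frame_arrays = [
            np.asarray(f, dtype=np.float64).reshape(len(rows), 3) for f in frames
        ]
        if not frame_arrays:
            frame_arrays = [np.empty((0, 3))]
        mol = Molecule(atoms=atoms, frames=frame_arrays, remarks=remarks)
        if pdbqt and any(aux_types):
            mol.extra["autodock_type"] = aux_types
        if infer_bonds:
            from .bonds import create_bonds_by_distance

            mol.bonds = create_bonds_by_distance(mol, frame_index=0)
        return mol
    finally:
        if close:
            stream.close()


def load_pdb(source: PathOrTextIO, infer_bonds: bool = False) -> Molecule:
    """Load a single- or multi-frame (MODEL/ENDMDL) PDB file."""
    return _load_pdb_like(source, pdbqt=False, infer_bonds=infer_bonds)


def load_pdbqt(source: PathOrTextIO, infer_bonds: bool = False) -> Molecule:
    """Load an AutoDock PDBQT file.

    Columns 67-76 hold the partial charge (stored in ``charge``); columns
    78-79 hold the AutoDock atom type, mapped to an element where known and
    kept verbatim in the ``autodock_type`` auxiliary column. Torsion-tree
    records (ROOT/BRANCH/ENDBRANCH/TORSDOF) are preserved in ``remarks``.
    """
    return _load_pdb_like(source, pdbqt=True, infer_bonds=infer_bonds)


def _format_name(name: str, element: str) -> str:
    """PDB name justification: names start in column 14 unless the element
    symbol is two characters (or the name fills all four columns)."""
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def _format_charge(charge: float) -> str:
    if charge == 0:
        return "  "
    magnitude = abs(charge)
    if magnitude == int(magnitude) and magnitude <= 9:
        return f"{int(magnitude)}{'+' if charge > 0 else '-'}"
    return "  "  # non-integer charges cannot be rendered in 2 columns


def _atom_line(mol: Molecule, i: int, coords: np.ndarray) -> str:
    at = mol.atoms
    fields = []
    for v in coords:
        text = f"{v:8.3f}"
        if len(text) > 8:
            raise FieldOverflowError(
                f"coordinate {v} cannot be rendered in an 8-column field"
            )
        fields.append(text)
    serial = int(at.serial[i])
    if serial > 99999:
        serial = serial % 100000  # keep the fixed width; identity is positional
    line = (
        f"{at.record_kind[i]:<6}"
        + f"{serial:>5}"
        + " "
        + _format_name(at.name[i], at.element[i])
        + (at.alt_loc[i][:1] or " ")
        + f"{at.resname[i]:>3.3}"
        + " "
        + (at.chain[i][:1] or " ")
        + f"{int(at.resseq[i]):>4}"
        + (at.insertion_code[i][:1] or " ")
        + "   "
        + fields[0] + fields[1] + fields[2]
        + f"{at.occupancy[i]:6.2f}"
        + f"{at.bfactor[i]:6.2f}"
        + " " * 10
        + f"{at.element[i].upper():>2.2}"
        + _format_charge(float(at.charge[i]))
    )
    return line.rstrip()


def save_pdb(mol: Molecule, sink: PathOrTextIO, frames="all") -> None:
    """Write PDB text; multi-frame molecules wrap frames in MODEL/ENDMDL.

    Coordinates render at 3 decimals, occupancy/B-factor at 2. A molecule
    with one frame (or ``frames=<index>``) is written without MODEL records.
    Ends with END.
    """
    if mol.n_frames < 1:
        raise ValueError("molecule has no frames to write")
    stream, close = _open_text(sink, "w")
    try:
        for remark in mol.remarks:
            stream.write(remark + "\n")
        if frames == "all" and mol.n_frames > 1:
            for fi in range(mol.n_frames):
                stream.write(f"MODEL     {fi + 1:>4}\n")
                coords = mol.frames[fi]
                for i in range(mol.n_atoms):
                    stream.write(_atom_line(mol, i, coords[i]) + "\n")
                stream.write("ENDMDL\n")
        else:
            fi = 0 if frames == "all" else frames
            coords = mol.get_frame(fi)
            for i in range(mol.n_atoms):
                stream.write(_atom_line(mol, i, coords[i]) + "\n")
        stream.write("END\n")
    finally:
        if close:
            stream.close()


def _pack_string_column(values: list[str]) -> bytes:
    blobs = [v.encode("utf-8") for v in values]
    offsets = np.zeros(len(blobs) + 1, dtype="<u4")
    if blobs:
        offsets[1:] = np.cumsum([len(b) for b in blobs])
    return offsets.tobytes() + b"".join(blobs)


class _Reader:
    """Tracks the read offset so truncation errors can report a position."""

    def __init__(self, stream: BinaryIO):
        self._stream = stream
        self.offset = 0

    def read(self, n: int, what: str) -> bytes:
        data = self._stream.read(n)
        if len(data) != n:
            raise PymTruncationError(
                f"stream ended while reading {what} ({len(data)}/{n} bytes)",
                self.offset + len(data),
            )
        self.offset += n
        return data


def _read_string_column(reader: _Reader, n_atoms: int, what: str) -> list[str]:
    offsets = np.frombuffer(
        reader.read(4 * (n_atoms + 1), f"{what} offsets"), dtype="<u4"
    )
    if n_atoms and (np.diff(offsets.astype(np.int64)) < 0).any():
        raise PymFormatError(f"non-monotonic offsets in {what} column")
    blob = reader.read(int(offsets[-1]) if n_atoms >= 0 else 0, f"{what} bytes")
    return [
        blob[offsets[k]: offsets[k + 1]].decode("utf-8") for k in range(n_atoms)
    ]


def save_pym(mol: Molecule, sink: PathOrBinaryIO) -> None:
    """Serialize a molecule to the binary columnar PYM layout (bit-exact)."""
    stream, close = _open_binary(sink, "wb")
    try:
        at = mol.atoms
        aux_items = sorted(mol.extra.items())
        flags = PYM_FLAG_ELEMENT
        if mol.remarks:
            flags |= PYM_FLAG_REMARKS
        if aux_items:
            flags |= PYM_FLAG_AUX
        stream.write(
            _HEADER_STRUCT.pack(
                PYM_MAGIC, PYM_VERSION, mol.n_atoms, mol.n_frames, flags
            )
        )
        for col in (at.name, at.alt_loc, at.resname, at.chain,
                    at.insertion_code, at.record_kind, at.element):
            stream.write(_pack_string_column(col))
        if aux_items:
            # one aux column only: name column then values
            key, values = aux_items[0]
            stream.write(_pack_string_column([key]))
            stream.write(_pack_string_column(list(values)))
        stream.write(np.asarray(at.serial, dtype="<i8").tobytes())
        stream.write(np.asarray(at.resseq, dtype="<i8").tobytes())
        stream.write(np.asarray(at.occupancy, dtype="<f8").tobytes())
        stream.write(np.asarray(at.bfactor, dtype="<f8").tobytes())
        stream.write(np.asarray(at.charge, dtype="<f8").tobytes())
        for frame in mol.frames:
            stream.write(np.ascontiguousarray(frame, dtype="<f8").tobytes())
        if mol.remarks:
            stream.write(struct.pack("<I", len(mol.remarks)))
            stream.write(_pack_string_column(mol.remarks))
    finally:
        if close:
            stream.close()


def load_pym(source: PathOrBinaryIO) -> Molecule:
    """Deserialize a PYM byte stream; exact inverse of :func:`save_pym`."""
    stream, close = _open_binary(source, "rb")
    try:
        reader = _Reader(stream)
        header = reader.read(_HEADER_STRUCT.size, "header")
        magic, version, n_atoms, n_frames, flags = _HEADER_STRUCT.unpack(header)
        if magic != PYM_MAGIC:
            raise PymFormatError(f"bad magic {magic!r}, expected {PYM_MAGIC!r}")
        if version != PYM_VERSION:
            raise PymFormatError(f"unsupported PYM version {version}")
        if n_frames < 1:
            raise PymFormatError("PYM requires n_frames >= 1")
        name = _read_string_column(reader, n_atoms, "name")
        alt_loc = _read_string_column(reader, n_atoms, "alt_loc")
        resname = _read_string_column(reader, n_atoms, "resname")
        chain = _read_string_column(reader, n_atoms, "chain")
        icode = _read_string_column(reader, n_atoms, "insertion_code")
        record_kind = _read_string_column(reader, n_atoms, "record_kind")
        if flags & PYM_FLAG_ELEMENT:
            element = _read_string_column(reader, n_atoms, "element")
        else:
            element = [""] * n_atoms
        extra: dict[str, list[str]] = {}
        if flags & PYM_FLAG_AUX:
            key = _read_string_column(reader, 1, "aux column name")[0]
            extra[key] = _read_string_column(reader, n_atoms, "aux column")
        serial = np.frombuffer(reader.read(8 * n_atoms, "serial"), dtype="<i8").copy()
        resseq = np.frombuffer(reader.read(8 * n_atoms, "resseq"), dtype="<i8").copy()
        occupancy = np.frombuffer(reader.read(8 * n_atoms, "occupancy"), dtype="<f8").copy()
        bfactor = np.frombuffer(reader.read(8 * n_atoms, "bfactor"), dtype="<f8").copy()
        charge = np.frombuffer(reader.read(8 * n_atoms, "charge"), dtype="<f8").copy()
        frames = []
        for fi in range(n_frames):
            block = reader.read(8 * 3 * n_atoms, f"frame {fi}")
            frames.append(
                np.frombuffer(block, dtype="<f8").reshape(n_atoms, 3).copy()
            )
        remarks: list[str] = []
        if flags & PYM_FLAG_REMARKS:
            (count,) = struct.unpack("<I", reader.read(4, "remark count"))
            remarks = _read_string_column(reader, count, "remarks")
        atoms = AtomTable(
            serial=serial, name=name, alt_loc=alt_loc, resname=resname,
            chain=chain, resseq=resseq, insertion_code=icode,
            occupancy=occupancy, bfactor=bfactor, element=element,
            charge=charge, record_kind=record_kind,
        )
        return Molecule(atoms=atoms, frames=frames, remarks=remarks, extra=extra)
    finally:
        if close:
            stream.close()


_FORMATS = {".pdb": "pdb", ".pdbqt": "pdbqt", ".pym": "pym"}


def sniff_format(path: str | Path) -> str:
    """Map a file extension to a format name ('pdb' | 'pdbqt' | 'pym')."""
    suffix = Path(path).suffix.lower()
    try:
        return _FORMATS[suffix]
    except KeyError:
        raise ValueError(
            f"cannot determine format from extension {suffix!r}; "
            f"known: {sorted(_FORMATS)}"
        )


def load_any(path: str | Path, fmt: str | None = None,
             infer_bonds: bool = False) -> Molecule:
    fmt = fmt or sniff_format(path)
    if fmt == "pdb":
        return load_pdb(path, infer_bonds=infer_bonds)
    if fmt == "pdbqt":
        return load_pdbqt(path, infer_bonds=infer_bonds)
    if fmt == "pym":
        mol = load_pym(path)
        if infer_bonds:
            from .bonds import create_bonds_by_distance

            mol.bonds = create_bonds_by_distance(mol, frame_index=0)
        return mol
    raise ValueError(f"unknown format {fmt!r}")


def save_any(mol: Molecule, path: str | Path, fmt: str | None = None) -> None:
    fmt = fmt or sniff_format(path)
    if fmt == "pdb":
        save_pdb(mol, path)
    elif fmt == "pym":
        save_pym(mol, path)
    else:
        raise ValueError(f"cannot write format {fmt!r}")
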