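"""Reading CA traces from PDB files and writing the pipeline's outputs.

The reader is a deliberately minimal fixed-column ATOM-record parser
(PDB v3.3 columns): only the first MODEL, only CA atoms with blank or 'A'
alternate-location codes, one chain, one CA per residue (first wins).
HETATM records are ignored, so selenomethionine CA atoms are not read.
Residues keep file order; no renumbering from insertion codes is attempted.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinStructure",
    "StructureParseError",
    "read_structure",
    "three_to_one",
    "write_alignment_fasta",
    "write_pdb",
    "dump_coords_tsv",
    "read_coords_tsv",
]


class StructureParseError(ValueError):
    """Malformed or empty structure input."""


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: one-letter code -> three-letter code (inverse of the standard table)
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class ProteinStructure:
    """One chain's CA trace.

    Attributes
    ----------
    id : structure label (file stem by default).
    residue_names : ordered 3-letter residue codes.
    residue_numbers : ordered author residue numbers.
    coords : (L, 3) CA positions in angstroms.
    flagged : True when any consecutive CA-CA distance falls outside
        (1.0, 10.0) A — a chain-break or unit warning, not a rejection.
    """

    id: str
    residue_names: list[str]
    residue_numbers: list[int]
    coords: np.ndarray
    flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        L = len(self.residue_names)
        if L < 3:
            raise StructureParseError(f"{self.id}: need at least 3 residues, got {L}")
        if self.coords.shape != (L, 3):
            raise StructureParseError(f"{self.id}: coords shape {self.coords.shape} != ({L}, 3)")
        if len(self.residue_numbers) != L:
            raise StructureParseError(f"{self.id}: residue_numbers length mismatch")
        if not np.isfinite(self.coords).all():
            raise StructureParseError(f"{self.id}: non-finite coordinates")
        gaps = np.sqrt(((self.coords[1:] - self.coords[:-1]) ** 2).sum(axis=1))
        if ((gaps <= 1.0) | (gaps >= 10.0)).any():
            self.flagged = True
            warnings.warn(
                f"{self.id}: consecutive CA distance outside (1, 10) A; "
                "possible chain break or wrong units",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residue_names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinStructure):
            return NotImplemented
        # author residue numbers are labels, not structural identity
        return (
            self.id == other.id
            and self.residue_names == other.residue_names
            and np.array_equal(self.coords, other.coords)
        )


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue code to its IUPAC letter; unknowns give 'X'."""
    return _THREE_TO_ONE.get(resname.strip().upper(), "X")


def read_structure(source, chain: str | None = None, id: str | None = None) -> ProteinStructure:
    """Parse a CA trace from PDB text or a PDB file path.

    Parameters
    ----------
    source : path to a PDB file, or PDB-format text (anything containing a
        newline or an ATOM record is treated as text).
    chain : chain identifier to select; default is the first chain seen.
    id : structure label; defaults to the file stem (or "structure" for text).
    """
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source) and os.path.exists(source):
        path = os.fspath(source)
        with open(path) as fh:
            text = fh.read()
        label = id or os.path.splitext(os.path.basename(path))[0]
        name = path
    else:
        text = str(source)
        label = id or "structure"
        name = "<text>"

    names: list[str] = []
    numbers: list[int] = []
    coords: list[tuple[float, float, float]] = []
    seen_residues: set[tuple[str, int, str]] = set()
    selected_chain = chain
    in_first_model = True
    model_seen = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            if model_seen:
                in_first_model = False
            model_seen = True
            continue
        if rec.startswith("ENDMDL"):
            in_first_model = False
            continue
        if not in_first_model or not rec.startswith("ATOM"):
            continue
        atom_name = line[12:16].strip()
        if atom_name != "CA":
            continue
        altloc = line[16:17]
        if altloc not in (" ", "", "A"):
            continue
        chain_id = line[21:22]
        if selected_chain is None:
            selected_chain = chain_id
        if chain_id != selected_chain:
            continue
        resname = line[17:20].strip()
        icode = line[26:27]
        try:
            resnum = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise StructureParseError(
                f"{name}: unparseable ATOM fields at line {lineno}: {line.rstrip()!r}"
            ) from exc
        key = (chain_id, resnum, icode)
        if key in seen_residues:
            continue  # first CA wins on duplicate residues
        seen_residues.add(key)
        names.append(resname)
        numbers.append(resnum)
        coords.append((x, y, z))

    if not coords:
        raise StructureParseError(f"empty structure: no CA atoms found in {name}")
    return ProteinStructure(id=label, residue_names=names, residue_numbers=numbers,
                            coords=np.array(coords, dtype=float))


def write_pdb(structure: ProteinStructure, chain: str = "A") -> str:
    """Serialize a CA trace as fixed-column PDB ATOM records."""
    lines = []
    for k in range(len(structure)):
        x, y, z = structure.coords[k]
        lines.append(
            "ATOM  {serial:>5} {name:^4}{alt}{res:>3} {chain}{num:>4}{icode}   "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2}".format(
                serial=k + 1, name=" CA ", alt=" ",
                res=structure.residue_names[k], chain=chain,
                num=structure.residue_numbers[k], icode=" ",
                x=x, y=y, z=z, occ=1.00, b=0.00, elem="C",
            )
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_alignment_fasta(msta, structures) -> str:
    """Write a multiple alignment as gapped FASTA.

    One record per alignment row, header = structure id, sequence =
    1-letter residue codes with '-' at gap entries. All records come out
    the same length (alignment rectangularity).
    """
    from .msta import GAP  # local import to avoid a cycle

    by_id = {s.id: s for s in structures}
    records = []
    for row_idx, sid in enumerate(msta.structure_ids):
        if sid not in by_id:
            raise StructureParseError(f"alignment row {row_idx} references unknown structure {sid!r}")
        s = by_id[sid]
        seq = []
        for entry in msta.rows[row_idx]:
            if entry == GAP:
                seq.append("-")
            else:
                if entry < 0 or entry >= len(s):
                    raise StructureParseError(
                        f"alignment row {row_idx}: residue index {entry} out of range for {sid!r}"
                    )
                seq.append(three_to_one(s.residue_names[entry]))
        records.append(f">{sid}\n{''.join(seq)}")
    return "\n".join(records) + "\n"


def dump_coords_tsv(structure: ProteinStructure) -> str:
    """Debug dump of the parsed CA trace: id, index, resname, x, y, z."""
    lines = ["id\tindex\tresname\tx\ty\tz"]
    for k in range(len(structure)):
        x, y, z = (float(v) for v in structure.coords[k])
        lines.append(
            f"{structure.id}\t{k}\t{structure.residue_names[k]}\t{x!r}\t{y!r}\t{z!r}"
        )
    return "\n".join(lines) + "\n"


def read_coords_tsv(text: str) -> ProteinStructure:
    """Rebuild a ProteinStructure from its own debug dump (lossless)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != ["id", "index", "resname", "x", "y", "z"]:
        raise StructureParseError("coords TSV: missing or malformed header")
    sid = None
    names, coords = [], []
    for rowno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 6:
            raise StructureParseError(f"coords TSV: malformed row {rowno}")
        sid = parts[0]
        names.append(parts[2])
        coords.append((float(parts[3]), float(parts[4]), float(parts[5])))
    if sid is None:
        raise StructureParseError("coords TSV: no data rows")
    return ProteinStructure(
        id=sid,
        residue_names=names,
        residue_numbers=list(range(1, len(names) + 1)),
        coords=np.array(coords, dtype=float),
    )
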