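"""PDB-format reading/writing and ribonucleotide classification.

The in-memory model is a plain hierarchy: a :class:`MolecularStructureFile`
(an information content entity carrying a PDB identifier) holds one
:class:`StructureModel` per MODEL record, each mapping chain ids to ordered
residue lists.  Only ATOM/HETATM/MODEL/ENDMDL/TER records are interpreted;
everything else is ignored.

Alternate locations are resolved at parse time: for each (residue, atom
name) the highest-occupancy altloc wins, ties broken by file order.
Residue classification is by chemical content, not record type: a residue
with a ribose O2' and a complete base ring is a ribonucleotide whatever
its record says (HETATM nucleotides such as ligand AMP classify as
nucleotides).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "MolecularStructureFile",
    "PDBParseError",
    "PDBWriteError",
    "read_pdb",
    "read_pdb_file",
    "write_pdb",
    "classify_residue",
    "RESIDUE_CLASSES",
]

RESIDUE_CLASSES = ("A", "C", "G", "U", "modified", "non_nucleic")

#: Legacy residue-name spellings accepted for the standard ribonucleotides.
_STANDARD_NAMES = {
    "A": "A", "ADE": "A",
    "C": "C", "CYT": "C",
    "G": "G", "GUA": "G",
    "U": "U", "URA": "U",
}

_PURINE_RING = {"N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"}
_PYRIMIDINE_RING = {"N1", "C2", "N3", "C4", "C5", "C6"}


class PDBParseError(ValueError):
    """Malformed PDB input; message carries the offending line number."""


class PDBWriteError(ValueError):
    """Structure cannot be expressed in PDB fixed columns."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def residue_class(self) -> str:
        return classify_residue(self)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.res_name} {self.seq_num}: no atom {name!r}")
        return a.position

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)


@dataclass
class StructureModel:
    model_num: int
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    def skeleton(self) -> list[tuple[str, int, str, str]]:
        return [(r.chain_id, r.seq_num, r.icode, r.res_name) for r in self.residues()]


@dataclass
class MolecularStructureFile:
    pdb_id: str
    models: list[StructureModel]
    source_path: str = ""

    def __post_init__(self):
        self.pdb_id = self.pdb_id.upper()


def read_pdb(source: str | TextIO, pdb_id: str = "XXXX", source_path: str = "") -> MolecularStructureFile:
    """Parse PDB-format text into a :class:`MolecularStructureFile`.

    A file without MODEL records yields exactly one model numbered 1.
    Raises :class:`PDBParseError` (with the line number) on malformed
    ATOM/HETATM records and on empty input.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    if not text.strip():
        raise PDBParseError("empty PDB input")

    models: list[StructureModel] = []
    current: StructureModel | None = None
    saw_model_record = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            try:
                num = int(line[6:].split()[0])
            except (IndexError, ValueError):
                num = len(models) + 1
            current = StructureModel(model_num=num)
            models.append(current)
        elif rec == "ENDMDL":
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model_record:
                    # coordinates outside MODEL framing: attach to a new model
                    current = StructureModel(model_num=len(models) + 1)
                else:
                    current = StructureModel(model_num=1)
                models.append(current)
            _parse_atom_line(line, lineno, current)
        # TER and all other records: ignored

    if not models:
        raise PDBParseError("no coordinate records found")

    for m in models:
        for chain in m.chains.values():
            for res in chain:
                _resolve_altlocs(res)
            chain.sort(key=lambda r: (r.seq_num, r.icode))

    msf = MolecularStructureFile(pdb_id=pdb_id, models=models, source_path=source_path)
    _check_skeletons(msf)
    return msf


def read_pdb_file(path: str, pdb_id: str | None = None) -> MolecularStructureFile:
    """Read a PDB file from disk; the id defaults to the file stem."""
    import os

    if pdb_id is None:
        pdb_id = os.path.splitext(os.path.basename(path))[0][:4].upper()
    with open(path) as fh:
        return read_pdb(fh, pdb_id=pdb_id, source_path=path)


def _parse_atom_line(line: str, lineno: int, model: StructureModel) -> None:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        seq_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record ({exc})") from exc
    if not name:
        raise PDBParseError(f"line {lineno}: empty atom name")
    if not element:
        element = _guess_element(name)

    chain = model.chains.setdefault(chain_id, [])
    res = None
    for r in reversed(chain):
        if r.seq_num == seq_num and r.icode == icode and r.res_name == res_name:
            res = r
            break
    if res is None:
        res = Residue(chain_id=chain_id, seq_num=seq_num, icode=icode, res_name=res_name)
        chain.append(res)
    res.atoms.append(Atom(name=name, element=element, position=np.array([x, y, z]),
                          occupancy=occupancy, altloc=altloc))


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _resolve_altlocs(res: Residue) -> None:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in res.atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    res.atoms = [best[n] for n in order]


def _check_skeletons(msf: MolecularStructureFile) -> None:
    if len(msf.models) < 2:
        return
    ref = msf.models[0].skeleton()
    for m in msf.models[1:]:
        if m.skeleton() != ref:
            warnings.warn(
                f"{msf.pdb_id}: model {m.model_num} residue skeleton differs "
                f"from model {msf.models[0].model_num}",
                stacklevel=3,
            )
            return


def write_pdb(f: MolecularStructureFile, single_model_writes_model_record: bool = False) -> str:
    """Serialize to PDB text (coordinates in columns 31-54, 3 decimals).

    MODEL/ENDMDL framing is emitted when there is more than one model, or
    always when ``single_model_writes_model_record`` is set.
    """
    if not f.models:
        raise PDBWriteError("structure has no models")
    frame = len(f.models) > 1 or single_model_writes_model_record
    out = io.StringIO()
    for model in f.models:
        if frame:
            out.write(f"MODEL     {model.model_num:>4}\n")
        serial = 1
        for chain_id, chain in model.chains.items():
            if len(chain_id) > 1:
                raise PDBWriteError(f"chain id {chain_id!r} exceeds the 1-character PDB column")
            for res in chain:
                for a in res.atoms:
                    if not np.all(np.isfinite(a.position)):
                        raise PDBWriteError(f"atom {a.name} has non-finite coordinates")
                    out.write(_format_atom_line(serial, a, res))
                    serial += 1
            if chain:
                last = chain[-1]
                out.write(f"TER   {serial:>5}      {last.res_name:>3} "
                          f"{chain_id}{last.seq_num:>4}{last.icode or ' '}\n")
                serial += 1
        if frame:
            out.write("ENDMDL\n")
    out.write("END\n")
    return out.getvalue()


def _format_atom_line(serial: int, a: Atom, res: Residue) -> str:
    # atom-name column convention: 1/2-char element names start in col 14
    name = a.name
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.position
    record = "ATOM" if classify_residue(res) != "non_nucleic" else "HETATM"
    return (
        f"{record:<6}{serial:>5} {name:<4}{a.altloc or ' '}{res.res_name:>3} "
        f"{res.chain_id}{res.seq_num:>4}{res.icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
        f"{a.element:>2}\n"
    )


def classify_residue(r: Residue) -> str:
    """Classify a residue as A/C/G/U, ``modified`` or ``non_nucleic``.

    A standard ribonucleotide must carry a standard residue name, an O2'
    atom and at least 6 base-ring atoms.  A residue with base-ring content
    but a nonstandard name is ``modified``.  The result is independent of
    atom order (a total, deterministic function).
    """
    names = {a.name for a in r.atoms}
    has_purine = len(names & _PURINE_RING) >= 9
    has_pyrimidine = len(names & _PYRIMIDINE_RING) >= 6
    n_ring = len(names & _PURINE_RING) if has_purine else len(names & _PYRIMIDINE_RING)
    std = _STANDARD_NAMES.get(r.res_name.upper())
    if std is not None and "O2'" in names and n_ring >= 6 and (has_purine or has_pyrimidine):
        return std
    if has_purine or has_pyrimidine:
        return "modified"
    return "non_nucleic"
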