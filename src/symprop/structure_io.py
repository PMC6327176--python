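"""Reading and writing protein structures in fixed-width PDB format.

The in-memory model keeps the author's residue numbering verbatim: motif
positions in symmetric propeller design are always cited by author numbers
(e.g. His11, Ser27, Asp31, Trp37 per blade), so file numbering is
authoritative everywhere and internal 0-based indices are never serialized.

CRYST1 metadata is retained so crystal solvent content can be computed from
the Matthews coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "UnitCell",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "ca_trace",
    "solvent_content",
    "AA3_TO_1",
    "AA1_TO_3",
    "MATTHEWS_PROTEIN_CONSTANT",
]

# Matthews' protein constant: 1/(partial specific volume * Avogadro scaling),
# conventional value for the solvent-fraction estimate 1 - 1.23/Vm.
MATTHEWS_PROTEIN_CONSTANT = 1.23

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class PDBParseError(ValueError):
    """Raised on malformed PDB input; the message names the offending line."""


@dataclass
class AtomRecord:
    """A single atom: label, element, position (Å), occupancy, altloc, B."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = " "
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    """One residue, identified by chain, author number and insertion code."""

    chain_id: str
    number: int
    name3: str
    atoms: list[AtomRecord]
    insertion_code: str = " "

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue must contain at least one atom")

    @property
    def is_standard(self) -> bool:
        return self.name3 in AA3_TO_1

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name3, "X")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class UnitCell:
    """Crystal unit cell: edges (Å), angles (deg), space group and Z."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"
    z: int = 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("degenerate unit cell (non-positive volume)")

    @property
    def volume(self) -> float:
        """Cell volume in Å^3 (general triclinic formula)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in
                      (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)


@dataclass
class StructureModel:
    """Ordered chains of residues plus optional crystal metadata."""

    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    unit_cell: UnitCell | None = None
    title: str = ""

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in structure "
                           f"(have {sorted(self.chains)})")
        return self.chains[chain_id]

    def residue(self, chain_id: str, number: int,
                insertion_code: str = " ") -> ResidueRecord:
        for res in self.chain(chain_id):
            if res.number == number and res.insertion_code == insertion_code:
                return res
        raise KeyError(f"no residue {number}{insertion_code.strip()} "
                       f"in chain {chain_id}")

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id)
                       if r.is_standard)


# ---------------------------------------------------------------------------
# PDB parsing (fixed-width dialect: ATOM/HETATM/CRYST1/TER/END)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[str, int, str, str, AtomRecord]:
    """Parse one ATOM/HETATM line into (chain, resnum, icode, resname, atom)."""
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record too short: {line!r}")
    try:
        name = line[12:16].strip()
        altloc = line[16] if line[16] != " " else " "
        resname = line[17:20].strip()
        chain_id = line[21]
        resnum = int(line[22:26])
        icode = line[26] if line[26] != " " else " "
        xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record "
                            f"({exc}): {line.rstrip()!r}") from None
    if not element:
        element = name[:1]
    atom = AtomRecord(name=name, element=element, position=np.array(xyz),
                      occupancy=min(max(occ, 0.0), 1.0), altloc=altloc,
                      b_factor=bfac, is_hetero=line.startswith("HETATM"))
    return chain_id, resnum, icode, resname, atom


def _parse_cryst1(line: str, lineno: int) -> UnitCell:
    try:
        return UnitCell(
            a=float(line[6:15]), b=float(line[15:24]), c=float(line[24:33]),
            alpha=float(line[33:40]), beta=float(line[40:47]),
            gamma=float(line[47:54]),
            space_group=line[55:66].strip() or "P 1",
            z=int(line[66:70]) if line[66:70].strip() else 1,
        )
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed CRYST1 record "
                            f"({exc})") from None


def read_structure(source: str | Path, altloc_policy: str = "highest-occupancy",
                   ) -> StructureModel:
    """Read a PDB-format structure from a path or from raw text.

    ``altloc_policy`` controls alternate locations: ``highest-occupancy``
    keeps the best-occupied copy of each atom (ties to the earlier altloc),
    ``first`` keeps the first copy encountered, ``all`` keeps every copy.
    """
    if altloc_policy not in ("highest-occupancy", "first", "all"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    text: str
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    if not text.strip():
        raise PDBParseError("empty PDB input")

    model = StructureModel()
    # residue key -> ResidueRecord, in file order
    order: list[tuple[str, int, str]] = []
    residues: dict[tuple[str, int, str], tuple[str, list[AtomRecord]]] = {}
    title_parts: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            chain_id, num, icode, resname, atom = _parse_atom_line(line, lineno)
            key = (chain_id, num, icode)
            if key not in residues:
                residues[key] = (resname, [])
                order.append(key)
            residues[key][1].append(atom)
        elif rec == "CRYST1":
            model.unit_cell = _parse_cryst1(line, lineno)
        elif rec == "TITLE ":
            title_parts.append(line[10:].strip())
        elif rec == "ENDMDL":
            break  # first model only
    if not residues:
        raise PDBParseError("no ATOM/HETATM records found")
    model.title = " ".join(title_parts)

    for key in order:
        chain_id, num, icode = key
        resname, atoms = residues[key]
        atoms = _apply_altloc_policy(atoms, altloc_policy)
        res = ResidueRecord(chain_id=chain_id, number=num, name3=resname,
                            atoms=atoms, insertion_code=icode)
        model.chains.setdefault(chain_id, []).append(res)
    return model


def _apply_altloc_policy(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy == "all":
        return atoms
    kept: dict[str, AtomRecord] = {}
    for a in atoms:
        prev = kept.get(a.name)
        if prev is None:
            kept[a.name] = a
        elif policy == "highest-occupancy" and a.occupancy > prev.occupancy:
            kept[a.name] = a
    return list(kept.values())


def write_structure(model: StructureModel, target: str | Path | None = None,
                    ) -> str:
    """Serialize a model as fixed-width PDB text; optionally write to a path."""
    lines: list[str] = []
    if model.title:
        lines.append(f"TITLE     {model.title}")
    cell = model.unit_cell
    if cell is not None:
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} "
            f"{cell.space_group:<11s}{cell.z:4d}"
        )
    serial = 1
    for chain_id, residues in model.chains.items():
        for res in residues:
            rec = "HETATM" if (res.atoms and res.atoms[0].is_hetero) else "ATOM  "
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                lines.append(
                    f"{rec}{serial:5d} {name:<4s}{a.altloc}{res.name3:>3s} "
                    f"{chain_id}{res.number:4d}{res.insertion_code}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                    f"{a.b_factor:6.2f}          {a.element:>2s}"
                )
                serial += 1
        last = residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name3:>3s} "
                     f"{chain_id}{last.number:4d}{last.insertion_code}")
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if target is not None:
        Path(target).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Derived views
# ---------------------------------------------------------------------------

def ca_trace(model: StructureModel, chain_id: str,
             ) -> tuple[list[tuple[int, str, np.ndarray]], int]:
    """Cα trace of one chain: (residue number, one-letter code, position).

    Returns the trace plus a count of residues skipped for lacking a CA atom.
    Hetero residues and waters are excluded.
    """
    trace: list[tuple[int, str, np.ndarray]] = []
    skipped = 0
    for res in model.chain(chain_id):
        if not res.is_standard:
            continue
        ca = res.atom("CA")
        if ca is None:
            skipped += 1
            continue
        trace.append((res.number, res.one_letter, ca.position.copy()))
    return trace, skipped


def solvent_content(cell: UnitCell, molecular_weight: float,
                    molecules_per_asymmetric_unit: int = 1,
                    symmetry_operators: int | None = None,
                    ) -> tuple[float, float]:
    """Crystal solvent fraction and Matthews coefficient Vm.

    Vm = V_cell / (MW * copies-in-cell) in Å^3/Da, with copies-in-cell =
    molecules per ASU times the number of space-group symmetry operators
    (defaulting to the cell's Z). The solvent fraction is the conventional
    estimate 1 - 1.23/Vm, clamped to [0, 1].
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if molecules_per_asymmetric_unit < 1:
        raise ValueError("need at least one molecule per asymmetric unit")
    n_ops = symmetry_operators if symmetry_operators is not None else cell.z
    if n_ops < 1:
        raise ValueError("need at least one symmetry operator")
    copies = molecules_per_asymmetric_unit * n_ops
    vm = cell.volume / (molecular_weight * copies)
    if vm <= 0:
        raise ValueError(f"non-physical Matthews coefficient Vm={vm:.3g}")
    fraction = 1.0 - MATTHEWS_PROTEIN_CONSTANT / vm
    return float(min(max(fraction, 0.0), 1.0)), float(vm)
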