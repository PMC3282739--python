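"""Crystal data model: unit cell, space-group symmetry, structures and file I/O.

Coordinates are stored orthogonal (Å). Symmetry operators act on fractional
coordinates; the :class:`UnitCell` owns the fractional ↔ orthogonal
transforms, using the PDB orthogonalization convention (cell vector **a**
along x, **b** in the x–y plane).

Space-group operators are shipped as an embedded table of ``x,y,z``-triplet
strings keyed by Hermann–Mauguin symbol, so the symmetry data the analysis
depends on is part of the package rather than a runtime lookup.  File parsing
(PDB with CRYST1, mmCIF) is delegated to :mod:`gemmi`; the parsed structure is
converted into the lightweight model defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroup",
    "Atom",
    "Residue",
    "Chain",
    "CrystalStructure",
    "NoCrystalFrameError",
    "SpaceGroupLookupError",
    "orthogonalization_matrix",
    "spacegroup_ops",
    "parse_structure",
    "write_pdb",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE SEC PYL".split()
)


class NoCrystalFrameError(ValueError):
    """Input carries no unit cell / space-group information."""


class SpaceGroupLookupError(KeyError):
    """Hermann–Mauguin symbol not in the supported operator table."""


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0°, 180°): {self}")
        if self.volume < 1e-9:
            raise ValueError(f"degenerate cell (volume ≈ 0): {self}")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orth(self) -> np.ndarray:
        """3×3 orthogonalization matrix (columns are a, b, c in Å)."""
        return orthogonalization_matrix(self)

    @property
    def frac(self) -> np.ndarray:
        return np.linalg.inv(self.orth)

    def orthogonalize(self, v: np.ndarray) -> np.ndarray:
        """Fractional → orthogonal (Å); accepts a vector or an (n, 3) array."""
        return np.asarray(v, dtype=float) @ self.orth.T

    def fractionalize(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.frac.T

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """PDB-convention orthogonalization matrix.

    Column 1 is **a** along x; **b** lies in the x–y plane; **c** completes a
    right-handed frame.  Multiplying a fractional coordinate by this matrix
    yields Å.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    if abs(sg) < 1e-12:
        raise ValueError("degenerate cell: gamma ≈ 0 or 180°")
    cz_y = c * (ca - cb * cg) / sg
    cz_sq = c * c - (c * cb) ** 2 - cz_y ** 2
    if cz_sq <= 0:
        raise ValueError(f"degenerate cell (volume ≈ 0): {cell}")
    m = np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, cz_y],
            [0.0, 0.0, math.sqrt(cz_sq)],
        ]
    )
    return m


# ---------------------------------------------------------------------------
# Symmetry operators
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def _parse_triplet_component(comp: str) -> tuple[np.ndarray, Fraction]:
    """One component of an xyz triplet, e.g. ``-y+1/2`` → row + translation."""
    row = np.zeros(3, dtype=int)
    trans = Fraction(0)
    token = ""
    sign = 1
    comp = comp.replace(" ", "").lower() + "+"  # sentinel terminator
    i = 0
    while i < len(comp):
        ch = comp[i]
        if ch in "+-" and (i == 0 or comp[i - 1] not in "/"):
            if token:
                if token in _AXES:
                    row[_AXES[token]] += sign
                else:
                    trans += sign * Fraction(token)
            token = ""
            sign = 1 if ch == "+" else -1
        else:
            token += ch
        i += 1
    return row, trans


@dataclass(frozen=True)
class SymOp:
    """Space-group operator in the fractional basis: ``x' = rot·x + trans``."""

    rot: tuple[tuple[int, int, int], ...]
    trans: tuple[Fraction, Fraction, Fraction]

    def __post_init__(self) -> None:
        det = round(np.linalg.det(self.rot_matrix))
        if det not in (1, -1):
            raise ValueError(f"operator rotation determinant {det} not ±1")

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        comps = triplet.split(",")
        if len(comps) != 3:
            raise ValueError(f"malformed xyz triplet: {triplet!r}")
        rows, trans = zip(*(_parse_triplet_component(c) for c in comps))
        return cls(
            rot=tuple(tuple(int(v) for v in r) for r in rows),
            trans=tuple(Fraction(t) % 1 for t in trans),
        )

    @classmethod
    def identity(cls) -> "SymOp":
        return cls.from_triplet("x,y,z")

    @property
    def rot_matrix(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def trans_vector(self) -> np.ndarray:
        return np.array([float(t) for t in self.trans])

    @property
    def is_identity(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            t == 0 for t in self.trans
        )

    @property
    def is_order_two_rotation(self) -> bool:
        """True for 2-folds and 2₁ screws: rot² = I, rot ≠ I, det(rot) = +1."""
        r = np.array(self.rot, dtype=int)
        return (
            not np.array_equal(r, np.eye(3, dtype=int))
            and np.array_equal(r @ r, np.eye(3, dtype=int))
            and round(np.linalg.det(r)) == 1
        )

    def compose(self, other: "SymOp") -> "SymOp":
        """``self ∘ other`` with the translation reduced mod 1."""
        r1 = np.array(self.rot, dtype=int)
        r2 = np.array(other.rot, dtype=int)
        rot = r1 @ r2
        trans = tuple(
            (sum(Fraction(int(r1[i, j])) * other.trans[j] for j in range(3)) + self.trans[i]) % 1
            for i in range(3)
        )
        return SymOp(rot=tuple(tuple(int(v) for v in row) for row in rot), trans=trans)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (vector or (n, 3) array)."""
        return np.asarray(frac, dtype=float) @ self.rot_matrix.T + self.trans_vector

    def triplet(self) -> str:
        parts = []
        for i in range(3):
            s = ""
            for j, ax in enumerate("xyz"):
                v = self.rot[i][j]
                if v:
                    s += ("+" if v > 0 and s else "-" if v < 0 else "") + ax
            t = self.trans[i]
            if t:
                s += f"+{t}"
            parts.append(s or "0")
        return ",".join(parts)


# Operator triplets from the standard crystallographic tables.  The five
# groups the analysis needs are all here; adding a group is adding a line.
_SPACE_GROUP_TABLE: dict[str, tuple[str, ...]] = {
    "P1": ("x,y,z",),
    "P21": ("x,y,z", "-x,y+1/2,-z"),
    "C2": ("x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"),
    "P212121": (
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "x+1/2,-y+1/2,-z",
        "-x,y+1/2,-z+1/2",
    ),
    "P4122": (
        "x,y,z",
        "-y,x,z+1/4",
        "-x,-y,z+1/2",
        "y,-x,z+3/4",
        "x,-y,-z+1/2",
        "-y,-x,-z+1/4",
        "-x,y,-z",
        "y,x,-z+3/4",
    ),
    "C2221": (
        "x,y,z",
        "-x,-y,z+1/2",
        "x,-y,-z",
        "-x,y,-z+1/2",
        "x+1/2,y+1/2,z",
        "-x+1/2,-y+1/2,z+1/2",
        "x+1/2,-y+1/2,-z",
        "-x+1/2,y+1/2,-z+1/2",
    ),
    "P3121": (
        "x,y,z",
        "-y,x-y,z+1/3",
        "-x+y,-x,z+2/3",
        "y,x,-z",
        "x-y,-y,-z+2/3",
        "-x,-x+y,-z+1/3",
    ),
}

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def _normalize_hm(symbol: str) -> str:
    return symbol.translate(_SUBSCRIPT_DIGITS).replace(" ", "").replace("_", "").upper()


@dataclass(frozen=True)
class SpaceGroup:
    """A space group as an ordered operator list (identity first)."""

    hm_symbol: str
    ops: tuple[SymOp, ...]

    def __post_init__(self) -> None:
        if not self.ops or not self.ops[0].is_identity:
            raise ValueError("operator list must start with the identity")

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self) -> Iterator[SymOp]:
        return iter(self.ops)

    def contains(self, op: SymOp) -> bool:
        return any(
            op.rot == o.rot and op.trans == o.trans for o in self.ops
        )


def spacegroup_ops(hm_symbol: str) -> SpaceGroup:
    """Resolve a Hermann–Mauguin symbol to its operator list.

    Accepts spaced (``P 41 2 2``), condensed (``P4122``) and
    subscript-unicode (``P4₁22``) spellings.
    """
    key = _normalize_hm(hm_symbol)
    if key not in _SPACE_GROUP_TABLE:
        raise SpaceGroupLookupError(
            f"space group {hm_symbol!r} not in the supported table "
            f"(supported: {sorted(_SPACE_GROUP_TABLE)})"
        )
    ops = tuple(SymOp.from_triplet(t) for t in _SPACE_GROUP_TABLE[key])
    return SpaceGroup(hm_symbol=hm_symbol, ops=ops)


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # orthogonal Å
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float = 0.0

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy(), self.occupancy, self.altloc, self.b_iso)


@dataclass
class Residue:
    name: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AMINO_ACIDS

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def copy(self) -> "Residue":
        return Residue(self.name, self.seqnum, self.icode, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino_acid]

    def heavy_coords(self) -> np.ndarray:
        """Non-hydrogen, non-water atom coordinates, (n, 3)."""
        pts = [
            a.xyz
            for r in self.residues
            if not r.is_water
            for a in r.atoms
            if a.element != "H"
        ]
        return np.array(pts) if pts else np.empty((0, 3))

    def ca_coords(self) -> np.ndarray:
        pts = [r.ca.xyz for r in self.protein_residues if r.ca is not None]
        return np.array(pts) if pts else np.empty((0, 3))

    def ca_map(self) -> dict[int, np.ndarray]:
        """Residue sequence number → Cα coordinate."""
        return {r.seqnum: r.ca.xyz for r in self.protein_residues if r.ca is not None}

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class CrystalStructure:
    """Chains in the asymmetric unit, bound to a cell and space group."""

    chains: list[Chain]
    cell: UnitCell
    sg: SpaceGroup
    name: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids: {ids}")

    @property
    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.protein_residues]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _reduce_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Single-conformer reduction.

    Keep altloc '' outright; among alternates of one atom name keep the
    highest occupancy, ties broken in favour of altloc 'A' (then
    alphabetically).
    """
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        plain = [a for a in group if a.altloc in ("", " ")]
        if plain:
            out.append(plain[0])
            continue
        group.sort(key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc))
        out.append(group[0])
    for a in out:
        a.altloc = ""
    return out


def parse_structure(path: str | Path, format: str | None = None) -> CrystalStructure:
    """Read a PDB or mmCIF file into a :class:`CrystalStructure`.

    The file must carry a crystal frame (CRYST1 record or the mmCIF cell and
    symmetry categories); the space-group symbol is resolved against the
    embedded operator table.  Alternate conformers are reduced to one
    (see :func:`_reduce_altlocs`); hydrogens and waters are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        st = gemmi.read_structure(str(path))
    else:
        fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[format]
        st = gemmi.read_structure(str(path), format=fmt)

    gcell = st.cell
    if not gcell.is_crystal() or gcell.a <= 0:
        raise NoCrystalFrameError(f"{path.name}: no crystal frame (missing cell)")
    hm = st.spacegroup_hm
    if not hm:
        raise NoCrystalFrameError(f"{path.name}: no crystal frame (missing space-group symbol)")
    sg = spacegroup_ops(hm)
    cell = UnitCell(gcell.a, gcell.b, gcell.c, gcell.alpha, gcell.beta, gcell.gamma)

    chains: list[Chain] = []
    model = st[0]
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(gres.name, gres.seqid.num, gres.seqid.icode.strip())
            raw = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=ga.altloc.strip(),
                    b_iso=ga.b_iso,
                )
                for ga in gres
            ]
            res.atoms = _reduce_altlocs(raw)
            if not all(np.all(np.isfinite(a.xyz)) for a in res.atoms):
                raise ValueError(f"{path.name}: non-finite coordinates in {res.name}{res.seqnum}")
            chain.residues.append(res)
        chains.append(chain)
    return CrystalStructure(chains=chains, cell=cell, sg=sg, name=path.stem)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_pdb(
    structure: CrystalStructure,
    path: str | Path,
    *,
    segids: Sequence[str] | None = None,
) -> None:
    """Write a minimal PDB file with a CRYST1 record.

    Chains beyond the 62nd reuse ids cyclically.  ``segids``, if given, is one
    segment identifier per chain (used to carry symmetry-operator provenance
    for expanded assemblies).
    """
    cell = structure.cell
    lines = [
        "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f %-11s%4d"
        % (
            cell.a,
            cell.b,
            cell.c,
            cell.alpha,
            cell.beta,
            cell.gamma,
            structure.sg.hm_symbol,
            1,
        )
    ]
    serial = 1
    for ci, chain in enumerate(structure.chains):
        cid = chain.chain_id if len(chain.chain_id) == 1 else _CHAIN_ALPHABET[ci % 62]
        segid = (segids[ci] if segids else "")[:4]
        for res in chain.residues:
            record = "HETATM" if res.is_water else "ATOM  "
            for atom in res.atoms:
                name = atom.name
                # PDB column alignment: 1-char elements start in column 14
                padded = f" {name:<3s}" if len(atom.element) == 1 and len(name) < 4 else f"{name:<4s}"
                lines.append(
                    "%s%5d %s%1s%3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f      %-4s%2s"
                    % (
                        record,
                        serial % 100000,
                        padded,
                        atom.altloc[:1],
                        res.name[:3],
                        cid,
                        res.seqnum,
                        res.icode[:1],
                        atom.xyz[0],
                        atom.xyz[1],
                        atom.xyz[2],
                        atom.occupancy,
                        atom.b_iso,
                        segid,
                        atom.element[:2].rjust(2),
                    )
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
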