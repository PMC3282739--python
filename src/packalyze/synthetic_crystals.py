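"""Synthetic crystal fixtures with known ground truth.

Generates a rigid poly-alanine helical motif (one or two chains), places it
in a chosen unit cell / space group without symmetry clashes, and writes the
result as a valid PDB file.  A form pair — two crystal forms of the same
motif differing by a known rotation about the c axis, optionally re-indexed
from a primitive tetragonal to a C-centred orthorhombic cell — provides the
ground truth against which twist recovery and fingerprint sensitivity are
tested, with no structure downloads.

The motif is an ideal Cα helix (rise 1.5 Å, 100° per residue, 2.3 Å radius,
consecutive Cα–Cα ≈ 3.8 Å) decorated with approximate backbone N, C, O and a
CB atom — geometrically plausible, rigid, and entirely determined by the
seed.  Two-chain motifs are related by an exact 180° rotation (a true local
2-fold) and positioned in contact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crystal_model import (
    Atom,
    Chain,
    CrystalStructure,
    Residue,
    UnitCell,
    spacegroup_ops,
    write_pdb,
)
from .symmetry_expansion import apply_symop

__all__ = [
    "MotifSpec",
    "FormPairSpec",
    "ClashError",
    "make_motif",
    "make_crystal",
    "make_two_fold_fixture",
    "make_form_pair",
    "write_form_pair",
]

CLASH_CUTOFF = 2.0  # Å, heavy-atom


class ClashError(ValueError):
    """Symmetry images collide; the motif does not fit the asymmetric unit."""


@dataclass(frozen=True)
class MotifSpec:
    n_residues: int = 10
    chain_count: int = 1
    rise: float = 1.5          # Å per residue along the helix axis
    turn_deg: float = 100.0    # rotation per residue
    ca_radius: float = 2.3     # Å, helix radius at Cα
    jitter: float = 0.01       # Å, seeded gaussian coordinate noise
    contact_gap: float = 3.8   # Å, target min distance between the two chains

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("motif needs at least 5 residues")
        if self.chain_count not in (1, 2):
            raise ValueError("chain_count must be 1 or 2")


def _helix_chain(spec: MotifSpec, rng: np.random.Generator, chain_id: str) -> Chain:
    n = spec.n_residues
    omega = math.radians(spec.turn_deg)
    ca = np.array(
        [
            [spec.ca_radius * math.cos(i * omega), spec.ca_radius * math.sin(i * omega), i * spec.rise]
            for i in range(n)
        ]
    )
    chain = Chain(chain_id)
    for i in range(n):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[i] - ca[i + 1]
        next_dir = ca[i + 1] - ca[i] if i < n - 1 else ca[i] - ca[i - 1]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        radial = np.array([math.cos(i * omega), math.sin(i * omega), 0.0])
        res = Residue("ALA", i + 1)
        pos = {
            "N": ca[i] - 1.45 * prev_dir if i > 0 else ca[i] + 1.45 * prev_dir,
            "CA": ca[i],
            "C": ca[i] + 1.52 * next_dir,
            "O": ca[i] + 1.52 * next_dir + 1.23 * radial,
            "CB": ca[i] + 1.53 * radial,
        }
        for name, xyz in pos.items():
            noisy = xyz + rng.normal(0.0, spec.jitter, 3)
            res.atoms.append(Atom(name=name, element=name[0], xyz=noisy))
        chain.residues.append(res)
    return chain


def _rotate_chain_180_x(chain: Chain, yc: float, zc: float, chain_id: str) -> Chain:
    """Exact 2-fold image about the x-axis line (y = yc, z = zc)."""
    out = chain.copy()
    out.chain_id = chain_id
    for res in out.residues:
        for a in res.atoms:
            x, y, z = a.xyz
            a.xyz = np.array([x, 2 * yc - y, 2 * zc - z])
    return out


def _min_heavy_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    if len(a) == 0 or len(b) == 0:
        return np.inf
    d, _ = cKDTree(b).query(a, k=1)
    return float(d.min())


def make_motif(spec: MotifSpec, seed: int = 0) -> list[Chain]:
    """Deterministic helical poly-alanine motif, one or two chains.

    Two-chain motifs are related by an exact 180° rotation about an axis
    perpendicular to the helix, separated so the closest heavy-atom contact
    sits at ``spec.contact_gap``.
    """
    rng = np.random.default_rng(seed)
    chain_a = _helix_chain(spec, rng, "A")
    if spec.chain_count == 1:
        return [chain_a]
    z_mid = float(np.mean([r.ca.xyz[2] for r in chain_a.residues]))
    heavy_a = chain_a.heavy_coords()
    # move the 2-fold axis outward until the mate sits at the target gap
    yc = 0.0
    for _ in range(200):
        chain_b = _rotate_chain_180_x(chain_a, yc, z_mid, "B")
        if _min_heavy_dist(heavy_a, chain_b.heavy_coords()) >= spec.contact_gap:
            break
        yc += 0.05
    return [chain_a, chain_b]


# ---------------------------------------------------------------------------
# Crystal assembly
# ---------------------------------------------------------------------------

_PLACEMENT_CANDIDATES = (
    (0.15, 0.20, 0.12),
    (0.25, 0.25, 0.25),
    (0.20, 0.30, 0.15),
    (0.30, 0.15, 0.20),
    (0.12, 0.12, 0.30),
    (0.35, 0.35, 0.10),
)


def _translate_chains(chains: list[Chain], delta: np.ndarray) -> list[Chain]:
    out = [c.copy() for c in chains]
    for c in out:
        for r in c.residues:
            for a in r.atoms:
                a.xyz = a.xyz + delta
    return out


def _motif_centroid(chains: list[Chain]) -> np.ndarray:
    return np.vstack([c.heavy_coords() for c in chains]).mean(axis=0)


def _check_clashes(structure: CrystalStructure, cutoff: float = CLASH_CUTOFF) -> float:
    """Minimum heavy-atom distance between the motif and any symmetry image
    (excluding exact self-images).  Raises :class:`ClashError` below cutoff."""
    ref = np.vstack([c.heavy_coords() for c in structure.protein_chains])
    worst = np.inf
    for oi, op in enumerate(structure.sg.ops):
        for si in (-1, 0, 1):
            for sj in (-1, 0, 1):
                for sk in (-1, 0, 1):
                    if oi == 0 and (si, sj, sk) == (0, 0, 0):
                        continue
                    pts = []
                    for chain in structure.protein_chains:
                        inst = apply_symop(chain, op, structure.cell, (si, sj, sk), oi)
                        pts.append(inst.chain.heavy_coords())
                    d = _min_heavy_dist(ref, np.vstack(pts))
                    if d < 1e-3:
                        continue  # motif maps onto itself (special position)
                    worst = min(worst, d)
    if worst < cutoff:
        raise ClashError(
            f"symmetry images clash (min heavy-atom distance {worst:.2f} Å < "
            f"{cutoff} Å); use a larger cell"
        )
    return worst


def make_crystal(
    chains: list[Chain],
    cell: UnitCell,
    sg_symbol: str,
    frac_origin: tuple[float, float, float] | None = None,
    name: str = "synthetic",
) -> CrystalStructure:
    """Place a motif in a cell under a space group and verify it packs.

    The motif centroid is moved to ``frac_origin`` (fractional).  When no
    origin is given, a fixed list of candidate placements is tried and the
    first clash-free one used.
    """
    sg = spacegroup_ops(sg_symbol)
    centroid = _motif_centroid(chains)
    candidates = [frac_origin] if frac_origin is not None else list(_PLACEMENT_CANDIDATES)
    last_err: ClashError | None = None
    for cand in candidates:
        target = cell.orthogonalize(np.asarray(cand, dtype=float))
        placed = _translate_chains(chains, target - centroid)
        structure = CrystalStructure(chains=placed, cell=cell, sg=sg, name=name)
        try:
            _check_clashes(structure)
            return structure
        except ClashError as e:
            last_err = e
    assert last_err is not None
    raise last_err


def make_two_fold_fixture(
    spec: MotifSpec | None = None,
    seed: int = 0,
    cell: UnitCell | None = None,
    sg_symbol: str = "P4122",
    gap: float = 4.0,
) -> tuple[CrystalStructure, int]:
    """Single-chain crystal placed just off a crystallographic 2-fold.

    The chain is positioned so its image under a chosen order-2 operator
    touches it at ``gap`` Å — the designed dimer mate is known by
    construction.  Returns the structure and the operator index of the mate.
    """
    spec = spec or MotifSpec(n_residues=10, chain_count=1)
    cell = cell or UnitCell(34.0, 34.0, 80.0)
    sg = spacegroup_ops(sg_symbol)
    # first pure 2-fold whose axis is not the helix axis: rot = diag(1,-1,-1)
    op_index = next(
        i
        for i, op in enumerate(sg.ops)
        if op.is_order_two_rotation and op.rot == ((1, 0, 0), (0, -1, 0), (0, 0, -1))
    )
    op = sg.ops[op_index]
    [chain] = make_motif(spec, seed)
    centroid = _motif_centroid([chain])

    def gap_at(delta: float) -> tuple[float, CrystalStructure]:
        origin = (0.25, delta, 0.25)
        target = cell.orthogonalize(np.asarray(origin))
        placed = _translate_chains([chain], target - centroid)
        st = CrystalStructure(chains=placed, cell=cell, sg=sg, name="two-fold-fixture")
        inst = apply_symop(placed[0], op, cell, (0, 0, 0), op_index)
        return _min_heavy_dist(placed[0].heavy_coords(), inst.chain.heavy_coords()), st

    lo, hi = 0.0, 0.45
    st = None
    for _ in range(60):
        mid = (lo + hi) / 2.0
        g, st = gap_at(mid)
        if g < gap:
            lo = mid
        else:
            hi = mid
    g, st = gap_at(hi)
    _check_clashes(st)
    return st, op_index


# ---------------------------------------------------------------------------
# Form pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormPairSpec:
    """Two crystal forms of one motif related by a known twist about c."""

    twist_deg: float = 2.69
    reindex_tetragonal_to_c: bool = False
    motif: MotifSpec = field(default_factory=lambda: MotifSpec(n_residues=10, chain_count=2))
    cell: UnitCell = field(default_factory=lambda: UnitCell(26.0, 34.0, 40.0))
    sg_symbol: str = "P1"
    frac_origin: tuple[float, float, float] | None = (0.25, 0.25, 0.25)


def _rotate_about_z(chains: list[Chain], angle_deg: float) -> list[Chain]:
    th = math.radians(angle_deg)
    rz = np.array(
        [[math.cos(th), -math.sin(th), 0.0], [math.sin(th), math.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    centroid = _motif_centroid(chains)
    out = [c.copy() for c in chains]
    for c in out:
        for r in c.residues:
            for a in r.atoms:
                a.xyz = rz @ (a.xyz - centroid) + centroid
    return out


def make_form_pair(
    spec: FormPairSpec, seed: int = 0
) -> tuple[CrystalStructure, CrystalStructure, dict]:
    """Two crystal forms whose dimers differ by exactly ``spec.twist_deg``
    about the c axis, plus the ground-truth record.

    Plain pair: both forms share cell and space group; the second form's
    motif is rotated about c through its centroid.  Re-indexed pair
    (``reindex_tetragonal_to_c``): the first form is tetragonal (a = b); the
    second is written in the C-centred orthorhombic setting whose a′, b′ run
    along a+b and a−b — its coordinates are rotated by the analytic −45°
    lattice rotation plus the injected twist.
    """
    chains = make_motif(spec.motif, seed)
    if not spec.reindex_tetragonal_to_c:
        form1 = make_crystal(chains, spec.cell, spec.sg_symbol, spec.frac_origin, name="form1")
        chains2 = _rotate_about_z(chains, spec.twist_deg)
        form2 = make_crystal(chains2, spec.cell, spec.sg_symbol, spec.frac_origin, name="form2")
        truth = {
            "twist_deg": spec.twist_deg,
            "axis": "c",
            "reindexed": False,
            "seed": seed,
            "space_groups": [spec.sg_symbol, spec.sg_symbol],
        }
        return form1, form2, truth

    if abs(spec.cell.a - spec.cell.b) > 1e-6 or abs(spec.cell.gamma - 90.0) > 1e-9:
        raise ValueError("tetragonal-to-C re-indexing requires a = b, gamma = 90°")
    tet_cell = spec.cell
    tet_sg = "P4122" if spec.sg_symbol == "P1" else spec.sg_symbol
    form1 = make_crystal(chains, tet_cell, tet_sg, None, name="form1-tetragonal")
    diag = math.sqrt(2.0) * tet_cell.a
    c_cell = UnitCell(diag, diag, tet_cell.c)
    chains2 = _rotate_about_z(chains, -45.0 + spec.twist_deg)
    form2 = make_crystal(chains2, c_cell, "C2221", None, name="form2-c-orthorhombic")
    truth = {
        "twist_deg": spec.twist_deg,
        "axis": "c",
        "reindexed": True,
        "lattice_rotation_deg": -45.0,
        "seed": seed,
        "space_groups": [tet_sg, "C2221"],
    }
    return form1, form2, truth


def write_form_pair(
    spec: FormPairSpec, seed: int, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write a form pair as two PDB files plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    form1, form2, truth = make_form_pair(spec, seed)
    p1 = outdir / "form1.pdb"
    p2 = outdir / "form2.pdb"
    pj = outdir / "ground_truth.json"
    write_pdb(form1, p1)
    write_pdb(form2, p2)
    pj.write_text(json.dumps(truth, indent=2) + "\n")
    return p1, p2, pj
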