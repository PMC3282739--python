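"""Dimer interface characterization: buried surface area and hydrogen bonds.

SASA is computed with the Shrake–Rupley method on a deterministic spiral
(generalized-Fibonacci) sphere point set, so areas are bit-reproducible run
to run.  The buried interface area per monomer is half the solvent-accessible
area lost on complex formation:

    buried = (SASA(A) + SASA(B) − SASA(AB)) / 2

Hydrogen bonds across the interface are detected by a distance-only criterion
on donor/acceptor heavy atoms — crystallographic models at ~2 Å resolution
carry no hydrogens, so no angle term is applied.  Charged pairs (e.g. Lys NZ
to Asp OD) count as hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .crystal_model import Chain
from .symmetry_expansion import DimerAssembly

__all__ = [
    "SasaResult",
    "HBond",
    "VDW_RADII",
    "sasa",
    "chain_sasa",
    "buried_interface_area",
    "find_hbonds",
]

#: Van der Waals radii (Å); fixed so that areas are reproducible.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
}

DEFAULT_PROBE = 1.4       # Å, water-sized probe
DEFAULT_N_POINTS = 960    # sphere points per atom
HBOND_CUTOFF = 3.9        # Å, heavy-atom donor–acceptor distance

# Donor/acceptor heavy atoms.  Backbone: N donates, O (and OXT) accepts.
# Side chains per residue type; Cys SG and Tyr OH act in both roles.
_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "CYS": ("SG",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}
_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "CYS": ("SG",),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}


@dataclass
class SasaResult:
    atom_areas: np.ndarray      # Å² per atom, input order
    total: float                # Å²
    probe: float
    n_points: int


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, str, int, str]     # (chain id, residue name, seqnum, atom)
    acceptor: tuple[str, str, int, str]
    distance: float                      # Å


def _spiral_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's area is the fraction of its expanded-sphere (vdW + probe)
    test points not occluded by any neighbour, times the sphere area.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("need at least 100 sphere points")
    coords = np.asarray(coords, dtype=float)
    unknown = sorted({e.upper() for e in elements} - set(VDW_RADII))
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    radii = np.array([VDW_RADII[e.upper()] for e in elements]) + probe
    n = len(coords)
    sphere = _spiral_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    max_r = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= radii[j]
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_points
    return SasaResult(atom_areas=areas, total=float(areas.sum()), probe=probe, n_points=n_points)


def _chain_heavy(chain: Chain) -> tuple[np.ndarray, list[str]]:
    coords, elements = [], []
    for res in chain.residues:
        if res.is_water:
            continue
        for a in res.atoms:
            if a.element.upper() == "H":
                continue
            coords.append(a.xyz)
            elements.append(a.element)
    return np.array(coords), elements


def chain_sasa(chain: Chain, probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS) -> float:
    coords, elements = _chain_heavy(chain)
    return sasa(coords, elements, probe, n_points).total


def buried_interface_area(
    dimer: DimerAssembly,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[float, float]:
    """Buried interface area per monomer (Å²) and as a fraction of the mean
    monomer surface."""
    c1, e1 = _chain_heavy(dimer.chain1.chain)
    c2, e2 = _chain_heavy(dimer.chain2.chain)
    s1 = sasa(c1, e1, probe, n_points).total
    s2 = sasa(c2, e2, probe, n_points).total
    s12 = sasa(np.vstack([c1, c2]), e1 + e2, probe, n_points).total
    buried = (s1 + s2 - s12) / 2.0
    fraction = buried / ((s1 + s2) / 2.0)
    return buried, fraction


def _polar_atoms(chain: Chain, role: str) -> list[tuple[tuple[str, str, int, str], np.ndarray]]:
    out = []
    for res in chain.residues:
        if not res.is_amino_acid:
            continue
        names: set[str] = set()
        if role == "donor":
            if res.name != "PRO":
                names.add("N")
            names.update(_SIDECHAIN_DONORS.get(res.name, ()))
        else:
            names.update(("O", "OXT"))
            names.update(_SIDECHAIN_ACCEPTORS.get(res.name, ()))
        for a in res.atoms:
            if a.name in names:
                out.append(((chain.chain_id, res.name, res.seqnum, a.name), a.xyz))
    return out


def find_hbonds(dimer: DimerAssembly, cutoff: float = HBOND_CUTOFF) -> list[HBond]:
    """Inter-chain hydrogen bonds by donor–acceptor heavy-atom distance.

    All cross-chain donor→acceptor pairs within ``cutoff`` are collected in
    both directions and deduplicated on the unordered atom pair, so a pair of
    dual-role atoms (e.g. two hydroxyls) is counted once.  Sorted by distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chains = (dimer.chain1.chain, dimer.chain2.chain)
    found: dict[frozenset, HBond] = {}
    for ci, cj in ((0, 1), (1, 0)):
        donors = _polar_atoms(chains[ci], "donor")
        acceptors = _polar_atoms(chains[cj], "acceptor")
        if not donors or not acceptors:
            continue
        d_xyz = np.array([p for _, p in donors])
        a_xyz = np.array([p for _, p in acceptors])
        pairs = cKDTree(d_xyz).query_ball_tree(cKDTree(a_xyz), cutoff)
        for di, ais in enumerate(pairs):
            for ai in ais:
                dist = float(np.linalg.norm(d_xyz[di] - a_xyz[ai]))
                key = frozenset((donors[di][0], acceptors[ai][0]))
                bond = HBond(donor=donors[di][0], acceptor=acceptors[ai][0], distance=dist)
                if key not in found or bond.distance < found[key].distance:
                    found[key] = bond
    return sorted(found.values(), key=lambda b: (b.distance, b.donor, b.acceptor))
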