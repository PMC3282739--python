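"""Inter-dimer distance fingerprints and their cross-form comparison.

The packing descriptor is the ordered vector of Cα–Cα distances between a
reference dimer and its closest neighbouring dimer in the lattice.  Two
crystal forms pack their dimers similarly exactly when these vectors agree,
which is scored by

    RMSD = sqrt( Σᵢ (xᵢ − yᵢ)² / n )          (Å)
    r    = Pearson correlation of (x, y)

over the n corresponding entries.  Identical packing gives RMSD 0 / r 1;
unrelated packing gives large RMSD and r near 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .crystal_model import CrystalStructure
from .symmetry_expansion import DimerAssembly, generate_neighbor_dimers

__all__ = [
    "PackingFingerprint",
    "ComparisonResult",
    "nearest_neighbor_dimer",
    "fingerprint",
    "compare",
    "fingerprint_for_structure",
    "compare_structures",
]

PAIRING_MODES = ("all-pairs", "min-per-residue")

#: Label of one fingerprint entry.  all-pairs: ((slot, resnum), (slot, resnum))
#: pairing a reference-dimer residue with a neighbour-dimer residue;
#: min-per-residue: ((slot, resnum), None).
Label = tuple[tuple[int, int], tuple[int, int] | None]


@dataclass
class PackingFingerprint:
    labels: tuple[Label, ...]
    distances: np.ndarray  # Å, same order as labels
    provenance: tuple[int, tuple[int, int, int]]  # (op index, shift) of the neighbour
    mode: str

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("empty fingerprint")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate fingerprint labels")
        if np.any(self.distances < 0):
            raise ValueError("negative distance")

    @property
    def n(self) -> int:
        return len(self.labels)

    def as_dict(self) -> dict[Label, float]:
        return dict(zip(self.labels, self.distances))

    def relabeled(self, swap_ref: bool, swap_nbr: bool) -> "PackingFingerprint":
        """Fingerprint with chain slots renamed in the reference and/or the
        neighbour dimer (deposited chain order is arbitrary)."""

        def flip(tag: tuple[int, int] | None, do: bool):
            if tag is None or not do:
                return tag
            slot, resnum = tag
            return (3 - slot, resnum)

        pairs = sorted(
            (
                ((flip(ref, swap_ref), flip(nbr, swap_nbr)), d)
                for (ref, nbr), d in zip(self.labels, self.distances)
            ),
        )
        labels = tuple(lbl for lbl, _ in pairs)
        dist = np.array([d for _, d in pairs])
        return PackingFingerprint(labels, dist, self.provenance, self.mode)


@dataclass
class ComparisonResult:
    rmsd: float
    pearson_r: float | None  # None when undefined (zero variance)
    n: int
    mapping: tuple[bool, bool]  # (slots swapped in fp2's ref dimer, in its nbr dimer)

    @property
    def pearson_defined(self) -> bool:
        return self.pearson_r is not None


def nearest_neighbor_dimer(
    ref: DimerAssembly,
    structure: CrystalStructure,
    radius: float | None = None,
) -> DimerAssembly:
    """The image of the reference dimer with minimal centroid–centroid
    distance; ties break on (operator index, shift).

    ``radius`` defaults to the largest cell edge, which always reaches the
    nearest lattice translate.
    """
    if radius is None:
        radius = max(structure.cell.a, structure.cell.b, structure.cell.c)
    neighbors = generate_neighbor_dimers(ref, structure, radius)
    if not neighbors:
        raise RuntimeError(
            f"no neighbouring dimer within {radius:.1f} Å; increase the search radius"
        )
    return neighbors[0]  # already sorted by (distance, op index, shift)


def fingerprint(
    ref: DimerAssembly,
    nbr: DimerAssembly,
    mode: str = "all-pairs",
) -> PackingFingerprint:
    """Cα distance fingerprint between a dimer and a neighbouring dimer.

    all-pairs: every Cα(ref) × Cα(nbr) distance over residues present in both
    dimers.  min-per-residue: for each reference residue, the minimum distance
    to any neighbour Cα.  Entries are sorted canonically by label.
    """
    if mode not in PAIRING_MODES:
        raise ValueError(f"unknown pairing mode {mode!r}; choose from {PAIRING_MODES}")
    ref_maps = ref.ca_maps()
    nbr_maps = nbr.ca_maps()
    # residues common to both dimers, slot-wise
    common = [sorted(set(ref_maps[s]) & set(nbr_maps[s])) for s in range(2)]
    if not any(common):
        raise ValueError("no common residues between reference and neighbour dimers")

    ref_pts = [(s + 1, rn, ref_maps[s][rn]) for s in range(2) for rn in common[s]]
    nbr_pts = [(s + 1, rn, nbr_maps[s][rn]) for s in range(2) for rn in common[s]]
    nbr_xyz = np.array([p for _, _, p in nbr_pts])

    labels: list[Label] = []
    dists: list[float] = []
    if mode == "all-pairs":
        ref_xyz = np.array([p for _, _, p in ref_pts])
        dmat = np.linalg.norm(ref_xyz[:, None, :] - nbr_xyz[None, :, :], axis=2)
        for i, (rs, rr, _) in enumerate(ref_pts):
            for j, (ns, nr, _) in enumerate(nbr_pts):
                labels.append(((rs, rr), (ns, nr)))
                dists.append(dmat[i, j])
    else:
        for rs, rr, pt in ref_pts:
            d = np.linalg.norm(nbr_xyz - pt, axis=1).min()
            labels.append(((rs, rr), None))
            dists.append(float(d))

    order = sorted(range(len(labels)), key=lambda i: labels[i])
    prov = (nbr.chain1.symop_index, nbr.chain1.shift)
    return PackingFingerprint(
        labels=tuple(labels[i] for i in order),
        distances=np.array([dists[i] for i in order]),
        provenance=prov,
        mode=mode,
    )


def _compare_fixed(f1: PackingFingerprint, f2: PackingFingerprint) -> tuple[float, float | None, int]:
    d1 = f1.as_dict()
    d2 = f2.as_dict()
    shared = sorted(set(d1) & set(d2))
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared fingerprint labels; need ≥ 2")
    x = np.array([d1[k] for k in shared])
    y = np.array([d2[k] for k in shared])
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = None  # Pearson undefined for a constant vector; never coerced to 0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return rmsd, r, len(shared)


def compare(
    f1: PackingFingerprint,
    f2: PackingFingerprint,
    optimize_mapping: bool = True,
) -> ComparisonResult:
    """RMSD and Pearson correlation between two fingerprints.

    Entries are matched by label after restriction to the shared label set.
    With ``optimize_mapping`` the four within-dimer chain-slot relabelings of
    the second fingerprint are evaluated and the minimum-RMSD one returned —
    chain naming in deposited files carries no meaning.
    """
    if f1.mode != f2.mode:
        raise ValueError(f"pairing modes differ: {f1.mode} vs {f2.mode}")
    swaps = (
        list(itertools.product((False, True), repeat=2))
        if optimize_mapping
        else [(False, False)]
    )
    best: ComparisonResult | None = None
    for swap_ref, swap_nbr in swaps:
        if f1.mode == "min-per-residue" and swap_nbr:
            continue  # neighbour slot is not part of min-per-residue labels
        rmsd, r, n = _compare_fixed(f1, f2.relabeled(swap_ref, swap_nbr))
        if best is None or rmsd < best.rmsd:
            best = ComparisonResult(rmsd=rmsd, pearson_r=r, n=n, mapping=(swap_ref, swap_nbr))
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Whole-structure convenience pipeline
# ---------------------------------------------------------------------------

def fingerprint_for_structure(
    structure: CrystalStructure,
    mode: str = "all-pairs",
    radius: float | None = None,
) -> PackingFingerprint:
    """Dimer reconstruction → closest neighbour → fingerprint, in one call.

    The neighbour is chosen independently for each crystal form: each form
    contributes the geometry of its own two closest dimers.
    """
    from .symmetry_expansion import build_dimer

    ref = build_dimer(structure)
    nbr = nearest_neighbor_dimer(ref, structure, radius)
    return fingerprint(ref, nbr, mode)


def compare_structures(
    s1: CrystalStructure,
    s2: CrystalStructure,
    mode: str = "all-pairs",
    radius: float | None = None,
    optimize_mapping: bool = True,
) -> ComparisonResult:
    return compare(
        fingerprint_for_structure(s1, mode, radius),
        fingerprint_for_structure(s2, mode, radius),
        optimize_mapping,
    )
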