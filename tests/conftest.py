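"""Shared fixtures: synthetic crystals and minimal hand-built assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from packalyze import (
    Atom,
    Chain,
    CrystalStructure,
    FormPairSpec,
    MotifSpec,
    Residue,
    UnitCell,
    make_crystal,
    make_form_pair,
    make_motif,
    spacegroup_ops,
)
from packalyze.symmetry_expansion import ChainInstance, DimerAssembly


@pytest.fixture(scope="session")
def p1_two_chain():
    """Two-chain motif in a P1 cell: the simplest complete crystal form."""
    form, _, _ = make_form_pair(FormPairSpec(twist_deg=0.0), seed=11)
    return form


@pytest.fixture(scope="session")
def p212121_crystal():
    """Single-chain crystal in P2₁2₁2₁, sized so screw mates touch but never
    clash — the packing unit is a symmetry-generated dimer."""
    chains = make_motif(MotifSpec(n_residues=8, chain_count=1), seed=5)
    return make_crystal(chains, UnitCell(18.0, 20.0, 24.0), "P212121")


def make_point_chain(chain_id: str, entries) -> Chain:
    """Chain from (resname, seqnum, [(atom, element, xyz), ...]) tuples."""
    chain = Chain(chain_id)
    for resname, seqnum, atoms in entries:
        res = Residue(resname, seqnum)
        for name, element, xyz in atoms:
            res.atoms.append(Atom(name=name, element=element, xyz=np.asarray(xyz, dtype=float)))
        chain.residues.append(res)
    return chain


def as_dimer(chain_a: Chain, chain_b: Chain) -> DimerAssembly:
    return DimerAssembly(
        ChainInstance(chain_a, 0, (0, 0, 0)),
        ChainInstance(chain_b, 0, (0, 0, 0)),
        provenance="asu-pair",
    )


@pytest.fixture()
def single_residue_dimer_7A():
    """Two one-residue chains whose Cα atoms sit exactly 7 Å apart."""
    a = make_point_chain("A", [("ALA", 1, [("CA", "C", (0, 0, 0))])])
    b = make_point_chain("B", [("ALA", 1, [("CA", "C", (7, 0, 0))])])
    return as_dimer(a, b)
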