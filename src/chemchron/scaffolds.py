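"""Bemis–Murcko scaffolds and generic (carbon-skeleton) frameworks.

A molecule's scaffold is its ring systems plus the linker atoms connecting
them, obtained here by iterative graph pruning: every atom that has exactly
one neighbour, is attached through a single bond, and is not in a ring is
deleted, until a fixed point. Atoms held by a double or triple bond survive
by construction, so exocyclic carbonyl oxygens on ring–ring linkers (as in
benzanilide or chalcone) stay in the scaffold. Acyclic molecules have no
scaffold and are reported as empty.

The generic framework reduces a scaffold to molecular shape only: every
heavy atom becomes an uncharged carbon and every bond a single bond, with
stereochemistry and aromaticity dropped. Benzene and cyclohexane therefore
collapse onto the same framework.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import BondType

from . import chem

#: Key used for acyclic molecules in scaffold count tables.
EMPTY_SCAFFOLD = ""


@dataclass(frozen=True)
class Scaffold:
    """Canonical ring-and-linker core of a molecule.

    ``is_empty`` is true exactly for acyclic inputs, in which case the
    canonical SMILES is the empty string and ``n_rings`` is zero.
    """

    canonical_smiles: str
    n_rings: int
    is_empty: bool

    @property
    def key(self) -> str:
        return self.canonical_smiles


@dataclass(frozen=True)
class GenericFramework:
    """All-carbon, all-single-bond skeleton of a scaffold."""

    canonical_smiles: str
    heavy_atom_count: int


def extract_scaffold(mol: chem.Mol, keep_stereo: bool = True) -> Scaffold:
    """Prune side chains down to the ring-and-linker core.

    ``keep_stereo`` controls whether scaffold keys distinguish
    stereoisomeric cores (the default, so stereo-bearing scaffolds such as
    trans-chalcone keep their double-bond geometry).
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot extract a scaffold from an empty molecule")
    if chem.num_fragments(mol) > 1:
        raise ValueError("multi-fragment molecule: desalt before scaffold extraction")
    if chem.num_rings(mol) == 0:
        return Scaffold(EMPTY_SCAFFOLD, 0, True)

    rw = Chem.RWMol(mol)
    while True:
        Chem.GetSymmSSSR(rw)
        doomed = [
            atom.GetIdx()
            for atom in rw.GetAtoms()
            if atom.GetDegree() == 1
            and not atom.IsInRing()
            and atom.GetBonds()[0].GetBondType() == BondType.SINGLE
        ]
        if not doomed:
            break
        for idx in sorted(doomed, reverse=True):
            rw.RemoveAtom(idx)

    core = rw.GetMol()
    Chem.SanitizeMol(core)
    # stereocentres can lose a defining substituent during pruning
    Chem.AssignStereochemistry(core, cleanIt=True, force=True)
    return Scaffold(
        chem.canonical_smiles(core, isomeric=keep_stereo),
        chem.num_rings(core),
        False,
    )


def scaffold_from_smiles(smiles: str, keep_stereo: bool = True) -> Scaffold:
    mol = chem.parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return extract_scaffold(mol, keep_stereo=keep_stereo)


def generic_framework(scaffold: Scaffold | str) -> GenericFramework:
    """Collapse a scaffold to its carbon skeleton.

    Idempotent and heavy-atom-count preserving; empty scaffolds are an
    error since shape is undefined without rings.
    """
    smiles = scaffold.canonical_smiles if isinstance(scaffold, Scaffold) else scaffold
    if not smiles:
        raise ValueError("empty scaffold has no generic framework")
    mol = chem.parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable scaffold SMILES: {smiles!r}")
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetIsotope(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for bond in rw.GetBonds():
        bond.SetBondType(BondType.SINGLE)
        bond.SetIsAromatic(False)
        bond.SetStereo(Chem.BondStereo.STEREONONE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return GenericFramework(chem.canonical_smiles(out), out.GetNumHeavyAtoms())


def framework_from_smiles(smiles: str) -> GenericFramework:
    """Generic framework of a molecule given directly as SMILES."""
    sc = scaffold_from_smiles(smiles)
    return generic_framework(sc)
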