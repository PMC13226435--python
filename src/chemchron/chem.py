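"""Thin adapter over the molecular toolkit.

All SMILES parsing and canonicalization in the package goes through this
module, so downstream code consumes a single molecular-graph abstraction
(the toolkit ``Mol``) behind one seam.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

# Parse failures are reported through return values, not the toolkit's stderr.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

Mol = Chem.Mol


def parse_smiles(smiles: str) -> Mol | None:
    """Parse a SMILES string; return ``None`` on failure instead of raising."""
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def canonical_smiles(mol: Mol, isomeric: bool = True) -> str:
    """Unique canonical SMILES spelling for string-keyed identity."""
    return Chem.MolToSmiles(mol, isomericSmiles=isomeric)


def canonicalize(smiles: str, isomeric: bool = True) -> str:
    """Canonicalize a SMILES string; raises ``ValueError`` if unparseable."""
    mol = parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return canonical_smiles(mol, isomeric=isomeric)


def num_fragments(mol: Mol) -> int:
    return len(Chem.GetMolFrags(mol))


def heavy_atom_count(mol: Mol) -> int:
    return mol.GetNumHeavyAtoms()


def num_rings(mol: Mol) -> int:
    """Size of the smallest set of smallest rings."""
    return len(Chem.GetSSSR(mol))
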