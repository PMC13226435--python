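"""Structure standardization: desalting and charge neutralization.

Compound libraries carry salts and registration-state charges that would
split one chemotype across several scaffold keys. Standardization keeps the
largest fragment (desalting) and removes protonation-state formal charges
by hydrogen adjustment (neutralization), then canonicalizes. Charges that
cannot be removed without breaking bonds — quaternary nitrogen, charge-
separated groups like nitro written in ionic form — are left intact.

The neutralization rule list is fixed and auditable:

* anionic O or S (carboxylate, sulfonate/phosphate O⁻, alkoxide, thiolate,
  and anionic N such as deprotonated amides): add one hydrogen, charge 0;
* cationic N or P carrying at least one hydrogen (protonated amines,
  anilinium, pyridinium): remove one hydrogen, charge 0;
* an ion adjacent to a bonded counter-charge (nitro, N-oxide, azide …) is
  skipped — removing one side of a charge-separated group would corrupt
  the valence model.

Stereochemistry is preserved; tautomers are not canonicalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from . import chem
from .library_io import CompoundRecord


@dataclass
class StandardizationResult:
    """Outcome of desalt → neutralize → canonicalize for one record."""

    canonical_smiles: str
    was_desalted: bool = False
    was_neutralized: bool = False
    removed_fragments: list[str] = field(default_factory=list)


def desalt(mol: chem.Mol) -> tuple[chem.Mol, list[str]]:
    """Keep the fragment with the most heavy atoms; return removed ones.

    Equal-sized fragments are tie-broken by the lexicographically smallest
    canonical SMILES, so the choice is deterministic across runs.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot desalt an empty molecule")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, []
    keyed = sorted(
        frags, key=lambda f: (-f.GetNumHeavyAtoms(), chem.canonical_smiles(f))
    )
    keep, removed = keyed[0], keyed[1:]
    return keep, [chem.canonical_smiles(f) for f in removed]


# Elements whose anions are protonated / whose protonated cations are stripped.
_NEG_PROTONATABLE = {7, 8, 16}  # N, O, S
_POS_DEPROTONATABLE = {7, 15}  # N, P


def neutralize(mol: chem.Mol) -> tuple[chem.Mol, bool]:
    """Remove protonation-state formal charges by hydrogen adjustment."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot neutralize an empty molecule")
    rw = Chem.RWMol(mol)
    changed = False
    for atom in rw.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        # charge-separated neighbour => not a protonation-state charge
        if any(n.GetFormalCharge() * charge < 0 for n in atom.GetNeighbors()):
            continue
        z = atom.GetAtomicNum()
        if charge < 0 and z in _NEG_PROTONATABLE:
            atom.SetFormalCharge(charge + 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            changed = True
        elif charge > 0 and z in _POS_DEPROTONATABLE and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(charge - 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
            atom.SetNoImplicit(True)
            changed = True
    if not changed:
        return mol, False
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out, True


def standardize_smiles(smiles: str) -> StandardizationResult:
    """Desalt, then neutralize, then canonicalize one SMILES string.

    Idempotent: standardizing the output reproduces it.
    """
    mol = chem.parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    kept, removed = desalt(mol)
    kept, was_neutralized = neutralize(kept)
    return StandardizationResult(
        canonical_smiles=chem.canonical_smiles(kept),
        was_desalted=bool(removed),
        was_neutralized=was_neutralized,
        removed_fragments=removed,
    )


def standardize_record(record: CompoundRecord) -> StandardizationResult:
    """Standardize one compound record; parse-failed input is an error."""
    if record.parse_failed:
        raise ValueError(f"record {record.id!r} is flagged parse-failed")
    return standardize_smiles(record.smiles)
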