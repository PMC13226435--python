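"""Synthetic compound-library generator for end-to-end testing.

Real bioactive libraries have three structural signatures this generator
reproduces under full control: a scaffold frequency distribution dominated
by a handful of privileged cores (emulated with a Zipf rank-frequency law
over a scaffold pool), registration noise in the form of salts and charged
protonation states, and an exponentially growing number of first-reported
molecules per year. Every molecule is built by decorating a pool scaffold
with small substituents, so its true scaffold is known by construction and
scaffold extraction can be validated round-trip.

Year allocation is deterministic given the spec (largest-remainder
apportionment of the geometric growth curve to the target library size),
so the realized annual counts follow (1+g)^(year-first) as closely as
integer counts allow; which molecules land in which year is randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem
from .library_io import CompoundRecord

#: The ten most common ring-and-linker cores of bioactive chemistry
#: (benzene, biphenyl, pyridine, indole, benzanilide, pyrrolidine,
#: quinoline, chalcone, isoflavone, naphthalene), used as the default
#: scaffold pool in rank order.
PRIVILEGED_SCAFFOLDS: list[tuple[str, str]] = [
    ("benzene", "c1ccccc1"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    ("pyridine", "c1ccncc1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("benzanilide", "O=C(Nc1ccccc1)c1ccccc1"),
    ("pyrrolidine", "C1CCNC1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("chalcone", "O=C(/C=C/c1ccccc1)c1ccccc1"),
    ("isoflavone", "O=c1cc(-c2ccccc2)oc2ccccc12"),
    ("naphthalene", "c1ccc2ccccc2c1"),
]

DEFAULT_SUBSTITUENTS = ["C", "CC", "O", "N", "F", "Cl", "OC"]

_COUNTERIONS = ["[Na+]", "[Cl-]", "[K+]", "[Br-]"]


@dataclass
class SyntheticLibrarySpec:
    """Parameters of one synthetic library.

    ``zipf_exponent`` skews scaffold usage (0 = uniform); ``annual_growth``
    g makes expected new-molecule counts grow as (1+g) per year across
    ``year_range``; ``salt_fraction`` of records are emitted as salts or
    charged forms whose standardization recovers the neutral parent.
    """

    n_molecules: int
    scaffold_pool: list[str] = field(
        default_factory=lambda: [s for _, s in PRIVILEGED_SCAFFOLDS]
    )
    zipf_exponent: float = 1.5
    year_range: tuple[int, int] = (1976, 2024)
    annual_growth: float = 0.116
    salt_fraction: float = 0.1
    substituents: list[str] = field(default_factory=lambda: list(DEFAULT_SUBSTITUENTS))
    max_substituents: int = 3
    seed: int = 0


def _decoration_sites(mol: chem.Mol) -> list[int]:
    """Ring carbons with at least one hydrogen to replace."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.IsInRing() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
        and a.GetFormalCharge() == 0
    ]


def decorate_scaffold(
    scaffold_smiles: str,
    rng: np.random.Generator,
    substituents: list[str] = DEFAULT_SUBSTITUENTS,
    max_substituents: int = 3,
    _mol_cache: dict = {},
) -> str:
    """Attach 0..max substituents at random ring hydrogens via single bonds.

    The result's extracted scaffold equals the input scaffold (side chains
    attached by single bonds prune away), which downstream tests rely on.
    """
    core = _mol_cache.get(scaffold_smiles)
    if core is None:
        core = chem.parse_smiles(scaffold_smiles)
        if core is None:
            raise ValueError(f"unparseable scaffold SMILES: {scaffold_smiles!r}")
        _mol_cache[scaffold_smiles] = core
    n_subs = int(rng.integers(0, max_substituents + 1))
    if n_subs == 0:
        return chem.canonical_smiles(core)
    sites = _decoration_sites(core)
    if not sites:
        return chem.canonical_smiles(core)
    # one substituent per site at most: each site is guaranteed one spare H
    n_subs = min(n_subs, len(sites))
    chosen = rng.choice(sites, size=n_subs, replace=False)
    rw = Chem.RWMol(core)
    for site in chosen:
        sub = substituents[int(rng.integers(0, len(substituents)))]
        frag = chem.parse_smiles(sub)
        amap = {}
        for atom in frag.GetAtoms():
            amap[atom.GetIdx()] = rw.AddAtom(Chem.Atom(atom.GetAtomicNum()))
        for bond in frag.GetBonds():
            rw.AddBond(amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()], bond.GetBondType())
        rw.AddBond(int(site), amap[0], Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return chem.canonical_smiles(out)


def _salt_form(smiles: str, rng: np.random.Generator) -> str:
    """Emit a molecule as a salt and/or charged form.

    Desalting plus neutralization must recover the input exactly, so the
    counter-ion is always smaller than the parent and any charge placed is
    a protonation-state charge.
    """
    mol = chem.parse_smiles(smiles)
    mode = int(rng.integers(0, 2))
    if mode == 1:
        # protonate a non-aromatic amine, or deprotonate a hydroxyl
        rw = Chem.RWMol(mol)
        done = False
        for atom in rw.GetAtoms():
            if (atom.GetAtomicNum() == 7 and not atom.GetIsAromatic()
                    and atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() > 0):
                atom.SetFormalCharge(1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                done = True
                ion = "[Cl-]"
                break
        if not done:
            for atom in rw.GetAtoms():
                if (atom.GetAtomicNum() == 8 and atom.GetFormalCharge() == 0
                        and atom.GetTotalNumHs() == 1 and atom.GetDegree() == 1):
                    atom.SetFormalCharge(-1)
                    atom.SetNumExplicitHs(0)
                    done = True
                    ion = "[Na+]"
                    break
        if done:
            charged = rw.GetMol()
            Chem.SanitizeMol(charged)
            return chem.canonical_smiles(charged) + "." + ion
    ion = _COUNTERIONS[int(rng.integers(0, len(_COUNTERIONS)))]
    return smiles + "." + ion


def _year_allocation(spec: SyntheticLibrarySpec) -> np.ndarray:
    """Largest-remainder apportionment of n_molecules over the year range."""
    first, last = spec.year_range
    if last < first:
        raise ValueError(f"invalid year range {spec.year_range}")
    years = np.arange(first, last + 1)
    weights = (1.0 + spec.annual_growth) ** (years - first)
    weights = weights / weights.sum()
    ideal = spec.n_molecules * weights
    counts = np.floor(ideal).astype(int)
    remainder = spec.n_molecules - counts.sum()
    if remainder > 0:
        frac = ideal - counts
        top = np.argsort(-frac, kind="stable")[:remainder]
        counts[top] += 1
    return np.repeat(years, counts)


def generate_frame(spec: SyntheticLibrarySpec) -> pd.DataFrame:
    """Generate a synthetic library as a provenance-rich table.

    Columns: id, smiles (possibly salted), base_smiles (neutral parent),
    scaffold_true (pool scaffold, canonical), year, salted (bool).
    Fully reproducible per seed.
    """
    if not spec.scaffold_pool:
        raise ValueError("empty scaffold pool")
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be positive")
    rng = np.random.default_rng(spec.seed)

    pool = [chem.canonicalize(s) for s in spec.scaffold_pool]
    ranks = np.arange(1, len(pool) + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs = probs / probs.sum()
    scaffold_idx = rng.choice(len(pool), size=spec.n_molecules, p=probs)

    year_pool = _year_allocation(spec)
    years = rng.permutation(year_pool)

    salted = rng.random(spec.n_molecules) < spec.salt_fraction

    rows = []
    for i in range(spec.n_molecules):
        scaffold = pool[int(scaffold_idx[i])]
        base = decorate_scaffold(
            scaffold, rng, spec.substituents, spec.max_substituents
        )
        smiles = _salt_form(base, rng) if salted[i] else base
        rows.append(
            {
                "id": f"syn{i + 1:06d}",
                "smiles": smiles,
                "base_smiles": base,
                "scaffold_true": scaffold,
                "year": int(years[i]),
                "salted": bool(salted[i]),
            }
        )
    return pd.DataFrame(rows)


def generate_library(spec: SyntheticLibrarySpec) -> list[CompoundRecord]:
    """Generate a synthetic library as compound records (pipeline entry form)."""
    frame = generate_frame(spec)
    return [
        CompoundRecord(id=row.id, smiles=row.smiles, origin_year=int(row.year))
        for row in frame.itertuples()
    ]
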