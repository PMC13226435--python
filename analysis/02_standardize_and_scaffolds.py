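#!/usr/bin/env python
"""Standardize the library and extract scaffolds and generic frameworks.

Desalts and neutralizes each structure, then derives the Bemis-Murcko
scaffold and its all-carbon framework. Writes results/scaffolds.csv and
reports how many records needed standardization.
"""

from pathlib import Path

from chemchron import library_io, scaffolds, standardize

ROOT = Path(__file__).resolve().parent.parent / "results"

records = library_io.read_compound_table(ROOT / "library.csv", format="csv")
rows = []
n_desalted = n_neutralized = n_acyclic = n_failed = 0
for rec in records:
    if rec.parse_failed:
        n_failed += 1
        continue
    std = standardize.standardize_record(rec)
    n_desalted += std.was_desalted
    n_neutralized += std.was_neutralized
    sc = scaffolds.scaffold_from_smiles(std.canonical_smiles)
    framework = "" if sc.is_empty else scaffolds.generic_framework(sc).canonical_smiles
    n_acyclic += sc.is_empty
    rows.append({"id": rec.id, "smiles": std.canonical_smiles, "year": rec.origin_year,
                 "scaffold": sc.canonical_smiles, "framework": framework,
                 "n_rings": sc.n_rings, "is_empty": sc.is_empty})

library_io.write_table(rows, ROOT / "scaffolds.csv")
print(f"standardized {len(rows)} molecules ({n_failed} parse failures)")
print(f"  {n_desalted} desalted, {n_neutralized} neutralized, {n_acyclic} acyclic")
print(f"wrote {ROOT / 'scaffolds.csv'}")
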