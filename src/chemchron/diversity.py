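"""Scaffold frequency tables and diversity statistics.

Treating each unique scaffold as a "species", the Shannon entropy

    SE = -sum_i p_i * log2(p_i)

over scaffold proportions p_i = count_i / n_molecules measures the
structural variety of a library in bits, and the Shannon equitability
(evenness)

    SEE = SE / log2(n_scaffolds)

normalizes it to [0, 1]: 1 is a perfectly even spread of molecules across
scaffolds, values near 0 mean a few scaffolds dominate. Both logs use base
2 so that SEE reaches exactly 1 at uniformity; a natural-log variant is
available for comparison and gives identical SEE (the base cancels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .scaffolds import EMPTY_SCAFFOLD


@dataclass
class ScaffoldCounts:
    """Frequency table mapping scaffold keys to molecule counts."""

    counts: dict[str, int]

    @property
    def n_molecules(self) -> int:
        return sum(self.counts.values())

    @property
    def n_scaffolds(self) -> int:
        return len(self.counts)

    def proportions(self) -> dict[str, float]:
        total = self.n_molecules
        return {k: v / total for k, v in self.counts.items()}


def scaffold_counts(keys: Iterable[str], include_empty: bool = False) -> ScaffoldCounts:
    """Tally scaffold keys; empty markers (acyclic molecules) excluded by default."""
    counts: dict[str, int] = {}
    for key in keys:
        if key == EMPTY_SCAFFOLD and not include_empty:
            continue
        counts[key] = counts.get(key, 0) + 1
    return ScaffoldCounts(counts)


def _as_table(table: ScaffoldCounts | Mapping[str, int]) -> ScaffoldCounts:
    if isinstance(table, ScaffoldCounts):
        return table
    return ScaffoldCounts(dict(table))


def shannon_entropy(table: ScaffoldCounts | Mapping[str, int], base: float = 2.0) -> float:
    """Shannon entropy of the scaffold distribution (bits for base 2)."""
    table = _as_table(table)
    n = table.n_molecules
    if n < 1:
        raise ValueError("entropy of an empty scaffold table is undefined")
    se = 0.0
    for count in table.counts.values():
        p = count / n
        if p > 0.0:
            se -= p * math.log(p, base)
    return se


def equitability(table: ScaffoldCounts | Mapping[str, int], base: float = 2.0) -> float:
    """Shannon equitability SE / log(n_scaffolds) in [0, 1].

    Defined as 0 for a single-scaffold table (maximally restricted space),
    where the normalizer log(1) vanishes.
    """
    table = _as_table(table)
    if table.n_molecules < 1:
        raise ValueError("equitability of an empty scaffold table is undefined")
    k = table.n_scaffolds
    if k == 1:
        return 0.0
    return shannon_entropy(table, base=base) / math.log(k, base)


@dataclass
class DiversityMetrics:
    se: float
    see: float
    n_scaffolds: int
    n_molecules: int


def diversity_metrics(table: ScaffoldCounts | Mapping[str, int]) -> DiversityMetrics:
    table = _as_table(table)
    return DiversityMetrics(
        se=shannon_entropy(table),
        see=equitability(table),
        n_scaffolds=table.n_scaffolds,
        n_molecules=table.n_molecules,
    )


def top_k_scaffolds(
    table: ScaffoldCounts | Mapping[str, int],
    k: int,
    total_molecules: int | None = None,
) -> list[tuple[str, int, float]]:
    """Ranked ``(scaffold, count, percent)`` list, descending by count.

    ``total_molecules`` sets the percentage denominator; by default it is
    the table total, but passing the full library size (including acyclic
    molecules) mirrors percentages quoted against whole databases. Ties
    break on the lexicographically smaller SMILES.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    table = _as_table(table)
    if table.n_scaffolds == 0:
        raise ValueError("cannot rank an empty scaffold table")
    denom = total_molecules if total_molecules is not None else table.n_molecules
    if denom <= 0:
        raise ValueError("percentage denominator must be positive")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(s, c, 100.0 * c / denom) for s, c in ranked[:k]]


def coverage_percent(part_count: int, whole_count: int, sig_figs: int | None = None) -> float:
    """Percentage part/whole, optionally rounded to ``sig_figs`` significant figures."""
    if whole_count <= 0:
        raise ValueError("whole_count must be positive")
    if part_count < 0:
        raise ValueError("part_count must be non-negative")
    pct = 100.0 * part_count / whole_count
    if sig_figs is not None:
        if pct == 0.0:
            return 0.0
        digits = sig_figs - 1 - math.floor(math.log10(abs(pct)))
        pct = round(pct, digits)
    return pct
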