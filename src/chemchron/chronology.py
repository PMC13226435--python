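"""Time-resolved library statistics: annual counts, diversity, growth.

Each compound is dated by its origin year — the earliest recorded year of
appearance in the scientific literature. The chronicle tallies, per
calendar year, molecules and scaffolds appearing for the first time, their
cumulative totals, Shannon entropy and equitability on the
cumulative-to-date scaffold table, and year-over-year growth percentages.

Growth can be measured on the annual new-molecule series (default: the
mean of n_t/n_{t-1} - 1 is an unbiased estimator of a constant exponential
rate) or on the cumulative series (which approaches the same rate only
asymptotically and is biased upward over short windows; exposed for
comparison with cumulative-framing growth figures in the literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .diversity import equitability, scaffold_counts, shannon_entropy
from .scaffolds import EMPTY_SCAFFOLD


def assign_origin_year(citation_years: Iterable[int]) -> int | None:
    """Earliest year among a compound's literature citations; None if undated."""
    years = list(citation_years)
    if not years:
        return None
    cleaned = []
    for y in years:
        if isinstance(y, bool) or not isinstance(y, int):
            try:
                iy = int(y)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"not a year: {y!r}") from exc
            if iy != y:
                raise ValueError(f"not a year: {y!r}")
            y = iy
        cleaned.append(y)
    return min(cleaned)


def yoy_growth(
    series: Sequence[float],
    window: tuple[int, int] | None = None,
) -> tuple[list[float], float]:
    """Year-over-year percentage growth of a count series, and its mean.

    growth_t = 100 * (C_t - C_{t-1}) / C_{t-1}. Leading zero-count years
    are excluded; a zero after the first positive entry is an error (the
    ratio is undefined). ``window`` restricts the mean to the index range
    [start, end] of the input series (inclusive, in series coordinates).
    """
    series = list(series)
    if len(series) < 2:
        raise ValueError("need at least two entries for year-over-year growth")
    first = next((i for i, v in enumerate(series) if v > 0), None)
    if first is None:
        raise ValueError("all-zero series has no defined growth")
    growth: list[float | None] = [None] * len(series)
    for t in range(first + 1, len(series)):
        prev = series[t - 1]
        if prev <= 0:
            raise ValueError(f"zero count at position {t - 1} after first positive year")
        growth[t] = 100.0 * (series[t] - prev) / prev
    lo, hi = window if window is not None else (0, len(series) - 1)
    in_window = [g for t, g in enumerate(growth) if g is not None and lo <= t <= hi]
    if not in_window:
        raise ValueError("no growth values inside the requested window")
    defined = [g for g in growth if g is not None]
    return defined, sum(in_window) / len(in_window)


@dataclass
class YearRecord:
    year: int
    n_new_molecules: int
    cumulative_molecules: int
    n_new_scaffolds: int
    cumulative_scaffolds: int
    se: float
    see: float
    yoy_growth_pct: float | None = None


@dataclass
class ChronicleSeries:
    """Per-year ledger over a contiguous year window (gap years included)."""

    records: list[YearRecord]
    year_span: tuple[int, int]
    n_undated: int
    mean_growth_pct: float
    growth_basis: str = "annual"
    n_acyclic: int = 0
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [r.year for r in self.records],
                "n_new_molecules": [r.n_new_molecules for r in self.records],
                "cumulative_molecules": [r.cumulative_molecules for r in self.records],
                "n_new_scaffolds": [r.n_new_scaffolds for r in self.records],
                "cumulative_scaffolds": [r.cumulative_scaffolds for r in self.records],
                "se": [r.se for r in self.records],
                "see": [r.see for r in self.records],
                "yoy_growth_pct": [r.yoy_growth_pct for r in self.records],
            }
        )


def build_chronicle(
    data: pd.DataFrame,
    window: tuple[int, int] | None = None,
    growth_basis: str = "annual",
    diversity_basis: str = "cumulative",
    growth_window: tuple[int, int] | None = None,
) -> ChronicleSeries:
    """Build the per-year ledger from a frame with ``year`` and ``scaffold``.

    ``year`` may be nullable; undated molecules are counted in
    ``n_undated`` and excluded. ``scaffold`` holds canonical scaffold keys,
    with the empty string for acyclic molecules (counted as molecules but
    not as scaffolds). Molecules dated before the window start seed the
    cumulative baselines; molecules after the window end are ignored.

    ``growth_basis``: "annual" (default) or "cumulative" molecule counts.
    ``diversity_basis``: "cumulative" (default) evaluates SE/SEE each year
    on all scaffolds to date; "annual" on that year's new molecules only.
    """
    if growth_basis not in {"annual", "cumulative"}:
        raise ValueError(f"unknown growth basis {growth_basis!r}")
    if diversity_basis not in {"cumulative", "annual"}:
        raise ValueError(f"unknown diversity basis {diversity_basis!r}")

    years = pd.to_numeric(data["year"], errors="coerce")
    dated_mask = years.notna()
    n_undated = int((~dated_mask).sum())
    dated = pd.DataFrame(
        {"year": years[dated_mask].astype(int), "scaffold": data.loc[dated_mask, "scaffold"].fillna(EMPTY_SCAFFOLD)}
    )

    if window is None:
        if dated.empty:
            raise ValueError("no dated molecules and no explicit window")
        window = (int(dated["year"].min()), int(dated["year"].max()))
    start, end = window
    if start > end:
        raise ValueError(f"window start {start} after end {end}")

    n_acyclic = int((dated["scaffold"] == EMPTY_SCAFFOLD).sum())

    baseline = dated[dated["year"] < start]
    in_window = dated[(dated["year"] >= start) & (dated["year"] <= end)]

    cumulative_molecules = len(baseline)
    seen_scaffolds: dict[str, int] = {}
    for key in baseline["scaffold"]:
        if key != EMPTY_SCAFFOLD:
            seen_scaffolds[key] = seen_scaffolds.get(key, 0) + 1

    by_year = {int(y): grp["scaffold"].tolist() for y, grp in in_window.groupby("year")}

    records: list[YearRecord] = []
    for year in range(start, end + 1):
        keys = by_year.get(year, [])
        n_new = len(keys)
        cumulative_molecules += n_new
        n_new_scaffolds = 0
        year_counts: dict[str, int] = {}
        for key in keys:
            if key == EMPTY_SCAFFOLD:
                continue
            if key not in seen_scaffolds:
                n_new_scaffolds += 1
                seen_scaffolds[key] = 0
            seen_scaffolds[key] += 1
            year_counts[key] = year_counts.get(key, 0) + 1

        table = seen_scaffolds if diversity_basis == "cumulative" else year_counts
        if table:
            se = shannon_entropy(table)
            see = equitability(table)
        else:
            se = float("nan")
            see = float("nan")
        records.append(
            YearRecord(
                year=year,
                n_new_molecules=n_new,
                cumulative_molecules=cumulative_molecules,
                n_new_scaffolds=n_new_scaffolds,
                cumulative_scaffolds=len(seen_scaffolds),
                se=se,
                see=see,
            )
        )

    basis_series = (
        [r.n_new_molecules for r in records]
        if growth_basis == "annual"
        else [r.cumulative_molecules for r in records]
    )
    mean_growth = float("nan")
    if any(v > 0 for v in basis_series) and len(basis_series) >= 2:
        gw = None
        if growth_window is not None:
            gw = (growth_window[0] - start, growth_window[1] - start)
        try:
            _, mean_growth = yoy_growth(basis_series, window=gw)
            first = next(i for i, v in enumerate(basis_series) if v > 0)
            for t in range(first + 1, len(records)):
                prev = basis_series[t - 1]
                records[t].yoy_growth_pct = 100.0 * (basis_series[t] - prev) / prev
        except ValueError:
            # interior zero-count year: per-year ratios undefined
            pass

    return ChronicleSeries(
        records=records,
        year_span=(start, end),
        n_undated=n_undated,
        mean_growth_pct=mean_growth,
        growth_basis=growth_basis,
        n_acyclic=n_acyclic,
        config={
            "growth_basis": growth_basis,
            "diversity_basis": diversity_basis,
            "window": [start, end],
        },
    )
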