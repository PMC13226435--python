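# Methods

## Standardization

Registration noise (counter-ions, protonation states) must be removed
before scaffolds can be counted, otherwise one chemotype fragments into
several keys. Two steps, in order:

**Desalting** keeps the fragment with the most heavy atoms. Equal-sized
fragments tie-break on the lexicographically smallest canonical SMILES so
the result is deterministic. Removed fragments are recorded.

**Neutralization** applies a fixed, auditable substructure rule list
rather than an open-ended heuristic: anionic O/S/N (carboxylates,
sulfonate and phosphate oxygens, alkoxides, thiolates, deprotonated
amides) gain one hydrogen; cationic N/P carrying at least one hydrogen
(ammonium, anilinium, pyridinium) lose one. Two guards keep the valence
model intact: an ion bonded to an opposite charge is skipped (nitro,
N-oxide, azide are charge-separated groups, not protonation states), and
a cation without hydrogens (quaternary ammonium) is untouchable without
breaking bonds and is left as is.

Stereochemistry survives standardization; tautomers are *not*
canonicalized — tautomer standardization changes scaffold identity in
ways that are themselves a modelling choice, and leaving it out keeps the
scaffold keys interpretable.

Idempotence (standardize ∘ standardize = standardize) is property-tested.

## Scaffolds and generic frameworks

The scaffold operator is implemented directly as the pruning rule: delete
every atom with exactly one neighbour that is attached by a single bond
and not in a ring, repeat to fixed point. Exocyclic double- and
triple-bonded atoms are retained *by the rule itself* (they never satisfy
the single-bond condition), not by a post-hoc patch, so carbonyl oxygens
on ring–ring linkers stay in the core. Acyclic molecules have no scaffold
and are reported as empty, counted separately, and excluded from scaffold
statistics — the framework concept is defined on ring-containing cores.

One documented edge: an acyl or carboxyl group attached directly to a
ring prunes down to its doubly-bonded oxygen (`CC(=O)c1ccccc1` →
`O=Cc1ccccc1`), whereas some toolkit Murcko routines drop the whole
group. Both conventions exist in the field; ours follows the stated
pruning rule. The cross-toolkit oracle test therefore uses molecules
with conventional single-bond substituents, where all conventions agree,
and the divergence is confined to this class of inputs.

Scaffold keys are canonical SMILES **with stereo retained** by default
(trans-chalcone and cis-chalcone are different cores); a
`keep_stereo=False` switch collapses them. Generic frameworks drop
stereo by definition: every heavy atom becomes neutral carbon, every
bond single, aromaticity erased, then canonicalized. The reduction is
idempotent and preserves heavy-atom count.

## Diversity statistics

Shannon entropy is computed in bits (log₂) with 0·log 0 = 0; the
equitability normalizer also uses log₂, which is required for SEE = 1 at
a perfectly even distribution and SEE ≤ 1 in general. The base in fact
cancels in the ratio, so any consistent base gives the same SEE (tested).
SEE for a single-scaffold table is defined as 0 — the maximally
restricted space — since SE/log 1 is otherwise undefined.

Top-*k* rankings use the full record count (including acyclic molecules)
as the percentage denominator by default, mirroring percentages quoted
against whole databases; a switch restricts the denominator to
scaffold-bearing molecules.

## Chronology and growth

A compound's origin year is the minimum over its citation years; the
reduction lives in the chronology module so upstream readers can expose
all years per compound. The chronicle materializes every calendar year in
the window (gap years carry zero counts) and evaluates SE/SEE per year on
the cumulative-to-date scaffold table (annual-only snapshots via flag).
Molecules dated before the window seed the cumulative baselines.

Year-over-year growth, growth_t = 100·(C_t − C_{t−1})/C_{t−1}, is
computed on the **annual new-molecule counts** by default. For a series
growing as (1+g)^t the annual ratio equals 1+g in every year, so the mean
of the annual-basis growth series is an unbiased estimate of 100·g. On
the cumulative series the same ratio only approaches 1+g asymptotically
(time constant ≈ 1/g years) and its finite-window mean overshoots g
substantially — for g = 0.116 over 40 years starting from an empty
library, by about 8 percentage points. The cumulative basis remains
available via `growth_basis="cumulative"` for comparison with
cumulative-framing growth figures in the enumeration literature, but the
default is the estimator that recovers the generating rate.

## Chemical-space maps

Generic frameworks are deduplicated and weighted by molecule frequency —
one node per distinct shape — then encoded as circular Morgan
fingerprints with radius 2 (diameter-4 neighbourhoods) on 2048 bits,
compressed by mean-centred PCA to 50 components, and projected to 2D by
t-SNE (perplexity 30, PCA initialization, fixed seed). Radius 2/2048 bits
is the standard ECFP4 convention; 50 components and perplexity 30 are
common practice for fingerprint t-SNE and are config-exposed. Bit-exact
agreement with other ECFP implementations is not a goal (hashing schemes
differ); the tests check similarity structure instead — family
separation (positive silhouette) and nearest-neighbour purity on
constructed ring-size families.

Era slicing is cumulative-to-date by default (each snapshot shows the
space known *so far*), windowed via flag. When an era holds fewer points
than the perplexity allows, the perplexity is clamped to (n−1)/3 with the
effective value recorded in the result parameters; eras with fewer than
three distinct frameworks are skipped with a warning. Stored coordinates
are never jittered; any jitter for plotting coincident points is a
render-time concern.

## Synthetic library generator

The generator emulates three structural signatures of real bioactive
registries:

- **Scaffold skew.** Scaffold indices are drawn with probability ∝
  rank^(−s) over a pool whose default is the ten privileged cores most
  common in bioactive chemistry (benzene, biphenyl, pyridine, indole,
  benzanilide, pyrrolidine, quinoline, chalcone, isoflavone,
  naphthalene). Default exponent s = 1.5, a strong but not degenerate
  skew under which the top core carries roughly half the library.
- **Registration noise.** A configurable fraction (default 10 %) of
  records is emitted as a salt (small counter-ion appended) and/or a
  protonation-state charged form (protonated amine + chloride, or
  deprotonated hydroxyl + sodium). Salting is constructed to be exactly
  invertible by standardization, which the tests verify record by
  record.
- **Exponential inflow.** Annual first-report counts follow (1+g)^t over
  the year range (defaults g = 0.116, 1976–2024, the observed regime for
  public bioactive collections). Year totals are apportioned by largest
  remainder — the realized counts match the growth curve as closely as
  integers allow, making g identifiable from small libraries — and the
  assignment of molecules to years is then randomized.

Molecules are built by decorating a pool scaffold with 0–3 small
substituents (methyl, ethyl, hydroxy, amino, fluoro, chloro, methoxy) at
ring-carbon hydrogens through single bonds, so the true scaffold of every
record is known by construction and scaffold extraction is validated
round-trip. One seeded generator stream drives the whole build;
generation is byte-reproducible per seed.

**What the generator does not emulate:** realistic substituent
distributions, physicochemical property profiles, scaffolds outside the
pool (so the number of distinct scaffolds saturates rather than growing
with the library), multi-citation dating conflicts, or parse failures.
Tests passing on synthetic data therefore establish correctness of the
*computations*, not distributional claims about any real database.

## Problem sizes and numerical choices

The test suite and analysis drivers use libraries of 400–20,000
molecules, chosen so every property of interest (multinomial evenness
error below 0.02, growth recovery within 2 percentage points) is already
resolvable at that scale. Entropy agreement with brute force is checked
to 1e−12; evenness bounds allow 1e−12 numerical slack. Degenerate inputs
are handled by explicit contracts: empty count tables, all-zero growth
series, windows with start > end, eras with under three frameworks, and
perplexity ≥ point count all raise (or warn-and-skip) rather than
returning silent defaults.

## Known limitations

- Scaffold keying by canonical SMILES means aromaticity-model differences
  between toolkits would change keys; all keys in one analysis must come
  from this package's adapter.
- The chronicle treats the origin year as exact; citation-lag noise in
  real dating is not modelled.
- t-SNE coordinates are comparable only within one embedding; era maps
  share a seed but are separate embeddings, so between-era comparisons
  should read cluster structure, not absolute positions.
- The neutralization rule list covers protonation-state charges only;
  exotic charged species (carbanions, metal complexes) pass through
  unchanged by design.
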