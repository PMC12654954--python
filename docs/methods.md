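# Methods

## Model

A species is represented solely by its vector of 64 codon frequencies,
normalized to the relative codon frequencies (RCF) `p(c)`, `Σ p(c) = 1`.
Every quantity in the package is a deterministic function of this vector
and the genetic code table; frequencies are treated as exact
probabilities (no small-sample entropy bias correction — see
Limitations).

Each *codon part* is a deterministic map from codons to a smaller
instance set: the base positions F, S, T (4 instances each), the ordered
duplets FS, FT, ST (16), the codon itself (64), and the amino-acid
signal *aa* (21: twenty amino acids plus stop, which is always retained
as a first-class signal). The distribution of a part is obtained by
summing `p(c)` over the part's preimages; joint distributions of two
parts likewise. Shannon entropies are in bits. Conventions:
`0·log₂ 0 = 0`; probabilities below 1e-15 are structural zeros;
distributions must sum to 1 within 1e-9 (inputs are validated, not
silently renormalized — `normalize` is the explicit way in).

Identities used and property-tested: `H(X|Y) = H(X,Y) − H(Y)`;
`I(X;Y) = H(X) + H(Y) − H(X,Y)`; chain rule
`H(codon) = H(FS) + H(T|FS)`; `H(aa|codon) = 0`.

### Standardized mutual information

`sI(X;Y) = I(X;Y)/min(H(X), H(Y))`. The `min` normalizer is the default
because it is the standard normalization that attains exactly 1 whenever
one part is fully determined by the other, matching the intended [0, 1]
dependence scale; when the denominator is 0 (a degenerate species),
sI is defined as 0. `sqrt` (geometric mean), `max` and `joint`
normalizers are available via the `normalizer` option wherever sI is
computed, since normalized-MI conventions differ between sources.

Pairs in which one part is a positional coordinate of the other
(F–FS, S–FS, F–FT, T–FT, S–ST, T–ST) have `I = min(H)` identically and
are excluded; the remaining 15 of the C(7,2) = 21 pairs over
{aa, FS, FT, ST, F, S, T} form the sI set. Dendrogram labels use the
compact `aa.T` / `ST.F` style.

### Measure registries

- `main8`: the eight marginals `H(codon), H(aa), H(FS), H(FT), H(ST),
  H(F), H(S), H(T)` — the main entropy space.
- `extended54` (default): main8 + the 15 joint entropies + the 30
  directed conditionals over non-redundant pairs + `H(codon|aa)` (the
  within-family codon-choice uncertainty), 54 measures. The composition
  is a package convention, exposed as a named preset so an alternative
  54-measure roster can be dropped in; all space analyses take the
  registry as a parameter.
- `sI15`: the 15 standardized-MI measures.

## Comparative statistics

Group summaries use the median (even *n*: midpoint of the central order
statistics) as the central-tendency statistic, robust to the outlier
species broad taxonomic samples always contain. *Efficiency* of a
bounded measure = 100 × pooled median / `log₂ k`. Hypothesis tallies
evaluate strict inequalities per species; values equal within 1e-12 are
ties and count as not satisfied (reported in a `ties` column);
percentages are rounded half away from zero. The 99% CI of the mean Diff
uses the normal approximation `mean ± z₀.₉₉₅·sd/√n`, adequate at the
hundreds-of-species scale this targets and documented as an
approximation. GC content is `Σ p(c)·gc(c)/3` with `gc(c)` the number of
G/C bases in codon `c`.

## Spaces, clustering, outliers

Feature spaces: the main-H space (8-d), extended-H (54-d), RCF (64-d)
and sI columns. Distances are Euclidean; features are *not* standardized
by default (the spaces' native scales are meaningful; a z-score flag
exists in the library for cross-scale experiments). Dendrograms use
complete linkage. The agglomeration is implemented in-house with a
Lance–Williams max update because the package guarantees deterministic,
input-order-independent output: among merge candidates at the minimal
linkage distance, the pair whose combined sorted leaf-label list is
lexicographically smallest is merged. scipy's `linkage(..., 'complete')`
and a naive O(n³) agglomeration serve as independent cross-checks in the
test suite. Newick branch lengths are parent merge height minus child
merge height, so root-to-leaf path length equals the root height and
trees round-trip exactly.

Outlier profiling computes, per species, the Euclidean distance to the
pooled componentwise-median vector in the H space and in the RCF space,
ranks both, reports the Pearson correlation between the two distance
vectors and the per-group farthest species.

## Synthetic data generator

The generator emulates a multi-group codon-frequency survey in which the
wobble position carries the within-family freedom:

1. `p(aa)` ~ symmetric Dirichlet over the 21 signals with concentration
   `aa_concentration` (large ⇒ compact group, small ⇒ diffuse).
2. Within each synonymous family, `p(codon|aa)` ~ Dirichlet whose base
   weights are `wobble_tilt` at the codon's third base (mean-normalized,
   scaled by `family_concentration`); positions 1–2 carry no tilt.
3. `p(c) = p(aa)·p(c|aa)`.
4. GC tilt: codon choice *within each family* is reweighted by
   `exp(γ·gc(c))` and renormalized per family. Tilting within families —
   rather than tilting and renormalizing the full 64-vector — keeps the
   amino-acid composition fixed, so γ tunes GC content without
   confounding it with proteome composition, and γ → +∞ drives GC
   content to its maximum attainable value given the drawn aa
   composition (property-tested at γ = 50 against a per-family argmax
   oracle).

The three six-fold families (Leu, Ser, Arg), whose codons also differ at
positions 1–2, are by default collapsed to their majority four-codon
block (CTN, TCN, CGN). With that collapse the first base is a
deterministic function of the signal in every family (the stop family
TAA/TAG/TGA varies at position 2 but not 1), hence `H(F|aa) = 0` exactly
while Dirichlet draws make `H(T|aa) > 0` almost surely: **every
generated species satisfies Diff > 0 by construction**, mirroring the
universal wobble excess in real genomes as a provable generator
property. A `collapse_sixfold=False` flag enables full six-fold sampling
(the guarantee then becomes empirical rather than structural).

Seeding is hierarchical — `(dataset seed, CRC32 of group key, species
index)` feeds a `numpy` `SeedSequence` — so any species or subset is
reproducible independently of the rest of the dataset.

### The `paperlike` preset

Eight groups sized 65/44/13/12/7/2/1/1 (An, Ar, Eb, Pl, Fu, Vi, Pr, Ob
= 145 species), a tenfold scale-down of a broad eight-group survey
(652/435/126/122/71/21/4/3), keeping default runs fast while preserving
the group-size imbalance. The Archaea-like group gets the weakest
concentrations (`aa_concentration` 15, `family_concentration` 1.5) so it
shows the widest Diff and dependency spread; animal- and plant-like
groups are the most concentrated (60/12); GC tilts vary mildly by group
(−0.2 … +0.2). These values were fixed once as a realistic emulation of
inter-group heterogeneity. Under the preset, per-species Diff falls
around 0.9–1.35 bits with a pooled median near 1.25.

What the generator does *not* emulate: phylogenetic correlation between
species (every species is an independent draw), mutation–selection codon
dynamics, genome-wide GC gradients within a group, or six-fold-family
position-1/2 usage (under the default collapse). Passing tests on
synthetic data therefore validate the measurement machinery and the
generator's stated properties — not claims about real taxa.

## Numerical choices

- Tolerance ladder: distribution validation 1e-9; identity tests 1e-9;
  brute-force-oracle agreement 1e-12 (all computations are short exact
  sums, so tight tolerances are appropriate).
- sI and MI are clamped into their theoretical ranges against rounding.
- `normalize` is exactly idempotent (vectors summing to 1 within 1e-12
  pass through unchanged), making measure vectors from counts and from
  RCFs bit-identical.
- CSV matrices are written with `%.17g` and read with round-trip float
  parsing, so write→read is lossless; CLI outputs use 12 significant
  digits for diffability.
- Codon order is fixed: lexicographic over T<C<A<G. RNA input (U) is
  mapped to T on read.

## Problem sizes in the shipped checks

The test suite and acceptance pipeline run on generated data: identity
and oracle suites use 100 random RCFs; the clustering oracle sweep uses
200 random 6-leaf instances; generator statistics use the 145-species
preset and 20-seed replicate sweeps at half scale. The structural
determinacy analysis needs no data at all (it enumerates the 64-codon
table).

## Limitations

- Entropies are plug-in estimates; with genome-scale codon counts the
  bias is negligible, but the package deliberately offers no
  Miller–Madow-style corrections for tiny samples.
- Only the standard nuclear code is validated against known structural
  values (2.375 determinacy ratio, family sizes); other NCBI tables load
  but their structural constants differ.
- The 54-measure registry composition and the `min` sI normalizer are
  conventions of this package (see above); published analyses using
  different rosters or normalizers will differ in the affected columns,
  which is why both are injectable parameters.
- Species-level dendrograms over thousands of leaves are supported but
  quadratic in memory and cubic in time; the default reports cluster
  group medians or measure columns instead.
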