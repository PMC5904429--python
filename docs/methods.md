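# Methods

## Distances

The only distance used is the uncorrected p-distance: for a pair of aligned
sequences, the proportion of mismatching columns among the columns where
both members carry a canonical base. Every residue outside {A, C, G, T} —
alignment gaps, `N`, `?` and all IUPAC ambiguity codes — is one "missing"
class; a column is excluded from a pair's comparison only when either member
is missing there (*pairwise deletion*), so each pair may be scored over a
different number of sites, which the matrix records alongside the distance.
Treating ambiguity codes as missing rather than as state sets is a
deliberate simplification; partially informative codes (e.g. `R` vs `A`)
are discarded rather than scored fractionally, which can shrink the
compared-site count slightly on noisy data. A pair sharing zero comparable
columns has no defined distance and raises an error naming the pair, since
it usually indicates disjoint sequencing coverage rather than divergence.

Per-species summaries pool, for species *S* with *n* specimens, the
C(*n*, 2) conspecific pairwise distances (intraspecific) and all
*n* × (*N*−*n*) pairs against the other ingroup specimens (interspecific);
each heterospecific pair therefore contributes to both species' rows, which
is what a one-row-per-species table requires. The mean is arithmetic over
those pairwise values and the SD is their sample standard deviation
(denominator *n*−1). This is the printed "mean ± SD" semantics; distance
software often reports a bootstrap standard error instead, so
`bootstrap_se_of_means` (1000 site resamples by default) is exposed for
comparison, but the SD of pairwise values is the headline statistic.
Undefined cells are `NA`: all intraspecific fields for singletons, the
intraspecific SD when only one conspecific pair exists, interspecific fields
when the dataset has one species. Outgroup specimens are excluded from the
summaries entirely.

The per-species barcode gap is `inter_min − intra_max` (NA-propagating); the
gap report also carries the global largest intraspecific maximum and the
global smallest interspecific minimum with the species attaining them —
under the double-counting pooling above, the two species of the closest
heterospecific pair share the same minimal `inter_min`.

## Neighbor joining and bootstrap

NJ follows the Saitou–Nei agglomeration: join the pair minimising
`Q(i,j) = (N−2) d(i,j) − r_i − r_j`, assign branch lengths
`l_i = d(i,j)/2 + (r_i − r_j)/(2(N−2))`, reduce with
`d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2`, and close the last three nodes
around a central trifurcation with the three-point formulas. Two numerical
conventions make the output deterministic and printable:

- **Tie-breaking**: among equal Q values the lowest (i, j) pair in the
  current node ordering wins (row-major argmin).
- **Negative branches**: a negative length is clamped to zero and the
  deficit moved to its sister branch, preserving the path length through
  the join; an all-zero input yields an arbitrary but fixed topology with
  all-zero branches.

On additive matrices NJ is exact, and the test suite asserts recovery of
random additive trees (up to 8 taxa) to 1e-9 in every leaf-to-leaf path.

Bootstrap: alignment columns are resampled with replacement to the original
length; each replicate's distance matrix and NJ tree are recomputed, and the
support of each internal bipartition of the reference tree is the percentage
of replicates containing that bipartition, rounded to the nearest integer.
Supports are keyed by unrooted split identity, not node identity, so
rerooting cannot detach them. A replicate whose resampled columns leave some
pair with no comparable site is discarded and redrawn (up to 10× the
requested replicates, then an error — such data is too sparse to bootstrap).
The replicate count defaults to 1000 and is a configuration choice, not an
estimate of anything. The random stream drives column indices only, so the
supports do not depend on specimen input order beyond genuine Q-ties.

Outgroup rooting places the root on the edge whose bipartition separates the
outgroup set from the ingroup, splitting that edge's length evenly. When the
outgroup is not monophyletic in the unrooted tree, the tree is rooted at the
edge maximising the number of correctly separated leaves, with a logged
warning. Species-clade support is looked up by split: a species with ≥ 2
specimens is monophyletic iff the split isolating exactly its specimens is in
the tree; singletons (and species missing at most one other leaf) are
"trivially monophyletic" with no support value.

## Site classification and diagnostic characters

Per column, over non-missing states only: zero distinct states → all
missing; one → constant; two or more → variable; parsimony-informative iff
at least two states each occur in at least two specimens. Counts conserve:
constant + variable + all-missing = total columns.

A *pure* diagnostic for species *S* is a (position, state) pair where every
non-missing specimen of *S* has the state, no non-missing specimen outside
*S* has it, and at least one specimen of *S* is non-missing there. The scan
is exhaustive over columns × species; outgroups are excluded by default
(whether published diagnostics were required to hold against outgroups too
is ambiguous, so a flag exposes both conventions). States private to a
species but not fixed in it are computed separately
(`private_nonfixed_sites`) and never mixed into the pure set. Multi-site
(compound) characters are out of scope.

## Synthetic data generator

The generator emulates the statistical shape of a small barcoding study —
its default, "study-sized" configuration is 9 species with specimen counts
(7, 3, 2, 6, 3, 2, 2, 5, 5) (35 sequences) over 662 sites:

1. root sequence uniform over the four bases;
2. species ancestors evolved down a random balanced binary species tree;
   each site mutates with probability 0.025 on tip branches and half that on
   internal branches (uniform choice among the three alternative bases, a
   Jukes–Cantor-like rule — the analysis itself is model-free, so the
   simplest sufficient model is used). Long tips keep even sister species
   ~5% apart while capping the deepest pairs near ~14%, matching the
   intra ≈ 0–3% / inter ≈ 5–14% regime such studies report;
3. three reserved columns per species are overwritten in that species'
   ancestor with a base differing from the root state; reserved columns
   never mutate otherwise, so each planted (species, position, state) triple
   is a pure diagnostic of the emitted alignment by construction;
4. each specimen copies its ancestor and receives Poisson(2) substitutions
   at non-reserved columns, giving expected conspecific distances of about
   2·2/662 ≈ 0.6%;
5. with probability 0.3 a sequence gets a terminal missing run (uniform
   length 1–60, head or tail), mimicking ragged sequencing coverage.

All randomness flows from one integer seed; identical configurations are
byte-identical on disk. What the generator deliberately does *not* model:
coalescent genealogies (species ancestors are points, not populations), rate
heterogeneity across sites, codon structure, transition/transversion bias,
sequencing error, interior gaps, or diagnostic sites that can be eroded by
intraspecific polymorphism. Consequently, passing recovery tests shows the
pipeline's machinery is correct on data with a clean planted signal; it does
not show that real groups with introgression, incomplete lineage sorting or
overlapping distance ranges would be delimited correctly.

## Pipeline

`run_all` chains the stages on one dataset and writes all reports
(distance matrix as square TSV + lower-triangular relaxed PHYLIP, summary
and gap tables, Newick tree, per-species clade supports, site counts,
diagnostic list/grid/mask, verdicts, log). Proportions are printed with 4
decimals, bootstrap percentages as integers; Newick labels omit supports
below a display threshold (default 50) without touching the in-memory
values. With fewer than 3 specimens the tree stage is skipped with a
warning. Reruns with the same seed are byte-identical except log
timestamps.

## Problem sizes in the checks

The acceptance script runs one full pipeline pass at the study size
(35 × 662, 500 bootstrap replicates) and a 20-seed recovery sweep at 200
replicates per seed; the recovery criterion (planted clades ≥ 95% support in
≥ 95% of species × seed cases) is insensitive to the replicate count at
these signal strengths. Property tests run on random alignments up to
~20 × 50 and additive trees up to 8 taxa, where brute-force oracles are
exact.

## Known limitations

- p-distances only; no model-corrected distances in the headline path.
- NJ only; no likelihood or Bayesian inference, no topology search beyond
  the agglomeration.
- The diagnostic scan treats ambiguity codes as missing, which can
  under-report diagnostics relative to tools that intersect state sets.
- Reproduction of the published 662-column alignment depends on alignment
  and trimming choices that the source analysis does not fully specify; the
  fetch script exposes a trimming window rather than guessing one.
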