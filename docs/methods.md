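# Methods

This note documents the models and procedures `gutnog` implements, the
parameters that matter, the numerical conventions, what the synthetic
generators do and do not emulate, and the design choices made where the
procedure left room.

## Best-hit ortholog-group assignment

Each protein's tabular homology hits against a NOG catalog are reduced to at
most one assignment: among hits with e-value strictly below `evalue_max`,
the hit with the lowest e-value wins; ties fall back to the highest bit
score, then to the lexicographically smallest subject id. The cascade makes
assignment a pure function of the hit multiset — file order can never change
the result, which is load-bearing because tabular search output order is
tool- and thread-dependent.

`evalue_max` defaults to 1e-5 and is exposed everywhere (library, CLI,
pipeline config) rather than hard-coded: the conventional threshold notation
"e-value < 10e-5" is ambiguous between 1e-4 and 1e-5, and the package takes
the stricter, conventional reading as its default. The comparison is strict
(`<`), not `<=`.

A protein assigned to a group that lacks a functional description still
counts as annotated; descriptions only matter at the description-grouping
stage.

The presence matrix records 1 for a (genome, group) cell when at least one
protein of that genome is assigned to the group. Rows follow the input
genome order, columns are sorted group ids, and columns exist only for
groups observed somewhere (no all-zero columns by construction).

## Habitat classification

A gene counts as present in the reference gut gene catalog when any of its
hits reaches `min_identity` (default 95 %) over at least `min_coverage`
(default 0.90) of the *longest* of the two aligned sequences,
max(query length, subject length) per hit pair. Both comparisons are
inclusive. The longest-length denominator is why the 12-column tabular
alignment format alone is insufficient and a companion length table (or the
extended 14-column dialect) is required.

The label is a pure function of the matched fraction: gut at
≥ `gut_min_fraction` (default 5 %), non-gut below `nongut_max_fraction`
(default 0.5 %), ambiguous between. Ambiguous genomes are excluded from all
cohort analyses; the screen refuses matrices containing them rather than
silently dropping rows.

## The representation screen

The screen statistic is an absolute genome-count difference, not a ratio or
a test statistic: with cohort sizes 23 + 23, a feature is overrepresented in
the gut cohort when gut_count − nongut_count ≥ 12, underrepresented when
nongut_count − gut_count ≥ 12. The admissible region therefore runs from
(12 gut, 0 non-gut) to (23 gut, 11 non-gut), and a feature in ≤ 11 gut
genomes can never be overrepresented. `delta_min` is a parameter (default
12); for other cohort sizes it has no canonical value and must be chosen by
the caller. No significance testing is attached — a Fisher or permutation
null would be a natural extension but is deliberately not part of the
screen, whose contract is the deterministic counting rule.

The screen runs on the unfiltered presence matrix; the informative-feature
filter (below) belongs to clustering only, and singleton exclusion applies
only to the distribution-grid display.

### Description-level grouping

NOG catalogs are deliberately high-resolution, so one function is often
split across many groups with identical descriptions. The screen therefore
also runs on "groups of NOGs": all NOGs whose descriptions are identical
after normalization (trim, collapse internal whitespace runs, casefold)
become one feature, present in a genome when any member is. Normalization is
configurable (`strict=True` compares byte-identically) because published
description tables capitalize inconsistently. Empty and "NA" descriptions
are treated as no description and excluded — information carried by
undescribed NOGs is lost at this level, which is a property of the method,
not a bug.

### Distribution grid and category composition

The grid tallies features on the (gut count) × (non-gut count) plane, gut on
the first axis; cell (0,0) is structurally empty for matrix-derived counts.
Features carried by exactly one genome overall can be excluded (the display
convention), and a companion transform returns log10 of nonzero cells for
heat-map rendering.

Category composition reports, per screen status, the percentage of features
carrying each functional-category letter, with features lacking any letter
tallied as `unknown`. A feature with several letters contributes one count
per letter and the denominator is total letter assignments (default), or
only its alphabetically first letter (`multi_category="first_letter"`) —
the published convention is unstated, so both are implemented and the
default documented.

## Profile clustering

Features present in fewer than `min_genomes` (default 2) or more than
`max_genomes` (default n−1) genomes carry no contrast and are removed first;
removing every column is an error, and the filter is idempotent.

Distances on 0/1 rows: `euclidean_binary` (default; √ of the
symmetric-difference size, the behavior of the generic heatmap routine this
reproduces) or `jaccard` (1 − |∩|/|∪|; the distance between two all-zero
profiles is defined as 0). Agglomeration is scipy complete linkage by
default, average linkage as the alternative. Because the original figure's
distance/linkage are unrecoverable from its description, the exact published
topology is not a contract here; the contract is recovery of planted cohort
structure on synthetic data.

Determinism under ties: rows are sorted by genome id before the merge tree
is built, so the result is a function of the profile set alone and re-runs
(or row-permuted inputs) give identical trees. This choice prefers
reproducibility over emulating any particular tool's tie order.

`partition_agreement` scores a flat cut against external labels as the
maximum-weight bipartite matching of clusters to labels divided by n — for
two balanced clusters, simply the better of the two label matchings.

## Localization statistics

Compartment fractions are count/total using the *printed* total, full
precision internally, one decimal for display. One published row is known to
be internally inconsistent (compartments sum below the printed total); it is
preserved as printed, flagged by a reader warning, and its fractions use the
printed total.

Cohort summaries: mean, and SEM = s/√n with the n−1 sample standard
deviation (the convention; the source tables do not define SEM, but this
choice reproduces every printed mean/SEM row of the packaged per-genome
table at display precision — verified exhaustively in the test suite).
Secreted-fraction cohort means are means of per-genome percentages, not
pooled-count percentages; this likewise reproduces the printed 3.1 % / 4.3 %.

Spearman correlation: mid-rank ties, ρ = Pearson correlation of ranks;
two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 df (the mainstream
approximation, used at cohort size 23), with an exact permutation
enumeration available for n ≤ 10. ρ within 1e-12 of ±1 is snapped to ±1
(rank correlations are rational with far larger spacing, so this only
removes float noise); |ρ| = 1 gives p = 0 under the approximation. Constant
vectors make ρ undefined and raise. The correlation panel computes
2 cohorts × {pse, sec, mem} against proteome size and requires ≥ 4 genomes
per cohort.

## Rounding

All displayed percentages and count means round half-up (0.05 → 0.1), via
decimal arithmetic, matching the source tables (e.g. 20/23 → 87.0 %).
Python's built-in banker's rounding is never used for display values.
Internal computation always keeps full precision.

## Synthetic data

The generators are pure functions of their scenario dataclasses (seed
included); ground truth is emitted alongside the data and no test reads
truth back out of the data itself.

**Pan-genome.** Defaults are the study design: 23 + 23 genomes, planted
delta 12, 5 core + 10 over + 10 under + 200 background groups, 31.2 % of
groups undescribed, shared-description blocks of sizes (6, 3, 2), category
letters drawn from a weight table with a heavy tail on S/R. Which genomes
carry a planted group is sampled, but per-cohort counts are constructed
exactly, so screen recovery is deterministic. Background draws are
constrained to |delta| < delta_min, at least one carrier, and *not* all
genomes — the last constraint keeps the planted classes disjoint in realized
incidence (an all-present background group would be indistinguishable from
core). Proteome sizes are set so annotated fractions sit near the
cohort-typical 60 % (gut) / 71 % (non-gut). Group counts are scaled down
from catalog scale (hundreds rather than tens of thousands) so the full test
suite stays fast; dataset-scale group counts are not a target of this
package.

**Catalog alignments.** Exactly round(target_fraction × n_genes) genes get
one passing hit (coverage 1.0 of equal lengths, identity sampled above the
floor); the rest are split randomly between no hit and one clearly failing
hit (identity or coverage below threshold), so the filter is exercised in
both failure modes.

**Localization.** Proteome totals uniform on 1500–7500 (the span of the
study genomes). PSE and MEM counts scale with the total in both cohorts
(slopes 0.087 and 0.14, Gaussian noise sd 40); SEC scales only in the
non-gut cohort (slope 0.045, sd 25) and is size-independent in the gut
cohort (mean 102, sd 25). Slopes and the gut SEC mean were set once from the
study cohort means (PSE ≈ 300, MEM ≈ 480, non-gut SEC ≈ 156, gut SEC ≈ 102
at total ≈ 3450). CYTO absorbs the remainder. With these defaults the
qualitative pattern — gut SEC not significant at α = 0.01, the other five
cohort × compartment correlations significant — reproduces in ≥ 95 % of
seeded replicates; "not significant" is judged at α = 0.01 because a true
null exceeds any fixed higher bar (like p > 0.2) only in the corresponding
fraction of replicates, which no generator can guarantee per-replicate.

**What the generators do not emulate:** real sequences (only
alignment/annotation records are produced), phylogenetic correlation between
genomes (gene gain/loss on a tree), open pan-genome size distributions, and
dataset-scale feature counts. Passing planted-recovery tests therefore shows
the screen/clustering machinery is correct, not that real cohorts separate
this cleanly — on real data the clustering contrast is an empirical result,
not a guarantee.

The 2-cluster habitat-recovery check runs on a strong-separation scenario
(25 + 25 differential groups at delta 20 over 200 background groups) chosen
a priori by a signal/noise argument: the expected across-cohort Hamming gap
(≈ 38 bits) then dominates the background distance noise (sd ≈ 7), so exact
recovery is robust by construction rather than seed-dependent.

## Pipeline

`gutnog run` executes annotate → classify-habitat → screen → cluster →
localization from one YAML config. Every threshold default equals the
documented analysis value (1e-5, 95, 0.90, 5, 0.5, 12, informative bounds
[2, n−1], euclidean/complete); config values override defaults and CLI flags
override the config. The manifest echoes the fully default-filled parameter
set, lists each stage's outputs with sha256 checksums (re-running an
identical config reproduces identical checksums), and records warnings
per stage. A stage failure writes a FAILED marker and aborts with the stage
name; prior outputs are retained. The classify-habitat and localization
stages are optional (skipped, and marked as skipped, when their inputs are
not configured); the habitat stage validates metadata labels against catalog
hits but the screen always uses the metadata labels. The habitat stage uses
each genome's protein count as its gene count, which is exact for the
synthetic inputs; the standalone `classify-habitat` subcommand accepts an
explicit gene count.

## Known limitations

* The screen is a fixed-threshold rule; no multiplicity-corrected inference
  is provided, by design.
* Description-level grouping is only as good as the catalog's description
  strings; paraphrased descriptions stay separate features, and undescribed
  groups are invisible at this level.
* `delta_min` does not generalize automatically to unbalanced or resized
  cohorts.
* Exact Spearman p-values are limited to n ≤ 10 (factorial enumeration).
* Newick export strips parentheses/commas/spaces from genome ids rather than
  quoting them.
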