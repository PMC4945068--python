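# gutnog

Comparative functional profiling of human-gut bacteria against closely
related non-gut bacteria, built as a reusable, tested Python pipeline.

## The scientific problem

Which molecular functions matter specifically in the human gut? One way to
ask is to compare the predicted proteomes of gut-dwelling species with those
of their closest relatives from other environments, so that differences
reflect the habitat rather than deep taxonomy. `gutnog` implements that
comparison for a balanced two-cohort design (e.g. 23 gut and 23 non-gut
*Firmicutes* genomes):

1. **Annotation** — each protein is assigned to an ortholog group (NOG) by
   its best catalog hit with e-value < 10⁻⁵ (ties broken by bit score, then
   subject id), yielding a binary genome × group presence/absence matrix.
2. **Habitat classification** — a genome's genes are matched against a
   reference gut gene catalog (identity ≥ 95 % over ≥ 90 % of the longest
   sequence length); a species is called *gut* when ≥ 5 % of its genes are
   in the catalog, *non-gut* below 0.5 %, *ambiguous* between.
3. **Representation screen** — the core statistic. For a feature *f* with
   gut genome count *g(f)* and non-gut count *n(f)*, *f* is
   **overrepresented** when *g(f) − n(f) ≥ δ* and **underrepresented** when
   *n(f) − g(f) ≥ δ*, with δ = 12 for the 23 + 23 design. The screen runs at
   the single-NOG level and at the level of "groups of NOGs" — NOGs sharing
   an identical functional description, OR-combined into one feature
   (undescribed NOGs drop out at this level). Companions: the shared core
   (features in every genome), the gut-count × non-gut-count distribution
   grid, and per-status functional-category composition.
4. **Profile clustering** — genomes are clustered hierarchically on their
   binary profiles after removing uninformative features (present in < 2 or
   > n−1 genomes); a 2-cut is compared against habitat labels.
5. **Localization statistics** — per-genome counts of potentially surface
   exposed (PSE), secreted (SEC), cytoplasmic (CYTO) and membrane (MEM)
   proteins are summarized per cohort (mean, SEM = s/√n) and rank-correlated
   against proteome size (Spearman's ρ, two-sided p). The diagnostic
   contrast: secretome size tracks proteome size in non-gut genomes but not
   in gut genomes.

A seeded synthetic-data module generates every input with exact planted
ground truth (core / enriched / depleted / background groups, catalog match
fractions, localization scaling patterns), so the whole pipeline is testable
without any downloads. Three small reference tables from the 46-genome study
design ship with the package (per-genome annotation/localization counts and
the 44 + 67 screened description-level groups).

## Worked example

```python
from gutnog import (PanGenomeScenario, generate_pangenome,
                    build_presence_matrix, screen_matrix, shared_core,
                    RepresentationStatus)

pg = generate_pangenome(PanGenomeScenario(seed=1))   # 23+23 genomes
matrix = build_presence_matrix(pg.assignments, pg.genomes)
records = screen_matrix(matrix, pg.genomes)          # delta_min = 12
over = [r for r in records if r.status is RepresentationStatus.OVERREPRESENTED]
print(len(over), sorted(r.feature_id for r in over)[:3])
print(over[0].gut_count, over[0].nongut_count, over[0].gut_abundance_pct)
print(len(shared_core(matrix)))
```

prints

```
10 ['synNOG00006', 'synNOG00007', 'synNOG00008']
17 5 73.9
5
```

— the screen recovers exactly the 10 planted gut-enriched groups (the first
is present in 17 of 23 gut and 5 of 23 non-gut genomes, a difference of 12,
displayed as 73.9 % gut abundance) and the 5 planted core groups.

The same analyses run from the shell:

```sh
gutnog simulate --seed 5 --out-dir data/
gutnog run --config config.yaml        # annotate → classify-habitat → screen → cluster → localization
```

`gutnog run` writes per-stage tables (presence matrix, screen records
mirroring the published table layout, distribution grid, cluster tree in
Newick, localization summaries and correlations) plus a `manifest.json`
with the parameters used and content checksums of every output.

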