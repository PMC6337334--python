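# Methods

## The screening model

The screen is a deterministic ratio-threshold filter, not a statistical
test: the study design it serves has one expression value per (gene,
sample) and no replicates, so there is no dispersion to estimate and no
multiple-testing machinery to apply. Selection of a gene as
reference-stage-specific requires, with `R` the reference level,

* `R > 0` — a gene silent at the reference stage cannot be specific to it,
  and excluding it avoids division by zero in the diagnostics;
* every strict-group sample strictly below `strict_threshold x R`
  (default 0.20);
* every relaxed-group sample strictly below `relaxed_threshold x R`
  (default 0.70).

The relaxed band exists because a larval cohort is not perfectly
synchronized: samples taken shortly before the reference stage may already
contain individuals transcribing reference-stage genes, so holding them to
the strict bound would discard genuine markers.

### Interpretation choices, made explicit

* **Reference statistic.** "Below x% of the reference" is ambiguous when
  the reference group has several samples. We default to **max** — a
  non-reference sample must be low relative to the larger reference value,
  the most natural permissive reading — and expose min and mean behind the
  same interface. `compare_reference_stats` runs all three and reports
  which genes' verdicts differ, so a count that deviates from an expected
  value can be attributed to this choice.
* **Per-sample comparison.** Thresholds are applied to every sample
  individually, which is equivalent to comparing the group maximum. This
  is stricter than (or equal to) any reading that first aggregates samples
  into stages.
* **Strict inequality, no epsilon.** Both bounds use `<` in raw double
  precision. The thresholds are exact decimal fractions of data values;
  an epsilon would create hidden nondeterminism exactly at the boundaries,
  whereas strict raw comparison makes boundary cases (e.g. a strict sample
  at exactly 20.0 with R = 100) deterministic and testable.

A consequence worth knowing: exact scale invariance (multiplying one
gene's row by c > 0) holds mathematically but can flip at the boundary in
floating point (`v < 0.2*R` and `c*v < 0.2*(c*R)` can round differently
when `v` is within one ulp of the bound). The property tests therefore use
continuous random values, where the boundary is a measure-zero event, and
the boundary semantics are pinned by exact-decimal unit tests instead.

The summary reports the selected fraction at full precision (the tests
check it to four decimals). Note that published per-cent restatements of
such fractions are sometimes rounded inconsistently; the package always
reports the computed value.

## Thresholds and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `strict_threshold` | 0.20 | Max allowed fraction of `R` in strict groups (dimensionless ratio of RPKM) |
| `relaxed_threshold` | 0.70 | Same for relaxed groups; must be >= strict |
| `reference_stat` | `max` | How reference samples collapse to `R` |

Composition flags default to glycine >= 0.20 ("collagen-like glycine"),
proline >= 0.10 ("collagen-like proline") and cysteine >= 0.05
("cysteine-rich"), inclusive bounds. Collagen triple helices are built
from Gly-X-Y repeats (glycine ~1/3 of residues, proline enriched), so
published collagen-like adhesive chains sit near 23–27% glycine and ~11%
proline; the defaults sit just below those levels because they are
descriptive observations, not published cutoffs, and they live in an
editable rules mapping. Fractions are computed over the standard-residue
denominator: ambiguity codes and rare symbols (B, J, O, U, X, Z, `*`, `-`)
are counted separately and excluded, matching the convention behind
published composition percentages. Reported percentages round to one
decimal; stored fractions keep full precision. Whole sequences are
profiled as given — no attempt is made to trim signal peptides or isolate
mature chains.

## Functional groups and localization vocabulary

Functional-group assignment in the pipeline path is rule-based on ordered
product-name keywords (inhibitor → protease inhibitor before any
protease/peptidase keyword → enzyme; collagen/tenascin/IgGFc/EGF →
structural; perlucin/calmodulin/cadherin/receptor → calcification- and
calcium-related), falling through to "Other". Expert-curated tables assign
groups by judgment; the rules make that judgment explicit and overridable,
and the default rules reproduce the packaged 59-row table exactly (tested).

Compartment labels normalize to a closed eight-class vocabulary (Ext, Cyt,
Lys, Mit, Pla, Mem, ER, Nuc). The normalization map accepts full DeepLoc
class names and printed variants ("Plast" → Pla, "Cell membrane" → Mem).
Localization is always parsed from predictor output, never computed here.

## The synthetic-data generator

The generator emulates the shape of the developmental table the screen was
designed for — 49 samples by default: 2 reference (P1/P2), 2 relaxed
(LU1/LU2), 45 strict (other stages and adult organs) — with three gene
populations (defaults: 1000 genes, 50 planted specific, 20 near-misses):

* **Background** genes draw a per-gene log-normal base level (log-mean 1.0,
  log-sd 1.5, a broad realistic RPKM spread) shared across all samples,
  times per-sample log-normal noise (log-sd 0.5). Because the base level
  is shared across groups, stage-specificity arises only from noise and is
  rare — qualitatively matching a regime where a fraction of a percent of
  genes passes.
* **Planted specific** genes draw `R` uniform in [1, 200] and every
  non-reference sample uniform in `[0, threshold/m x R)` with margin
  `m > 1` (default 10), so they pass by construction with known slack.
* **Planted near-misses** are identical except exactly one strict sample
  is placed at `strict_threshold x R x m` — above the bound — so they fail
  exactly one condition. Placing the violation at the exact boundary
  would be float-fragile; the boundary itself is covered by a
  decimal-exact unit test (R = 100, sample 20.0).

All draws come from one seeded NumPy generator; emitted values are rounded
onto a 1e-6 grid, rounding planted values toward zero so a bound is never
crossed by rounding, which makes output byte-stable across platforms. Gene
order is shuffled so planted genes are not positionally identifiable.

What the generator does *not* emulate: RNA-seq count noise and library-size
effects, correlated expression programs across stages, or annotation
errors. Passing the recovery tests therefore shows the filter implements
its definition and recovers planted signal under controlled margins — not
that the thresholds are biologically optimal for real transcriptomes.

Companion files (protein FASTA, gene-protein map, domain-scanner TSV,
localization TSV) share protein IDs derived from gene IDs. Planted genes
cycle through realistic product names; collagen-named proteins get Gly-X-Y
repeat sequences (glycine exactly 1/3) and a triple-helix scan row, and
planted localizations are biased 80% extracellular, mirroring the
enrichment expected of adhesive candidates.

## Packaged data

`data/pediveliger_candidates.tsv` is the 59-gene pediveliger candidate
table (gene ID, protein ID, product name, functional group, DeepLoc 1.0
compartment + score) transcribed from the published table it mirrors,
including its "Plast" spelling variant, which exercises the normalization
map. Its tallies — 42 extracellular; 21 hypothetical proteins (35.6%), 15
of them extracellular — are recomputed, not stored, by the report path and
the acceptance script.

## Numerical and degenerate-input choices

* Missing matrix cells are a hard load error; an explicit
  `fill_missing_zero` option converts blank/NA to 0.0. Silent imputation
  would alter selection.
* Duplicate gene or sample IDs are rejected at load; the loader performs
  no stage-level aggregation (one column = one sample) — grouping lives
  entirely in the scheme, which keeps both per-sample and per-stage
  readings expressible.
* An empty matrix screens to an empty result; the summary fraction over
  zero genes is NaN rather than a fabricated 0.
* `first_failing_group` reports the first group in scheme declaration
  order containing a violating sample ("reference" when R = 0), making
  rejection attribution deterministic.

## Verification strategy

The vectorized screen is checked verdict-by-verdict against an
independently written naive per-gene, per-sample Python loop
(`screen_oracle`) on 1000 randomized small matrices, plus seeded and
hypothesis-driven property tests: scale invariance, monotonicity under
lowering non-reference samples and under widening thresholds, degenerate
cases, and planted-truth recovery (sensitivity 1.0, zero near-miss hits at
margin 10). Composition profiling is checked against a literal
Counter-based oracle and permutation/self-concatenation invariances.

## Limitations

* The screen is a filter; it attaches no uncertainty to a verdict, and a
  gene missing the bound by 1% is reported only via its diagnostic ratios.
* Homology search, GO annotation, domain scanning and localization
  prediction are out of scope: the package consumes those tools' tabular
  outputs and never runs them.
* Reproducing the full published selection (59 of 27,902 genes) requires
  the original supplementary expression table, which must be obtained
  separately; the packaged candidate table covers the downstream stages,
  and the synthetic generator covers the screen itself.
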