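# Methods

## Model and procedure

The analysis operates on an orthogroup × species matrix of non-negative
gene copy counts for a panel partitioned into one focal species, a sister
pair, and ≥ 1 outgroups (defaults target the 16-species design of
1 + 2 + 13). It makes no use of gene trees, reconciliation, or sequence
data: presence in the gene tree is proxied by copy count ≥ 1, and the
ancestral state of the focal family is proxied by the sister-pair counts.
There is no statistical test of expansion significance — the method is a
deterministic rule cascade on fold changes, which is what it is meant to
be.

**Fold change.** Focal count divided by the arithmetic mean of a
comparison set, zeros included. Including zeros is the substantive choice:
it is what makes family-specific orthogroups (outgroups all zero) register
as infinitely expanded rather than undefined. 0/0 is defined as 0 (an
absent family is not expanded); x/0 with x > 0 is +∞, which compares
greater than any threshold.

**Screen.** `FC(focal, all others) > screen_fold` (strict) AND
(`n_represented ≥ min_represented` OR both sisters present). The sister
rescue exists because family-specific orthogroups are representation-poor
by construction; a property test verifies the rescue is inert for rows at
or above the representation floor.

**Category cascade.** Fixed first-match order: iv/v (outgroups absent),
then vi (sisters absent), then i, ii, iii, else `none`. The
absence-defined categories go first because clade-wide absences produce
infinite fold changes that would otherwise satisfy i–iii vacuously.
Category v strictly requires genes in all three family members; an
outgroup-absent row with one sister lost and no further expansion is
`none` rather than silently forced into a category. `none` rows are
retained in all outputs — forcing them into a category would fabricate
data.

**Ancestral-expansion test (i/ii).** "Expanded in all three members" is
ambiguous between per-species and clade-mean readings. The default,
`per_species`, requires each of the three counts individually to exceed
`category_fold × mean(outgroups)`; it reads the word "all" literally and
separates i/ii from iii cleanly. `clade_mean` (mean of the three counts vs
the outgroup mean) is available as a configuration switch; the two differ
exactly when one sister carries the whole ancestral signal (a unit test
pins one such vector).

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `screen_fold` | 2.5 | fold | screening threshold of the published strategy |
| `category_fold` | 3.0 | fold | within-classification threshold; all three uses share it |
| `min_represented` | 8 | species | half the 16-species panel |
| `ancestral_mode` | `per_species` | – | literal reading of "all members" |

All threshold comparisons are strict (`>`), so equality at 2.5 or 3.0
never passes; boundary tests pin this.

## Synthetic generator

The generator emulates the statistical *structure* the classifier assumes,
not bivalve biology. Background copy numbers are shifted Poisson,
`1 + Poisson(λ − 1)` with λ = 1.2, then zeroed per species with dropout
probability 0.1. This gives background focal fold changes ≈ 1 in
expectation with a thin right tail, so realized background rows only
rarely pass the 2.5 screen (they legitimately may — the tests assert on
realized values, and the specificity checks allow up to 1% of background
rows to land in a category).

Planted rows are drawn from per-category templates (e.g. category iv:
outgroups zero, sisters 1–2, focal = multiplier × sister mean, multiplier
uniform on 4–10) and rejection-sampled until they satisfy their category's
rule. The predicates used for rejection are a module-private transcription
of the rule text, deliberately not the classifier code path, so a
generator bug and a classifier bug cannot cancel; the test suite carries a
second, fully independent brute-force oracle as well. Rejection sampling
makes planted-category recovery exact by construction — recovery tests
assert 120/120, not a rate. The multiplier range must start above the
3-fold category threshold or the configuration is rejected before
sampling.

Annotations: every planted (and ~70% of background) family gets a primary
synthetic InterPro accession carried by all member proteins — making the
modal accession equal the assigned one by construction — plus secondary
domains, Pfam/GO rows and SignalP flags on random subsets to exercise
grouping, tie-handling and the signal-peptide fraction. Accessions use
clearly fake numeric ranges (`IPR9xxxxx`, `PF9xxxx`, `GO:99xxxxx`).

What the generator does **not** model: birth–death dynamics along the
tree, phylogenetic correlation between species (counts are independent
given the template), gene-tree discordance, annotation error, or
fragmented assemblies inflating counts. Passing recovery tests therefore
shows the rule cascade is implemented correctly and is robust to Poisson
noise and dropout — not that the categories are biologically identifiable
in real data, where assembly and orthology-inference artifacts dominate.

## Numerical and I/O choices

- Counts are exact integers; fold changes are the only floats. Division by
  a zero mean is mapped to ±0/∞ as above rather than raising.
- The Orthofinder dialect's `Total` column is dropped on read by exact
  name match; a test verifies it can never influence a result.
- Missing cells are disallowed (the source format has no NA concept);
  absence is 0.
- Classification tables are stable-sorted by orthogroup ID, fold changes
  written to 6 decimals (`inf` for clade-absent denominators), thresholds
  echoed as `#` comments so outputs are self-describing. Round-trip
  identity is tested field-for-field.
- Top-annotation ties break to the lexicographically smallest accession:
  deterministic and row-order independent (tested under permutation).
  Support counts distinct proteins, so duplicated annotation rows are
  harmless.
- The pipeline re-reads its own written TSVs and recomputes all report
  totals from them — a self-audit on every run; any writer/reader drift
  raises instead of reporting inconsistent numbers.

## Problem sizes

Tests and the acceptance script run the generator at 300–3,400
orthogroups with up to 500 planted families and cross-check the classifier
against the brute-force oracle on 11,500 random vectors; the whole suite
completes in well under a minute. These sizes were chosen because every
property asserted (exact recovery, strict boundaries, oracle agreement,
bookkeeping identities) is scale-free: nothing new is learned past the
point where every code path and category is exercised many times over.

## Known limitations

- Representation-by-count is a proxy for "present in the gene tree"; an
  orthogroup whose genes were dropped from the tree for alignment reasons
  would be treated as present here.
- One top annotation per namespace per family means a genuinely
  multi-domain family contributes to only one domain count; the
  `multi_domain` switch offers the alternative convention.
- SignalP is summarized as a per-family fraction of member proteins, not
  ranked — there is no meaningful modal accession for a binary predictor.
- The `none` label has no counterpart in the published six-way framework;
  it marks rows the printed rules genuinely do not cover rather than a
  seventh biological category.
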