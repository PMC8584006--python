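# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of phosflow.

## Data model

The atomic unit is the phosphosite: protein id, 1-based position, residue
(S/T/Y) and its 13-mer flanking window (±6 residues, `'_'`-padded at
termini; the padding character never matches any residue and is excluded
from background frequency denominators). Site ids are
`<protein>_<position><residue>` (e.g. `P0012_97S`). Quantification is a
site × sample matrix of strictly positive raw-scale intensities with a
sample → condition design; missing values are not imputed — a site must be
complete to enter a comparison (TMT data are near-complete within a plex,
so this default costs little; an imputation policy would be a caller-side
preprocessing step).

## Differential calling

For a (numerator, denominator) condition pair, log2 fold change is the
difference of mean log2 intensities, and *p* comes from a two-sided
two-sample Student's *t*-test on log2 intensities (equal-variance pooled
estimator by default; Welch available via `equal_var=False`). Testing on
the log scale is the conventional choice for lognormal reporter
intensities. Zero-variance degenerate inputs are handled explicitly: equal
constant groups give *t* = 0, *p* = 1; distinct constant groups give
*p* = 0.

A site is **up** iff log2fc ≥ log2(1.5) and *p* < 0.05, **down** iff
log2fc ≤ −log2(1.5) and *p* < 0.05, else **ns**. The ratio gate is applied
on the log2 scale so the ≥ boundary is exact in floating point. Selection
is on raw *p*; Benjamini–Hochberg *q*-values are computed and reported for
the user but never used for selection by default. With the additional
fold-change gate the realized false-positive rate is below the nominal
alpha (verified by the type-I property test).

Summary statistics (residue distribution, sites-per-protein histogram with
bins {1, 2, ≥3} and the auxiliary ≥7 bin, Venn overlap cells, two-omics
union by inclusion–exclusion) use half-up rounding of percentages — integer
precision for the residue split, one decimal elsewhere — matching how such
tables are conventionally printed.

## Motif discovery

Iterative single-position binomial enrichment (the motif-x scheme). Given
foreground and background window sets sharing a central residue:

1. for every offset o ∈ {−6…−1, +1…+6} and residue a, compute
   *p* = P(X ≥ k) with X ~ Binomial(n_fg, p₀), where k is the foreground
   count of a at o and p₀ the background frequency of a at o (pairs with
   zero background frequency are skipped — the test is undefined);
2. fix the pair with the smallest *p* if *p* < 10⁻⁶; tie-break: larger
   foreground count, then smaller |offset|, then lexicographic residue
   (deterministic);
3. restrict both sets to matching windows and repeat until no pair passes;
4. accept the motif if at least one position was fixed and the final
   foreground support is > 20 windows (`min_inclusive=True` relaxes to
   ≥ 20); remove its matched foreground windows and restart.

The default background is all same-centre windows extracted from the full
proteome (configurable to non-differential site windows). The default
foreground is all identified site windows. Discovery order, counts and
per-step statistics are reproducible by replaying the accepted steps with
plain counting, which the test suite does.

The position–residue heatmap reports log2((f + ε)/(b + ε)) per residue and
offset with pseudo-frequency ε = 10⁻⁴, optionally masked by a two-tailed
binomial test at 5%.

## Kinase–substrate prediction

GPS-like contract without GPS's proprietary scoring tables: a kinase is a
set of exemplar substrate 13-mers; a candidate scores the mean over
exemplars of the position-summed BLOSUM62 similarity ('_' scores 0 against
everything). The per-kinase threshold is the empirical (1 − fpr) quantile
("higher" interpolation, so fpr = 1 passes everything and fpr → 0
converges to the background maximum) of scores on ≥ 200 background windows
of the kinase's central-residue class; the default fpr 0.05 plays the role
of a "medium" stringency setting. Predictions can be filtered by PPI
evidence: the unordered (kinase protein, substrate protein) pair must be a
known edge at path length 1; self-pairs always pass. PPI filtering is a
pure subset operation and prediction is anti-monotone in fpr (both are
property-tested).

The kinase/phosphatase census tallies detected proteins against an
annotated catalogue (protein → family), reporting each family's detected
share of the catalogue and of the detected set, plus overall percentages
against the catalogue and an optional background size.

## Kinase-activity inference

Classic weighted Kolmogorov–Smirnov GSEA over a ranked site list.
Comparison context ranks by log2 fold change; sample context by z-scored
(population sd) log2 intensity. Ties break by site id, so ranking is
deterministic. Hits increment the running sum by |v|^w / Σ|v|^w (w = 1 by
default, w = 0 gives the unweighted KS variant; an all-zero hit-weight set
falls back to uniform increments), misses decrement by 1/(N − n_hits); ES
is the running-sum value of largest magnitude, positive preferred on an
exact tie. Summation is sequential (cumulative sum), so the score equals a
plain loop enumeration bit for bit.

Significance uses **gene-set permutation** — random same-size site sets
redrawn from the ranked list — because a three-replicate design cannot
support phenotype permutation. NES = ES / mean |ES*| over same-sign null
scores; *p* = (1 + #{same-sign |ES*| ≥ |ES|}) / (1 + #same-sign). A kinase
with no same-sign permutations is flagged (NES = NaN), and kinases whose
ranked-list overlap is below `min_set_size` = 3 are reported as skipped
rather than dropped, keeping output row counts auditable. Null scores are
computed with a closed form of the running-sum extremum (between hits the
sum decays linearly, so only the values flanking each hit are candidates);
this is algebraically identical to the cumulative-sum definition and tested
against it at 10⁻¹².

States: activated iff NES ≥ +1, inhibited iff NES ≤ −1, else
indeterminate. The symmetric ±1 convention is deliberate: a literal
"score < 1 means inhibited" reading would label NES = +0.5 inhibited,
which contradicts the score's sign semantics. Per-kinase child seeds are
spawned from the caller's seed in kinase-id order, so single-kinase reruns
reproduce.

## Network assembly

Kinases pass when their state is determinate (|NES| ≥ 1) **and** their
permutation *p* < 0.05 (the significance gate is configurable, since a
state-only rule is also defensible); sites pass when status ≠ ns. Edges are
predicted relations whose endpoints both pass; isolated nodes are dropped;
an empty network is a valid result. Exports: SIF
(`kinase TAB regulates TAB site`, sorted for byte-stable output) and
GraphML with node type/state/status and edge score attributes.

## Annotation enrichment

Exact two-tailed Fisher test per term: the sum of hypergeometric
probabilities of all same-margin tables whose probability does not exceed
the observed table's, with a 1 + 10⁻⁷ relative slack for floating-point
ties (the convention shared by the standard implementations, against which
the test suite cross-checks). Universe = all quantified proteins of the
relevant omic, not the whole proteome; hits must be a subset. Selection on
raw *p* < 0.05 with BH *q* reported; output is sorted by *p* with a top-20
view.

## Synthetic-data model

The generator defines the study conditions under which the pipeline is
validated:

* **Proteome** — 1200 proteins, lengths ~ round(N(400, 100)) truncated at
  50, residues i.i.d. from UniProt-average amino-acid frequencies.
* **Sites** — per-protein site count from pmf (0.561, 0.217, 0.100, 0.060,
  0.032, 0.020, 0.010) on 1…7 (single-site-dominated, mean ≈ 1.9);
  central residues S/T/Y with probabilities (0.83, 0.12, 0.05). Positions
  are ≥ 7 residues from either terminus with ≥ 13 spacing, so planted
  flanks never clip or collide; terminus padding is exercised by unit tests
  instead. If a drawn count cannot be placed, it is truncated with a
  warning (strict mode errors).
* **Kinases** — 20 kinases (13 S, 5 T, 2 Y). Three carry the field-classic
  single-position motifs [SP], [RxxS], [GS]; the rest carry two-position
  consensi on distinct (offset, residue) pairs, which keeps their substrate
  windows separable by similarity scoring without colliding in motif
  discovery. Each site becomes a substrate of one uniformly chosen
  same-centre kinase with probability 0.5, and the kinase's fixed flanking
  residues are written into the sequence. Note that [GS] sits near the
  motif-discovery detection boundary by construction — glycine is a common
  background residue, so at ~55 substrates its step *p* hovers around the
  10⁻⁶ threshold; [SP] and [RxxS] are recovered with wide margin.
* **Intensities** — per-site baseline log2 intensity ~ N(20, 1.5);
  replicate noise N(0, 0.25) on the log2 scale (lognormal on the raw
  scale, the standard model for TMT reporter intensities); three
  conditions (AC-MG, AC-B4, rin-B4) × three replicates.
* **Planted activities** — five kinases shifted on AC-B4 vs AC-MG with
  ratios 2.0, 0.5, 1.8, 0.55, 1.6 (three activated, two inhibited, all at
  least 1.5-fold); each substrate site's numerator-condition mean is
  multiplied accordingly. Ground truth records edges, per-site condition
  effects and per-kinase states.
* **Derived inputs** — exemplar tables are sampled from each kinase's
  substrate windows (the synthetic stand-in for a curated kinase–substrate
  resource; because exemplars are drawn from the scored population,
  measured recall is mildly optimistic relative to a fully external
  resource), and the PPI table is the true (kinase protein, substrate
  protein) pairs plus 10% random pairs.

Everything is deterministic: per-stage generators are spawned from the
single config seed, and equal configs give byte-identical proteomes, site
tables, truths and intensities.

**What passing tests show — and don't.** Recovery results on this generator
demonstrate that the inference machinery is correct and calibrated under
its own assumptions (lognormal noise, independent sites, exact motif
planting, complete data). Real phosphoproteomes add ratio compression,
co-isolation interference, peptide-level missingness, correlated sites on
shared peptides, and kinase motifs that are probabilistic rather than
exact — none of which the generator emulates, so recovery rates here are
upper bounds, not forecasts.

## Problem sizes and numerical choices

The test suite exercises the default study (≈2300 sites, 20 kinases, 1000
permutations) over 20 seeded runs for parameter recovery, 2000
kinase-trials at 199 permutations for null calibration, and 500 fuzzed
instances each for the motif argmin-p and enrichment-score oracles — sizes
chosen so the whole suite completes in a couple of minutes on one CPU while
keeping binomial sampling error well inside the asserted tolerances.
Binomial tails use the survival function; step p-values are floored at
10⁻³⁰⁰ before −log10 scoring; percentage rounding is half-up; quantile
interpolation for threshold calibration is "higher".

## Limitations

* Quantification is at site level throughout; peptide-level ambiguity
  (multiply phosphorylated peptides mapping to several sites) is upstream
  of this package.
* No cross-channel normalisation or batch correction — input intensities
  are assumed pre-normalised.
* No motif merging across central residues, no intensity-weighted motif
  scoring, no hierarchical kinase-group score aggregation, and no
  phosphatase–substrate prediction (phosphatases are censused only).
* The PPI filter is binary presence at path length 1; confidence scores and
  longer paths are not used by default.
* No FDR across kinases in the activity stage by default (per-kinase
  permutation p only); BH across terms is reported in enrichment but not
  used for selection.
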