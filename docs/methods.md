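# Methods

`snpmeth` implements a case-control analysis that asks whether genes hit by
rare damaging variants also show disturbed DNA methylation, and whether the
two signals point at the same candidate disease genes.  The pipeline was
designed around a congenital-heart-disease style study: a few hundred
exome-sequenced cases and controls for the variant arm, a much smaller
EPIC-array subcohort (tens of samples) for the methylation arm, and external
annotation resources (CpG islands, a meQTL pair table, gene sets, a PPI
network, a known disease-gene panel) tying them together.

## Rare-variant association

Variants enter annotated with a gene symbol, functional class, SIFT call and
minor allele frequency; per-sample carrier state is "any non-reference
allele" (dominant coding — diploid dosage is not modelled because the
downstream statistics only consume carrier counts).  The qualifying filter
keeps variants with MAF strictly below 0.05, SIFT = damaging, and a
non-synonymous functional class (non-synonymous SNV, stopgain, frameshift,
splicing).

Two association routes run on the qualifying variants:

* **Per-variant Fisher scan.**  Each variant's carrier/non-carrier ×
  case/control 2×2 table gets a two-sided Fisher exact test
  (`scipy.stats.fisher_exact`); a gene's Fisher evidence is the minimum p
  over its variants.  Variants absent from every sample are retained with
  p = 1 and a monomorphic flag so counts remain auditable.
* **CMC burden test.**  A sample is a gene carrier iff it carries ≥ 1
  qualifying variant in the gene; the collapsed carrier 2×2 gets the same
  exact test.  Carrier collapsing with an exact test is the minimal
  defensible burden test for cohorts of this size and needs no
  per-variant weights.

Candidate genes are selected at raw α = 0.05 on either route (`union` by
default; `intersection`, `fisher_only`, `burden_only` are available), with a
"top" tier at α = 0.01.  No multiple-testing correction is applied at this
stage — the selection is deliberately liberal because three orthogonal
methylation criteria and a network filter follow.

A note on monotonicity: adding a case-only carrier to a gene lowers its
burden p only while the gene is enriched in cases.  Because the test is
two-sided, the same edit on a control-enriched gene moves the table toward
the null and the p-value rises; the test suite asserts monotonicity in the
enrichment direction only.

## Differential methylation

Beta values (methylated fraction, in [0, 1]) are compared between groups
probe by probe.  The effect size is `deltaBeta = mean(case) − mean(control)`
on plain arithmetic group means, never shrunk.  The test statistic is an
empirical-Bayes moderated t: per-probe pooled variances s²_g (d_g = n₁+n₂−2
df) are shrunk toward a prior s₀² with d₀ prior df,

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t_g  = Δ̄_g / (s̃_g · √(1/n₁ + 1/n₂)),   t_g ~ t(d₀ + d_g),

with (d₀, s₀²) estimated from the ensemble of log variances by
digamma/trigamma moment matching (the trigamma inverse solved by Newton
iteration).  When the log-variance spread shows no excess over the
sampling expectation, d₀ = ∞ and every probe uses the common variance
(arithmetic mean of the s²_g); the total df is capped at
(#probes)·d_g, the reference behaviour of the moderated t.  The
implementation is checked against Bioconductor `limma::eBayes` to < 1e-9 on
a shared fixture; d₀ = 0 reproduces the classical pooled t exactly.

Tests run on the beta scale by default because the deltaBeta thresholds are
defined on that scale; an M-value (logit-beta) mode exists for users who
prefer variance-stabilised inputs.  A DMS is a probe with |deltaBeta| > 0.1
(strict) and p < 0.01 (strict); BH q-values are reported but not used for
calling.  QC is a sample × sample Pearson matrix with flagging of samples
whose median within-group correlation falls below 0.9.  Genomic context is
summarised as DMS vs background proportions over island relation × gene
feature × direction.

## Cross-talk integration

Candidate genes are flagged by three criteria: (1) the gene carries a DMS
(direction hyper/hypo from the probe signs, mixed when both); (2) a
qualifying variant lies inside a CpG island (a 1-based position p is inside
a BED interval (start, end] iff start < p ≤ end); (3) a variant matches a
meQTL pair — exact (chrom, pos) locus match preferred, gene-symbol fallback
when the pair table carries no coordinates — whose target probe is by
default required to be a called DMS.  The union is reported with all flags
plus Venn region counts (three-way, or four-way with the known-gene panel);
the region counts partition the union exactly.  A reporting option keeps
only genes whose case carrier frequency exceeds the control frequency.

## Enrichment and network prioritization

Over-representation of any gene list in GMT term sets uses the one-sided
hypergeometric upper tail P(X ≥ k) with BH FDR across terms; the default
universe is all genes in the term map plus the query.  Terms with p ≤ 0.05
and FDR < 0.05 are marked significant.  GO ancestor propagation and term
de-duplication are out of scope; the GMT is taken as-is.

The PPI stage thresholds edges at score ≥ 0.4 (the common medium-confidence
convention), keeps the maximum score over duplicate undirected edges, and
computes multi-source unweighted hop distances from the known disease-gene
panel.  Candidates within `max_distance` hops are kept — 1 by default,
i.e. direct interactors of a known gene — and the induced subnetwork over
kept candidates plus known genes is exported as an edge table.
Unreachable candidates are always excluded, even with an unbounded cutoff.

## Synthetic cohorts and planted truth

The generator emulates the target study design end to end, with every
planted signal recorded in a `GroundTruth`:

* **Cohort** — 216 cases / 100 controls by default.  Carrier states are
  Bernoulli(background rate, default 0.01 per variant); enriched genes
  multiply the carrier *odds* in cases by a configurable odds ratio.
  Variants of planted genes are forced rare/damaging/non-synonymous so the
  qualifying filter cannot erase the planted signal.  Gene and variant
  coordinates follow a fixed arithmetic layout (genes tiled over chr1–22 at
  1 Mb spacing, variants 10 kb apart) so interval fixtures are reproducible
  and islands can never straddle two variants.
* **Methylation** — 11 cases / 5 controls by default.  Baseline probe means
  come from a two-mode (0.25/0.75) logit-normal mixture; per-sample values
  are logit-normal around the group mean with logit-scale SD 0.08.  The
  logit-normal respects [0, 1] by construction; its small mean bias
  (≤ ~3·10⁻⁴ at this SD) is negligible against the sampling SE.  Spiked
  probes shift the case mean by a signed delta; their baseline is drawn
  uniformly from the range keeping both group means inside (0.02, 0.98),
  and a delta admitting no such baseline is rejected.
* **Annotations** — islands of ±150 bp are centred on exactly the planted
  island variants (an explicit contradiction check fails generation if an
  island would cover a non-planted variant); meQTL pairs connect each
  planted gene's anchor variant locus to one of its spiked probes, labelled
  cis within a 1 Mb same-chromosome window (configurable) and trans
  otherwise; the PPI is a Barabási–Albert preferential-attachment graph
  over the simulated genes plus a known-core clique and one
  high-confidence edge from every planted gene to a core gene.

All randomness flows from a mandatory seed through per-stage
`numpy.random.default_rng` spawns; identical parameters give byte-identical
files.  What the generator does **not** emulate: linkage disequilibrium and
relatedness, array batch/position effects, cell-composition heterogeneity,
probe cross-reactivity, disease-subtype effect differences.  Passing tests
therefore demonstrate correctness and calibration of the statistics, not
robustness to those real-data artefacts.

## Validation scale and numerical choices

`scripts/acceptance.py` (and the mirrored pytest suite) validates at these
problem sizes, chosen to exercise each property at meaningful scale:
the exact tests against exact-fraction enumeration (all 2×2 tables with
N ≤ 30; hypergeometric configurations exhaustively for N ≤ 40 and a seeded
sweep to N = 200); burden calibration and power on 1000-gene, 300-sample
cohorts over 20 and 50 seeds; DMS spike-in recovery on 5000 probes
(11 vs 5, 200 spiked probes at |deltaBeta| = 0.25); and full-pipeline
recovery of 10 planted cross-talk genes on 200-gene, 2000-probe bundles
over 10 seeds.

Numerical details worth knowing: p-values are clipped into (0, 1];
odds ratios use the sample convention ad/bc with +inf when bc = 0 and NaN
(undefined) for the empty table, whose p is 1; zero-variance probes are
excluded from the variance-prior fit and obtain a finite moderated t via
shrinkage; ties in BH adjustment are preserved; p-value sorts are stable
(mergesort) so output order is deterministic under ties.

## Known limitations

* The burden test is unweighted and covariate-free (no SKAT-style
  kernels, no population-structure adjustment).
* Allele-based (rather than carrier-based) Fisher testing is not
  implemented.
* DMS calling is per-probe; differentially methylated *regions* are not
  aggregated.
* The meQTL criterion inherits whatever biology the supplied pair table
  encodes; no transferability assessment is attempted.
* Enrichment results depend entirely on the supplied GMT and universe.
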