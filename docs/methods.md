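# Methods

This note documents the statistical models, the defaults and why they were
chosen, the synthetic-data generator's assumptions, and the numerical
decisions a maintainer would want to know. Empirical figures quoted here are
the ones the test suite and `scripts/acceptance.py` themselves compute.

## Read counting and normalisation

Mature miRNA species are counted by exact matching of a read's first
k = 19 nt against the mature-sequence dictionary. The scheme is 5′-anchored:
a 1–2-nt 5′ shift changes the prefix, so 5′ isoforms are separate counting
species, while 3′ heterogeneity is invisible. Species whose 19-mers collide
are pooled into a joint species (named by joining their ids with `&`) and
reported — this mirrors the pooling of sequence-identical matures from
paralogous loci, which prefix counting cannot distinguish; locus-level
analyses expand pooled species back through their parent loci. Reads
shorter than k or containing non-ACGU characters are tallied as unassigned;
assigned + unassigned always equals the input read count. Reads matching a
spike-in prefix are assigned to the spike-in species (spike-in priority; no
collision with endogenous prefixes is expected from designed oligos).

Expression filter: a species is analysed in a tissue only with ≥ 5 reads in
each of the tissue's four libraries. CPM divides by the summed
miRNA-matching counts after removing spike-ins, × 10⁶. Two modes exist
because both are needed downstream: per-library CPM (for the 5-CPM display
detection threshold, which requires > 5 CPM in *every* library) and
tissue/genotype CPM, where replicate counts are averaged before normalising
to the summed mean counts; its SE is the SE of the mean of per-replicate
CPMs (|difference|/2 for two replicates).

## Differential expression

A two-group negative-binomial Wald engine for the 2 × 2 design:

* size factors by median-of-ratios over species positive in all libraries
  (library-total fallback with a warning);
* group means profile the NB score equation
  Σⱼ (kⱼ − sⱼq)/(1 + α sⱼ q) = 0 by fixed-point iteration;
* per-species dispersion maximises the Cox–Reid-adjusted profile likelihood
  on a 48-point log grid over [10⁻⁶, 10] with parabolic refinement, floored
  at 10⁻⁸;
* **dispersion moderation**: with two replicates per group the per-species
  estimate is far too noisy for calibrated Wald tests (18% of null p < 0.05
  in simulation). The final dispersion therefore maximises the penalised
  likelihood with a log-normal prior centred on a parametric trend
  a₀ + a₁/mean fitted across species (prior variance = robust spread of
  log-residuals minus the sampling variance 1.645, floored at 0.25), the
  standard empirical-Bayes treatment for small-replicate RNA-seq. Species
  whose estimate lies > 2 SD above the prior keep their own estimate, so
  genuinely noisy species are not overconfident. With moderation, simulated
  null p-values are near-uniform (KS ≈ 0.03–0.04; 3.5% below 0.05) and an
  implanted log2fc of +1 is recovered with bias ≈ 0.015 and 94.8% coverage
  of ±1.96·SE intervals. Tables computed on a single pooled species (see
  below) accept an externally supplied prior dispersion instead of a trend.
* log2fc = log₂(q_ko/q_het) with a 0.5 pseudo-level when a group mean is
  zero; SE from the observed Fisher information of the two group log-means;
  p two-sided normal.

The engine is deliberately not a DESeq2 clone: downstream rules consume
only (log2fc, se, p), and externally produced tables in the same schema can
be substituted.

Guide-vs-passenger comparison: diff = lfc_g − lfc_p,
se = √(se_g² + se_p²), one-sided upper-tail normal p; α = 0.05 (the
sidedness follows the direction the biology predicts and matches the
pipeline's other thresholds). Multi-locus guides whose parent loci
contribute different passenger strands are compared against a *pooled*
passenger: the cognate counts are summed and passed through the same DE
engine. Strand and isoform ratios propagate error to the log2 scale by the
first-order delta method: se_log2 = √((SE_n/n)² + (SE_d/d)²)/ln 2.

## BBUM model and FDR

Two-sided p-values are split by fold-change sign. Both branches share a
uniform component (weight λ) and a secondary Beta(a, 1) with a ∈ (0, 1]
(direction-symmetric spurious signal and test miscalibration); the up
branch adds a primary Beta(r·a, 1), r ∈ (0, 1), of fraction θ within the
non-uniform mass. Joint ML estimation shares λ and a across branches and is
run by L-BFGS in logit coordinates from an 8-point start grid
(λ ∈ {0.3, 0.9} × a ∈ {0.3, 0.7} × (θ, r) ∈ {(0.05, 0.1), (0.2, 0.5)});
near-ties between starts break toward the more-uniform, less-primary
solution. p-values at or below the 10⁻¹² clip are treated as
**left-censored** (log-CDF likelihood contribution): an extreme p-value
says "at most this", not "a density atom here". This matters — with a
density likelihood, a quarter of the primary mass can sit at the clip and
drags θ̂ and r̂ upward even asymptotically, inflating the empirical FDR from
0.05 to 0.065. With censoring, parameters at the canonical point
(λ, a, θ, r) = (0.7, 0.5, 0.1, 0.1) are recovered essentially unbiased at
n = 5000 per branch.

FDR: q(p) = null-plus-secondary mass over total fitted mass of the signal
branch CDF at p, monotonized q-value-style (padj(pᵢ) = min over pⱼ ≥ pᵢ);
down-direction species get padj = 1. When the fit lands on the
unidentifiable ridge (r → 1 or θ → 0, e.g. uniform data), the `boundary`
flag is set and no discoveries are made — on that ridge the fitted density
is uniform and a primary component cannot be separated. Empirical FDR of
padj < 0.05 calls over 200 simulation replicates: 0.0505 (bound
0.05 + 2·MC-SE ≈ 0.053).

## Classification

Per tissue, every species with padj < 0.05: passenger undetected →
sensitive(passenger_undetected); passenger test p < 0.05 →
sensitive(bbum+passenger_test); otherwise both strands secondary. Both arms
are evaluated symmetrically — an annotated passenger can earn the sensitive
call (the sensitive strand is then treated as the miRNA in reports; the
annotation itself is never mutated).

**Broad rescue.** Species not sensitive anywhere are rescued when their
log2fc is positive in ≥ 11 of the 12 tissues with median > 0.2, and the
margin over the (pooled) passenger satisfies the same two conditions. The
quota is absolute: an undetected tissue cannot count as an increase, so the
rule effectively requires near-complete detection. A scaled-quota variant
(ceil(11/12 · n_detected), evaluated over detected tissues) is available as
`rescue_broad(scale_quota=True)` but is not the default: under partial
detection it rescues sparsely-detected null species by chance alone (for a
species detected in 2–4 tissues the all-positive requirement is satisfied
by a few percent of nulls, which across ~2,000 species yields several false
sensitive calls per dataset). Rescued species are labelled in every tissue
where they pass the expression filter. Note the rule's power is modest by
construction: at dispersion 0.05 the per-tissue lfc SE is ≈ 0.33 log2
units, so a true broad effect of 0.35 satisfies the double sign condition
in only ~10% of species; the rescue is a high-precision, low-recall
complement to the per-tissue calls.

**Marginal.** A species sensitive in another tissue or in the external
reference list (e.g. published cell-line calls, a plain text input) becomes
marginal where it is detected, not otherwise called, and beats its
passenger. If the passenger is undetected there, the test cannot run and no
marginal call is made.

**Exclusions.** The cross-context manual curation of suspected false
positives is accepted as a plain input list of (species, tissue-or-ALL);
matching sensitive calls become not_called(excluded_manual) and the
originals are retained as an audit trail. No automated replication of the
curation is attempted.

**Arm and isoform switching.** Per tissue and genotype the dominant arm
compares the sensitive strand's mean CPM with the summed CPM of its pooled
cognates; an event requires the dominant arm to depend on genotype; exact
ties yield no event. The 5′-isoform analysis finds the dominant isoform
among {−2…+2} above the detection threshold per genotype and flags both
dominance switches and non-annotated isoforms exceeding both annotated
strands in the knockout. Family ranking sums ΔCPM (ko − het) over member
guide strands (absolute change, not fold-change, since downstream target
repression tracks the number of added miRNA molecules) and reports the pool
share in percent; families lacking conserved predicted targets are flagged
so the targeting stage skips them.

## Cluster analysis

Clusters chain loci on one (chromosome, strand) when the end-to-start gap
(floored at 0 for overlaps) is ≤ 10 kb, transitively; maximal chains of
≥ 2 are clusters. Start-to-start distance is available as an option. Only
family-confident loci (family table category among "broadly conserved",
"conserved", "poorly conserved but confidently annotated",
case-insensitive) enter the analysis. A query locus counts as clustered iff
it belongs to a cluster of the full-set partition; clusters are not
re-called on subsets, matching the random-cohort design. Enrichment is the
exact upper-tail hypergeometric probability plus a 10,000-cohort
without-replacement Monte-Carlo mean ± SD, seeded.

## Targeting analysis

3′-UTR length bins are 20 equal-population quantile bins over the full
annotation (before expression filtering), with ties broken by transcript id
for determinism. Cohorts per family: all (expressed, any canonical 7–8-nt
site), conserved, top (top decile by most-negative cumulative weighted
context++ score over the family's full annotated target list, then
intersected with the expressed set; ranking within the expressed set is a
config switch). No-site cohorts draw 5 transcripts per target from the
target's own length bin, without replacement within a cohort; repetition i
uses seed + i, so individual cohorts are reproducible and transcripts may
recur across repetitions. Fold repression per repetition is the median
log2fc of the fixed target cohort minus the no-site cohort's; 21
repetitions give the mean, SE (SD/√21), and median two-sided Mann–Whitney
p. Constant fold-changes carry no rank information and report p = 1.
Expressed transcripts require > 10 TPM in all four libraries of the tissue.

## Synthetic-data generator

The generator emulates the survey design so every stage can be scored
against ground truth: 12 tissues × 2 genotypes × 2 replicates; 1,000
hairpin loci (2,000 mature species) with 100 clusters holding 460 loci
(~46% clustered, the genomic background rate), including a 38-hairpin
polycistron and a trio of 6-hairpin paralogous clusters two of which share
a sequence-identical guide (exercising the species-merge and
pooled-passenger paths); 10,000 transcripts.

Counts are negative binomial (dispersion 0.05) around log-normal species
abundances (σ = 1.5), log-normal library depths (3 × 10⁶, σ = 0.2), and a
locus-level tissue factor (σ = 0.5) shared by both arms and all 5′
isoforms of a hairpin — the arms are co-transcribed, so arm ratios are
stable across tissues. Each locus is additionally silent in a random ~30%
of tissues (≥ 2 expressed tissues guaranteed), reproducing the partial
detection map of real tissue panels; implanted effects are only placed in
expressed tissues. Knockout effects multiply ko means by 2^effect:
sensitive strands carry effects of 0.5–2.5 log2 units in 4–10 tissues
(60 strands, ~15% of them annotated passengers); secondary
(transcriptional) effects move both strands of 20 hairpins together in 3
tissues each; 5 broad-weak strands carry 0.35 everywhere; one sensitive
strand is placed at a third of its cognate's abundance with strong effects
in the three brain tissues (the arm-switch case); one hairpin emits the
full −2…+2 isoform ladder with the +1 isoform strongly sensitive
everywhere (the isoform-switch case). Spike-ins are genotype-independent.
mRNA tables give log-normal UTR lengths and TPMs; targets of the three
most-affected families shift by −δ·w(score) with δ = 0.2 and
w = |score|/median|score| capped at 2 — monotone in score strength so the
top decile is repressed more, with the median target shift equal to δ; a
constant-w mode exists for testing. All outputs are byte-deterministic
given (config, seed).

What the generator does *not* model: sequencing error and adapter
artefacts, 3′ isomiR heterogeneity, mapping ambiguity beyond exact
19-prefix identity, correlated biological covariates across tissues of one
embryo, and composition effects larger than those implied by the implanted
effect sets. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated noise model, not robustness to
every artefact of real libraries.

## Recovery characteristics

At the default study conditions (dispersion 0.05, two replicates), measured
over 20 seeds: recall of implanted sensitive miRNAs ≈ 0.92; implanted
secondary effects labelled secondary rather than sensitive in ≈ 95% of
evaluable cases; species-level false-discovery proportion ≈ 0.18. The FDP
floor is structural: with ~30 BBUM calls per tissue at the 0.05 FDR
threshold and twelve tissues, a handful of chance-up null species per
dataset survive the passenger test (their observed fold-change is inflated
by selection), and ~4–5% of strong secondary cases pass the one-sided
passenger test. The original survey removed exactly this class of
single-tissue false positives by manual cross-tissue curation, which this
package deliberately keeps as an explicit exclusion-list input rather than
an automated step.

## Problem sizes

Default analyses use the full generator scale (2,000 species × 48
libraries; 10,000 transcripts); the acceptance script runs the cluster
benchmark at the 604-locus genome scale, classification recovery over 10
seeds, and 100 BBUM FDR replicates at n = 5,000 per branch, completing in
a few minutes on one CPU.
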