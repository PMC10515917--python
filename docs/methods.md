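# Methods

## Overview

`epilineage` analyses the DNA-sequence evolution of brain gene-regulatory
elements (GREs; open-chromatin peaks from snATAC-seq) along the ape lineage.
The pipeline has five analysis stages plus a synthetic-data generator:

1. **Ancestral reconstruction** (`ancestral`): per-GRE maximum-likelihood
   reconstruction of ancestral sequences under the F81 substitution model.
2. **Substitution calling** (`substitutions`): single-event substitutions
   assigned to one of five lineages, with branch-time and length
   normalization.
3. **Divergence classification** (`divergence`): lineage-divergent and
   conserved GRE sets via a resampling null, plus LD-score-regression
   annotation preparation.
4. **Linkage / RDGs** (`linkage`): GRE–gene links from pseudobulk
   accessibility–expression correlation with a matched background, and a
   permutation test for regulation-divergent genes.
5. **TFBS evolution** (`tfbs`): PWM scanning of the reconstructed node
   sequences, single-transition gain/loss calling, expansion/depletion
   statistics, and cell-type enrichments.

All cross-module statistics (Fisher tests, chi-square tests, logistic
regression, BH correction) live in `enrichment` or are delegated to scipy /
statsmodels.

## The lineage chain

Substitutions are polarized on the ordered node path

```
Catarrhine → Ape → GreatApe → AfricanGreatApe → Hominin → Human
```

whose five transitions define the lineages **Ape** (13 MY), **GreatApe**
(4 MY), **AfricanGreatApe** (8 MY), **Hominin** (2 MY) and **Human** (6 MY)
(lower-bound divergence-time estimates, used as the time denominators of
all normalized rates). The chain has *six* nodes: the catarrhine ancestor
is required to polarize changes on the branch leading to the ape ancestor,
which is exactly why Old World monkeys (sister group) and New World monkeys
(outgroup) are kept in the alignments. A `LineageChain.five_node()` variant
drops the catarrhine node (leaving four assignable lineages) for
sensitivity analyses.

## Ancestral reconstruction

- **Gap handling.** Columns where the human record carries a gap
  (human-specific deletions) are removed so positions map onto the human
  genome; non-human gaps and Ns become missing data (all-ones partial
  likelihood vectors). Indels are otherwise outside the model.
- **Model.** F81: equal exchangeabilities, free equilibrium frequencies
  π, rate normalization β = 1/(1 − Σπ²) so branch lengths are expected
  substitutions per site. P(t) = e^(−βt) I + (1 − e^(−βt)) 1π.
- **Fitting.** Frequencies are fixed to the empirical base composition
  first (+0.5 pseudocount); branch lengths are then optimized one at a
  time by bounded Brent search on the pruning log-likelihood, cycled until
  Δlogℓ < 1e-6 or 20 cycles. Invariant alignments keep their input
  lengths (no signal → no update). Bulk pipeline runs default to
  `reuse_tree=True` (guide-tree lengths kept): a several-hundred-bp GRE
  carries little per-branch length signal, and reusing the cohort tree
  keeps per-GRE reconstruction stable and fast.
- **Posteriors.** Marginal per-site, per-node posteriors by the up–down
  pruning algorithm (downward subtree partials combined with upward
  outside probabilities), with per-site rescaling against underflow.
  Site patterns are compressed before the passes.
- **Calling.** Per node and site, the argmax base is emitted only when its
  posterior strictly exceeds 0.75, otherwise `N`; ties resolve to `N`.
  The human sequence is copied from the alignment, never reconstructed.

## Substitution calling and rates

A site yields a record only when every chain state is a confident base (no
`N`) and *exactly one* transition exists between consecutive chain nodes.
This single rule covers both stated discard cases — multiple occurrences
and daughter-lineage reversals both produce ≥ 2 transitions. The record
carries the lineage, ancestral and derived base, position within the GRE
and on the pseudo-genome (0-based, half-open conventions throughout).

Normalized rates: count / branch MY, then / GRE length (bp) × 1000 →
substitutions per MY per kb. The GC conversion ratio is the fraction of
records converting A/T to G/C (the biased-gene-conversion signature); it
is reported as missing — not 0 — for empty record sets, since a zero would
bias comparisons among sparse regions. Under the generator's uniform-F81
conditions its expectation is 1/3.

## Divergence classification

Per GRE, per lineage the statistic is the *proportion* of the GRE's
substitutions falling in that lineage. The null pools proportions over
1,000 draws of 10,000 GREs each (draws without replacement; the draw size
clamps to the cohort size when smaller, which makes the null degenerate at
the pooled proportion — the fold-change/z cutoffs then carry the
selectivity). A GRE is divergent in lineage L when all four hold:

- empirical p (fraction of null draws exceeding the observation),
  BH-adjusted within lineage, < 0.05. The empirical p is the literal
  k/1000 (zeros allowed); a `pseudocount` option switches to (k+1)/(n+1);
- fold change (observed / null median) > 1.5;
- z-score of the proportion across all GREs with ≥ 1 substitution > 1;
- raw lineage count ≥ 2.

GREs may be divergent in several lineages (observed Jaccard between
lineage sets stays low). Conserved GREs sit strictly below the per-lineage
median normalized rate in *every* lineage and are divergent in none.
The conservation score is 1 / mean fold change across lineages.

LDSC annotation preparation emits ranked top-N (20,000 / 10,000 / 5,000)
BED files expanded ±25 kb (clipped at 0), and a sliding-window mode with
50 kb windows shifted −100 kb … +100 kb in 5 kb steps (41 files). Running
LD-score regression itself is out of scope.

## Linkage and RDGs

Candidate pairs are GRE–gene combinations within 500 kb of the gene body
(configurable; the distance window is not fixed by the upstream tooling we
mirror, so it is exposed as a parameter). For each pair, the Pearson r
between the GRE's pseudobulk accessibility and the gene's pseudobulk
expression is standardized against the correlations of 200 background
GREs — nearest neighbours of the focal GRE in (GC content, mean
accessibility) space — with the same gene: z = (r − μ_bg)/σ_bg, two-sided
normal p, BH over all tested pairs. Significant links require FDR < 0.05
and r > 0.01 (the raw correlation is the "score", so negative links never
pass).

RDGs: per lineage, the observed statistic is a gene's number of
significant links to lineage-divergent GREs. The null redraws
|divergent set| GREs from the full GRE universe 1,000 times and recounts
(a `restrict_to_linked` option limits the pool to linked GREs). Empirical
p counts ties against significance (#{null ≥ obs}/n_perm), BH over genes;
RDGs additionally need ≥ 2 divergent links and ≥ 5 total links. The
HS-DEG overlap test draws random same-size gene sets from the universe and
reports the empirical exceedance p plus the fraction of HS-DEGs that are
RDGs.

## TFBS evolution

PWMs (JASPAR text format) are converted to log₂-odds against the
background base composition with a 0.8/4 pseudocount per cell. The match
threshold is calibrated to a null exceedance probability of 5e-5 by exact
dynamic programming over the score distribution, with scores discretized
to a 1e-4 log₂-odds grain; scanning uses the same integer scale, so
threshold and scan are consistent to the bit and the DP is checkable
against exhaustive window enumeration. Presence is GRE-level: any window
on either strand at or above threshold; windows containing N never match.

Gain/loss events reuse the single-transition rule on the presence vector
over the six chain nodes. Expansion/depletion per motif × lineage uses two
chi-square tests — (i) 1-df goodness-of-fit of the (gains, losses) split
against the global split over all motifs and lineages, and (ii) a 2×2 test
against the same motif's pooled other lineages (0.5 added to all cells
when any is zero) — flagged only when both FDRs < 0.01 with the gain
fraction on the same side of both references. Motif–lineage cells with
< 5 events are not tested; motifs whose TF detection fraction is below
25% in every cell type are dropped. Family aggregation unions member
events (deduplicated per family × GRE × lineage × direction). Cell-type
enrichment of event GREs in marker GREs uses Fisher tests (one-sided
`greater` by default for the cell-type panels, two-sided available),
enriched at FDR < 0.05 and OR > 1.3.

## Synthetic data generator

The generator emulates every input with planted, bookkept truth:

- **Guide tree**: 5 apes (ladder Human/Chimp/Gorilla/Orangutan/Gibbon),
  ≥ 2 OWM sister to apes, ≥ 2 NWM outgroup; chain branches take the MY
  values above, scaled to per-site units by the background rate.
- **Alignments**: gapless root→tip F81 evolution (uniform frequencies by
  default). Planted substitutions force the ancestral base above and the
  derived base at/below the named branch, with the site masked from
  background mutation — exactly one chain transition exists by
  construction, so planting never needs retries and cannot be destroyed
  by homoplasy. Divergent GREs multiply the named chain branch's rate
  (default spec: 5×). Optional flags inject non-human gap runs (missing
  data) and human-gapped columns to exercise the gap-stripping path.
- **Background substitution rate**: default 3e-3 substitutions/site/MY
  against the lower-bound branch times, i.e. ≈ 35–40 chain substitutions
  per 500 bp GRE. This load is the classifier's informative operating
  regime: per-GRE lineage proportions then have binomial noise below the
  fold-change (1.5×) and z (1 SD) cutoffs, so planted 5× rate shifts
  separate cleanly from background. At sparser, strictly neutral-rate
  loads (~1e-3) the same cutoffs admit ~12% of null GREs for the human
  lineage — a property of the three-cutoff procedure at low counts, not of
  this implementation — so passing tests here demonstrate classifier
  correctness in its operating regime rather than performance on
  arbitrarily sparse data.
- **Multiome**: pseudobulk accessibility (GRE × unit) and expression
  (gene × unit) as standard normals; a planted link gives the gene a
  latent factor and loads the GRE on it with weight r, so the expected
  Pearson correlation equals the target exactly; linked genes are placed
  amid their GREs, all genes land within 300 kb of some GRE so null pairs
  are tested. Read-level ATAC/RNA data, doublets and batch effects are
  *not* emulated.
- **Motifs/markers**: informative PFMs (consensus frequency 0.85 ≥ 0.8);
  a planted gain embeds the consensus at/below the event branch and a
  verified non-matching shuffle elsewhere (losses reversed), the window
  masked from mutation; coincidental background matches of a planted
  motif elsewhere in the GRE are overwritten with a shared non-matching
  block (constant column block: contributes no transitions). Marker
  tables take exact ⌊fraction × n⌋ disjoint GRE sets per cell type, with
  an option to concentrate planted divergent GREs in one cell type.
  Detection-fraction tables default to 0.3–0.9, with designated
  low-detection TFs below the 25% filter.
- **Randomness**: one seed; independent `numpy` Generator streams per
  stage (stream key = CRC32 of the stage name), so stages replay
  identically and all outputs are byte-reproducible.

## Numerical choices

- Pruning uses per-site rescaling and site-pattern compression.
- Posterior ties and sub-threshold maxima call `N` (conservative).
- Degenerate inputs: empty stripped alignments are skipped and counted;
  zero-variance pseudobulk rows are skipped and logged; Fisher tests on a
  class equal to the universe are flagged degenerate; odds ratios get a
  0.5 display continuity only when a margin cell is 0.
- Resampling p-values are k/n (ties and zeros allowed) unless the
  pseudocount option is set; permutation p-values use ≥ (ties count
  against significance).
- Perfect separation in the logistic model is detected and flagged rather
  than reported as an estimate.

## Problem sizes in the shipped tests and acceptance script

End-to-end checks run at: 1,000 GREs × 500 bp (substitution recovery),
5,000 GREs with 100 planted human-divergent across 3 seeds (classifier
recovery), 400 GREs × 200 pseudobulk units (linkage/RDG), ~170 planted
motif events over 300 GREs (TFBS). The acceptance script uses a 2,000-GRE
cohort for the substitution/divergence metrics. These sizes give stable
recovery estimates while keeping a full run in minutes on one CPU.

## Known limitations

- Marginal (not joint) reconstruction: at homoplasious sites the
  node-wise argmax can confidently produce an apparent single transition
  that is absent from the true history (~3% of background calls at the
  default load, measured against generator truth). Joint reconstruction
  would trade this for other artifacts and is out of scope.
- Only F81 is implemented; GTR/HKY model mismatch on real alignments is
  not represented in the synthetic benchmark (by design: the generator
  matches the inference model so reconstruction error is attributable to
  data, not model mismatch).
- The resampling classifier's error rates depend strongly on per-GRE
  substitution counts (see above); on sparser real cohorts the z and
  fold-change cutoffs admit more count noise.
- TFBS presence is binary at the GRE level; affinity changes that do not
  cross the match threshold are invisible.
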