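# Methods

## Scope and model

trapscore scores single-nucleotide variants by transcript-level splicing
damage. For every transcript whose gene span contains the variant, a
20-feature vector is extracted and fed to a 1,000-tree random forest; the
TraP score is the fraction of trees voting pathogenic, so scores are exact
multiples of 1/1000 and survive 3-decimal rounding losslessly. Variants are
scored per transcript; when a single per-variant value is needed, the
maximum over transcripts is the recommended (worst-case, clinically
conservative) aggregation.

All coordinates are 1-based inclusive throughout (the GTF/VCF convention);
every sequence-window helper takes (contig, start, end, strand) and
reverse-complements on the minus strand. This single convention is what the
strand-invariance property tests lock in: a variant and its
reverse-complement twin on the mirrored gene produce identical vectors.

## Splice-site PSSMs

Matrices are tallied from annotated introns whose strand-oriented ends read
G[T/C]..AG; both matrices come from the same intron set. Windows: acceptor
= 20 intronic + 3 exonic nt (K=23), donor = 3 exonic + 6 intronic nt (K=9).
Scoring is the sum of per-position log2 frequencies, normalized to 0-100
between Min and Max.

Numerical choices:

* **Pseudocounts** — add-one (Laplace) per base per position, so log2 never
  sees zero. Standard, and order-preserving at realistic counts.
* **Min/Max** — by default the analytic bounds over all possible K-mers
  (sum of per-position extreme log-frequencies). This is deterministic,
  independent of which motifs happen to be annotated, and guarantees every
  genomic motif normalizes into [0, 100], with the per-position argmax
  motif at exactly 100 and the argmin at exactly 0 (the bounds are
  accumulated in the same summation order as motif scoring, so the extremes
  are bit-exact). `bounds="annotated"` instead takes the extremes over the
  training windows, for comparison: under it the best annotated site scores
  100. The wording "minimum and maximum scores over motifs in the genome"
  is genuinely ambiguous between these two readings; the analytic reading
  is the default because it never clips real sites.
* **Ambiguous bases** — windows containing N score as missing and the
  affected feature is imputed 0, with a logged warning.

## Features

The registry is fixed, in order: `acc_score_ref, acc_score_alt,
don_score_ref, don_score_alt, acc_delta, don_delta, cryptic5_score,
cryptic3_score, cryptic5_lost, cryptic3_lost, splice_site_overall,
variant_splice_score, esr_created, esr_disrupted, silencer_created,
silencer_disrupted, combined_esr_score, negated_esr_score, gerp_rs,
dist_nearest_ss`.

* Splice deltas: the post-variant score differs from the pre-variant score
  only when the variant lies inside the corresponding window (windows are
  re-extracted from a substituted genome view, which encodes that rule
  structurally).
* Cryptic sites: both dinucleotide frames overlapping the variant are
  examined on the transcript strand. A GT (donor) or AG (acceptor) core
  present in one allele but not the other triggers scoring of the implied
  full window on that allele; the best normalized score per class is kept.
  The scan radius is exactly the frames overlapping the variant — a
  substitution cannot change a core it does not touch — with ±25 nt of
  local sequence kept so either window class fits in either frame.
* Interactions: `splice_site_overall = max(0, cryptic − existing same-class
  score)` over both classes (a strong existing site nullifies a cryptic
  competitor); `variant_splice_score = max(splice_site_overall, −acc_delta,
  −don_delta, cryptic5_lost, cryptic3_lost, 0)`, a single worst-damage
  summary. The published feature set names these two composite features but
  their exact published formulas are not restated in any accessible source;
  these max-of-damage compositions implement the stated logic and are
  isolated behind the registry so alternative formulas are pluggable. They
  are TraP-like, not bit-compatible with the original implementation.
* ESR turnover: exonic variants only. For each motif set of length k the
  2k−1-nt windows centred on the variant (truncated to the exon) are
  compared between alleles position-wise; a k-mer offset whose alt k-mer is
  in the set while the ref k-mer is not counts as a creation, the reverse
  as a disruption. `combined_esr_score = esr_created − esr_disrupted −
  silencer_created + silencer_disrupted`; `negated_esr_score = −(esr_created
  + esr_disrupted)`, a magnitude-of-perturbation term (the original names
  this feature without giving a formula).
* CpG gain/loss is computed and exported but excluded from the registry,
  matching the published finding that it did not improve the model.
* Missing conservation is imputed as 0 with a flag column rather than
  dropping the variant: scoring non-conserved positions is core behavior,
  not an error path.
* Intronic variants attach to the nearest exon by minimal distance;
  equidistant ties attach to the upstream exon.

## Forest

scikit-learn's `RandomForestClassifier` with 1,000 trees, floor(√N)
features per split, bootstrap + out-of-bag error, mean-decrease-Gini
importances, and no class reweighting by default (the historical training
set was 75 pathogenic vs 402 controls and was used unweighted); balanced
weights are available for synthetic experiments. Scoring bypasses
probability averaging: each tree's hard vote is counted, so `value ×
n_trees` is always an integer. Tier thresholds: 0.459 / 0.93 (benign,
possibly damaging, probably damaging); the 19-feature conservation-free
model uses 0.66 / 0.955.

Cross-validation shuffles, splits into contiguous unstratified folds
(stratification exists but is off by default, since the original scheme is
not described as stratified), trains on the remainder, pools each repeat's
held-out scores into one AUC, and averages over repeats. A shuffle that
leaves a training fold single-class is redrawn with a logged note. Repeat r
derives its generator from `seed + r`, so repeat 1 is identical regardless
of how many repeats follow.

## Evaluation toolkit

ROC/AUC by trapezoid over the full tie-grouped sweep; sensitivity/
specificity at a threshold (score ≥ t called positive); Mann–Whitney U
(exact for n ≤ 8 without ties, tie-corrected normal otherwise);
score-quantile binned MAF correlation (20 equal-count bins, Pearson over
the bin means — quantile bins rather than fixed-width ones because both
scores and MAF are heavily right-skewed, and fixed-width bins above 0.5
would be nearly empty); non-parametric QQ comparison interpolating the
larger sample's order statistics at the smaller sample's plotting positions
(a set against itself returns the identity exactly); and one-sided Fisher
enrichment. The enrichment table contrasts the gene list (k, n−k) with a
genome-wide reference column (K, N−K) taken as-is — the construction used
when a published gene catalog is the comparison column.

## Synthetic study conditions

The generator's defaults are the package's study conditions: 40 three-exon
genes (alternating strands, one contig each), exons 60–90 nt, introns
40–70 nt (≥ 26 nt so the donor and acceptor windows of one intron never
overlap), 10% GC donors, splice sites tuned to strong (85) or weak (60)
normalized strengths with 20% weak, and 500 variants in a 1:4
pathogenic:benign imbalance (donor 6%, acceptor 5%, cryptic 5%, ESR 4%,
neutral 80%) echoing a 75:402-style curated training set. Conservation is
Normal(0, 1) noise mean-shifted by +3 at functional elements, with 20% of
elements left unelevated to emulate pathogenic variation at non-conserved
positions. Splice-site-disrupting variants are drawn at five discrete
magnitude levels so monotone damage response is testable.

Design choices worth knowing:

* **Motif alphabet.** Toy enhancer/silencer hexamers are drawn over {A, C}
  only: they can never contain a GT/AG core nor overlap splice consensus,
  which keeps each engineered variant class activating exactly its own
  feature block. Real SRSF1/2/5/6 catalogs are user-supplied files.
* **Site-strength tuning.** Normalized site scores are self-referential:
  the matrix is built from the very windows being tuned, and weakening
  edits flatten it, inflating everyone's normalized score. Greedy in-place
  editing therefore diverges. The generator instead re-derives each window
  each round from the fixed design consensus (matrix argmax is unstable at
  low-information positions), descending along a per-site shuffled
  candidate order until the score sits inside the band; donor windows
  (4^7 free combinations) are solved exactly when greedy descent stalls.
  Later rounds touch only the worst offenders so the counts settle, and
  the loop exits only after verifying every window against the matrices it
  itself induces. The internal band is 4.0 normalized units against the
  generator's contract of ±5; matrices tallied from fewer than ~50 introns
  are too volatile for that band, so small test fixtures explicitly pass a
  looser `site_tolerance`.
* **Engineered cryptic donors** are planted as the consensus donor 9-mer
  with its core T knocked out; the A→T variant restores the full consensus,
  which scores ≈ 100 — comfortably above the "strong cryptic" threshold of
  84 — under any matrix the generator produces.
* **Neutral variants** are rejection-sampled and verified not to touch
  splice windows, change any GT/AG frame, or toggle any motif k-mer.
* All randomness flows from `(seed, stream)` spawns of one NumPy generator;
  identical seeds reproduce byte-identical FASTA/GTF/VCF/track files.

## What the synthetic conditions do not emulate

No codon structure or realistic mutation-rate model; no branch points,
polypyrimidine-tract features beyond the 23-nt acceptor window, or RNA
secondary structure; conservation is a caricature (iid noise plus a mean
shift); classes are orthogonal by construction, whereas real variants mix
mechanisms. Passing tests therefore demonstrate that the machinery is
correct and self-consistent — features fire exactly when engineered
lesions are present, the forest recovers recoverable labels, statistics
match enumeration oracles — not that the trained toy forest transfers to
real genomes. Scoring real data requires a real genome build, transcript
annotation, GERP-style track and SR-protein motif catalogs, and retraining
on curated labels.

## Problem sizes used in the checks

The default bundle (500 variants, 40 genes) drives label-recovery and
determinism checks; monotone damage response uses a dedicated 80-gene,
250-donor-variant family at five magnitude levels; the exhaustive feature
oracle enumerates all 264 SNVs of an 88-nt toy gene; PSSM brute-force
equivalence enumerates all motifs for K ≤ 6; Fisher enrichment is checked
against full hypergeometric enumeration for table populations up to 60.
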