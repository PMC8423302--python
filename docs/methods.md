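# Methods

## CpG and dinucleotide metrics

For a transcript of length L (full length, N bases included):

* CpG frequency = #CG / (L − 1). The denominator is the number of
  overlapping dinucleotide windows in a gapless sequence.
* normalised CpG = CpG frequency / (Prop(C) · Prop(G)), the
  observed/expected odds ratio; 1 means CG occurs as often as expected
  from the C and G content, < 1 means suppression.
* expected CpG = Prop(C) · Prop(G) · (L − 1).

General dinucleotide bias for an ordered pair XY uses the observed
frequency over *valid* windows (windows without N) divided by the product
of the mononucleotide proportions; dinucleotide proportion is
count(XY)/valid windows.

**N handling.** Windows containing N are removed from both the count and
the valid-window denominator of biases/proportions; mononucleotide
proportions are over non-N bases; but L in the three printed CpG formulas
above stays the total length so those formulas hold verbatim. A bias whose
expected term is zero (a base absent from the sequence) raises
`UndefinedCompositionError` from the standalone functions and is encoded as
0.0 inside the feature vector, which must be finite.

## The 185-feature scheme

34 whole-transcript features (GC, AT, 16 dinucleotide biases, 16
dinucleotide proportions) plus 151 ORF features (GC, AT, 16 + 16
dinucleotide biases/proportions, 64 codon usage biases, 21 amino-acid
proportions including stop, 16 bridge and 16 non-bridge dinucleotide
biases). The canonical order is versioned
(`composition.FEATURE_SCHEME_VERSION`): whole-transcript block then ORF
block, dinucleotides in AA..TT lexicographic order, codons lexicographic,
amino acids alphabetical by one-letter code with stop (`*`) last.

Definitions where more than one convention exists:

* **Codon usage bias** is RSCU-style: observed codon count divided by
  (family count / family size), where a family is the set of codons for
  one amino acid (stop codons form their own family). Families absent from
  a CDS contribute 0 for each member codon.
* **Amino-acid bias** is the proportion of each of the 21 translated
  symbols (20 amino acids + stop).
* **Bridge bias** is the dinucleotide bias computed over the n−1 windows
  spanning codon position 3 → next codon position 1, with the expected
  term taken from position-specific mononucleotide frequencies
  (f₃(X)·f₁(Y)). **Non-bridge bias** pools the within-codon windows 1–2
  and 2–3, with expected term (f₁(X)·f₂(Y) + f₂(X)·f₃(Y))/2.

These position-specific definitions are the package's own, stated here
because the upstream literature cites rather than restates them; they are
stable under the version tag above.

## Input conventions

One transcript per gene: the longest cDNA wins; exact ties go to the
lexicographically smallest transcript id. Sequences are uppercased and
IUPAC ambiguity codes outside {A,C,G,T,N} map to N (logged). The
"longer than 100 nt" transcript filter is strict (length > min_len).
CDSs whose length is not a positive multiple of 3 are dropped (logged)
rather than truncated. DE tables are consumed as given — the package never
refits differential expression.

## Gene sets and statistics

ISGs/IRGs are the n most up-/downregulated genes by mean log2FC among
genes with FDR < 0.05 (up = log2FC ≥ 0 so that the up/down split
partitions the significant genes); if fewer than n are significant, all
are returned. Ties break by gene id. Random control sets are uniform
draws without replacement from genes with FDR ≥ 0.05 and expression
evidence in every sample.

Two-group comparisons use the two-sided Wilcoxon rank sum test in its
normal approximation with continuity and tie correction
(`scipy.stats.mannwhitneyu`). Multi-group comparisons use Kruskal–Wallis
followed by Dunn's pairwise z-tests (mean-rank differences with tie
correction, implemented here) and Benjamini–Hochberg adjustment across the
pair set (statsmodels). Degenerate input — every observation identical —
returns p = 1 by convention instead of an error.

## Classifier

`InterferomeClassifier` wraps XGBoost's DART booster (drop-out regularised
gradient-boosted trees) behind the sklearn estimator API. Defaults:
max_depth 4, learning_rate 0.1, n_estimators 60, rate_drop 0.1,
subsample 0.8, colsample_bytree 0.8, min_child_weight 1, single thread.
These defaults are deliberately modest so repeated cross-validation stays
cheap; `tune_and_train` performs the random hyperparameter search
(default 100 combinations from the documented grid in
`classifier.DEFAULT_PARAM_GRID`, scored by stratified 5-fold CV accuracy)
and refits the winner on all data. The grid is configuration, not science.

Model evaluation: 50 replicates of stratified 5-fold cross-validation.
Folds are stratified by class so per-class accuracy is defined in every
fold; per replicate, per-class accuracy is the proportion of genes of that
class correctly identified among pooled out-of-fold predictions, and the
report carries the replicate mean and the central 95% interval of observed
accuracies. All randomness (fold shuffles, parameter draws, tree fitting)
derives from one run seed.

**Feature importance.** Shapley values come from TreeSHAP as implemented
natively by XGBoost (`pred_contribs`), on the log-odds margin of the
positive class. Per feature we take the mean absolute value across genes
(the sum is available as an option; after rescaling the two are
proportional at fixed gene count, so rankings are identical). Feature
classes pool correlated measures: each dinucleotide's class sums its
whole-transcript bias and proportion, ORF bias and proportion, and bridge
and non-bridge biases; each codon and amino acid is its own class; GC and
AT pool their two versions. Class aggregates are divided by their maximum
so the top class is exactly 1. Local accuracy (attributions + base value
reproduce the margin) holds to float32 rounding (~1e-6).

## Codon Adaptation Index

Weights w_c = f_c / max over the synonymous family, with frequencies
pooled across the reference CDS collection supplied by the caller
(per-genome in practice). Codons unobserved in the reference get a 0.5
pseudo-count before weights are formed so no weight is zero. Stop codons
are excluded from the weight table and from the codon length L; CAI is the
geometric mean of the remaining weights, computed as exp(mean log w).

## CpG conservation

Degree d of an aligned column pair = number of rows with C then G there
(gap or N in either column disqualifies that row only). Each carrying row
contributes one CpG *instance* to bin d — instances, not unique sites, so
the units match CpG per kb of summed (ungapped) gene length; with gapless
equal-length rows the two conventions are proportional. Overlapping CpGs
are counted at every column pair. "Total gene length" is the ungapped
length summed over all rows and genes.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated.

* **Sequences**: a first-order Markov chain whose transition matrix is
  solved in closed form so the designed base composition π is *exactly*
  stationary and the stationary CG odds ratio equals the target t: row C
  has P(C→G) = t·π_G with the remainder proportional to π, and the other
  three rows share the compensating distribution q = (π − π_C·row_C)/(1 −
  π_C). Infeasible targets (a negative entry) raise an error naming the
  bound. Realised normalised CpG is within ±0.05 of target at L = 10,000.
* **ORFs**: ATG … stop with no internal stops; each successive codon is
  drawn with probability proportional to its base-composition weight times
  t per CG dinucleotide it would create (within-codon or bridging). The
  realised odds is steered, not exact — ORF constraints make some targets
  unreachable — but designed targets 0.4 vs 1.2 separate by well over 0.4
  in realised normalised CpG.
* **Gene sets** (`GeneSetDesign` defaults): 50 genes per class; normalised
  CpG targets ISG 0.4, RANDOM 0.8, IRG 1.2, bracketing the suppression
  observed in real interferomes (these are test conditions, not measured
  biology); transcript lengths log-normal with median 1,500 nt and log-sd
  0.4; half of each transcript is ORF, the rest UTRs with the same
  compositional target; log2FC ~ N(+4, 1) for ISGs, N(−4, 1) for IRGs
  (clipped away from 0), N(0, 0.25) for random genes; FDR < 0.05 for
  ISG/IRG and ≥ 0.05 for random genes; base composition A 0.26, C 0.24,
  G 0.24, T 0.26.
* **Alignments**: CpG-free background with CpG sites planted at chosen
  conservation degrees (carrying rows drawn uniformly), one site per three
  columns at most, so the ground-truth conservation profile is exact.

**What passing tests do and do not show.** Synthetic transcripts are
compositionally homogeneous along their length and carry no promoter,
splicing, expression-level or phylogenetic structure; classes differ only
in the dials set by the design. Recovering a designed CpG gap therefore
validates the machinery (features, CV, importance aggregation), not the
biological claim — real interferomes carry correlated features and weaker,
messier signals, and cross-species heterogeneity that these generators do
not emulate. Likewise the planted alignments contain no substitution
process, so conservation round trips validate only the binning arithmetic.

## Problem sizes and numerical choices

Default validation runs use a few hundred genes per class (the
chance-level control uses 200/class, the engineered-signal check
500/class) and 50×5-fold CV — sizes chosen so the full suite runs
comfortably on a laptop core while keeping binomial noise on accuracy
estimates near one percentage point. Probabilities from the booster are
float32; determinism is guaranteed only at fixed thread count (the package
pins one thread). JSON summaries are written with sorted keys so reruns
are byte-identical.

## Known limitations

* Only two-class classification; the three published-style comparisons are
  three separate binary models.
* The amino-acid and position-specific bias definitions above are one
  consistent choice among several in the literature; any consistent choice
  feeds the classifier equivalently.
* CAI weights are computed per reference set supplied; cross-species
  pooling is the caller's decision.
* Dunn's test uses the normal approximation; very small groups (< ~5) are
  better served by exact tests.
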