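# ifncomp

Compositional genomics of the interferome — the set of transcripts whose
abundance changes when a cell is treated with type I interferon (IFN).

Interferon-stimulated genes (ISGs) tend to carry strongly suppressed CpG
dinucleotide content, plausibly because the same CpG-directed antiviral
machinery (such as ZAP) that destroys CpG-rich viral RNA would otherwise
destroy the host's own antiviral transcripts. `ifncomp` packages the
quantitative side of that analysis as a tested, reusable pipeline for
anyone working with transcript composition and interferon biology:

* **CpG metrics** per transcript:
  `CpG frequency = #CG / (L − 1)`,
  `normalised CpG = CpG frequency / (Prop(C) · Prop(G))` (the
  observed/expected odds ratio; < 1 means suppression), and
  `expected CpG = Prop(C) · Prop(G) · (L − 1)`.
* **185 compositional features** per gene: a 34-entry whole-transcript
  block (GC, AT, 16 dinucleotide biases, 16 dinucleotide proportions) plus
  a 151-entry ORF block (GC, AT, dinucleotide biases/proportions, 64 codon
  usage biases, 21 amino-acid proportions including stop, and 16 + 16
  dinucleotide biases at codon *bridge* — position 3 → next position 1 —
  and non-bridge positions).
* **Expression-class classification**: a DART (drop-out regularised)
  gradient-boosted tree classifier (`InterferomeClassifier`, sklearn
  estimator API) distinguishing ISGs, IFN-repressed genes (IRGs) and
  random expressed genes from composition alone, evaluated by 50 replicates
  of stratified 5-fold cross-validation, with random hyperparameter search.
* **Shapley feature importance** (TreeSHAP): per-gene attributions,
  mean absolute value per feature, summed into broad feature classes (all
  six measures of one dinucleotide pool into e.g. the CpG class) and
  rescaled to [0, 1].
* **Codon Adaptation Index**: `w_c = f_c / max(f_c′)` over synonymous
  codons, `CAI = (∏ w_c)^(1/L)` computed in the log domain.
* **CpG conservation** across multi-species alignments: CpG instances per
  kb binned by the number of species carrying each aligned CpG site.
* **Gene-set selection and statistics**: top-n ISGs/IRGs by mean log2 fold
  change at FDR < 0.05, random non-DE control sets, Wilcoxon rank sum with
  continuity correction, Kruskal–Wallis + Dunn post hoc with
  Benjamini–Hochberg correction.
* **Synthetic data** with known structure: first-order Markov sequences
  with exact stationary base composition and CpG odds ratio, valid ORFs
  with steered CpG content, DE tables with designed effect sizes, and
  alignments with planted conservation spectra — so every stage is
  testable without downloads.

Inputs are plain files: Ensembl-style cDNA/CDS FASTA (one longest
transcript per gene is retained), tab-separated DE tables
(`gene_id  log2fc  fdr  expressed_all_samples`), and aligned FASTA.
Upstream RNA-seq processing (read mapping, edgeR) is out of scope: the DE
table is the interface.

## Worked example

```python
import numpy as np
from ifncomp import (GeneSetDesign, generate_gene_set, feature_table,
                     cpg_frequency_normalised, repeated_cv,
                     InterferomeClassifier, feature_importance,
                     wilcoxon_rank_sum)

design = GeneSetDesign(n_isg=50, n_irg=50, n_random=50, seed=42)
records, de_table, labels, _ = generate_gene_set(design)

cpg = {cls: [cpg_frequency_normalised(r.cdna) for r in records
             if labels[r.gene_id] == cls] for cls in ("ISG", "RANDOM", "IRG")}
for cls, vals in cpg.items():
    print(f"median normalised CpG {cls}: {np.median(vals):.3f}")
print(f"Wilcoxon ISG vs IRG p = {wilcoxon_rank_sum(cpg['ISG'], cpg['IRG']):.3g}")

keep = [r for r in records if labels[r.gene_id] != "RANDOM"]
X = feature_table(keep)
y = np.array([labels[g] for g in X.index])
report = repeated_cv(X, y, folds=5, replicates=10, seed=42)
for cls, acc in report.per_class_accuracy.items():
    lo, hi = report.interval_95[cls]
    print(f"CV accuracy {cls}: {acc:.3f} (95% interval {lo:.3f}-{hi:.3f})")

model = InterferomeClassifier(random_state=42).fit(X, y)
print(feature_importance(model, X).top(3).round(3).to_string())
```

prints

```
median normalised CpG ISG: 0.475
median normalised CpG RANDOM: 0.851
median normalised CpG IRG: 1.167
Wilcoxon ISG vs IRG p = 7.07e-18
CV accuracy IRG: 0.978 (95% interval 0.964-0.980)
CV accuracy ISG: 1.000 (95% interval 1.000-1.000)
CpG    1.0
AT     0.0
GC     0.0
```

The synthetic ISG class was designed with normalised CpG ≈ 0.4 and the IRG
class ≈ 1.2; the measured medians recover that ordering, the rank-sum test
finds the separation overwhelming, the classifier distinguishes the classes
almost perfectly from composition alone, and the rescaled Shapley
importance identifies CpG as the feature class carrying the signal (here it
carries essentially all of it, so other classes score ≈ 0).

## Command line

Each stage is a subcommand of `ifncomp`:

```bash
ifncomp simulate --design design.yaml --out sim/
ifncomp features --cdna sim/cdna.fa --cds sim/cds.fa --out features.tsv
ifncomp cv --features features.tsv --labels sim/labels.tsv \
           --folds 5 --replicates 50 --seed 1 --out cv.json
ifncomp cai --reference ref_cds.fa --cds query_cds.fa --out cai.tsv
ifncomp conserve --alignments alignments/ --out profile.tsv
ifncomp run --config config.yaml     # full pipeline + summary.json
```

Every output directory receives the resolved configuration and seed;
rerunning with the same config and seed reproduces `summary.json` byte for
byte.

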