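# Methods

## Feature encoding

Residues are mapped onto seven classes defined by side-chain volume and
dipole moment (1 = A,G,V; 2 = I,L,F,P; 3 = Y,M,T,S; 4 = H,N,Q,W; 5 = R,K;
6 = D,E; 7 = C). The mapping is total over the 20 standard amino acids and
nothing else: ambiguity codes (X, B, Z, U, J, O) and gaps raise an error
by default, because silently guessing a class would corrupt frequencies.
An opt-in mask mode (`--skip-ambiguous` on the CLI) instead drops every
n-gram window touching an ambiguous residue and renormalizes over the
remaining windows; a sequence left with no valid window is an error either
way. Cysteine sits alone in class 7 exactly as tabulated.

The n-gram vector of a sequence of length *L* has one entry per digit
gram, indexed lexicographically (gram c₁c₂c₃ → 49(c₁−1) + 7(c₂−1) +
(c₃−1)); that convention is part of the on-disk feature contract
(`pdz_tg_111` … `pep_bg_77`) so persisted models stay portable. Each
entry is the window count divided by the number of windows counted, so
every per-sequence block sums to 1 and an interaction vector (domain block
‖ peptide block) has total mass 2. Length normalization is also why
peptides shorter than the 10-residue truncation window are used as-is:
their block remains comparable without padding.

## Class rules

Peptide classes read two positions of the C-terminus: Class I iff
position −2 ∈ {S,T} and position 0 ∈ Φ; Class II iff −2 ∈ Φ and 0 ∈ Φ;
Class III iff −2 ∈ {D,E} and 0 ∈ Φ; anything else is unclassified. Φ
defaults to {A,C,F,I,L,M,V,W,Y}: the hydrophobic residues of the standard
scales minus S/T/D/E, which keeps the three rules mutually exclusive. Φ is
a config knob because reclassification is sensitive to it. A domain's
class comes from its *binding* partners only: ≥1 Class I and ≥1 Class II
partner → I-II; only Class I → I; only Class II → II; otherwise
unassigned (domains binding only Class III or unclassified peptides carry
no class evidence and are excluded from the class task).

## Random Forest and OOB tuning

Training wraps scikit-learn's `RandomForestClassifier` with bootstrap
bagging, `numFeature` split candidates per node (default 30) and
`numTree` trees (default 200). Scores are majority-vote fractions over
tree *labels* — not averaged leaf probabilities — matching the ensemble's
stated decision rule; ties go to the first class in sorted order. The OOB
error (1 − OOB accuracy) drives parameter selection: one forest per grid
point, minimum OOB wins, ties break toward smaller `numFeature` then
smaller `numTree`.

The default feature grid is the ladder {5, 10, 20, 30, 50, 100} extended
with the dimension-aware points d/4 and d/2. The extension matters when
few informative columns hide among many noise columns: on the synthetic
686-dimensional benchmark the OOB error at `numFeature` = 100 is ~0.10
but ~0.07 at 262, so a grid capped at an absolute 100 would systematically
undersell the model on trigram interaction spaces.

Supervised resampling (a stratified bootstrap that preserves per-class
counts exactly) is provided for imbalanced tables but is **off by
default** during cross-validation. Two observations drove this: the
bootstrap discards ~37% of each training fold and duplicates
noise-flipped labels, costing about four accuracy points on the balanced
synthetic benchmark; and applying it *before* the CV split (the classic
pre-process order, available as `--resample pre`) lets duplicated
instances straddle folds and leak. `--resample fold` applies it inside
training folds only, which is the safe way to use it on imbalanced data.

## Evaluation

Binary metrics follow TPR = TP/(TP+FN), FPR = FP/(FP+TN), P = TP/(TP+FP),
accuracy = (TP+TN)/total, with zero-denominator ratios reported as
undefined (`null` in reports) rather than 0. ROC construction sweeps the
distinct scores with ties grouped; the trapezoid area equals the
Mann–Whitney pair-concordance statistic with half-credit for ties (tested
to 1e−12 against a brute-force oracle). PR curves report (recall,
precision) per threshold with recall running upward; the degenerate
all-equal-scores case collapses to the single point (1, prevalence).

Cross-validation is stratified and seeded; every instance is tested
exactly once. Fold confusions are pooled (micro-averaged) for the
headline metrics because per-fold ratios on small folds are unstable;
per-fold accuracies are retained in the report. Multi-class tasks report
per-class correct/total counts, overall accuracy, and a class-size-
weighted mean of one-vs-rest AUCs computed from the vote-fraction score
vectors — a convention chosen because it degrades gracefully to the
binary AUC when only two classes are present.

## CFS feature selection

Merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff) for |S| = k, where r̄_cf is the
mean feature–class correlation (absolute point-biserial for binary
labels; for 3-class labels the multiple correlation √(SS_between/SS_total)
of the column against the one-hot label matrix) and r̄_ff the mean
absolute pairwise Pearson correlation. Correlations run on the raw
frequency columns without discretization — a deliberate choice that
avoids an arbitrary binning step and makes results exactly reproducible;
zero-variance columns are defined to have correlation 0.

Two deterministic searches are provided. Greedy-forward adds the best
single feature until merit stops improving (strict improvement beyond
1e−12, ties to the lowest index). Best-first keeps a merit-ordered open
list, expands the best node by single additions and removals, and stops
after 5 consecutive expansions that fail to improve the best merit seen.
Because expansion follows merit order, best-first traverses the greedy
chain first and its result can never score below greedy's. "Run several
searches and consider all results" is realized as: run all configured
strategies and take the union of their subsets (intersection by flag).
For interaction instances, selection runs separately on the domain and
peptide blocks so each block's grams are reported in its own right.

## Motif mapping

A motif (digit gram) is scanned across every column window of a supplied
alignment. Per column, a row counts only if its window is gap-free; the
occupancy is matched/gap-free rows, so gap-heavy columns are neither
inflated nor penalized. Columns with occupancy ≥ 0.7 (configurable) are
reported; 0.7 operationalizes "strongly conserved" and is a declared
default, not a reproduction of any published threshold. Consensus motifs
are the selected bigrams contained in at least one selected trigram.
Secondary-structure regions (βA–βF, αA, αB) arrive as a user-supplied
table of half-open column intervals, since structure assignment is out of
scope; overlapping intervals are rejected.

## Synthetic world

The generator emulates the shape of a real PDZ screen: 85 domains of
80–90 residues, 181 peptides of length 10, domain classes in the 45:20:21
(I : II : I-II) proportions of a curated class table, peptide classes
40/30/30 across I/II/III, and a binding rule — a domain binds a peptide
iff the peptide's class is in the domain's specificity set — with
independent label flips at ε = 0.05, so Bayes-optimal accuracy is 1 − ε
by construction. Backgrounds are i.i.d. uniform over the 20 residues
(a frequency table can be supplied).

Signal is planted at two levels. Domains carry two copies of their
class-tag trigrams ("774" for Class I specificity, "775" for Class II,
both for I-II), realized as random residues of the right classes.
Peptides carry their C-terminal class pattern *plus* one interior tag
trigram ("747"/"757"/"767"). The interior tag exists because the
C-terminal pattern alone is not legible to a bag-of-n-grams model on a
uniform background: the rules' anchor residues collide in reduced space
(S/T and M/Y both map to class 3) and background windows mimic pattern
grams at a rate that caps recoverable accuracy well below the noise
ceiling. For the same reason the Φ anchor positions are generated from
{V, I, L} — the anchors that dominate natural PDZ ligands — though class
*rules* still use the full Φ set. Tags are built around class 7
(cysteine, rarest under a uniform background), keeping chance collisions
near 10⁻³ per window. Every generated peptide is re-verified against the
class rules; ground-truth labels are always emitted alongside observed
ones.

The planted alignment pads sequences with terminal gaps and overwrites
one gap-free column window so its reduced digits equal the configured
motif ("12" by default) in ~95% of rows.

What a green recovery test establishes: the pipeline can extract planted
class-discriminative composition signals and a planted conserved column
from data of realistic shape and noise. What it does not establish:
performance on real PDZ sequences, whose class signal is weaker, spread
over many covarying positions, and entangled with phylogeny — the
generator models neither sequence relatedness nor binding energetics.

## Numerical and degenerate-input choices

Seeds propagate explicitly: every generator stream, fold split, bootstrap
and forest derives from the master seed, and identical configurations
reproduce byte-identical reports (modulo a timestamp field). Frequency
vectors assert normalization to 1e−9. Sequences shorter than the window,
empty datasets, single-class training sets, ragged alignments, duplicate
ids/pairs, unknown labels and overlapping regions all fail loudly with
the offending item named. Model files carry a format header and the
feature convention id so a foreign or stale file is rejected rather than
silently misapplied.

## Known limitations

* The forest's OOB estimate comes from scikit-learn's probability-
  averaged OOB votes, which can differ slightly from a hard-vote OOB
  count at small ensemble sizes.
* Best-first search is exact only in the limit of an unbounded stall
  budget; with the default of 5 it matches the exhaustive optimum on
  ≥95% of random 10-feature instances but carries no guarantee beyond
  dominating greedy-forward.
* The comparison backends (kNN, naive Bayes, single tree, SVM) share the
  train/score contract but not the OOB machinery; only the forest is the
  reference model.
* Multi-class AUC has no unique definition; the weighted one-vs-rest
  choice here is stated, not canonical.
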