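# Methods

## Problem and model

Given a patient's candidate variants (a VCF plus an Annovar-style annotation
table) and a set of phenotype ontology classes describing the patient, the
package ranks variants by how likely they are to cause the observed
phenotypes.  Two channels are fused per variant *v*:

* **MS(v)** — the maximum, over the gene(s) the variant is assigned to, of a
  gene–patient relatedness score s(g, p) ∈ [0, 1] produced by an embedding of
  an ontology-backed knowledge base;
* **GP(v)** — the variant's pathogenicity (CADD, PHRED-like scale),
  min–max-normalized within the patient's candidate set;

combined as **S(v) = w·MS(v) + (1−w)·GP(v)** with default w = 0.5, after
removing common variants (max population MAF ≥ 1%, strict inequality;
missing MAF counts as rare).  Variants are ranked by descending S, ties
broken by descending GP and then genomic coordinate, so output is fully
deterministic.

The knowledge base is an EL-normal-form ontology (axiom shapes C⊑D, C⊓D⊑E,
C⊑∃R.D, ∃R.C⊑D) plus annotation edges linking genes and diseases to ontology
classes and a set of supervised gene–disease association pairs, split
80/15/5 into train/validation/test.  Only training associations ever enter
the embedding substrate; validation drives early stopping and the held-out
pairs measure generalization.

## Embedding channels

All channels score a gene against a *subject* (disease or patient node) and
expose plausibility in [0, 1], increasing in plausibility.

**Random walks + skip-gram (`dl2vec` / `owl2vec`).**  The ontology is
projected onto a labeled directed graph by fixed rules (C⊑D → subclass edge;
C⊑∃R.D and ∃R.C⊑D → an R-labeled edge; C⊓D⊑E → two subclass edges;
annotations and training associations become labeled edges; patients attach
via `has_phenotype` edges).  k walks start at every vertex; each step picks a
uniform outgoing edge and emits the edge label between vertices, so a walk
visiting n vertices has 2n−1 tokens and terminates early at sinks.  The
corpus trains a skip-gram model with negative sampling (window c, unigram^0.75
negative table, word2vec-style frequent-token subsampling at threshold 1e−3 —
edge labels occur in nearly every walk and would otherwise dominate the
updates).  Scoring: s(g, d) = σ(g̃·d̃).  The skip-gram trainer is mini-batched
(batch 256, linearly decaying learning rate from 0.025), with a generous
per-vector norm cap (10) because batched scatter-adds evaluate many pairs at
stale parameters and can overshoot for very frequent tokens.  It runs a fixed
number of epochs (word2vec convention) rather than validation early stopping.

**Knowledge-graph embeddings (`transe`, `transd`, `distmult`).**  Trained
with the margin-ranking loss Σ [s(h,r,t) − s(h′,r,t′) + γ]₊ where negatives
corrupt the head xor the tail with a uniform entity, rejecting existing edges
(filtered sampling).  Raw scores: TransE ‖h̃+r̃−t̃‖₂; TransD ‖h⊥+r̃−t⊥‖₂ with
h⊥ = h̃ + w_r(w_h·h̃) (per-entity and per-relation projection vectors);
DistMult Σᵢ h̃ᵢr̃ᵢt̃ᵢ.  Every method is reoriented internally to "higher =
more plausible", and gene–subject plausibility is σ(−dissimilarity) — a
monotone, bounded, parameter-free mapping; only the induced ranking matters
downstream.  Entity vectors are L2-normalized after each step for the
translational methods (standard constraint preventing trivial margin
inflation).  Gradients are hand-derived and verified against central finite
differences at 1e−4 in the test suite.  The interface admits additional
methods (TransR, ConvE slots) but only the three above are implemented.

**Geometric EL embeddings (`elem` n-balls, `elbox` boxes).**  Concepts are
regions (ball: center c, radius r ≥ 0; box: center c, offsets o ≥ 0), roles
are translations.  Inclusion losses are zero exactly when the margin-relaxed
containment holds:

* ball NF1: max(0, ‖c_C − c_D‖ + r_C − r_D − γ); NF3/NF4 translate the left
  center by ±v_R first; NF2 uses a midpoint-intersection surrogate
  (C,D must overlap; the midpoint with radius min(r_C, r_D) must fit in E);
* box NF1: Σ_d max(0, |c_C − c_D|_d + o_C,d − o_D,d − γ), translated
  analogously for NF3/NF4; NF2 mirrors the ball surrogate with the midpoint
  box and elementwise-min offsets.

Annotations and training associations are fed in as NF3 axioms (g ⊑ ∃rel.C,
g ⊑ ∃is_associated_with.d).  Negatives corrupt the right-hand concept and are
pushed to an inclusion distance of at least the negative margin (1.0); the
positive margin γ defaults to 0.1 for training and 0 for scoring, so
s(g, d) = σ(−loss) has maximum 0.5 at exact containment.  Ball centers are
kept inside the unit ball and radii in [0, 1]; box centers in [−1, 1]^d and
offsets in [0, 1].

*Region-size regularization.*  An L2 shrinkage on radii/offsets (default 1.0
for balls, 20.0 for boxes — per-dimension offsets need a stronger pull than a
scalar radius) keeps region sizes comparable across entities.  Without it,
entities that appear on the right-hand side of supervised axioms grow larger
regions than entities that never do, and the score — which rewards large
target regions — then reflects training exposure rather than position; with
the shrinkage, ranking is carried by the learned geometry.  This is the one
place the box model needed a choice beyond the classical loss family.

## Training loop

A single loop (Adam, default lr 0.02 at benchmark scale, batch 256) serves
the KGE and EL channels: per epoch it shuffles positives, draws filtered
corruptions, steps, applies the method's constraints, and evaluates a
validation loss — the margin loss of held-out associations against a fixed
set of 10 corruptions each (fixed so the criterion is stable across epochs).
Early stopping restores the parameters of the epoch with minimal validation
loss (the initialization counts as epoch 0) after `patience` (default 20)
non-improving epochs.  All randomness flows from one integer seed; training
is bitwise reproducible single-threaded, and every set-to-list boundary is
sorted so results do not depend on hash randomization.

**Inductive update.**  A new disease or patient absent from training receives
a randomly initialized block and `iters` (default 30) update steps whose
positives are only the new entity's phenotype edges.  With `iters=0` existing
parameters are bit-identical; a `freeze_existing` flag restricts updates to
the new block (default off: all parameters may drift, matching the brief
fine-tune semantics).  The walks channel fine-tunes by generating walks
started at the new node and continuing skip-gram training on those pairs.
Transductive mode instead attaches patients to the graph before training.

## Synthetic study conditions

The generator emulates every input at desk scale.  Defaults:

| knob | default | meaning |
|---|---|---|
| n_phenotypes / branching | 150 / 3 | rooted DAG (tree + 10% extra parents), NF1 axioms |
| n_genes / n_diseases | 200 / 20 | one causative gene per disease |
| phenotypes_per_disease | 8 | disease profile size |
| overlap | 0.8 | fraction of the profile shared by the causative gene |
| parent_signal_fraction | 0.5 | shared terms generalized to a parent class (signal through subclass axioms) |
| noise | 0.1 | patient terms replaced (random class or parent, equal odds) |
| n_variants | 100 000 | background size; 90% intronic / 10% exonic |
| MAF | Beta(0.5, 300), truncated < 0.01 | post-filter rare background; a prefilter mode (Beta(0.3, 10)) exercises the MAF filter |
| CADD | Gamma(2, 2.5) benign + 2.5% N(24, 5) high component | background deleteriousness |
| spike CADD | N(27, 2) | causative variant, high tail but overlapping the background's top component |

Genes are 3 kb intervals on one synthetic chromosome (first 30% exonic,
remainder intronic, 2 kb gaps); patients copy the background plus one exonic
spike inside the causative gene.  The spike's CADD is deliberately *not*
separated from the background's high component: pathogenicity alone usually
places the causative variant near — but not inside — the top 10, so the
phenotype channel does measurable work and ablations (inductive mode, axiom
removal, zero overlap) move the metrics.  What the generator does **not**
emulate: linkage structure, realistic allele-frequency spectra, multi-gene
or non-Mendelian architectures, inter-patient variant sharing beyond the
common background, and real ontology scale — so passing tests demonstrate
correctness of the machinery and the direction of effects, not clinical
performance.

Benchmark runs in the tests and the acceptance script use a 2000-variant
background, 20 patients (one per disease), embedding dimension 32, ≤100
epochs, and walk settings k=20, n=20, c=5, 15 epochs — sizes chosen so the
whole study retrains in well under a minute per channel while every planted
effect remains detectable.

## Evaluation

Per patient the causative spike is the single positive among the post-filter
candidates.  Metrics: hits@{1,10,30,50} on causative ranks; ROC AUC in the
Mann–Whitney formulation (ties counted ½); AUPR as step-wise average
precision.  AUC/AUPR are macro-averaged across patients by default so
patients with large candidate sets do not dominate; micro-pooling is a flag.
Both metrics are checked against independent brute-force oracles (O(n²)
pairwise counting; threshold-sweep PR integration) to 1e−9.  Gene–disease
recovery reports the mean 1-based rank (ties halved) of the true disease
among all diseases for held-out genes, against the random expectation
(N+1)/2; "held out" means the validation+test associations — test alone is a
single pair at the default split, and validation pairs never touch model
parameters, only the stopping epoch.

## Numerical choices and degenerate inputs

* GP normalization: min–max within the candidate set (affine-invariant, makes
  a PHRED-scale score commensurate with a [0,1] similarity); all-equal CADD
  maps to 0.5, missing CADD to 0 (flagged).  A `phred` mode (raw/100,
  clipped) is available.
* Unscorable genes are skipped inside the MS maximum; a variant with no
  scorable gene gets MS = 0 and a flag.
* Gene assignment converts VCF 1-based positions to 0-based half-open
  intervals in exactly one place; intergenic variants go to all genes at the
  minimal distance (ties kept).
* Multi-allelic VCF records are decomposed per ALT; records without an
  annotation row become unannotated variants with a warning; duplicate
  annotation keys are an error.
* Empty phenotype profiles, empty graphs, and annotation classes missing from
  the ontology warn rather than fail (merged annotation sources overlap
  imperfectly); conflicting re-attachment of a patient ID is an error.
* NaN in a training or validation loss aborts with a diagnostic.

## Known limitations

* TransR and ConvE are interface slots only.
* The walks channel has no label-text (lexical) document channel; only the
  structural projection is implemented.
* EL support ignores disjointness and role chains; ⊥ is representable as a
  zero-radius ball but receives no special semantics.
* The inductive update is a brief fine-tune, not a true inductive encoder;
  as the transductive-vs-inductive benchmark shows, it trades accuracy for
  not retraining.
* At default desk scale the held-out association set is small (4 pairs), so
  per-family mean ranks are coarse; they are seed-pinned in the tests.
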