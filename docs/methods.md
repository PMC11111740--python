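# Methods

## Problem and model

Matching lytic phages to *Klebsiella* strains is bottlenecked by the
narrowness of phage host ranges: most phages recognize one or a few
capsule polysaccharide types (KL-types) through their receptor-binding
proteins (RBPs — tail fibers and spikes, frequently with depolymerase
activity). The package predicts, at the strain level, whether a phage and a
bacterium interact at the adsorption step, and turns the prediction scores
into an actionable ranking of phage candidates for a newly sequenced
isolate.

The model is a pairwise classifier over protein-set representations:

1. **Per-protein embedding.** Every phage RBP and every bacterial K-locus
   protein is mapped to a real vector of dimension *d*. Two embedders are
   provided: an adapter for the pre-trained ESM-2 protein language model
   (`t33_650M_UR50D`; final-layer per-residue states mean-pooled over
   positions, *d* = 1280), and a built-in deterministic stand-in
   (`KmerHashEmbedder`) that counts overlapping 3-mers, hashes them into
   *d* buckets (blake2b keyed by `hash_seed`) and L2-normalizes
   (default *d* = 64). The stand-in is not a language model and carries no
   evolutionary information; it is sequence-sensitive and reproducible
   without downloads, which is what the hermetic tests need.
2. **Multi-instance aggregation.** The vectors of a phage's RBPs (1–8 per
   phage) and of a bacterium's K-locus proteins (10–25 per locus) are each
   averaged column-wise into one vector per entity. Mean pooling is
   order-invariant and size-invariant but dilutes signal carried by a
   single protein in a large set — a known limitation discussed below.
3. **Pair features.** A (phage, bacterium) pair is the concatenation
   phage-block-first, giving a 2*d* vector (2560 with ESM-2 embeddings).
4. **Classifier.** An XGBoost binary classifier
   (`PhageHostClassifier`, scikit-learn estimator API). Defaults are
   max_depth 7, learning rate 0.3, 250 estimators; with `tune=True` the
   4×3×3 grid {3,5,7,9} × {0.2,0.3,0.4} × {250,500,750} is searched by
   stratified five-fold cross-validated ROC AUC. AUC is used as the tuning
   objective because it is also the headline evaluation metric. Ties are
   broken toward the cheaper model (fewer estimators, then shallower
   trees). Fold assignment happens after sorting rows by a content digest,
   so tuning is invariant to input row order. Class imbalance (~3.3%
   positives) is left unweighted by default; `scale_pos_weight` is exposed.

Labels come from spot tests: positive means a visible spot at a 1:10
phage dilution — an RBP–receptor interaction, not necessarily productive
replication. Only tested pairs enter training and evaluation; pairs absent
from the interaction table are untested, never imputed negatives.

## Evaluation protocol

The clinically relevant question is performance on a *new* strain, so the
evaluation controls leakage through capsule similarity:

* **Pairwise identity.** Global (Needleman–Wunsch) alignment of K-locus
  nucleotide sequences with match +1, mismatch −1, gap −2; identity =
  matches / alignment columns × 100. Among co-optimal alignments the one
  maximizing matches, then diagonal columns, is used, making the value
  canonical; the DP encodes the lexicographic objective
  (score, matches, diagonal steps) in a single int64 per cell so rows
  vectorize. Identity is 100 exactly iff the sequences are identical.
* **Grouping.** Single-linkage connected components of the graph with
  edges at identity ≥ threshold, thresholds 75–100%. At 100% only
  identical loci share a group; lowering the threshold merges whole
  K-locus families. Grouping at a higher threshold always refines the
  grouping at a lower one.
* **LOGOCV.** One fold per group: all tested pairs of the held-out group's
  bacteria are predicted by a model retrained on everything else. By
  default hyperparameters are not re-tuned per fold (`tune_per_fold`
  exposes the alternative).
* **Metrics.** Pooled ROC AUC over held-out pairs (ties ½, equivalent to
  Mann–Whitney U; pooled across folds rather than averaged per fold);
  mean hit ratio @ k — for each bacterium with ≥ 1 tested positive, the
  indicator that a true interaction appears among its k top-scored phages,
  averaged over such bacteria, for k = 1..panel size. Bacteria with no
  tested positive are excluded from the mean (consistent with reporting a
  15/16 wet-lab hit ratio over 28 isolates of which 16 had confirmed
  interactions). Score ties in rankings break lexicographically by
  phage id for reproducibility.
* **Baseline.** The "informed microbiologist": phages known to infect the
  isolate's KL-type first (narrowest host range first), otherwise broadest
  host range first.
* **Wet-lab accounting.** `confusion_summary` counts TP/FP/FN over top-k
  recommendations against laboratory outcomes; true negatives are "not
  considered" in a ranking setting. Recall 26/(26+7) = 78.8% and precision
  26/140 = 18.6% reproduce the published confusion-table arithmetic.

## Synthetic data generator

The generator emulates the statistical shape of the study so every stage
is testable hermetically: 105 phages with 1–8 RBPs, 200 bacteria with
10–25 K-locus proteins spread over KL-types, ~3.33% positive rate, and a
partially tested interaction matrix (half of all pairs by default).

Design choices, and why:

* **Planted compatibility rule.** Each KL-type gets a distinct 40-residue
  "binding domain" sequence. All K-locus proteins of a type carry it (the
  locus is the type's signature), and each RBP of a phage carries the
  domain of one KL-type in the phage's host range, cycling so every
  compatible type lands in at least one RBP. Narrow-host-range phages thus
  carry their domain in every RBP, as redundant fiber variants targeting
  the same capsule. A pair interacts iff the bacterium's type is in the
  phage's host range, XOR-ed with optional label noise. A motif-based
  (rather than random-label) signal means any sequence-sensitive embedder
  can carry the information, so end-to-end recovery is meaningful.
  The 40-residue length mirrors the scale of real receptor-binding
  modules; much shorter domains make the planted signal undetectable
  after mean pooling, and indeed signal recovery degrades the same way
  the real system degrades for KL-types with few confirmed interactions.
* **Positive rate by construction.** With 36 KL-types, 10% broad-host
  phages (host ranges of 2–4 types) and uniform type assignment, the
  expected positive rate is (0.9·1 + 0.1·3)/36 = 3.33%, the study's rate.
  The generator refuses configurations whose compatibility structure
  cannot approximate the requested `target_positive_rate` (>50% relative
  gap).
* **K-locus families.** Each KL-type has an ancestral locus sequence;
  every bacterium's locus is a point-mutated copy (3% divergence by
  default), so loci of one type sit near 97% pairwise identity and loci of
  different types near random-sequence identity. Grouping at 100% then
  yields one group per bacterium; ~90% merges families — exactly the
  regimes the evaluation sweeps. `mutate_klocus` applies substitutions
  only, so identity ≈ 100×(1−divergence).
* **Genomes.** Phage genomes are concatenated reverse-translated genes
  (ATG + codons + TAA with random spacers), enough for the built-in ORF
  caller to find the genes back; decoy "hypothetical" proteins exercise
  the RBP detector's negative path.

What the generator does **not** emulate: real sequence homology and
phylogenetic correlation between phages, protein-family structure,
horizontal transfer, partial or mosaic host ranges, defense systems, or
any biophysics of adsorption. Passing end-to-end tests therefore shows
the machinery recovers a planted sequence-level compatibility rule — not
that the stand-in embedder would reach the published accuracy on real
genomes (that requires the external language model and the deposited
dataset).

## Problem sizes used in tests and the acceptance script

Evaluation-heavy checks run on a desk-scale preset (`demo_config`):
30 phages, 48 bacteria, 9 KL-types (expected positive rate 1.2/9 ≈ 13.3%),
600-nt loci, RBPs of 200–300 residues, stand-in embedder with d = 64.
These sizes keep full LOGOCV with per-fold retraining (48 folds at the
100% threshold) in the tens of seconds on one CPU while preserving the
study's structure. On this preset, noiseless LOGOCV at threshold 100
reaches pooled AUC ≈ 0.96–0.98 with mean hit ratio @ 10 ≈ 1.0, and
dropping the threshold to 90% (holding out whole K-locus families, i.e.
predicting for capsule types never seen in training) collapses the AUC —
the same direction of degradation the published system shows between the
100% and 90% thresholds, in exaggerated form because the synthetic signal
is purely KL-type-specific.

The model-recovery check (held-out AUC ≥ 0.95 on a random split) uses a
denser instance (6 KL-types, 60 bacteria, ≈15 positives per type): a
type's pattern is only learnable once it has enough positive examples,
which matches the published observation that prediction quality per
KL-type tracks its number of confirmed interactions.

## Numerical and degenerate-input conventions

* Identity thresholds live in [75, 100]; matrices must be symmetric with
  diagonal 100.
* `hit_ratio_at_k` requires 1 ≤ k ≤ panel size; curves are non-decreasing
  with terminal value 1.0 whenever every counted bacterium has a positive.
* ROC AUC and LOGOCV training require both classes present; single-class
  inputs raise rather than return a degenerate value.
* RBP length filtering keeps the closed interval [200, 1500] (candidates
  "shorter than 200" or "longer than 1500" are discarded; the boundary
  values stay).
* Phages left with zero RBPs after detection and filtering are dropped
  from training with a logged warning, never silently kept.
* Gene calls use 0-based half-open coordinates on the forward strand,
  explicit strand, translation table 11, ATG starts, and require a stop
  codon inside the sequence.
* All randomness flows from a single integer seed (fold assignment,
  booster training, data generation); reruns with the same configuration
  are byte-identical, which the pipeline manifest verifies by hashing.

## Known limitations

* Mean pooling dilutes per-protein signal; attention-style aggregation is
  deliberately out of scope.
* The stand-in embedder ignores residue order beyond k-mers and carries no
  transfer learning; it exists so the pipeline is testable and usable
  offline, not as a substitute of equal quality for the language model.
* The informed-microbiologist baseline needs host-range annotations
  (known KL-types per phage), which only the generator's ground truth or
  external curation can provide.
* Identity computation is exact global alignment; for very long loci
  (tens of kb) the O(nm) DP becomes the dominant cost, and the pipeline
  deduplicates identical sequences but does not approximate alignments.
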