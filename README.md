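# phagematch

Strain-level prediction of *Klebsiella* phage–host interactions from phage
receptor-binding proteins (RBPs) and bacterial capsule (K-locus) proteins.

Finding phages that infect a given clinical isolate is slow because most
*Klebsiella* phages recognize only one or a few capsule types. `phagematch`
ranks a phage panel against a newly sequenced isolate: proteins are
embedded (ESM-2 adapter, or a built-in deterministic k-mer stand-in),
averaged into one multi-instance vector per phage and per bacterium,
concatenated into pair features x = [u_phage ; v_host] ∈ R^{2d}, and scored
with an XGBoost classifier P(interaction | x). Evaluation follows the
"new bacterium" setting: bacteria are grouped by K-locus nucleotide
identity (75–100% thresholds, single linkage) and leave-one-group-out
cross-validation reports pooled ROC AUC and the mean hit ratio @ k — the
probability that at least one true interaction appears among an isolate's
k top-ranked phages.

## Worked example

Run the whole pipeline — simulate a synthetic dataset, detect and filter
RBPs, embed, train, evaluate, rank — on the desk-scale preset:

```
phl --outdir run --preset demo --seed 1 --thresholds 90,100 pipeline
```

which prints the evaluation summaries:

```json
{
  "t100": {
    "auc": 0.9706,
    "hit_ratio": {"1": 0.9556, "5": 1.0, "10": 1.0},
    "n_groups": 48,
    "threshold": 100.0
  },
  "t90": {
    "auc": 0.2573,
    "hit_ratio": {"1": 0.3333, "5": 0.4889, "10": 0.6},
    "n_groups": 9,
    "threshold": 90.0
  }
}
```

Reading this: at the 100% identity threshold (only identical K-loci are
grouped, so training always contains close relatives of the held-out
strain) the classifier recovers the planted receptor-compatibility rule
almost perfectly — AUC 0.97, and every isolate with a true match has one
in its top five. At the 90% threshold whole K-locus families are held
out, the model has never seen the capsule type it must predict for, and
performance collapses — the synthetic, purely capsule-specific analogue
of the degradation the real system shows for dissimilar strains. The run
directory contains per-fold scores, hit-ratio curves, the top-5
recommendation report (`ranking/top5_report.csv`) and a hash manifest
(reruns with the same config are byte-identical).

The library mirrors the CLI, in scikit-learn style:

```python
from phagematch import (KmerHashEmbedder, PhageHostClassifier,
                        demo_config, generate_dataset)
from phagematch.features import represent_entities, build_pair_matrix

phages, bacteria, table, truth = generate_dataset(demo_config(seed=1))
emb = KmerHashEmbedder(dim=64)
phage_reps = represent_entities(((p.phage_id, "phage", p.rbps) for p in phages), emb)
bact_reps = represent_entities(
    ((b.bacterium_id, "bacterium", b.klocus_proteins) for b in bacteria), emb)
X = build_pair_matrix(table.frame, phage_reps, bact_reps)
clf = PhageHostClassifier(random_state=1).fit(X, table.frame["label"])
scores = clf.predict_scores(X)          # one interaction score per tested pair
```

See `docs/methods.md` for the model, the evaluation protocol, what the
synthetic generator does and does not emulate, and the problem sizes used.

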