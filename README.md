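# abte — hybrid drug–drug interaction prediction

`abte` predicts drug–drug interactions (DDIs) by combining two
complementary signals:

* **known interactions** — adjacency matrix factorization with latent-factor
  propagation (AMFP) over the symmetric binary interaction matrix *R*, with
  one latent vector per drug shared between rows and columns;
* **biomedical text** — a feed-forward classifier over pre-trained drug
  concept/word embeddings *L_i* (word2vec text format), scoring a pair from
  the concatenation `[L_i, L_j]` or the element-wise product `L_i ⊙ L_j`.

Matrix factorization fails for *cold-start* drugs — drugs with few or no
known interactions at training time, typically newly approved ones. The
hybrid therefore routes each pair by a switching rule on the training
interaction counts *I*:

```
r̂_ij = r̂_ij^Stacking   if I_i ≥ M and I_j ≥ M
       r̂_ij^Text        otherwise
```

where the stacking model is a small neural network over the two component
probabilities and the threshold *M* is tuned on a validation split. The
package implements the full retrospective evaluation protocol (temporal
train/test releases, per-epoch negative sampling, AUROC / AUPR /
precision@K / recall@K with rare-drug stratification) and a synthetic-study
generator, so every stage runs and is testable without external downloads.

It is aimed at computational drug-safety researchers who have an
interaction edge list (e.g. derived from a DrugBank release) and a
pre-trained biomedical embedding table, and want ranked candidate
interactions with honest cold-start behaviour.

## Worked example

Generate a synthetic study (300 drugs in 6 interaction communities,
embeddings correlated with community structure, half the interactions held
out as a "future release", 15% of drugs forced cold), train the hybrid, and
evaluate on the held-out pairs:

```python
import abte

study = abte.generate(abte.SynthConfig(seed=1))
ds = study.dataset
dvm = abte.resolve_drugs(ds.catalog, study.embeddings)
model, info = abte.train_abte(ds, dvm, seed=1)

batch = abte.temporal_split(
    abte.InteractionDataset(ds.catalog, ds.R_train),
    abte.InteractionDataset(ds.catalog, ds.R_test))
text, amfp = model.component_scores(dvm, batch.pairs)
stacked = model.stacker.predict(text, amfp)
print("M =", model.M)
print("text  AUROC %.3f  AUPR %.3f" % (abte.auroc(text, batch.labels),
                                       abte.aupr(text, batch.labels)))
print("amfp  AUROC %.3f  AUPR %.3f" % (abte.auroc(amfp, batch.labels),
                                       abte.aupr(amfp, batch.labels)))
print("stack AUROC %.3f  AUPR %.3f" % (abte.auroc(stacked, batch.labels),
                                       abte.aupr(stacked, batch.labels)))
```

Output:

```
M = 2
text  AUROC 0.643  AUPR 0.057
amfp  AUROC 0.654  AUPR 0.069
stack AUROC 0.666  AUPR 0.071
```

The tuned threshold M = 2 means pairs where either drug has fewer than two
training interactions are scored by the text classifier alone; all other
pairs go to the stacking combiner, which here beats both single components
on the held-out release (AUPR 0.071 against 0.069 and 0.057; the positive
rate is 0.023, so all three rank far above chance). On the rare stratum
(either drug with fewer than three training interactions) the text
component's AUROC exceeds AMFP's by several points — the cold-start gap the
switching rule exploits.

The same pipeline runs from the shell:

```bash
abte simulate --config synth.yaml --out data/
abte train --train data/train_edges.tsv --embeddings data/embeddings.txt \
     --config cfg.yaml --out model/
abte evaluate --model model/ --train data/train_edges.tsv \
     --test data/test_edges.tsv --report report.json
abte predict --model model/ --pairs pairs.tsv --out scores.tsv
```

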