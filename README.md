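# hsqcnet

Structure dereplication from 2D HSQC NMR spectra.

Natural-product chemists routinely need to know whether an isolated
compound is already known before investing in full structure elucidation.
A ¹H–¹³C HSQC spectrum is quick to record and highly structure-specific:
one cross-peak per protonated carbon at (δ_H, δ_C), with the peak sign in
multiplicity-edited spectra encoding CH/CH₃ (positive) vs CH₂ (negative).
`hsqcnet` turns that spectrum into a database query:

* a **multi-task convolutional network** maps the peak list — rendered as
  a 128×128 image — to a 6144-bit Morgan fingerprint (radius 0–2,
  hydrogen-explicit, hash-folded; sigmoid/binary cross-entropy), a
  compound-class distribution (softmax/categorical cross-entropy), a
  molecular-weight estimate in daltons (softplus head, mean absolute
  percentage error) and a glycoside probability;
* a **retrieval layer** ranks candidate structures from a reference
  library by cosine similarity between the predicted fingerprint
  probabilities and each candidate's binary fingerprint, with optional
  molecular-weight and class pre-filters;
* **evaluation metrics** score retrieval the way the field reports it:
  identification rate@k (fingerprint cosine 1.0 to truth), annotation
  rate@k (cosine ≥ 0.8), and precision/recall/F1@k;
* a **chemical-shift baseline matcher** (0.5 ppm ¹³C / 0.05 ppm ¹H
  tolerances, optimal one-to-one peak pairing) provides the classic
  lookup-style comparison point;
* **occlusion sensitivity** removes each peak in turn and maps the
  resulting fingerprint-probability changes onto the atoms of a candidate
  structure, showing which substructures each HSQC signal supports;
* a **synthetic HSQC simulator** generates (structure, peak list) pairs
  with the statistical shape of real corpora — deterministic
  environment-to-shift mapping plus sub-pixel Gaussian noise — so the
  entire pipeline is trainable and testable offline.

The network estimator follows scikit-learn conventions
(`fit`/`predict`, `get_params`, fitted attributes with trailing
underscores) and composes with sklearn tooling.

## Worked example

```python
import numpy as np
import hsqcnet as hq

# 1. simulate a small reference corpus (12 molecules, seeded)
cfg = hq.SimulatorConfig(n_molecules=12, seed=3)
examples, splits = hq.make_dataset(cfg)
db = hq.ReferenceDB([e.record for e in examples], hq.SYNTHETIC_VOCABULARY)

# 2. train a small network on the simulated spectra
model = hq.HSQCNet(channels=1, conv_stack=((8, 3, 2), (16, 3, 2)),
                   embedding_dim=16, n_classes=4,
                   learning_rate=1e-3, epochs=8, batch_size=4, seed=0)
X = np.stack([hq.rasterize(e.peaklist).grid for e in examples])
model.fit(X, [e.record for e in examples])
print(model.history_[["epoch", "train_loss", "val_mape"]].tail(3).round(3))

# 3. search a query spectrum against the database
query = examples[0]
pred = model.predict_one(hq.rasterize(query.peaklist))
print(f"predicted MW: {pred.mw:.1f} Da (true {query.record.mw} Da)")
for h in hq.search(pred, db, k=3):
    print(f"rank {h.rank}: {h.record_id}  cosine={h.cosine:.3f}  |dMW|={h.mw_delta:.1f}")

# 4. the chemical-shift baseline for comparison
refs = [(e.record.id, e.peaklist) for e in examples]
for h in hq.baseline_shift_match(query.peaklist, refs, k=3):
    print(f"baseline rank {h.rank}: {h.record_id}  score={h.score:.3f}")
```

Output:

```
   epoch  train_loss  val_mape
5      5      50.572    58.066
6      6      42.691    57.950
7      7      45.687    57.801
predicted MW: 251.4 Da (true 330.33 Da)
rank 1: syn00000  cosine=0.225  |dMW|=79.0
rank 2: syn00003  cosine=0.222  |dMW|=89.0
rank 3: syn00007  cosine=0.211  |dMW|=84.0
baseline rank 1: syn00000  score=1.000
baseline rank 2: syn00003  score=0.261
baseline rank 3: syn00007  score=0.240
```

Twelve molecules and eight epochs are only enough for the network to
start organising the fingerprint space — the query's own record already
tops the ranking (`syn00000`, and the baseline matcher scores it 1.0
because the query *is* its library spectrum), but the cosine scores are
still low and the MW head is still converging from its mean-MW
initialization.  `hsqcnet.benchmark.learning_sanity_experiment` runs the
properly sized version of this experiment (300 molecules, 50 epochs); at
that scale the held-out fingerprint cosine clears a permuted-label
control by ~0.19 and top-1 identification is ~50× the random-ranking
expectation.

A command-line interface wraps the same steps:

```sh
hsqcnet simulate --n 300 --seed 1 --out data/
hsqcnet train --data data/ --config train.json --out model.npz
hsqcnet build-db --smiles data/structures.tsv --classes classes.txt --out db.npz
hsqcnet search --model model.npz --peaks query.tsv --db db.npz -k 10
hsqcnet evaluate --model model.npz --db db.npz --cases data/ --k 1,5,10
hsqcnet occlude --model model.npz --peaks query.tsv --structure "Oc1ccc..." --out occ
```

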