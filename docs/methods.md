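# Methods

## Problem and approach

Dereplication — recognising that an isolated natural product is already
known, or close to a known compound — normally requires full structure
elucidation.  A 2D ¹H–¹³C HSQC spectrum is fast to acquire and already a
compact structural signature: one cross-peak per protonated carbon at
(δ_H, δ_C), with peak sign in the multiplicity-edited variant encoding the
attached-proton count (CH/CH₃ positive, CH₂ negative).  This package maps
an HSQC peak list directly to chemical properties with a multi-task
convolutional network and ranks candidate structures from a reference
library by fingerprint similarity.

The pipeline is:

1. **Rasterization.** A peak list is rendered onto a fixed 128×128 grid
   spanning δ_H ∈ [0, 12.8] ppm × δ_C ∈ [0, 230] ppm (wide enough for
   aldehyde signals near δ_C/δ_H 207/9.7), one channel for normal HSQC,
   two (positive/negative phase) for edited HSQC.  High ppm sits at
   row/column 0, matching conventional spectrum display.  Peaks are
   single-pixel impulses combined by max; an optional Gaussian blur is
   available.  A fixed global frame, rather than per-spectrum bounds,
   keeps images comparable across spectra — a requirement for a single
   network.  The frame is configurable but must be identical at train and
   query time.
2. **Prediction.**  A conv/batch-norm/ReLU trunk with stride-2
   downsampling, global max pooling and dropout feeds four fully connected
   heads: a 6144-bit Morgan-fingerprint head (sigmoid, binary
   cross-entropy), a compound-class head (softmax, sparse categorical
   cross-entropy), a molecular-weight head (softplus-positive scalar in
   daltons, mean absolute percentage error) and a glycoside head (sigmoid,
   binary cross-entropy).  Normal and edited inputs get separate networks
   of identical layout (no weight sharing).
3. **Retrieval.**  The predicted fingerprint probability vector is scored
   against the binary fingerprints of a reference library by cosine
   similarity.  Cosine is the sole ranking key; molecular-weight windows
   and class filters are optional pre-filters (off by default).  Ties
   break by |ΔMW| then id, making rankings total and reproducible.
   Probabilities are scored raw by default — binarizing at 0.5 discards
   ranking information — with a binarize option.

## Chemical targets

* **Fingerprint** — circular Morgan environments of radius 0–2 enumerated
  on the hydrogen-explicit molecular graph and hash-folded into 6144
  presence bits (RDKit Morgan generator).  Folding is used rather than a
  corpus-derived vocabulary of 6144 environments because it requires no
  corpus, is deterministic, and preserves the vector width; a
  corpus-vocabulary variant could be layered on top without changing any
  interface.  Presence bits (not counts) match the sigmoid/BCE head.
* **Molecular weight** — average-isotopic weight, rounded half-up to two
  decimals on the decimal representation (so 18.015 → 18.02).  Ceiling
  rounding was rejected: it would bias every weight upward.
* **Glycoside flag** — a substructure definition: a saturated ring carbon
  of a pyranose or furanose ring bonded to the ring oxygen and to an
  exocyclic oxygen (the anomeric acetal/hemiacetal motif).  Free reducing
  sugars therefore count.  The flag can be overridden by a label column
  when curated labels exist.
* **Class label** — supplied as data against a configurable vocabulary
  (e.g. natural-product superclasses); the package does not re-derive
  ontology assignments from structure.  Glycoside status is a separate
  fourth head rather than an extra class because it is orthogonal to the
  structural class.

## Network and training

Default architecture: four 3×3 conv stages of 32/64/128/256 filters,
stride 2, each with batch normalization and ReLU; global max pooling; a
dense embedding (default 256) with ReLU and dropout 0.2; four linear
heads.  The stack is fully configurable as `(filters, kernel, stride)`
stages.  The total loss is the weighted sum of the four head losses, all
weights defaulting to 1.

Optimization is Adam with the corpus-scale defaults lr 1e-5, inverse-time
decay 1e-6 (`lr_t = lr/(1+decay·t)`), batch size 16.  At desk scale
(hundreds of molecules, tens of epochs) 1e-5 cannot move the loss
measurably; the synthetic-data experiments therefore use lr 1e-3, set
explicitly in their configs.

Two numerical choices matter for sparse multi-task targets:

* **Head-bias initialization from training marginals.**  Each sigmoid head
  bias starts at the logit of the training-split bit frequency (clipped to
  [1/2n, 1−1/2n]), the class head at the log class prior, and the softplus
  MW head at softplus⁻¹(mean training MW).  This is the standard prior
  initialization for sparse detection targets: without it every bit starts
  at p = 0.5 and the optimizer spends its entire budget dragging thousands
  of biases toward the ≈ −5 logits of rarely-set bits (Adam moves each
  parameter by at most ≈ lr per step) instead of learning per-example
  signal.
* **Seeded determinism.**  Weight init, the validation split, minibatch
  shuffling and dropout masks all derive from the training seed; two runs
  with the same seed produce bit-identical histories.  Inference runs with
  dropout off and batch-norm in running-statistics mode, so predictions
  are deterministic.

The network core (im2col convolution, batch norm, global max pool,
dropout, dense, Adam) is a compact NumPy implementation inside the
package; its backward passes are pinned by finite-difference tests.

## Baseline shift matcher

The classic dereplication baseline matches query shifts against library
shifts within fixed tolerances: 0.5 ppm for ¹³C and 0.05 ppm for ¹H,
inclusive (with a 1e-9 ppm guard so exact-boundary differences are not
lost to binary-float representation).  Peaks pair one-to-one; the matcher
computes a **maximum-cardinality** pairing (minimum total normalized
distance |Δδ_C|/0.5 + |Δδ_H|/0.05 among maximum pairings, via the
Hungarian assignment with a penalty for ineligible pairs).  A greedy
nearest-first pairing was considered and rejected: it is not optimal (two
queries competing for overlapping references can strand a matchable peak)
and optimality also makes the score symmetric and deterministic.  The
score is Dice-style, 2·matched/(n_query + n_ref), 1.0 for identical lists.

## Evaluation metrics

A retrieved candidate is *identified* when its binary fingerprint has
cosine 1.0 with the query's true fingerprint and *annotated* ("similar")
at cosine ≥ 0.8.  Both thresholds are inclusive; identity is tested as
≥ 1−1e-9 and similarity as ≥ 0.8−1e-9 to absorb floating error.  Note that
distinct molecules can fold to identical fingerprints; such collisions
count as identified, which is the fingerprint-level definition of the
task.  Identification/annotation rate at k is the fraction of queries with
a qualifying hit in the top k; precision@k counts annotated hits over k;
recall@k divides by the number of similar structures in the whole
database, found by exhaustively scoring the truth fingerprint against
every record (1.0 by convention when no similar structure exists; a flag
excludes the query's own identical record).  Precision/recall/F1 are
macro-averaged over queries.

## Occlusion sensitivity

Each peak is removed from the peak list in turn, the reduced spectrum
re-rasterized and re-predicted; the row of per-bit probability changes
(occluded − full) forms the occlusion map.  Whole peaks are occluded
before rasterization — not single pixels — because the peak is the
physical unit of the spectrum.  Bits map back to atoms through the
environments that set them (center plus atoms within the radius;
hydrogens fold onto their heavy atom); each bit's |Δ| is shared equally
among its atoms, so total attribution per peak equals the total |Δ| over
atom-mapped bits (conservation).  Sign-preserving aggregation is available
by flag.  Class and MW changes are reported alongside but not attributed
to atoms.

## Synthetic data

The simulator exists so that every stage is testable without any spectral
corpus or commercial prediction software.  It emulates the statistical
structure of real HSQC data, not its chemistry:

* structures come from a fragment grammar (benzene/naphthalene cores,
  terpenoid-like rings and chains, N-heterocycles, acyl chains, an
  optional O-linked pyranose) spanning four synthetic classes with a
  glycoside fraction of 0.25;
* each protonated carbon emits one peak whose noise-free position is a
  deterministic hash (splitmix64) of the carbon's radius-2 Morgan
  environment identifier into the textbook shift window of its category
  (aromatic CH: δ_H 6.0–8.6/δ_C 100–150; anomeric O–CH–O: 4.0–5.6/88–112;
  O–CH: 3.1–4.6/55–90; aldehyde: 9.2–10.1/185–208; olefinic, N–CH,
  carbonyl-adjacent, and aliphatic CH/CH₂/CH₃ windows similarly);
  identical substructures therefore always produce identical peaks — the
  regularity a spectrum-reading network must exploit;
* Gaussian ppm noise, default sd 0.02 (¹H) / 0.4 (¹³C) — under half a
  pixel of the raster — emulates solvent and referencing scatter;
* phase is negative iff the carbon bears exactly two hydrogens; quaternary
  carbons are silent.

Because shifts are keyed on the same environment identifiers the
fingerprint folds, the fingerprint-from-spectrum task is
information-theoretically solvable on these data.  What the synthetic data
does **not** model: real shift physics (ring currents, anisotropy,
electronegativity trends beyond the category windows), solvent-dependent
shift changes, peak overlap statistics of large molecules, intensity
variation, or artifacts.  Passing synthetic tests therefore demonstrates
that the pipeline is implemented correctly and can learn a
structure-determined spectrum mapping — not that the network reaches
corpus-scale accuracy on real spectra, which would require the real
training corpus.

## Sanity experiment (the package's own benchmark)

`hsqcnet.benchmark.learning_sanity_experiment` trains a small stack
(16/32/64 filters, embedding 64) on 300 noise-free synthetic molecules for
50 epochs at lr 1e-3 with a 20% held-out split, trains an identical
network on permuted fingerprint labels as a control, and searches every
training spectrum against the 300-record database.  Reported quantities:
held-out mean fingerprint cosine vs the control (the learning signal),
first/final validation MAPE, and top-1 identification vs the expectation
of a random ranking.  Problem sizes were chosen so the whole experiment
runs in about two minutes on one CPU core.  `scripts/acceptance.py` is a
thin wrapper that runs exactly this experiment at a given seed and writes
the numbers as JSON.

## Known limitations

* The hash-fold fingerprint admits bit collisions; identification is
  defined at the fingerprint level, so colliding molecules are
  indistinguishable by design.
* The simulator's category windows are coarse; simulated shifts are
  plausible but not chemically accurate, and models trained on them do not
  transfer to real spectra.
* The NumPy network core is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not corpus-scale training.
* Intensity information is carried through rasterization but the bundled
  simulator emits unit intensities, so intensity-weighted training is
  untested beyond unit contracts.
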