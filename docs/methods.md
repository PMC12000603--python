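# Methods

## Problem

Transition-metal-catalyzed asymmetric hydrogenation of olefins (AHO) is a
workhorse route to enantiopure compounds. Published AHO data is plentiful
but heterogeneous: thousands of literature reactions spanning many
substrate/ligand families, three metals (Ir, Rh, Co, with Rh and Ir
dominating and Co rare), and diverse conditions. A practitioner starting a
new reaction family has only a handful of labelled examples. `rxnproto`
treats this as a few-shot classification problem: predict whether a
reaction's enantiomeric excess exceeds a threshold (80 %ee by default;
70/90 supported), given only a small labelled support set, by meta-learning
a shared embedding over many related tasks.

## Reaction representation

Each reaction is a fixed 1544-dimensional composite vector:

| slots | content |
|---|---|
| [0, 512) | olefin Morgan fingerprint, 512 bits, radius 2 |
| [512, 1024) | ligand fingerprint |
| [1024, 1536) | solvent fingerprint |
| [1536, 1539) | metal one-hot (Ir, Rh, Co) |
| [1539, 1541) | additive one-hot (absent, present) |
| [1541, 1544) | standardized pressure, temperature, log10 S/C |

The one-hot widths (3 + 2) and the condition scaling are declared package
conventions: 512·3 + 3 + 2 + 3 is the only small-integer layout consistent
with the composite's total width. Conditions are z-scored with statistics
fitted on the training split only; the substrate-to-catalyst ratio is
log10-transformed first because catalyst loading spans orders of magnitude
and raw values would otherwise dominate Euclidean prototype distances.
Fingerprints are binary presence vectors (not counts).

The alternative learned representation replaces the three fingerprints
with MPNN embeddings: atom/bond-featurized molecular graphs, an edge
network mapping bond features to 64×64 message transforms, a GRU node
update over exactly 3 message-passing steps (64-dimensional node states),
and a set2set readout with 3 processing steps. Set2set natively emits
2×64 = 128 dimensions; a learned linear projection maps it to the declared
512-dimensional component embedding. One encoder is shared across the
olefin, ligand and solvent roles (fewer parameters; a per-role encoder
would triple them with no benefit at desk scale). Graphs are 2D
topological; chirality and conformers are out of scope. Encoders are
trained end-to-end with the downstream objective, not pre-trained.

All neural components run on a small NumPy reverse-mode autodiff engine
written for this package (`rxnproto.nn`): float64, single-threaded, and
bit-reproducible from a single integer seed. Batches of molecules are
encoded in one pass — message passing on the disjoint union of graphs,
masked-softmax set2set attention on a padded node tensor — so the
operation count is independent of batch size.

## Tasks and episodes

The labelled dataset is split train/test/validation (default fractions
0.7/0.2/0.1; the source protocol's absolute sizes are 9032/2400/500 on the
full literature dataset). Tasks are built three ways:

- **random**: near-equal random partition of a split;
- **cluster**: UMAP (10 output dimensions, n_neighbors 15, min_dist 0.1,
  Euclidean) on the 1544-dim fingerprint encodings of the *full* dataset,
  then k-means (k-means++, 10 restarts); each cluster's train-side and
  test-side members form matched train/test tasks. Clustering the full
  dataset is transductive by design — labels are never used;
- **leave-one-cluster-out**: each cluster in turn is the held-out test
  task, the rest are training tasks.

An episode is a disjoint (support, query) sample from one task, without
replacement. Support sampling is stratified so both classes are present
(episodic training and testing require it); query sampling is unstratified
so evaluation sees the natural class imbalance that AUPRC is sensitive to.

## Prototypical network

An embedding network f_θ (default 1544 → 512 → 256 feed-forward, ReLU,
dropout 0.1) maps reaction vectors into a metric space. For an episode,
each class prototype c_k is the arithmetic mean of that class's support
embeddings; a query x is classified by

  p(y = k | x) = softmax_k( −d(f_θ(x), c_k) )

with d the squared Euclidean distance (the canonical Bregman choice;
plain Euclidean is available as a config switch — rankings and argmax are
identical, only confidences differ). Training minimizes the mean query
negative log-likelihood over batches of 5 tasks, with 512/64 support/query
episodes per training task (tasks smaller than 576 use the largest
feasible sizes at the same 8:1 ratio), Adam at lr 1e-3, validation AUPRC
checks on 64/128 validation episodes, and early stopping.

Three meta-test support protocols are provided: **episodic** (support and
query are disjoint random splits of the test task), **full-train support**
(the entire training split is the support; test records are never in it),
and **cluster support** (support drawn from the training-side task of the
same cluster — the protocol that needs no labels from the test task at
prediction time). Per repeat, query predictions are pooled over all test
tasks before computing AUPRC/AUROC (a per-task switch exists); means and
standard errors are taken over 10 repeated splits by default.

## Baselines and metrics

Single-task comparators are trained from scratch on whatever support the
protocol supplies: random forest (500 trees, balanced class weights), SVM
(RBF, probability scores), gradient boosting (200 rounds, depth 3), and a
GNN (the graph encoder plus a 2-layer softmax head, cross-entropy,
full-batch Adam). For a fixed evaluation seed, every method sees
byte-identical support and query manifests, so comparisons isolate the
method, not the split.

AUPRC is average precision (step-function integral, no interpolation) —
the convention under which a constant or random scorer's AUPRC equals the
positive prevalence. AUROC is the pairwise ranking probability with
half-credit for ties. Standard errors are sample SD / √n over repeats.

## Synthetic data generator

The generator emulates the *statistics* of literature AHO data, not its
chemistry: three metals at frequencies 0.42/0.535/0.045 (Ir/Rh/Co), a
target 65/35 class split at the 80 %ee threshold, and latent clusters that
tie components and conditions to selectivity. Each cluster owns disjoint
pools of curated, parseable SMILES (simple olefins, phosphine-type
ligands, common solvents) and Gaussian condition distributions. The label
model is logistic: per-cluster base effects (scale 2.0), per-(cluster,
olefin) effects (scale 1.0), and small condition terms (scale 0.4), with a
temperature parameter controlling label noise; the intercept is calibrated
by bisection to hit the target positive fraction. %ee is drawn from
Beta-shaped distributions concentrated above/below 80 so that
binarization recovers the intended label exactly and the 70/90 thresholds
remain meaningful.

Fixtures: `tiny` (30 records), `separable` (600 records, labels perfectly
aligned with 4 alternating clusters), `shuffled-null` (the separable set
with (label, %ee) pairs permuted), `heldout-chemistry` (pools disjoint
from every other fixture, emulating an out-of-sample test set).

What passing tests on this generator do **not** show: real literature data
has label noise from curation, long-tailed ligand families, duplicated
near-identical entries, and within-family structure-selectivity cliffs
none of which the generator models. Synthetic results validate the
machinery and the qualitative method ordering, not chemical accuracy.

## Benchmark problem sizes and observed behaviour

The bundled benchmark (`experiments.run_comparison_benchmark`) uses 2000
records with 5 latent clusters, 5 random training tasks, 2 random test
tasks, 400 training episodes (validation check every 25, patience 6), and
10 repeated support/query splits — sizes chosen so the full workflow runs
comfortably on one CPU. The GNN baseline in the benchmark uses 32-dim
nodes (same topology, smaller width) and 40 full-batch epochs.

Two findings from this benchmark are worth stating plainly:

- The meta-trained prototypical network beats RF and GNN trained from
  scratch on the same 16/32/64-example supports by a wide margin, and a
  16-example support already recovers most of its performance — the core
  few-shot claim reproduces qualitatively.
- Cluster-matched support (no test-task labels) performs on par with a
  random support split of the test task itself, with the direction of the
  small difference varying by seed. On this generator the cross-cluster
  label signal is stronger than the within-cluster signal, so a
  globally-trained embedding leaves little room for local adaptation to
  help; the practical content — prediction without new experiments at
  test time — is preserved.

## Null control caveat

The label-shuffled control permutes (label, %ee) pairs of the study
dataset. A *single* permutation retains a realized cluster-label
association (hypergeometric fluctuation of per-cluster class rates), and
any classifier refit on supports from the same permuted population
exploits it: at n = 2000 this lifts RF/GNN AUPRC ~0.02–0.04 above
prevalence — right at the edge of a 3-standard-error band over repeats,
while the prototypical network stays well inside it. This is a property
of permutation nulls at finite n, not information leakage; support and
query sets are verifiably disjoint.

## Numerical choices and edge cases

- Boundary %ee exactly at the threshold goes to the low class (label = 1
  iff ee > threshold, strictly).
- Zero-variance condition features get scale 1 (logged), keeping the
  scaler invertible.
- Single-atom molecules (no bonds) pass through message passing with
  zero messages; the GRU and set2set still run.
- k-means producing an empty cluster triggers a re-run with a new
  initialization (logged, bounded retries).
- Episode sampling retries a bounded number of times to get both classes
  into the support and fails loudly on single-class tasks, naming the task.
- Missing pressure/temperature/S-C values are imputed with training-split
  medians (logged); the literature source tables are sparse.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; repeated runs are bitwise identical.

## Known limitations

- No chirality-aware features, 3D conformers, or descriptor (DFT/steric)
  featurization.
- No MAML/relation networks, no %ee regression, no uncertainty
  calibration.
- The transductive clustering step sees test-set *features*; this mirrors
  the protocol it implements and is documented, not hidden.
- Desk-scale benchmark sizes are far below the ~12k-reaction literature
  dataset; absolute AUPRC values here are not comparable to results on
  real data.
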