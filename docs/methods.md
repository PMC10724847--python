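# Methods

## The prediction problem

Given a molecule as a SMILES string and a binary endpoint (for instance an
androgen-receptor, estrogen-receptor or endocrine-disruption association),
estimate P(active | structure).  Labels may be missing per endpoint; missing
labels are masked out of the loss and every metric, never imputed.
Stereochemistry is deliberately not encoded: both molecular encodings below
operate on the heavy-atom constitution graph, so enantiomers are
indistinguishable by construction.

## Molecular representations

**Heavy-atom graph.**  SMILES are parsed and canonicalized with RDKit;
hydrogens are kept as implicit counts, atom indices are 0-based, and
dot-disconnected inputs (salts, mixtures) are reduced to their largest
fragment by heavy-atom count (ties broken by molecular weight).  The
canonical SMILES is the identity key: two inputs denoting the same molecule
produce identical fingerprints, graphs and predictions.

**Directed-edge featurization.**  Every bond contributes two directed
edges, linked by a `reverse_index` involution.  Atom features are
fixed-vocabulary one-hot blocks — element {B, C, N, O, F, Si, P, S, Cl, Br,
I}, degree 0–5, formal charge −2…+2, each with a trailing "unknown" slot —
plus an aromaticity flag and the hydrogen count scaled by 1/4.  Bond
features are a bond-order one-hot {single, double, triple, aromatic} plus
in-ring and conjugation flags, identical for the two directed twins
(direction lives in the incidence structure, not the feature vector).  The
vocabulary is serialized with every trained model so prediction-time
featurization is bit-identical to training.

**Topological fingerprint.**  The RDKit path-based (Daylight-style) hashed
fingerprint, 2048 bits by default (configurable; the fingerprint length and
path parameters are conventions, not fitted quantities).

## The directed-edge message-passing encoder

Edge states are initialized from the source-atom and bond features,
h⁰_vw = ReLU(W_i·[x_v‖e_vw]), and updated for T steps (default T = 3,
hidden width 300) by summing the states of edges entering the source atom
while always excluding the reverse twin:

    m_vw = Σ_{k ∈ N(v) \ {w}} h^t_kv,   h^{t+1}_vw = ReLU(h⁰_vw + W_m · m_vw).

Excluding the reverse edge is the defining property: on a two-atom molecule
the incoming set is empty and the states are exactly h⁰ after any number of
steps, which the tests assert bit-exactly.  W_i and W_m carry no bias term,
matching the update equations above; the readout dense layer and the
classifier head do use biases.  The readout sums incoming edge states per
atom, applies ReLU(W_o·[x_v‖m_v] + b_o), and aggregates over atoms by
summation (the default; summation makes the embedding of two disconnected
copies exactly twice the single-copy embedding, a property used as a test
oracle; mean aggregation is available).  A feed-forward head (one hidden
layer of 300 by default, optional inverted dropout, logistic output) maps
the embedding to a probability.

The encoder, autoencoder and heads are trained by a small reverse-mode
automatic-differentiation engine written on NumPy arrays (dense affine
maps, ReLU/logistic, row gather/scatter segment sums, stable
softplus-based binary cross-entropy).  Analytic gradients are verified
against central-difference numerical gradients in the test suite, and the
vectorized message passing is verified against a brute-force per-edge loop
oracle.  Optimization uses Adam (learning rate 1e-3 by default) on
minibatches; all reductions are order-independent up to float-point
associativity, so tests compare with tolerances rather than bit equality,
while fixed seeds make entire runs replayable (one root seed feeds named
substreams for fold assignment, initialization and shuffling).

## The fingerprint-autoencoder path

A deep autoencoder (default 2048 → 1024 → 512 → 256, mirrored decoder)
compresses fingerprints to a latent code.  Hidden layers are ReLU; the
reconstruction layer is logistic so outputs lie in [0, 1] against binary
targets; the loss and the reported histories are mean squared error.  The
autoencoder is pretrained on an unlabeled pool, with the validation side of
the chosen split strategy monitoring reconstruction under that strategy's
distribution shift; the encoder is then frozen (the default) and a
feed-forward head is trained on the latent codes.  Validation-side
reconstruction MSE is systematically higher under a scaffold split than
under a random split at matched configuration, because held-out ring
systems contain bit patterns the encoder never saw.

## Splitting strategies

- **random** — seeded uniform shuffle; |train| = round(n·fraction),
  half-up rounding.
- **scaffold** — molecules grouped by Bemis–Murcko scaffold key (ring
  systems plus linkers, canonical SMILES; all acyclic molecules share the
  empty key as one ordinary group).  Groups are assigned whole to the train
  side in descending size (ties by lexicographic key) until the target size
  is reached; the remainder forms the test side, so no scaffold key spans
  both sides.  If the greedy fill would consume every group, the last-added
  group is moved back to test so both sides stay non-empty.  A single
  scaffold group is an error directing the user to the random strategy.
- **weight** — indices sorted by molecular weight (ties by canonical
  SMILES); the train side takes the lighter molecules by default
  (`heavy_to_light` available), so max(train weight) ≤ min(test weight).
  The held-out contiguous range is the harsher of the two readings of a
  weight-based split (interleaving strata would make train and test
  *similar*); it is the reading consistent with the observation that
  weight-based splitting increases train/test divergence, and the direction
  flag documents the ambiguity rather than hiding it.
- **k-fold** — seeded permutation cut into k validation folds differing in
  size by at most one; default k = 5.  The best fold maximizes validation
  ROC-AUC (ties toward the lower index); the selection criterion is a
  package convention, as is every default above — none is a fitted or
  literature-reported value.

## Metrics

Binary accuracy thresholds probabilities at 0.5 (configurable).  ROC-AUC is
the Mann–Whitney statistic — the probability that a random positive
outscores a random negative, ties counted one half — computed from average
ranks; it is checked against an all-pairs brute-force oracle to 1e-12 and
cross-checked against scikit-learn, which is never used as the
implementation.  Single-class label sets raise an undefined-metric error
instead of returning a silent default.

## The synthetic data generator

The generator emulates the situation the real task presents — a labelled
table of diverse small molecules whose activity depends on structure —
without requiring downloads.  Molecules are assembled from ring-scaffold
cores (benzene, pyridine, cyclohexane, naphthalene, furan, thiophene,
cyclopentane, pyrimidine, piperidine, indole; default pool 8) by attaching
0–3 substituents (methyl, ethyl, hydroxyl, methoxy, amino, chloro, fluoro,
carboxyl, nitro) at ring carbons through single bonds, which guarantees
validity without a rejection loop.  Core frequencies are Zipf-like
(probability ∝ 1/rank), reproducing the long-tailed scaffold distributions
of real inventories: a few common ring systems and many rare ones, so a
scaffold split holds out a *mixture* of small groups rather than one block.

The clean label has two components: a local functional-group trigger
(default: presence of the nitro group, checked by SMARTS match) and
scaffold-intrinsic activity (a per-seed random quarter of the core pool is
active regardless of substitution).  The second component reflects how
activity behaves across scaffold series — molecules sharing a scaffold tend
to share target relationships — and is what makes scaffold-held-out test
sets genuinely harder: the activity of an unseen core cannot be inferred
from local features.  With `active_scaffold_fraction=0` the label reduces
to pure substructure presence.  Clean labels are then flipped with
probability `noise` (default 0.1, capped below 0.5 so the signal stays
learnable) and masked with probability `missing_rate`; the clean labels are
returned alongside so noise recovery is testable.  The unlabeled-pool
generator additionally allows alkyl/ether chains up to C24, giving a much
wider molecular-weight range, as a pretraining pool should have.

Default conditions (n = 2000 labelled molecules, 10% label noise, 8 cores,
~55% positive prevalence) are the package's study conditions throughout the
tests and the acceptance script.  What passing tests on this generator do
show: the encoders detect local substructure and ring-system identity, the
splits induce real distribution shift, and the expected orderings (random ≥
scaffold test performance; scaffold > random AE validation MSE) emerge.
What they do not show: performance levels transfer to real assay data —
real chemical space is vastly larger, labels are noisier and biased, and
activity cliffs are sharper than this two-component label model.

## Evaluation protocol notes

Learnability of the planted rule is measured by training on noisy labels
and scoring against the clean ground truth: with a 10% flip rate even a
perfect model cannot exceed ≈ 0.9 AUC against the noisy labels themselves,
so the clean labels are the correct reference for rule recovery.  The
random-versus-scaffold comparisons score against the observed noisy labels
on both sides (a paired comparison, so the noise ceiling cancels) and are
averaged over five seeds with a small slack band (0.002 MSE, 0.02 AUC)
because single-seed differences are dominated by which cores land in the
held-out tail.

## Problem sizes

Tests and the acceptance script run reduced configurations chosen as the
smallest that exhibit each phenomenon stably: hidden widths 12–64, depths
1–3, 2–25 epochs, n = 80–2000 molecules, 6–8 autoencoder epochs at widths
(256,)→64.  The library defaults (hidden 300, depth 3, 2048→1024→512→256
autoencoder) remain the recommended starting point for real datasets.

## Known limitations

- No stereochemistry, 3D geometry, tautomer normalization or InChI support.
- Per-endpoint models only; no shared-trunk multi-task training, no
  ensembling or uncertainty quantification.
- The graph encoder is not pretrained (only the fingerprint autoencoder
  is), so its generalization depends entirely on the labelled data.
- Message passing cannot distinguish some locally identical structures at
  small depth (e.g. cyclopentane vs cyclohexane differ only through the
  magnitude of the summed readout), which bounds how well scaffold-intrinsic
  activity can be learned for such core pairs.
- CPU-only NumPy training: comfortable up to tens of thousands of
  molecules, not millions.
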