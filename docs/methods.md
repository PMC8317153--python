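# Methods

## The model

`graphsig` predicts the anticancer bioactivity of small molecules from
*graph-based signatures*. A molecule is reduced to its heavy-atom graph
G = (V, E): vertices are non-hydrogen atoms, edges are covalent bonds, and
every edge has unit weight, so the shortest-path distance d(i, j) between
two atoms is the number of bonds on the shortest path connecting them.
Each atom is tagged with zero or more *pharmacophore classes* — categorical
physicochemical roles assigned by substructure rules. The signature is the
cumulative distribution of class-pair distances:

    sig(A, B, k) = #{ {i, j} ⊆ V : i ≠ j, A ∈ classes(i), B ∈ classes(j)
                                     (or symmetrically), d(i, j) ≤ k }

for every unordered class pair {A, B} and every cutoff k. An atom pair is
counted once per class pair even when both atoms carry both classes; atoms
never pair with themselves. Distances are computed exactly by breadth-first
search from every vertex — the special case that Johnson's all-pairs
algorithm reduces to when all edge weights are equal.

With 8 classes (36 unordered pairs) and cutoffs k ∈ {1, …, 6} the signature
block has 216 entries; appending 48 general physicochemical descriptors
gives the fixed 264-dimensional feature vector. Counts are raw (not
normalised by atom count): the signature expresses numbers of atoms, and
any scaling is left to the learner.

### Pharmacophore alphabet

The eight classes, in frozen order: Hydrophobe, Aromatic, Donor, Acceptor,
PosIonizable, NegIonizable, Halogen, Sulfur. Each is defined by a list of
single-atom SMARTS environments in `src/graphsig/data/pharmacophores.json`
(versioned; its SHA-256 travels with every run). The table is a
reconstruction in the cutoff-scanning/pkCSM tradition, and two choices in
it are genuinely open:

* **Basic amines are PosIonizable + Donor, not Acceptor.** Under assay
  conditions an aliphatic amine is largely protonated; treating it as an
  H-bond acceptor would double-count its role. Pyridine-type aromatic
  nitrogens and nitriles are Acceptors.
* **Hydrophobe is any carbon not doubly bonded to a heteroatom**, plus all
  aromatic carbons. This deliberately overlaps with Aromatic; overlap is
  meaningful because class pairs are counted independently.

### General descriptors

The 48 descriptors (`src/graphsig/data/descriptors.json`) are computed with
RDKit and cover size (MolWt, heavy atoms), lipophilicity (Crippen logP,
MR), polarity (TPSA, H-bond donor/acceptor counts), flexibility (rotatable
bonds, fraction sp³), ring systems (aromatic/aliphatic/saturated ring and
heterocycle counts, spiro and bridgehead atoms), composition (elemental
counts, halogens), drug-likeness (Lipinski violation count) and topology
(Balaban J, Bertz CT, Chi and Kappa indices). The manifest order is frozen;
changing it is a breaking change to every stored model.

## Activity labelling and data curation

Growth-inhibition evidence is converted to labels with two strict
thresholds at a dose of 10⁻⁵ mol: *inactive* when the mean one-dose growth
inhibition is below 5%, *active* when the mean dose-response growth
inhibition exceeds 50%. Boundary values (exactly 5% or 50%) satisfy
neither rule and stay unlabelled, as do molecules whose evidence falls in
the 5–50% gap; unlabelled molecules are excluded from classification
training. A molecule satisfying both rules is a conflict and is excluded
with a warning (or raises, on request).

GI50 potencies are handled as −log₁₀(molar); replicate (molecule, cell
line) observations are combined by arithmetic mean on that log scale, and
one regression table is produced per cell line.

## Non-redundant splitting

Random splits leak: near-duplicate molecules land on both sides and
inflate blind-test metrics. Molecules are therefore clustered on Morgan
fingerprints (radius 2, 2048 bits — the community default; the
fingerprint parameters are frozen in `datasets.py`) with Butina leader
clustering at Tanimoto ≥ 0.6, and whole clusters are assigned to train or
blind. Centroids are picked by descending neighbour count with ties broken
by lexicographic molecule id, which makes the clustering deterministic;
the implementation is cross-checked against RDKit's Butina in the test
suite. Cluster assignment is greedy largest-first to whichever side is
furthest below its quota (train fraction 0.80 by default, realised within
±5 percentage points on non-degenerate inputs); equal-size clusters are
ordered by the split seed. The degenerate case — everything in one
cluster — puts the whole set in train and warns that the blind set is
empty rather than silently splitting a cluster.

## Learning and evaluation

Learners: random forest, extremely randomized trees, gradient boosting,
extreme gradient boosting, AdaBoost, and k-nearest neighbours, for both
tasks. Hyperparameters are library defaults with the ensemble size frozen
at 300 trees and an explicit seed everywhere — reproducibility is
preferred over speculative tuning. Random forest is the reference final
model.

**Greedy forward selection** starts from zero features; each round adds,
from the remaining candidates, the feature whose addition maximises the
cross-validated metric (rank AUC for classification, Pearson r for
regression), ties going to the earlier manifest column. The search stops
after `patience = 5` consecutive rounds that fail to beat the running best
by more than `tolerance = 1e-4`, and returns the globally best prefix.
Two scalability knobs exist for wide matrices: `candidate_pool` restricts
the search to the top features of a univariate screen, and
`selection_params` lets the search use a smaller ensemble than the final
model. Selection runs on the training partition only; metrics from the
selection CV are optimistically biased, which is why the blind set exists.

**Evaluation** pools out-of-fold predictions from stratified 10-fold CV
(per-fold values are reported alongside). Classification metrics are
closed forms from the 2×2 confusion table at threshold 0.5 — accuracy,
precision, sensitivity, FPR, Matthews correlation — plus AUC computed as
the Mann–Whitney rank statistic with half-credit for ties (the tests check
it against both a brute-force concordant-pair count and trapezoidal ROC
integration). A single-class truth vector makes AUC undefined; it is
reported as NaN, never as 0. Regression reports Pearson, Kendall and RMSE
on 100% of the points and again after *trimming*: removing the
⌈0.10·n⌉ points with the largest absolute residual (ties broken by index,
lower index removed first) isolates the influence of outliers. Trimming is
refused below n = 10.

## Enrichment analyses

Two views of what separates actives from inactives: (1) two-sample
Kolmogorov–Smirnov tests on physicochemical property distributions
(D = sup |ECDF_a − ECDF_i|, asymptotic two-sided p); (2) presence
frequencies of a fixed SMARTS panel — naphthalene, lactone,
N-methylaniline, quinoline, benzene, pyridine, amide — reported as the
percentage of molecules in each set with at least one match. The panel
encodes parent scaffolds (substitution tolerated); de-novo frequent
subgraph mining is deliberately out of scope, being a separate third-party
tool, and the panel is versioned configuration, not code.

## Synthetic screens

The generator builds molecules by joining 1–4 scaffolds drawn uniformly
from a 15-entry vocabulary through single C–C/C–N bonds at
hydrogen-bearing carbons; invalid assemblies are resampled, so every
emitted SMILES re-parses. Three scaffolds (naphthalene, quinoline,
lactone) are *active*: each planted occurrence adds `fragment_effect` to
the activity log-odds and `gi50_effect` to the −log₁₀ GI50 of every cell
line.

Defaults are the package's reference study conditions and were fixed by a
power analysis of the group-probability AUC bound before any end-to-end
test was run: `base_active_prob = 0.05` and `fragment_effect = 6.0` make
one planted scaffold nearly decisive (P(active) ≈ 0.95) while leaving
~5% irreducible label noise, bounding the achievable AUC near 0.95 at
n = 1000 — high enough that a working pipeline clears 0.85 on a blind set,
low enough that label noise is actually exercised. `gi50_base = 4.5`
(≈30 µM, a weak screening hit), `gi50_effect = 0.8` log-units per scaffold
and `noise_sd = 0.3` give a regression ceiling of Pearson ≈ 0.85.

What the generator does *not* emulate: realistic medicinal-chemistry
property marginals, activity cliffs, assay batch effects, or the class
imbalance of real screens. Passing the recovery tests shows the pipeline
can learn a planted structure–activity relationship of realistic
dimensionality; it says nothing about accuracy on real NCI-60 data, which
requires the external downloads and full-scale retraining.

## Numerical and degenerate-input choices

* Multi-fragment SMILES keep the largest heavy-atom fragment (ties: the
  lexicographically smallest canonical SMILES) — inter-fragment distances
  would otherwise be infinite.
* Molecules are re-parsed from their canonical SMILES before
  featurization, so descriptor floating-point sums are bit-identical
  across input spellings of the same molecule.
* Feature assembly aborts on any length mismatch; it never truncates.
* All stochastic steps take explicit seeds (default 42); repeated runs
  with one seed are byte-identical.

## Problem sizes

The reference synthetic screen used throughout the end-to-end tests and
the acceptance script is 1000 molecules (800/200 split, 5 cell lines);
oracle and property tests run on 50–500 molecules. These desk-scale sizes
are the package's chosen defaults for self-contained verification; the
library itself has no size-dependent logic and runs unchanged on larger
tables.

## Known limitations

* The pharmacophore SMARTS table and the 36×6 + 48 feature decomposition
  are principled reconstructions; other alphabets/cutoff grids of the same
  total dimension exist.
* Feature selection is not nested within the evaluation CV; selection
  metrics are biased upward and only blind-set numbers are honest
  generalization estimates.
* Tautomers, protonation states, stereochemistry and 3D geometry are
  ignored; the graph is the 2D connectivity.
* KNN has no ensemble size or seed; its results depend only on the data.
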