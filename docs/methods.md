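# Methods

## Problem setting

Site-level cysteine ligandability records from multiple chemoproteomic
sources are binary (`pos`/`neg`) observations contaminated by three noise
channels: detection dropout (a probe simply never sees a site), false
positives (a site reported engaged that is not reproducibly ligandable), and
false negatives. The package's job is to (i) quantify the disagreement,
(ii) distill high-confidence labels via consensus rules and
embedding-similarity clustering, (iii) train and expand sequence-only
classifiers on those labels, and (iv) validate with ranked, per-protein
metrics and a structural proximity analysis.

## Consensus rule

For a pooled record set, criteria *n*S–*m*R assign:

* `pos` iff (# positive records ≥ *m*) and (# distinct sources with ≥ 1
  positive record ≥ *n*);
* `neg` iff (zero positive records) and (# observed negative records ≥ *m*)
  and (# distinct sources with ≥ 1 negative ≥ *n*);
* `excluded` otherwise.

The *m*-record clause counts records pooled across sources, so 1S–5R means
"≥ 5 positive records with at least one supporting source"; this is the only
reading under which the 1S–1R … 1S–5R family forms a nested, shrinking
series. Unquantified records never count toward *m* or *n* at the record
level; they act only as cluster-level default negative votes (below).

Diagnostics: per site, `p` = supporting sources / quantifying sources and
label variability is `100·H₂(p)` (binary Shannon entropy scaled to 0–100 %).
Accumulation curves draw random source subsets of size *k*, count
consensus-positive sites from the subset alone, and normalize by the naive
total (sites with ≥ 1 positive record anywhere); a 95 % normal-approximation
band accompanies each curve.

## Clustering and label propagation

Sites are clustered on the cosine similarity of their per-residue embedding
vectors with greedy leader clustering: deterministic processing order
(sorted by uid, position), join the first cluster whose representative
similarity ≥ threshold (default 0.90), else found a new cluster; after a
pass, representatives are re-selected as the member with maximal mean
similarity to the rest (ties to the lexicographically smallest site) and
membership is re-checked once. The algorithm was chosen for determinism
without a seed and O(N·K) cost; the output always partitions the site set.

Cluster labels apply the consensus rule to the pooled observed records of
all members, with each member's unquantified record contributing one
negative record from a per-site pseudo-source. The pseudo-source counts
toward the distinct-source clause — otherwise a cluster of only undetected
cysteines could never satisfy the negative condition, and extending negative
coverage to undetected cysteines is the point of the vote. Every member of
a labeled cluster inherits the label; excluded clusters label nothing.

Partitioning: uid-connected components of clusters (union–find over shared
uids) are placed whole into train/validation/test, greedily into the
partition with the largest remaining deficit after a seeded shuffle. A
component larger than the largest quota goes to train with a warning.
External evaluation sites remove both their clusters and every cluster
sharing a uid with them from training material.

## Classifier heads and ensembles

The ligandability head is an MLP over frozen per-residue embeddings with two
hidden layers (default 256 and 64 units, ReLU) and a logistic output; the
binding-residue head is a single linear layer to a probability. Heads are
fit with scikit-learn (MLPClassifier / LogisticRegression, Adam for the MLP,
learning rate 1e-3, fixed budget of 150 epochs) and their weights are
extracted into a plain numpy forward pass, so prediction and persistence do
not depend on the fitting backend. Class imbalance is handled by
deterministic integer replication of the minority class to the balanced
ratio (the sklearn MLP exposes no class weights). Training uses a fixed
epoch budget without early stopping: the datasets are small, the budget is
part of the deterministic contract, and validation-based stopping would add
a stochastic dependence on the split for little gain at this scale. A
degenerate (single-class) training set raises an error rather than fitting.

Ensembles are (n_splits × models_per_split) heads: each split re-partitions
the labeled clusters under the leakage rules with a split-specific seed and
holds out 15 % of sites (never trained on, which decorrelates members); each
member gets its own derived seed. The ensemble score is the member mean, the
uncertainty the member population standard deviation, and `blend` is the
unweighted mean of two prediction sets. Only cluster representatives enter
training by default (members-mode is available for ablation).

## Expansion protocols

Both protocols grow a baseline training set from a candidate pool while a
fixed evaluation interface gates acceptance; pool, baseline and evaluation
material never share uids, and every evaluated batch is logged to a
replayable history keyed off one seed (counter-derived streams per
iteration).

*External-recovery guided.* Per iteration, sample N random batches of the
scheduled size (default schedule 80, 100, 150, then 175 repeating), score
each by Top-1 recovery of a screening ensemble trained on baseline+batch,
revalidate the best batch with a larger ensemble, and accept only if the
revalidated Top-1 strictly exceeds the running baseline. The first
non-accepting iteration terminates.

*Cross-validation guided.* Batches have fixed composition (25 positives,
remainder negatives; size 100 in the first two tournaments, 175 after) and
are assembled by sampling candidates with probability proportional to
ensemble uncertainty. Tournaments of four iterations each: evaluate the
population by cluster-respecting k-fold cross-validated PRCE, keep the top
performers, and breed crossover variants (equal-count same-class swaps of
members unique to each parent, which preserves composition exactly) and
mutation variants (replace ~10 % of each class from the unused pool).
"Significantly exceeds" is implemented as: candidate mean PRCE > baseline
mean + one standard error of the baseline's across-fold PRCE, and also >
the last accepted candidate's PRCE so the accepted-metric sequence is
strictly increasing by construction. A full tournament without an
acceptance, or four tournaments, ends the protocol. Batch evaluation
retrains from scratch each time; warm-starting would couple evaluations
across batches and break the replayable-history property.

## Structure analysis

Ligand-binding residues are labeled when the minimum heavy-atom distance
between residue and ligand is ≤ 4.5 Å; ligands are filtered to 150–600 Da.
The radial distribution g(r) instead uses minimum *all-atom* distances from
each classified cysteine (TP/TN/FP/FN at score ≥ 0.5) to every predicted
binding residue in the same protein — the two distance rules intentionally
differ. Histogram counts are divided by the spherical shell volume 4πr²Δr
and normalized by the mean shell density over the last 20 % of [0, r_max]
(defaults: 0.5 Å bins, r_max 20 Å — fine enough to resolve a 4–6 Å contact
peak, long enough for a stable tail), so a uniform point cloud has tail
g(r) ≈ 1. Empty classes are flagged, never silently zeroed. The predicted
binding set defaults to the score-ranked Top-20 per protein; a 0.5-threshold
set is also available. PDB I/O goes through gemmi (highest-occupancy
altloc, insertion codes folded into the residue key).

## Synthetic data generator

The generator emulates the regime the pipeline targets, with every output a
pure function of one seed:

* **Proteome.** 300 proteins of length 100–400, background residues from a
  cysteine-free alphabet; each cysteine arrives inside a 9-mer motif drawn
  from a library of 2000. A motif hashes to one of 6 latent archetypes
  (hash shared with the embedding provider), and the archetype's
  ligandability probability (defaults 1.0, 0.95, 0.9, 0.1, 0.05, 0.0)
  draws each site's true label. Cysteine counts are Binomial(length, 0.03)
  with motif placements spaced to keep windows intact.
* **Embeddings.** Cysteine vectors are
  `normalize(centroid[archetype] + 0.655·motif_direction) + 0.022·noise` in
  64 dimensions: same-motif cosine ≈ 0.97, same-archetype/cross-motif
  ≈ 0.70, cross-archetype ≈ 0. The default 0.90 clustering threshold
  therefore isolates motif-level clusters (mean size ≈ 1.7 sites at the
  default proteome size) while a mid-gap threshold merges whole archetypes.
  The motif-library size was fixed at design time so that per-cluster record
  counts stay sparse, mirroring real multi-source corpora where most sites
  are quantified by only one to three sources; much coarser clusters pool
  enough records that 30 % false-positive noise alone satisfies a 4-source
  positive clause, which is a record-density artifact rather than a
  property of the consensus rule.
* **Records.** Each of 8 sources detects each site with probability 0.5;
  detected ligandable sites are reported `pos` with probability 1 − FN
  (FN = 0.4), non-ligandable sites `pos` with probability FP = 0.3.
  Noise is independent per source and site.
* **Complexes.** Toy coordinates with the focal cysteine at the origin, the
  ligand center 7 Å away (14–40 heavy atoms within 1.2 Å, MW inside the
  150–600 Da band), binding residues placed 4–6 Å from the cysteine and
  1.6–4.2 Å from the nearest ligand atom, and all other residues ≥ 6.5 Å
  clear of every ligand atom — so contact labeling recovers exactly the
  planted set with margin on both sides of the 4.5 Å cutoff, and the
  cysteine-to-binding-residue distances concentrate in the 4–6 Å band.

What the generator does **not** emulate: correlated noise across sources
(shared cell lines, probes and protocols correlate errors in real data; a
correlation hook is future work), realistic sequence composition, per-cell-
line heterogeneous ligandability, and the marginal record counts of any real
corpus. Passing tests therefore demonstrate that the machinery is correct
and that consensus + clustering beat naive labeling under independent
multi-source noise — not that any particular real-data accuracy will be
reached.

## Problem sizes used in tests and the acceptance script

The study conditions are the generator defaults (300 proteins, 8 sources,
FP 0.3, FN 0.4, detection 0.5, five seeds). Ensemble checks use the
(6 × 4) = 24-model configuration on consensus representatives. The
expansion checks run the protocols at reduced search breadth — 5 batches
per iteration, schedules (20, 30, 40), screening/revalidation ensembles of
(2 × 2)/(3 × 3), 2 tournaments × 2 iterations with 10 positives per batch,
3 CV folds, (32,)-unit heads — sizes chosen so the whole suite is a
desk-scale experiment while every acceptance rule, leakage guard and
history invariant is exercised verbatim. Expansion baselines and candidate
pools in these checks carry clean (ground-truth) labels, since the claims
under test are about the acceptance machinery, not label distillation.

## Numerical conventions

* Classification threshold is score ≥ 0.5; Top-k ties break by (uid,
  position).
* AUROC is the Mann–Whitney statistic with ties counted ½; AUPRC is
  step-wise precision–recall integration (average precision). Pooled
  aggregation is the default; a per-protein-averaged mode (mean over
  proteins with both classes) is provided because ranked per-protein
  reporting is common, and neither mode is asserted against any external
  table.
* Representative ties and partition assignment are deterministic; every
  stochastic component consumes an explicit seed, and derived seeds come
  from SHA-256 hashes (stable across processes, < 2³¹).
* RDF distances at exactly r_max fall into the last bin; the cysteine's own
  position never contributes a zero-distance pair.

## Known limitations

* The consensus/clustering benefit is demonstrated under independent noise;
  correlated sources could defeat the distinct-source clause in ways the
  generator cannot currently produce.
* The real-model embedding adapter only reads caches; no inference, so
  2,560-dimensional embeddings are exercised structurally (shape/contract
  tests) but not scientifically.
* The cross-validation-guided protocol's "significance" gate is a one-SE
  heuristic, not a formal test; a paired t-test variant is configurable.
* Sub-sequence/peptide-to-protein mapping is out of scope: inputs are
  assumed site-resolved, and records whose position does not index a
  cysteine are rejected rather than remapped.
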