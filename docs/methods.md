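# Methods

## Problem setting

The package models the reported literature on microbial synthesis of
inorganic nanomaterials as a typed knowledge graph and learns embeddings
to rank unreported microbe–material pairs. Two empirical regularities
motivate the design: (i) biosynthetic ability clusters on the microbial
phylogeny — strains of a capable genus are far more likely to be capable
themselves — and (ii) the identity of a material is dominated by its
principal element (silver reducers tend to make other silver-based
particles). The graph therefore carries a taxonomy backbone
(`taxon_parent` edges, phylum → genus → species → strain), elemental
composition (`composed_of`), and year-stamped `synthesizes` facts, under
a small class ontology (Element/Metals/Nonmetals, Genus/Species/
Microorganism, Material, SynthesisMethod) with `rdf:type`-style instance
typing and an N-Triples serialization.

## Embedding model

**Semantic module.** Descriptions are lowercased, tokenized on
non-alphanumerics, and embedded by a learned token matrix mean-pooled per
entity. Tokens rarer than `min_token_count` (default 2) share one UNK
slot, so strain-unique tokens cannot serve as entity identifiers. The
backend is a pluggable contract: a pretrained sentence encoder can be
adapted behind the same `TextEmbeddingTable` (seeded linear projection to
the working dimension); the trainable bag-of-tokens default keeps the
whole pipeline self-contained and desk-scale. Mean pooling is
permutation-insensitive by construction, and an entity's initial vector
is exactly the mean of its token rows.

**Graph module.** A relational graph convolution with one transform per
relation plus a self transform, in-degree normalization
c_{i,r} = |N_r(i)|, inverse relations for every edge type (tail-only
entities would otherwise receive no messages), tanh between layers, L = 2
layers, d_g = 64. The standalone `encode_graph` operation runs on learned
per-entity input embeddings, the conventional choice for this
architecture. Inside the joint model, however, the convolution runs on a
learned projection of the *semantic* vectors rather than on free
per-entity embeddings: with only ~90 training edges and ~90 entities,
free input embeddings let the network memorize every training edge
within a few epochs (training loss → 0 while the planted-capability
signal in the embeddings drops to chance, AUC ≈ 0.5). Tying the graph
input to shared text features removes the per-entity capacity and forces
generalization through tokens and graph structure. This is the one place
the implementation deviates from the conventional free-embedding RGCN
input, and it is a deliberate design choice of this package.

**Fusion and scoring.** The two d=64 vectors are concatenated and
linearly projected to d = 64, then L2-normalized. Pairs are scored with
1/(1+‖m₁−m₂‖); distances and scores induce identical rankings.
Normalization bounds the geometry so the listwise objective cannot be
driven to zero by pushing negatives to infinity.

**Objective.** The listwise MRR surrogate is a softmax cross-entropy
over negated distances with the numerator restricted to the positive
candidates. The published form of this loss sums numerator and
denominator over the same candidate set and is identically zero; the
positive-restricted numerator is the only reading that yields a
trainable ranking objective, and the degenerate literal form is retained
behind `mode="literal"` as a documented regression case, alongside a
`sigmoid-rank` smooth-rank variant. Distances are divided by a
temperature τ = 0.05 before the softmax; on the unit-normalized
geometry raw distance gaps are small and the sharpened contrast is what
makes the hardest negatives informative.

**Training.** Full-batch Adam (lr 0.01, decoupled weight decay 0.1),
queries in both directions — each microbe over material candidates and
each material over microbe candidates — since the score is symmetric and
predictions are made in both directions. 60 epochs in two phases: full
step size for 15 epochs, then a 0.3× tail during which per-epoch fused
snapshots are accumulated; inference uses the renormalized tail average.
Single late checkpoints oscillate between sharp minima of the listwise
loss and rank held-out pairs erratically; the tail average is markedly
more stable. All defaults were fixed by measuring held-out edge recovery
across 15 generator seeds and then frozen. Training this model takes
about one second on one CPU core.

## Synthetic data generator

The generator emulates the structure the method assumes, at roughly one
tenth of the reported-literature scale with the same microbe:material
ratio (defaults: 2 phyla × 5 genera × 2 species × 2 strains = 40
strains; 10 materials over 6 elements, 1–3 elements each; years uniform
on 2010–2022). Materials sharing a leading element form a family; each
(genus, family) is capable with probability `clade_trait_prob` = 0.3;
each strain inherits its clade's trait with probability
`trait_heritability` = 0.9 and otherwise redraws independently, so
heritability interpolates clade-level and strain-level traits; capable
pairs receive an edge with probability 0.8, others 0.05. Descriptions
are templated: strain texts name the lineage plus the element keywords of
the families the strain is capable of (with seeded noise words), and
material texts name the principal element explicitly ("gold rich
alloy..."), the way nanomaterials are conventionally described — with
elements listed only alphabetically, the family identity would be
invisible to any order-insensitive text encoder and the generator would
fail its purpose of carrying the planted signal in text. Every Bernoulli
draw is recorded in a `GroundTruth` table, so each edge is attributable
to exactly one draw.

What the generator does *not* emulate: real abstracts (texts are short
templates), unbalanced taxonomies, chemically valid stoichiometry,
temporal drift of discovery, and annotation noise. Passing tests
therefore demonstrate that the pipeline recovers a planted, heritable,
text-correlated signal at desk scale — not that it attains any
particular accuracy on the literature corpus.

## Evaluation protocols

Metrics are MR (mean first-relevant rank), MRR, and HITS@{5,10,20}.
Candidate lists are *filtered* by default (known training positives
removed); score ties assign the positive the worst rank in its tie
group, so reported metrics are lower bounds. Confidence intervals are
Student-t over independent runs (appropriate at n = 3, where a bootstrap
is meaningless).

* **Temporal split**: train on `synthesizes` facts before a cutoff
  (default 2019), test on the rest; structural triples (taxonomy,
  composition, ontology) are kept on both sides as time-invariant
  background knowledge, and the entity set is never filtered so
  test-side microbes remain embeddable. Undated facts are excluded from
  both sides with a warning.
* **Incremental series**: training cutoffs 2013/2016/2019 with the test
  side fixed beyond the final cutoff; training sets are nested and the
  metric trend is reported.
* **Leave-one-genus-out**: each genus's edges are removed from training
  and used as that fold's test set; folds partition the positive set
  exactly, and an edge-free genus is skipped with a warning.
* **Planted-signal recovery**: 30% of edges held out at random; each
  held-out fact becomes one query ranking microbes for its material —
  the direction with the large candidate space — with every *other*
  known positive of that material filtered, leaving one relevant
  candidate per query (the standard filtered completion convention).
  The comparison floor is the same queries under random candidate
  permutations. In the microbe→materials direction the default graph
  offers only ~10 candidates, so the permutation floor is ≈ 0.35–0.45
  MRR and no model could exceed it threefold; the material→microbes
  direction is the meaningful one at this scale. Even there the margin
  is bounded: an oracle ranking by the generator's true strain-level
  capability reaches only 2.7–5× the floor across seeds (capable
  strains whose edge draw came up negative are indistinguishable from
  true positives), and the trained model typically reaches 55–75% of
  that ceiling (≈ 2–3× the floor). Ratios near or above 3 should be
  read as strong recovery at this candidate-set size, not as a universal
  threshold.

## Numerical choices and degenerate inputs

Distances include a 1e-12 floor inside the square root to keep gradients
finite at zero distance; padded candidate slots carry a constant 1e6
distance so exp(−d) underflows to exactly zero; log-sum-exp subtracts a
detached row maximum. Empty descriptions yield zero semantic vectors and
a warning. Ranking ties break by candidate id for deterministic output
files. All randomness flows through `numpy.random.SeedSequence` chains
from a single seed; reruns are byte-identical.

## Known limitations

The autodiff core is dense and single-threaded: entity counts in the low
thousands are comfortable, web-scale graphs are not the target. The
bag-of-tokens encoder has no word order or subword structure, so it
cannot separate e.g. "non-reducing" from "reducing"; the pretrained
adapter exists for that. Checkpoints store parameters as JSON, which is
transparent and diffable but not compact. Ontology classes participate
in validation and serialization but are not message-passing nodes unless
explicitly requested via `relations_to_use`.
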