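# Methods

## Graph construction

Each parsed sentence becomes a directed multigraph: one vertex per token
labelled with its lowercased lemma, one edge per dependency with its relation
label. When the CoNLL-U DEPS column is present its enhanced edge set is used
for the whole sentence; enhanced graphs may contain undirected cycles, which
both kernels handle. Basic-mode input with a cyclic HEAD chain is rejected.

For a candidate entity pair the pipeline is: build the sentence graph(s);
merge root-to-root with a `SentenceBoundary` edge when the mentions lie in
different sentences; weight the edges on the shortest undirected path between
the two mention head tokens at `w_path = 0.9` and all others at
`w_default = 0.3`; attach `Entity1`/`Entity2` focus vertices to the pair.
Parameter defaults and the reasoning behind the open choices:

| parameter | default | rationale |
|---|---|---|
| `w_path` | 0.9 | emphasized weight for shortest-dependency-path edges |
| `w_default` | 0.3 | background weight for all other edges |
| focus edge | label `focus`, directed focus→entity, weight 0.9 | the focus marker deserves the same emphasis as path edges; direction keeps the marker a source so it never absorbs unrelated paths |
| `SentenceBoundary` edge | earlier root → later root, weight 0.3 | re-weighted to 0.9 automatically when it lies on the entity path |
| `w_linear` (APG) | 0.9 | the linear-order chain is the positional signal carrier |
| `max_cross_sentence_distance` | unlimited | cap available to bound the quadratic sentence-pairing blowup |

Shortest paths are minimum-hop on the undirected graph, found by BFS that
expands neighbours in ascending (vertex id, edge index) order; ties are
therefore broken deterministically, which keeps repeated runs and the
label-pair feature tables reproducible. Hop count rather than weight-optimal
search is used because weights are assigned *from* the shortest path, not
before it.

Mention head tokens: the unique mention token whose syntactic head falls
outside the mention, else the last mention token. Multi-sentence pairing for
cross-level relations builds one instance per (sentence with C, sentence with
D) pair using the first mention of each concept in its sentence; co-mention
sentences build one instance per mention pair. A concept pair therefore
yields either sentence-level or cross-level instances, never both.

## ASM kernel

Node labels are mapped bijectively to vertices (dummy vertices for labels a
graph lacks; duplicate labels within a graph resolve to the lowest-id
bearer). For every ordered label pair the shortest path between the mapped
vertices is summarized by an explicit sparse feature map — distance, forward,
backward, and one feature per dependency label on the path, all products of
edge weights — and the kernel is the sum of feature dot products over label
pairs. Label self-pairs are excluded by default (`include_diagonal=False`):
their feature maps are degenerate all-ones vectors that only add a constant.
Pairs with a dummy or disconnected endpoint contribute zero, so enlarging the
vocabulary (batch processing) never changes a kernel value.

Because every instance's features depend only on that instance, the kernel is
an explicit inner product: Gram matrices are computed by sparse
featurization and a single sparse matrix product, which is exactly equal to
(and tested against) pairwise kernel calls, and guarantees symmetry and
positive semi-definiteness.

## APG kernel

The dependency graph is rewritten edge-label-free (each labelled edge becomes
an edge-node vertex with two unlabelled edges inheriting the weight) and
paired with a disconnected linear-order chain whose vertices carry the lemma
plus a position tag relative to the focus pair. Total connectivity is the
Neumann series W = Σ_{i≥1} Aⁱ = (I−A)⁻¹ − I, well defined while the spectral
radius ρ(A) < 1. Dependency graphs are near-acyclic so this rarely binds, but
enhanced parses can create heavy directed cycles; when ρ(A) ≥ 1 − 10⁻⁶ the
adjacency matrix is rescaled by 0.99·(1−10⁻⁶)/ρ with a logged warning
(`convergence_mode="error"` raises instead). Matrices at sentence scale
(≤ ~300 vertices after transformation) are inverted densely via one LU solve.

Label-pair connectivity Gᵐ = L·W·Lᵀ uses a 0/1 label allocation matrix L with
rows in sorted label order; vertices sharing a label aggregate. The kernel is
the Frobenius inner product of two Gᵐ matrices aligned on the label union
(equivalently a sparse dot product over shared labels — a global corpus
vocabulary would not change the value).

## Classification and evaluation

Precomputed-kernel soft-margin SVM, C = 1 by default and deliberately
untuned; both kernels are cosine-normalized by default since unnormalized APG
magnitudes grow with sentence length. No class weighting by default (a config
hook exists). Document-level scoring follows the BioCreative convention:
P/R/F over (document, chemical, disease) triples, a pair predicted positive
iff any of its instances is, with the max instance decision score used for
document-level AUC. McNemar's test uses the exact two-sided binomial p-value
below 25 discordant pairs and the continuity-corrected chi-square
(|b−c|−1)²/(b+c) above.

## Synthetic corpus

The generator emulates CDR-like documents: 2–4 sentences of 6–10 tokens,
random dependency trees drawn by sequential head-attachment (token i attaches
to a uniformly random earlier token — connected and parser-like), plus
occasional extra edges between random non-entity tokens to exercise the
cyclic-graph code paths. Each document carries one chemical and one disease
mention with document-specific lemmas (real corpora almost never repeat the
same mention pair). Defaults: positive rate 0.35 (CDR-like imbalance), 30%
of relations split across sentences, trigger-omission noise 0.1.

The planted signal is lexical *and* structural, mirroring how CID relations
surface in text: a positive pair uses the compact subject–trigger–object
construction — both mentions syntactic dependents of a trigger token
(`induce`/`cause`) that sits between them in linear order — while a negative
pair's mentions fall at arbitrary positions with their random attachments.
Cross-sentence positives put the trigger at the root of the chemical-bearing
sentence, so the merged shortest path passes through it. With zero noise a
one-line rule ("trigger lemma on the focus shortest path") reproduces the
labels perfectly, which upper-bounds what the kernels can learn and confirms
the signal is present and clean.

What passing tests on this corpus do **not** show: linguistic realism (token
sequences are random), realistic mention ambiguity (one mention per concept
per document), or the class ratios of any specific benchmark. Absolute
scores on CDR or the PPI five are out of reach without those corpora; the
harness reads their formats when the data is supplied.

### Desk-scale behaviour of the two kernels

On the planted corpus (200 train / 200 test instances, noise 0.1) the ASM
kernel reaches test F1 ≈ 0.94 with a label-shuffled control near zero. The
APG kernel ranks almost perfectly (AUC ≈ 0.95) but its F1 stays lower
(≈ 0.67): the position-tag labels of its linear subgraph are shared by every
instance and their connectivity mass grows with sentence length squared, so
under cosine normalization they compress the class margin, and the untuned
C = 1 SVM under-predicts the scarcer positives — especially cross-sentence
ones. Ablating the position tags at desk scale *raises* APG's synthetic
F-score (to ≈ 0.98) because the small synthetic lexicon leaves the tags no
information to add; on large natural corpora the opposite was observed (tags
carry positional information a diverse lexicon cannot), so the tags stay on
by default and the ablation test asserts only that they measurably enter the
kernel. This asymmetry between the two kernels at desk scale — sharp
shortest-path features versus diluted all-path connectivity — is a real
property of the methods under a small lexicon, not an implementation
artifact: the connectivity matrix is verified entry-wise against exhaustive
path enumeration, and the feature maps against the worked example.

## Numerical notes

Weights live in (0, 1]; products over ≤ ~20 edges stay well inside double
precision, so no tolerances are needed in the feature maps. Gram symmetry is
exact by construction; PSD is checked empirically to −10⁻⁸ in tests. The
Neumann inverse is compared against truncated series and path enumeration at
10⁻⁹ on graphs of ≤ 8 vertices. Degenerate inputs: empty documents produce no
instances; a concept pair with a missing mention is skipped with a warning; a
disconnected focus pair keeps default weights and sets a `no_path` flag; self
kernels of zero make the normalized kernel 0 by convention.
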