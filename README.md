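# relkern

Graph kernels for biomedical relation extraction from dependency parse
graphs — for text-mining researchers who want a kernel-SVM baseline for
chemical-induced-disease (CID) or protein-protein-interaction (PPI) style
tasks, including relations whose two entity mentions never share a sentence.

## What it implements

A sentence's dependency parse is a directed graph whose vertices are tokens
(labelled with lemmas) and whose edges carry grammatical relations (`nsubj`,
`nmod:by`, ...). For a candidate entity pair, the edges on the shortest
dependency path between the two mentions get weight 0.9 and all others 0.3,
and two focus vertices labelled `Entity1`/`Entity2` are attached to the pair
so the classifier knows which of several co-mentioned pairs an example is
about. A relation expressed across a sentence boundary is handled by joining
the two sentence graphs root-to-root with a `SentenceBoundary` edge.

Two graph kernels score the similarity of such graphs:

* **ASM (approximate subgraph matching)** maps every node label *l* in the
  joint vocabulary to its bearing vertex (disconnected dummies fill gaps) and
  compares, per ordered label pair, the shortest paths between the mapped
  vertices via the feature map

  φ_distance(P) = ∏_{e∈P} W_e,  φ_forward(P) = ∏_{f∈P} W_f,
  φ_backward(P) = ∏_{b∈P} W_b,  φ_l(P) = ∏_{e∈P} W_e^{I_e^l}

  where W_e is the edge weight, f/b are forward/backward-traversed edges and
  I_e^l indicates that edge e bears dependency label l. The kernel is
  K(G₁,G₂) = Σ_{i≠j} φ(P¹_{ij}) · φ(P²_{ij}).

* **APG (all-path graph)** first turns each labelled edge l(a,b) into an
  unlabelled pair a→l→b through a new vertex labelled l, adds a disconnected
  left-to-right token chain whose vertices carry the lemma plus a position
  tag (before / entity1 / middle / entity2 / after), and computes the total
  connectivity over all directed paths, W = (I−A)⁻¹ − I (the Neumann series
  of the weighted adjacency matrix A). With the label allocation matrix L,
  the label-pair connectivity is Gᵐ = L W Lᵀ and the kernel is the Frobenius
  inner product K(G₁,G₂) = Σ_{ij} G₁ᵐ[i,j]·G₂ᵐ[i,j] over the label union.

Both kernels are cosine-normalized and fed to a precomputed-kernel SVM
(C = 1, untuned). Instance-level predictions are aggregated to document-level
concept pairs existentially (a pair is positive if any of its instances is),
and results are scored by precision/recall/F1 and AUC; paired classifiers are
compared with McNemar's test.

## Worked example

The enhanced parse of *"Seizures were caused by Alcohol and Fatigue"* is
cyclic in its undirected form (caused–alcohol–fatigue). For the entity pair
(seizures, fatigue), the shortest path runs through "caused": one backward
`nsubj` edge and one forward `nmod:by` edge, both on the entity path and so
weighted 0.9:

```python
>>> from relkern import fig1_fixture
>>> from relkern.asm import shortest_path, path_feature_map
>>> g, (e1, e2) = fig1_fixture()
>>> path_feature_map(shortest_path(g, e1, e2))
{'distance': 0.81, 'forward': 0.9, 'backward': 0.9,
 'edgelabel:nsubj': 0.9, 'edgelabel:nmod:by': 0.9}
```

`distance` is the weight product over the whole path (0.9² = 0.81);
`forward`/`backward` split it by traversal direction; the two edge-label
features record which grammatical relations the path uses.

End-to-end on a 100-document synthetic corpus (50 train / 50 test, ASM
kernel, document-level scoring):

```
P=1.000 R=0.625 F1=0.769 AUC=0.958
```

A command-line pipeline covers the same steps from files:
`relkern generate | build-instances | gram | train | predict | eval | mcnemar`.

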