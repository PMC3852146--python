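# plw — Probabilistic Local Walks for protein complex detection

`plw` detects protein complexes in protein–protein interaction (PPI)
networks. Complexes — sets of proteins that physically assemble to carry
out a function — manifest in an interactome as dense subgraphs, but
experimental PPI data is noisy: real interactions are missed and spurious
ones appear. `plw` is aimed at systems biologists who have an interactome
as a flat edge list (DIP/BioGRID-style) and want a reproducible,
near-linear-time complex prediction with match-based evaluation against a
curated catalogue such as CYC2008.

## The method

The detector follows a core-attachment model in four stages over the
undirected simple graph G = (V, E):

1. **Seed selection.** Every vertex v is scored
   `score(v) = deg(v) · density(G_v)`, where G_v is the subgraph induced
   by v and its neighbours and `density(G') = 2|E'| / (|V'|(|V'|−1))`.
   The top λ fraction (default λ = 0.3) become seeds — vertices central
   to dense, functionally homogeneous neighbourhoods.

2. **Common neighbour similarity.** Each edge (u, v) is weighted by the
   cosine similarity of the closed neighbourhoods V_u = {u} ∪ N_u and
   V_v = {v} ∪ N_v:
   `sim(u, v) = |V_u ∩ V_v| / √(|V_u||V_v|)`,
   i.e. `(c + 2)/√((deg u + 1)(deg v + 1))` for adjacent vertices with c
   shared partners. Proteins that interact with the same partners likely
   share function.

3. **Probabilistic local walks.** From each seed, w = 100 walks start
   with energy α = 2.00. At each step the walker moves to neighbour u of
   the current vertex v with probability `sim(v, u) / Σ_p sim(v, p)` and
   pays the penalty `γ = max(1 − sim(v, u), 0.01)` from its energy; the
   walk ends when the energy goes negative. Visits to non-seed vertices
   are counted. The energy budget confines each walk to the seed's
   α-vicinity, so distant proteins can never join a core.

4. **Core mining and attachment.** All nonzero counts are pooled;
   ln(visitCount) values whose z-score exceeds the upper-tail critical
   value at significance p = 0.005 mark core members. Each seed's core
   (seed + significant vertices, ≥ 3 members, deduplicated) is then
   expanded with every protein interacting with strictly more than half
   of the core.

Evaluation uses the neighbourhood affinity score
`NA(p, b) = |p ∩ b|² / (|p||b|)` with match threshold ω = 0.2, yielding
Ncp/Ncb, precision/recall/F-measure, and the complex-wise sensitivity Sn,
cluster-wise positive predictive value PPV and geometric accuracy
√(Sn·PPV).

A planted-complex generator (`plw.synthetic`) produces sparse
Erdős–Rényi backgrounds with embedded dense subgraphs and configurable
edge dropout plus the exact ground-truth catalogue, so the whole pipeline
is testable without any download.

## Worked example

Generate a 1000-protein synthetic interactome with 30 planted complexes,
run the detector, and score it against the ground truth:

```sh
plw synth --out-network net.tsv --out-truth truth.txt \
    --n-vertices 1000 --n-complexes 30 --dropout 0.1 --rng-seed 7
plw run --network net.tsv --out clusters.txt --rng-seed 7
plw evaluate --pred clusters.txt --benchmark truth.txt
```

which prints

```
stage=synth vertices=1000 edges=2986 complexes=30
stage=load vertices=993 edges=2986 self_loops_removed=0 duplicates_removed=0
stage=pipeline vertices=993 edges=2986 seeds=298 cores=101 clusters=49 mean_walk_length=3.7813
stage=write path=clusters.txt clusters=49
complexes=49 avg_size=6.00 covered=199 Ncp=42 Ncb=27 precision=0.857 recall=0.900 f_measure=0.878 sn=0.862 ppv=0.993 accuracy=0.925
```

Reading the numbers: 993 of the 1000 proteins appear in at least one
interaction; the top 30% (298) become seeds; walks average 3.78 steps;
101 cores survive the significance and size filters and collapse to 49
distinct clusters after attachment. Of those, 42 match a planted complex
at NA ≥ 0.2 (precision 0.857) and 27 of the 30 planted complexes are
found (recall 0.900), for an F-measure of 0.878; PPV 0.993 means the
predicted members are almost all genuine.

The same pipeline is available as a library, scikit-learn style:

```python
import networkx as nx
from plw import PLW, load_network

est = PLW(lam=0.3, alpha=2.0, w=100, random_state=7)
clusters = est.fit_predict(load_network("net.tsv"))   # ComplexSet
est.mean_walk_length_, len(est.cores_), len(est.clusters_)
```

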