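# Methods

## Model and assumptions

The detector assumes the two regularities that underpin core-attachment
complex prediction: (i) complex cores appear as dense regions of the PPI
graph, and (ii) core members are functionally homogeneous, which in the
absence of annotation data is proxied by *common neighbour similarity* —
proteins binding the same partners likely share biochemical properties.
The input graph is treated as undirected and simple; edge direction,
weights and interaction confidence scores in the source data are ignored
(only the first two columns of an edge list are read). The graph is not
restricted to its largest connected component; isolated vertices can only
enter via the synthetic generator or an explicit vertex list, since the
edge-list loader induces vertices from edges.

Closed neighbourhoods are used in the similarity: V_v = {v} ∪ N_v, so two
adjacent proteins always share at least themselves and the similarity of
every edge is strictly positive. Consequently every vertex with degree
≥ 1 has a well-defined transition distribution; the uniform fallback for
an all-zero similarity row is defensive and reachable only through
explicitly supplied edge labels.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lam`) | 0.3 | fraction of vertices, ranked by `deg · density`, expanded as seeds. The recommended operating point; larger λ yields more, noisier clusters. `x = round(λ·|V|)` with round-half-up; the ranking is deterministic (score, then degree, then ID). |
| α (`alpha`) | 2.00 | walk energy budget, in units of accumulated penalty. Chosen to cover neighbours-of-neighbours: most curated complexes have PPI diameter ≤ 2, and one "perfect" step costs ≈ 0 while a dissimilar step costs ≈ 1. |
| w | 100 | walks per seed. Visit counts scale linearly; 100 gives stable log-count z-scores at interactome scale. |
| γ floor (`gamma_floor`) | 0.01 | minimum per-step penalty, applied at model build; bounds any walk to ⌈α/0.01⌉ + 1 = 201 steps even across similarity-1 edges. |
| p (`significance`) | 0.005 | upper-tail significance level on z-scores of ln(visitCount); critical value ≈ 2.576. |
| min core size | 3 | cores with ≤ 2 proteins are discarded — pair detection reflects data quality more than clustering quality. |
| attachment threshold | 0.5 (strict) | a protein joins a cluster iff it interacts with **more than** half of the core; fixed, not exposed as a flag. |
| ω | 0.2 | neighbourhood-affinity match threshold in evaluation, inclusive (NA ≥ ω). |

## Design choices made where the design was open

* **Termination is post-deduction.** The step that drives the energy
  negative is taken, but the vertex it reaches is never counted: the
  count-then-move loop exits on the energy test before the next count.
  This reproduces the worked 10-step trace ending at −0.26 exactly.
* **Numerical guard at the zero boundary.** Penalties like 0.20 are not
  binary-exact, so "energy < 0" is implemented as
  `energy < −1e−9`; a budget that lands exactly on 0.00 (ten 0.20 steps
  from 2.00) still allows one more step, as the exact arithmetic implies.
* **Global z-score population.** One mean/sd pools all nonzero
  (seed, vertex) log-counts across seeds, matching the order of
  operations in the mining procedure (statistics first, per-seed
  selection second). Significance is one-tailed upper — only unusually
  *frequent* visitation indicates core membership. The sd is the
  population sd; at interactome scale the distinction from the sample sd
  is immaterial, but fixing it makes runs bit-reproducible.
* **PPV definition.** With T_ij = |b_i ∩ p_j|, PPV is the standard
  clustering-wise Σ_j max_i T_ij / Σ_j Σ_i T_ij (the printed source
  formula is garbled); Sn is Σ_i max_j T_ij / Σ_i |b_i| and accuracy
  their geometric mean.
* **Simultaneous attachment.** All candidates are evaluated against the
  original core; attachments never recruit further attachments. Duplicate
  clusters (distinct cores expanding to the same set) are collapsed.
* **Determinism.** One integer seed drives a single `numpy` Generator
  consumed sequentially over seeds in ranking order; identical
  configuration therefore yields byte-identical cluster files. Transition
  distributions are precomputed as cumulative arrays (O(log deg)
  inverse-CDF sampling).
* **Degenerate inputs.** Degree-0 vertices score 0 and are skipped as
  seeds with a warning; a degree-1 vertex's neighbourhood graph (2
  vertices, 1 edge) has density 1 by the formula. All-equal visit counts
  have zero log-variance: nothing is significant and no cores are mined
  (warned). An empty network or seed set produces empty output, not an
  error.

## The synthetic generator

`SyntheticSpec` plants `n_complexes` dense subgraphs (each intra-complex
edge present with probability `density`, then removed with probability
`edge_dropout`, emulating false-negative interactions) on an Erdős–Rényi
background G(n, p). Sizes are `3 + Poisson(3.68)` clipped to [3, 20]
(mean ≈ 6.68, matching the average size in the CYC2008 curated yeast
catalogue); `overlap_fraction` lets complexes share proteins, as real
catalogues do. The background is the weakest structural assumption that
still exercises noise handling; the generator does **not** reproduce the
heavy-tailed degree distribution, date-hub structure, or study bias of
real interactomes, so passing recovery tests demonstrates correctness of
the pipeline under the stated noise model, not field performance on real
data.

Test and acceptance problem sizes are the package's own scaling choices:
the end-to-end recovery check uses 1000-vertex networks with 30 planted
complexes (density 0.9, dropout 0.2, background p = 0.005, i.e. mean
background degree ≈ 5) over ten generator seeds; smaller unit fixtures
keep the same mean background degree (p ≈ 5/n) so that the pooled
log-count distribution remains representative at reduced n.

## Known limitations

* The significance cut is *relative*: it needs a pooled count
  distribution in which core visitation is an upper-tail event. On
  degenerate inputs where every seed sits in an equally dense region and
  there is no background — the extreme case being a bare clique as the
  whole graph — counts are near-uniform, no pair clears the cut, and no
  complex is reported even though the clique is a perfect core. Any
  realistic interactome (and any synthetic network with a background)
  provides the needed contrast.
* Overlapping cores are found only insofar as different seeds yield
  different significant sets; there is no explicit overlap control or
  merging of highly similar (non-identical) cores.
* λ is fixed by the user; no automatic selection is attempted.
* Benchmark proteins absent from the network are kept in benchmark sets,
  which deflates Sn/recall rather than inflating them.
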