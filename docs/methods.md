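# Methods

## Model and procedure

The package ranks the proteins of an undirected, unweighted PPI network
by a fused essentiality score. The pipeline is:

1. **Distances.** Per-node BFS hop distances within the node's own
   connected component. Disconnected networks are legal everywhere;
   nothing ever reaches across components.
2. **Local (fuzzy) fractal dimension.** For node *v* with eccentricity
   ecc(*v*), the sphere count B_v(r) is the number of nodes at distance
   ≤ r (center included) and the fuzzy sphere value N_v(r) is the mean
   Gaussian membership exp(−d²/(2r²)) over those same nodes. The
   dimensions D_v (LFD) and D_f(v) (LFFD) are the OLS slopes of
   ln B_v(r), resp. ln N_v(r), against ln r over r = 1..ecc(v).
3. **Compartment scores.** From a labeled reference set of essential and
   non-essential proteins with compartment annotations, each of the 11
   compartments gets the Bayes posterior P(E|C_i); a protein's SCS is
   the mean posterior over its compartments, 0 when unannotated. The
   reference set is supplied separately from the ranked network: in the
   yeast setting it is a curated genome-wide list, not the node set of
   any particular interaction dataset, so the two are deliberately
   decoupled in the API.
4. **Fusion and ranking.** LDS(v) = α·ND_f(v) + (1−α)·SCS(v) with ND_f
   the min-max-normalized LFFD; descending sort with deterministic
   tie-breaks.
5. **Evaluation.** Top-k essential counts and the six confusion-matrix
   ratios (SN, SP, PPV, NPV, F-measure, ACC) at a configurable cutoff,
   with every ranked protein not on the essential list treated as
   non-essential.

## Conventions that pin the numbers

- **Fit convention.** Unweighted ordinary least squares on
  (ln r, ln y) over *all* radii 1..ecc(v), including r = 1 (where
  ln r = 0); natural logarithms; no point dropping or weighting. This
  convention reproduces both canonical worked examples — the
  ball-growth tree's slope 0.8295 over B = [6, 11, 15, 19] and the kite
  hub's LFFD 0.2312 — to four decimal places, and both are regression
  tests.
- **Center inclusion.** The center participates in B_v(r) (the "+1")
  and contributes the e⁰ = 1 term to every N_v(r).
- **Degenerate nodes.** ecc(v) < 2 leaves fewer than two fit points;
  LFD and LFFD are then defined as exactly 0.0 (with a log warning), so
  isolated or leaf-component proteins rank lowest on topology. Nodes in
  small components with 2–3 radii are fitted as-is.
- **Radii are per-node.** Each node's fit runs to its own eccentricity,
  not to a global diameter.
- **Multi-compartment counting.** A protein annotated to several
  compartments contributes one count to each of them when forming
  P(C_i|E) and P(C_i|NE); the per-compartment probabilities therefore
  need not sum to 1. Algebraically the posterior then reduces to the
  count ratio n_ess_in_C / (n_ess_in_C + n_noness_in_C); the tests
  assert this identity and the total-probability identity on random
  tables.
- **Zero-probability compartments** (annotated on nobody in the
  reference set) score 0.0 with a warning rather than raising, so
  sparse synthetic data flows through.
- **Ties.** LDS ties are common because SCS takes few distinct values;
  they break by descending degree, then ascending protein ID, making
  every ranking fully deterministic.
- **Ratio conventions for baselines.** Betweenness is unnormalized
  (pair convention s < t); closeness is component-local,
  (n_comp − 1)/Σd; LID is implemented as the raw interaction count
  among a node's neighbors (the density reading divides by the possible
  pairs; the count reading is used here and pinned by tests).
- **0/0 metrics** are defined as 0.0 with a warning; they arise only on
  degenerate inputs.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | weight of topology vs. localization | 0.5 | endpoints allowed; α=1 is pure ND_f, α=0 pure SCS |
| cutoff | rank threshold separating predicted essential / non-essential | 1500 | the CLI clamps it to the network size with a warning |
| top-k grid | cutoffs for enrichment counts | 1000..1500 step 100 | |
| compartment vocabulary | allowed annotation names | the 11 listed in the README | configurable in `AnnotationTable` |

## Synthetic data generator

`ldsrank.datasets` emulates a yeast-interactome-like study without any
database download:

- **Topology:** preferential attachment (`n` nodes, `m` edges per new
  node, star-seeded), giving a connected, heavy-tailed network. Default
  n = 1000, m = 3 (mean degree ≈ 6, the density of the classical yeast
  DIP datasets).
- **Essentials:** ⌈fraction·n⌉ nodes sampled without replacement with
  probability ∝ degree^bias. Defaults fraction = 0.24 (the essential
  fraction of the classical yeast datasets) and bias = 2, a strong
  centrality–lethality coupling.
- **Annotations:** 1–3 compartments per protein, ~5% of proteins left
  unannotated; for essential proteins the sampling weight of a
  designated essential-rich subset (Nucleus, Mitochondrion, Cytosol) is
  multiplied by the enrichment factor (default 5; 1 is the null model).
- All stages draw sub-seeds from one `numpy` SeedSequence, so a dataset
  is bit-for-bit reproducible from a single integer.

What this does *not* emulate: false-positive/false-negative interaction
noise, study-specific ascertainment bias, correlated annotations, or
essentiality mechanisms beyond the degree bias. Passing tests on this
generator show the pipeline is internally correct and that the fused
score recovers planted signal; they do not certify performance on real
interactomes.

A consequence worth stating: because essentials are planted with
probability ∝ degree², raw degree is itself the generative covariate,
so the DC baseline is near-optimal at the very top of the list on this
synthetic data. The fused LDS ranking vastly exceeds the random-ranking
expectation there (≈82 vs 24 essentials in the top 100 at the default
seed) and peaks at intermediate α, but does not overtake DC — on real
data, where essentiality is not a deterministic function of degree and
localization carries independent signal, the fusion is the point.

## Numerical choices

- OLS via `numpy.polyfit` degree 1; tests cross-check against
  closed-form Σ-formula slopes at 1e-10.
- Subgraph centrality via the adjacency spectrum (networkx); the test
  oracle is an independent truncated Taylor series of exp(A).
- Membership values live in (0, 1]; fits therefore operate on strictly
  negative ln N values — no clipping is ever needed.
- All randomness in the generators flows through explicit integer
  seeds; nothing reads global RNG state.

## Known limitations

- LFFD is O(V·E) in the worst case (a BFS per node); fine for
  interactome scales (~10⁴ nodes), not tuned beyond that.
- No PSI-MI/MITAB parsing; the edge-list reader expects two-column TSV.
- No confidence-weighted edges or alternative membership kernels.
- The information-centrality and expression-based (PeC) comparison
  methods are out of scope: the first has no self-contained definition
  in this setting and the second requires expression profiles outside
  the package's data model.
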