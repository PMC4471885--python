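# Methods

## Spreading model

Propagation is simulated with a discrete-time SIR (susceptible →
infected → recovered) process under parallel update. Each news item
starts at a single source node, which receives it at time 0. At every
step, each currently infected node independently attempts to infect
each of its susceptible neighbors (out-neighbors on directed networks)
with probability μ, then recovers; newly infected nodes record the
current step as their reception time and act at the next step. A node
infected by several neighbors in the same step records that step once.
A cascade ends when no node is infected; an infected node gets exactly
one round of infection attempts.

A full spreading experiment draws one Bernoulli(*f*) submission per
node, so the number of news is Binomial(*N*, *f*) with mean *f·N*, and
runs each submitted news as an independent cascade. Each cascade draws
from a random substream keyed by the submitting node's id, derived from
the master seed via `numpy`'s `SeedSequence`; the record is therefore
invariant to cascade execution order and fully reproducible from one
integer seed. Assumptions worth keeping in mind: all cascades see the
same static network, cascades do not interact, recovery is immediate
after one infection round (no tunable recovery rate), and the time
origin of every news is its own submission step.

## Similarity scoring

All metrics are computed from the reception matrix *R* (nodes × news)
and time matrix *T* only. Writing *k_i* for the number of news node *i*
received (row sum of *R*), *d_α* for the audience of news *α* (column
sum), and CN_ij for the common-news count, the classic indices are
CN, Jaccard CN/(k_i+k_j−CN), RA Σ 1/d_α, LHN CN/(k_i k_j), cosine
CN/√(k_i k_j), hub-depressed CN/max(k_i,k_j), hub-promoted
CN/min(k_i,k_j), Sørensen 2·CN/(k_i+k_j) and preferential attachment
k_i·k_j. Zero denominators yield a score of 0 rather than NaN.

Temporal variants multiply each common-news term in the numerator by
w_α = 1/|T_iα − T_jα|, and set w_α = 0 when T_iα = T_jα (equal-time
receptions cannot reflect direct transmission). Three choices here were
genuinely open and are resolved as follows:

- the absolute time difference is used, because a similarity must be
  symmetric in (i, j);
- the weight applies to the numerator only — denominators keep their
  classic form, so the temporal index remains "the classic index with
  its evidence terms re-weighted" rather than a new normalisation;
- since time steps are integers, w_α ≤ 1, which makes every temporal
  index a term-wise lower bound of its classic counterpart (a property
  the test suite checks).

The all-pairs computation is a dense matrix product (*R Rᵀ* for the
counts; a per-news accumulation over audience blocks for the temporal
weights), verified pair-for-pair against the naive per-pair definitions
on random records. Cost is O(N²·M) time and O(N²) memory; networks up
to a few thousand nodes are comfortable on one core.

## Reconstruction and evaluation

The inferred network is the set of the *E* top-scoring candidate pairs,
*E* being the true link count (assumed known, as is standard for this
problem). Pairs strictly above the cutoff score are always selected;
remaining slots are filled by a uniform seed-controlled draw among
pairs tied exactly at the cutoff, and the tie-group size is reported —
score degeneracy (huge tie groups) is one of the two causes of
precision collapse, so it is kept diagnosable.

Evaluation uses:

- **sampled AUC**: n independent (true-link, non-link) draws with
  replacement; strict wins count 1, exact score ties 0.5; default
  n = 10⁵ (standard error ≤ 0.0016). An exhaustive rank-based AUC
  (mid-rank ties) is provided as the oracle for small networks.
- **precision**: overlap of the selected set with the true link set,
  divided by *E*.
- **degree correlation**: Pearson correlation between reconstructed and
  true degree vectors (total degree on directed networks). When either
  vector is constant — e.g. a regular ring — the statistic is undefined
  and NaN is returned; sweep aggregation uses NaN-aware means so
  degenerate realizations do not silently bias averages.
- **P₀ baseline**: E/C(N,2) undirected, E/(N(N−1)) directed — the mean
  precision of a uniformly random reconstruction.

Directed networks use ordered candidate pairs throughout (scores,
precision, P₀); spreading follows out-links, and component extraction
before evaluation uses weak connectivity.

## Synthetic networks and study conditions

Experiments run on Barabási–Albert networks (preferential attachment,
m = ⟨k⟩/2 links per added node, grown from a complete graph on m
nodes; heterogeneous degrees) and Watts–Strogatz networks (ring lattice
with ⟨k⟩/2 neighbors per side, each link rewired with probability p;
homogeneous degrees, E = N⟨k⟩/2 exactly). Default experiment
conditions are N = 500, ⟨k⟩ = 10, p = 0.1, f = 0.5, μ swept over
[0.02, 0.5], 50 realizations per cell; the bundled tests use a scaled
copy (N = 200, 10 realizations) so the full suite runs in well under a
minute of simulation per sweep. Sweep cells derive their seeds from
(master seed, metric index, μ index, f index, realization index), so
every cell is independently reproducible, and the network is redrawn
per realization unless a fixed topology is requested.

What the generator emulates — and what it does not: cascades are clean,
complete observations (every reception and its exact step is recorded),
the network is static, and all news follow identical SIR dynamics.
Real spreading data have missing and censored receptions, heterogeneous
per-item infectivity, and bursty clocks; passing tests here show the
estimator chain is correct under the model, not that the model fits any
particular empirical system. Real edge lists can be supplied to the
same pipeline for that purpose.

## Observed phenomenology and the special range

Under the default conditions the pipeline reproduces the expected
qualitative behavior: CN's AUC peaks at an interior μ near 1/⟨k⟩;
temporal metrics match classic ones at small μ and dominate them
strongly at μ ≥ 2/⟨k⟩ (where saturated cascades make reception sets
uninformative but reception *times* still order the spreading front);
and degree-punishing metrics (LHN most severely) develop negative
degree correlation over a mid-μ band while their top-E precision falls
toward P₀ — links get assigned to node pairs whose low news counts are
sampling noise, not structure.

The package ships an operational detector for that last regime:
`special_range_report` flags cells with mean AUC ≥ 0.7 and mean
precision ≤ 2·P₀ (both thresholds are arguments). One caveat from our
own measurements: on the scaled-down synthetic conditions above, the
joint condition is strict — as μ grows, LHN's AUC decays below 0.7
while its precision ratio is still ≈ 2.5–6× P₀, so the default detector
can report an empty set even though the collapse (negative degree
correlation, precision ratio → 1) is plainly visible in the sweep
table. When hunting the phenomenon on homogeneous networks at N of a
few hundred, inspect the sweep table directly or relax the AUC
threshold; on larger, degree-heterogeneous networks the separation is
wider.

## Numerical notes and limitations

- Reception matrices are kept dense (uint8); fine to N ≈ several
  thousand, not intended for million-node graphs.
- AUC sampling and tie-breaking use `numpy.random.Generator` seeded
  explicitly; identical seeds give bit-identical results.
- The sampled-AUC "random ranking ⇒ 0.5" check needs care: one fixed
  random score assignment has an exhaustive AUC that fluctuates by
  sd ≈ √((1/E + 1/(P−E))/12) around 0.5, so tight bands require either
  large E or averaging over independent assignments (the test suite
  does the latter).
- Partial or noisy time information is not modelled; temporal weights
  assume exact integer reception steps. Continuous-time dynamics,
  SIS/SEIR variants and complex contagion are out of scope.
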