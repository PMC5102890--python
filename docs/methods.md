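# Methods

## Scope

The package benchmarks six weighted, undirected community detection
algorithms on synthetic planted-partition matrices of three families: 0/1
sparse count graphs, sample Pearson correlation matrices, and reflected
Euclidean distance (EucD) matrices. No empirical data are processed;
directed, overlapping, thresholded-binary and resolution-swept analyses are
out of scope.

## Condition registries

Two fixed registries define the study (`commbench.conditions`): 28 count
conditions varying graph size (25–1000), average/maximum degree, mixing
parameter μ ∈ {0.1, 0.3} and community-size power-law exponent τ ∈ {1, 2};
and 39 similarity conditions varying graph size, within-community loading
range, community-size scheme, number of communities (1–20), between-community
factor correlation ("overlap" ∈ {0.1, 0.25, 0.75}), and community mean
offsets ("level differences" ∈ {0, 1, 5}). The number of time points is 502
for graphs up to 500 nodes and 1002 for 1000-node graphs — the stated lower
bounds, chosen so observations always outnumber nodes.

## Similarity-matrix generator

The population model is a confirmatory-factor structure: node i loads
λ_i ~ U(low, high) on its community's latent factor only; Φ is compound
symmetric with off-diagonals equal to the overlap; Θ = diag(1 − λ_i²)
completes unit variances, so R = ΛΦΛ′ + Θ is an exact correlation matrix.
Within-community population correlations are λ_iλ_j and between-community
ones overlap·λ_iλ_j, so planted communities are communities in the strong
sense whenever overlap < 1. R is verified positive semi-definite (eigenvalue
tolerance −1e−8) for every registry condition.

Time points are i.i.d. draws from N(μ, R) with node mean (k − 1)·level_diff
for community k — the assignment rule for level differences is a declared
convention, since only "level differences according to community" is
specified by the design. There is no autocorrelation: the matrices encode
lag-0 relations only. From one realization both similarity matrices are
computed: `np.corrcoef` across time, and pairwise Euclidean distances
reflected as |d_ij − max d| so the farthest pair maps to exactly 0 and the
distance ordering reverses. Diagonals are set to zero as the final
construction step, before any detection.

Unequal community-size schemes use a 3:1 large:small node ratio with
large:small community counts of 50/50 ("as many large as small"), 75/25
("more large") and 25/75 ("more small"), rescaled so sizes sum to N with the
last community absorbing the rounding remainder. For the 50/50 scheme this
reduces to large = 1.5·N/K and small = 0.5·N/K exactly.

What the generator does **not** emulate: hemodynamic filtering or
autocorrelated noise, scanner artifacts, non-Gaussian marginals, or planted
negative relationships. Loadings are strictly positive, so negative sample
correlations arise only from sampling noise around small positive population
values. This matters for one published observation: the original study
reports negative correlations at roughly half of all entries, which the
stated positive-loading construction cannot reproduce (we observe ~15–20%
negatives at overlap 0.1, far fewer at 0.25/0.75). The practical consequence
is that after negative-clipping our matrices remain dense, and Label
Propagation almost always collapses to a single community under community
overlap (pooled ARI ≈ 0.05 where ≈ 0.33 is reported at full scale). All
other headline contrasts are insensitive to this density difference.

## Count-matrix generator

Degrees are drawn from a continuous power law x^−2 truncated at max_degree,
with the lower cutoff solved numerically (Brent) so the distribution's mean
equals the condition's average degree; draws are rounded to integers in
[1, max_degree] and the total is forced even. Community sizes follow a power
law with exponent τ, bounded below by max_degree + 1 (so any node fits its
internal degree — this also guarantees the strong-community property in
expectation for μ < 0.5) and above by ceil(0.2·N), minimally widened when
that point bound admits no integer partition of N (needed for the 75-node
conditions, where max_degree + 1 = 16 > 0.2·75).

Each node's external degree is μ·k in expectation via stochastic rounding
(floor plus a Bernoulli on the fractional part). Deterministic rounding was
rejected: at μ = 0.1 it zeroes the external degree of every node with k < 5,
detaching communities entirely in the small-graph conditions and collapsing
realized mixing, whereas the expectation-preserving split keeps realized
mixing within 0.01 of μ at N ≥ 500 and reproduces the published
small-graph difficulty. Internal stub sums are made even per community and
repaired to a graphical (Erdős–Gallai) sequence by shifting stubs external;
stubs are then matched by configuration-model pairing with local rewiring
rejecting self-loops, multi-edges and (for external stubs) within-community
pairs. Infeasible splits — possible at very small stub counts — are retried
with a fresh split; a final relaxed attempt drops unresolvable external stub
pairs (a bounded degree shortfall). At μ = 0 parity-freed stubs are dropped
rather than externalized, so zero mixing yields exactly zero
between-community edges.

Known limitation: the continuous-power-law degree tail reaches down to
degree ≈ 3 in the N = 500 conditions, and such nodes are occasionally
misplaced by Walktrap (ARI 0.98–0.99 instead of 1.00), which lowers the
perfect-recovery percentage on large count graphs below the published 100%.
The reference LFR binary's exact degree bounds are not published; we did not
tune ours to match.

## Detection layer

All methods share one contract (`fit(X) → labels_` with labels canonicalized
to 1..K by first appearance): negatives are clipped to zero for every method
except the signed Louvain, which receives the signed matrix; count matrices
pass through unchanged; an all-zero matrix after clipping is a degenerate
input error. Walktrap (walk length 4), Fast Modularity, Label Propagation
and Infomap delegate to python-igraph. Non-deterministic methods draw igraph
randomness through Python's `random`, seeded per run, so every run is
reproducible; deterministic methods run under a fixed internal seed.

Newman's spectral approach is implemented directly as plain iterative
bisection on the modularity matrix B = W − kk′/2w (generalized form for
subgraphs), splitting along the sign of the leading eigenvector of a dense
symmetric eigendecomposition and stopping when the split no longer increases
modularity; no Kernighan–Lin refinement is applied. A dense solver is used
because ARPACK-based routines carry mutable state across calls that breaks
bitwise reproducibility; near-zero eigenvector entries (degenerate leading
eigenspace) are grouped with the positive side rather than split by
numerical noise.

The signed Louvain optimizes
Q = c⁺ Σ_c [W⁺_in(c) − S⁺(c)²/2w⁺] − c⁻ Σ_c [W⁻_in(c) − S⁻(c)²/2w⁻]
with c⁺ = c⁻ = 1/(2w⁺ + 2w⁻) by default — the Gómez–Jensen–Arenas (GJA)
weighting the method's name refers to; the asymmetric alternative
(c⁺ = 1/2w⁺) is available via `objective="sta"`. Optimization is two-phase
Louvain (random-order local moves, then community aggregation) with a 1e−12
move-gain tolerance, ties resolved in favor of staying.

## Scoring conventions

Modularity and the modularity ratio MR = Q^r/Q^max are always computed on
the clipped nonnegative matrix — including for the signed Louvain's output —
so MR is comparable across methods; the signed objective is a detection-time
concern only. MR is recorded as missing (not zero) when the planted
partition's modularity is zero (e.g. the one-community condition), and is
not clamped: recovered partitions can out-score the planted one. Majority
placement uses the ≥ 50% threshold with the membership fraction computed
over the full true community including the node itself; both choices are
explicit in the implementation and the threshold direction is the printed
formula's (≥, not the prose's >). The ARI is computed from pair counts and
verified against brute-force pair enumeration and an independent library
implementation to 1e−12.

## Orchestration, seeds, replication scales

One master seed drives everything. Child seeds derive from
`SeedSequence(master, spawn_key=(stream, condition, replicate, …))`, recorded
in every instance and record, so re-running a study yields byte-identical
record CSVs. The `paper` preset uses 100 replicates per condition; the `desk`
preset (3 replicates) runs the identical pipeline at reduced replication —
only Monte Carlo error changes. The acceptance script uses 3–10 replicates
per condition and the test suite 1–3; at these scales a per-condition mean
ARI carries sampling error of roughly ±0.05–0.15 for the unstable
method/condition pairs and essentially none for the stable ones.

Condition regressions z-score the ARI and the dummy-coded condition
indicators and report OLS coefficients; reference categories are the
smallest graph size and the typical factor levels (equal sizes, low overlap,
0.25–0.95 loadings, low μ, low degree rank). Constant or collinear dummies
are dropped with a warning. The "MR coherence" effect size is the Pearson
correlation between per-record ARI and MR, pooled over the selected
conditions with missing-MR records excluded pairwise — an interpretation
choice, since the published table calls it only an "effect size". Matrix
types are fit separately throughout.

## What passing tests do and do not show

Green results here demonstrate that the algorithms behave as published on
matrices with exactly the planted structure described above: Gaussian
lag-0 similarity data with positive within-community loadings, and simple
power-law count graphs with controlled mixing. They do not certify behavior
on empirical connectivity data, which adds autocorrelation, measurement
artifacts, genuine negative coupling, and community structure that is at
best approximately block-like.
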