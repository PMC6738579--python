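# Methods

## The model

An architecture is a rooted tree `G = (V, E)` embedded in 3D (millimetres).
`V` contains the base `v₀`, the terminal organs `v₁…vₙ` (rosette leaves,
cauline leaves, flowers, siliques — always leaves of the tree), and any
number of interior branch/bend points. Edges are straight segments; their
length is the Euclidean distance between endpoints; edges are undirected
for every distance computation (nutrients flow both ways), and the rooting
is used only for traversal and child counting.

Two objectives are in tension:

    Travel(G) = Σᵢ dist_E(v₀, vᵢ)        (performance; path length summed
                                          over terminal organs only)
    Length(G) = Σⱼ |Eⱼ|                  (cost; all edges, bends included)

and the joint objective for a weight `α ∈ [0, 1]` is
`α·Travel(G) + (1−α)·Length(G)`. `α = 1` is solved exactly by the Satellite
(star) tree; `α = 0` is the Euclidean Steiner tree problem, which is
NP-hard, so the whole family is approximated by a greedy construction.

## Greedy construction and the front

The greedy algorithm starts from `{v₀}` and runs exactly `n` insertion
steps. Adding an unconnected terminal `u` via an in-tree point `w` changes
the joint objective by exactly
`α·(d_root(w) + ‖u−w‖) + (1−α)·‖u−w‖`, so each step minimizes this
increment over all `(u, w)` pairs, where `w` ranges over every in-tree
point including previously created subdivision points. The chosen edge is
subdivided by `k = 10` equidistant interior points (candidate branch points
for later steps, `d_root` interpolated linearly). Ties are broken toward
the smallest-index terminal, then the earliest-created in-tree point — the
root first — which makes `α = 1` reproduce the Satellite star exactly even
with collinear subdivision points.

The Pareto front is the set of `(α, Length, Travel)` triples over the
default grid `α = 0.00, 0.01, …, 1.00` (101 greedy trees). Because the
greedy solution is approximate, occasional entries are dominated by
neighbours; dominance is resolved explicitly in the ε geometry below.

## Distance to the front (ε)

Non-dominated front points, sorted by length, form a strictly monotone
staircase. They are joined piecewise-linearly and extended by a vertical
ray above the minimum-length end and a horizontal ray beyond the
minimum-travel end, so the ray from the origin through the plant's
`(Length, Travel)` point always meets the curve. ε is the factor by which
the front must be inflated about the origin to pass through the plant:
if the ray meets the curve at `q`, `ε = ‖plant‖ / ‖q‖`. A plant on the
(pruned) front gets exactly 1; interpolation removes grid artifacts
relative to scaling a discrete point set and converges to the same answer
as the grid refines. Because the greedy front is approximate, ε < 1 is
possible and is reported unclamped. ε is invariant under global rescaling
of coordinates and scales linearly if both plant objectives are inflated
together — both properties are under test.

Note one consequence of pruning: a tree built at a grid α whose entry is
itself dominated sits marginally outside the interpolated staircase, so its
ε can exceed 1 by a fraction of a percent. This is faithful — that tree is
genuinely beaten on both objectives by other trees in the family.

## Closest α and the trade-off ratio

The closest-α feature returns the grid α whose entry lies nearest the plant
in normalized coordinates (length divided by the α = 0 entry's length,
travel by the α = 1 entry's travel), so both axes are measured relative to
their individual optima; raw-unit distance is available via
`normalize=False`. Adjacent grid values often produce identical greedy
trees; ties resolve to the smallest α of the identical run.

The Pareto trade-off ratio is

    (Length_plant / Length_Steiner) / (Travel_plant / Travel_Satellite)

with `Travel_Satellite = Σ‖v₀−vᵢ‖` in closed form and `Length_Steiner`
taken from the α = 0 greedy entry — the only Steiner proxy the pipeline
constructs. The ratio is dimensionless and scale-invariant; high values
mean the plant spends excess length to keep travel short.

## Baselines

All baselines take the identical point set `v₀…vₙ`:

- **Stable** — a hub at the terminal centroid, a stem from `v₀`, spokes to
  each terminal. If the centroid coincides with `v₀` or a terminal (within
  1e−9 mm) the coincident nodes are merged rather than creating a
  zero-length edge.
- **PrefAttach** — Barabási–Albert with m = 1: all `n+1` points (the base
  included) arrive in a uniformly random order, the first two are joined,
  and each arrival attaches to an existing node with probability
  proportional to its degree (repeated-endpoint sampling). Always a tree.
- **Random** — a uniform labeled spanning tree via Wilson's loop-erased
  random walk on the unweighted complete graph; edge lengths enter only the
  objectives. The test suite checks uniformity against the Prüfer-sequence
  bijection (exhaustive enumeration at |V| ∈ {3, 4}, chi-square).

Every stochastic operation takes an explicit integer seed; ensembles derive
per-replicate seeds from one root seed through `numpy.random.SeedSequence`.

- **Sugar-transport reference** — the complete leaf-to-flower bipartite
  graph, whose transport distance and construction cost both equal the
  aggregated straight-line distance over all (leaf, flower-or-silique)
  pairs. The aggregate is a **sum** by default (consistent with the travel
  objective, which also sums over endpoints); a mean is available via the
  `aggregate` switch, and siliques count as flowers. The plant-vs-bipartite
  comparison reports how much worse the plant's summed leaf-to-flower
  tree-path distance is (percent of the bipartite optimum) and how much
  more the bipartite graph would cost to build (percent of the plant's
  length) — the second number is phrased as "cost lower than the
  bipartite's" since a cost cannot be more than 100% below a baseline.

## Statistics

- Coefficient of variation: sample SD (n−1 denominator) over mean. The n−1
  estimator is used throughout because genotype ensembles are small
  (5–11 replicates).
- Genotype comparisons: two-sample two-sided KS (exact for small samples,
  asymptotic otherwise), significant iff `p < 0.05 / n_comparisons`, with
  the Bonferroni divisor always an explicit argument (10 mutants in the
  motivating panel).
- Plant-vs-baseline: one-sided binomial test on paired front distances; a
  success is a baseline draw strictly closer to the front than the plant,
  ties count against the plant (they are measure-zero for continuous
  objectives), and the alternative is "successes are rare". The one-sided
  choice matches the directional claim being tested; calibration under the
  null is itself a test.

## The synthetic generator

The generator provides study conditions with known ground truth, because
the analysis needs inputs whose "true" prioritization weight is known.
Defaults describe a Columbia-wildtype-like plant: 15 rosette leaves on a
jittered ~40 mm ring at z ≤ 20 mm (the rosette is Satellite-like), a
350 mm inflorescence with 3 side branches carrying 3 cauline leaves and 12
flowers/siliques, `α* = 0.143`, 2 mm coordinate noise. Replicate diversity
has two sources: a per-plant lognormal size factor (σ = 0.3, matching the
replicate-to-replicate spread of total length reported for real genotype
panels, CoV ≈ 0.35) and uniform count jitter (±2 by default) on organ
counts.

Plants are built **by the greedy mechanism itself** at `α*`, then interior
nodes are displaced by Gaussian curvature noise (sd = 1% of the parent
edge's length). This is deliberately *not* a developmental model: it is
the minimal structure under which "near-front architectures with stable
trade-off ratios" is exactly true by construction, which makes every
pipeline contract testable — ε slightly above 1 (the curvature inflates
both objectives a few percent, typical ε ≈ 1.05–1.08), trade-off monotone
in `α*`, and dimensionless features invariant to the size factor. Terminals
that acquire children during greedy growth hand those children to their
parent subdivision point so organ labels stay on leaves. Growth series
extend one plant online: later time points attach new terminals greedily
without disturbing existing structure, so each snapshot is a subgraph of
the next and shares its curvature displacements.

What passing tests therefore show: the pipeline's machinery (front
construction, ε geometry, feature extraction, statistics) behaves correctly
on architectures with the stated geometry and ground truth. What they do
not show: that real scanned plants are near-front — the generator assumes
the very mechanism the analysis detects, and real skeletons bring manual
tracing choices, non-greedy topology, and organ-placement biology the
generator does not model.

## Numerical choices and problem sizes

- Degenerate convex hulls (fewer than 4 points, or coplanar/collinear
  node sets) get volume 0 rather than an error.
- Branch points are nodes with ≥ 2 children in the rooted tree (the root
  counts if it has ≥ 2 children).
- The rosette-excluded re-analysis prunes excluded terminal nodes, strips
  dangling interior stubs iteratively, and re-runs the full pipeline on the
  pruned skeleton; the plant's length is recomputed on that pruned skeleton
  so numerator and denominator of the trade-off describe the same
  structure.
- Coordinates round-trip bit-exactly through JSON; CSV serializes 6
  decimal places.
- Simulation-based tests run at desk scale chosen for a single CPU: 30
  scans with 200 baseline draws each for the ordering comparison, 20
  replicate simulations of 6 plants for the CoV comparisons, 1,000
  repetitions of 10-vs-10 ensembles for the separation power check, and
  64,000 draws for sampler uniformity. The analysis scripts use 8
  replicates per genotype and 4 growth time points.

## Known limitations

- The greedy front is an approximation; no optimality guarantee is claimed
  beyond the small-instance brute-force comparisons in the tests.
- Branch radii, branch angles, and light capture are outside the model:
  two architectures over the same points with different branch angles get
  identical fronts.
- Hull volume is computed over skeleton node coordinates, not raw scan
  cloud points — a deliberate deviation (point clouds are out of scope),
  so absolute volumes are smaller than cloud-based ones, though equally
  usable for variability comparisons.
- The generator's branch-point variability is structural (driven by organ
  counts), which is tamer than the annotator- and biology-driven
  variability of traced skeletons.
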