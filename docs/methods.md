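# Methods

## Scope and model

rppaflow implements a two-stage prioritization of upstream signaling
regulators from paired RPPA time courses:

1. a **conservation screen** that finds proteins whose baseline-normalized
   trajectories are strongly linearly related between two cell lines, and
2. a **network-flow ranking** that scores candidate regulators by the
   maximum signal flow they can drive through a typed signaling network to
   downstream sink genes.

The premise is that a regulator's importance in a response is set not only
by its own expression change but by its connectivity: a molecule of modest
fold-change can still be the network's bottleneck controller. Maximum flow
operationalizes this — flow from a source molecule to a sink gene measures
how much of the network's signaling capacity that molecule can mobilize.

## Baseline normalization

Trajectories are normalized to the pre-treatment time point: division on
the linear scale (fold-changes; the baseline column becomes exactly 1),
subtraction on the log2 scale (the baseline column becomes 0). The matrix
carries an explicit `scale` flag because fold-change division and log-ratio
subtraction are only equivalent after a log transform; the default
assumption for intensity data is linear. A consequence the user should
know: after normalization every protein's series passes exactly through the
point (1, 1), which makes the null distribution of downstream slope tests
mildly anti-conservative (measured ≈ 0.07 rejections at nominal 0.05 for
six-point series). This is intrinsic to regressing anchored fold-change
series, not an implementation artifact; the screen's realized error rates
are therefore validated by simulation (below) rather than assumed from the
nominal level.

For heat-map display a separate transform standardizes each antibody
(log2, center, scale by sample standard deviation, n − 1 denominator) and
clusters rows with Euclidean distance and complete agglomeration. Rows are
pre-sorted lexicographically so linkage ties resolve deterministically;
zero-variance antibodies are emitted as all-zero rows and flagged rather
than dropped, preserving row alignment with the screen output.

## The screen

Per protein, OLS with intercept regresses the response cell line's
trajectory on the predictor cell line's; the slope p-value is the two-sided
t-test with n − 2 degrees of freedom and r is the Pearson correlation of
the paired series (with an intercept these are mutually consistent:
r² equals the regression's R²). Panel-wide p-values are adjusted by the
Benjamini–Hochberg step-up procedure — the standard choice where the FDR
procedure is otherwise unspecified — and recorded as such in output
provenance. Selection requires q < `fdr_max` (default 0.3) and
`r_min` < r ≤ `r_max` (defaults 0.7, 1.0; the lower bound is strict because
the screen targets correlations *exceeding* 0.7). Zero-variance series
yield flagged, never-selected records instead of errors so protein counts
stay synchronized. The permissive FDR of 0.3 trades specificity for
sensitivity deliberately: the screen feeds a network stage that tolerates
false positives, while a missed true regulator cannot be recovered later.

## Flow networks and capacity schemes

Relationship classes map to nonnegative integer capacities. Integrality
guarantees Ford–Fulkerson termination and integer flows. Undirected
interaction edges become antiparallel arc pairs at full capacity each (the
standard reduction; a single such edge still carries at most its one-way
capacity for any single s–t query); parallel arcs merge by capacity
summation; zero-capacity arcs are dropped. Because the relative weighting
of interaction vs. indirect vs. direct control is a modeling choice with no
principled single value, the ranking sweeps ten schemes — (interaction,
indirect, direct) = (1,1,1), (1,1,2), (1,2,2), (1,2,3), (1,2,4), (1,3,5),
(2,2,3), (2,3,4), (1,4,4), (2,3,5) — spanning uniform to strongly
direct-weighted regimes while keeping direct ≥ indirect ≥ interaction. The
set is fully overridable in configuration.

## Maximum flow

The solver is Edmonds–Karp: breadth-first search finds a shortest
augmenting path in the residual graph, the bottleneck is pushed, and the
loop ends when the sink is unreachable — at most |V|·|E| augmentations.
Neighbors are explored in lexicographic order, making the augmenting-path
log byte-reproducible across platforms. The implementation uses the
skew-symmetric net-flow formulation, so flows along antiparallel arcs
cancel; reported per-arc flows are the positive parts, which satisfy
capacity bounds and conservation. The min cut is extracted as the arcs
leaving the residual-reachable set; its capacity equals the flow value
(max-flow min-cut), which the test suite checks against an exhaustive s–t
cut enumeration oracle (all 2^(|V|−2) bipartitions, feasible to 12
intermediate nodes) and against networkx as a second independent reference.

## Candidate scoring

For every (capacity scheme, sink) combination, max flow is computed from
every candidate source (default: all non-sink molecules that can emit
signal; a curated regulator whitelist may be supplied instead). Each
combination identifies its regulator(s) once: sources attaining the maximal
flow value earn one source credit (ties all credited; combinations where no
source achieves positive flow credit nobody), and molecules lying on the
winning flow's arcs — excluding the winning run's own source and the sink —
earn one path credit. Credits therefore count *identification events* (at
most one per category per scheme–sink combination), not raw runs; counting
every run instead would let molecules adjacent to the sink accumulate path
credit from every source's query and drown the regulators the sweep is
meant to surface. Ranking is by total credit, dense and 1-based, with
lexicographic ordering among ties; path credit on the final flow assignment
(rather than the augmenting-path decomposition, which is algorithm-order
dependent) is used, though both are exposed for inspection.

## Synthetic benchmarks

The generators define the study conditions under which the pipeline is
validated:

- **RPPA panels** — 100 proteins × 6 time points per cell line, all series
  anchored at exactly 1 at baseline. Twenty planted proteins share a latent
  trajectory (a baseline-anchored Gaussian random walk, step sd 0.3, giving
  fold-change excursions in the realistic 0.5–2× range); cell line B sees an
  affine image of it, slope drawn uniformly in [0.5, 2] with intercept fixed
  at 1 − slope so the affine map carries baseline to baseline, plus Gaussian
  noise of sd 0.05 at non-baseline points. The walk's amplitude is shrunk
  when needed so both the latent and its affine image stay positive —
  clamping would break the exact affine relation the benchmark plants.
  Decoys are generated independently in each cell line; the default decoy
  model is iid Gaussian fluctuation about the baseline (sd 0.3), under which
  null slope p-values are approximately uniform and the BH guarantee
  applies. An `independent-random-walk` decoy model is also provided as a
  deliberately harder regime: autocorrelated series exhibit spurious linear
  trends (the classic spurious-regression effect), inflating the realized
  false-discovery proportion well beyond the nominal FDR level, which is why
  it is not the default validation condition.
- **Planted-hub networks** — 50 nodes, two sinks (CCNB1, CCND1), a hub with
  six direct-control edges onto intermediates that each feed every sink, and
  decoy nodes emitting at most two random edges (class probabilities 0.5
  interaction / 0.3 direct / 0.2 indirect; interaction edges undirected).
  The hub's flow advantage is structural, so its rank-1 recovery tests the
  whole build-flow-score path, not a tuned constant.
- **Flow fixtures** — named small networks (single edge, disconnected,
  diamond, random ≤ 8 nodes with capacities ≤ 9) whose `true_max_flow` is
  always computed by cut enumeration at generation time, never stored as an
  assumed constant. Random fixtures are capped at 8 nodes so enumeration
  stays well under a second.

One global seed fans out to per-stage substreams via
`numpy.random.SeedSequence`, so any stage re-run in isolation reproduces its
data bitwise.

What the synthetic data does *not* emulate: RPPA slide-level artifacts,
antibody cross-reactivity, replicate noise structure, or the connector
molecules a curated pathway tool inserts between seed proteins. Passing the
planted-recovery benchmarks shows the statistical machinery and the flow
analytics are correct under the stated noise model; it does not certify
recovery rates on real panels, whose noise is unknown.

## Validated performance (computed by the test suite and acceptance script)

Under the default study conditions: planted-protein recovery averages
≈ 99.7% over 200 seeded panels with the realized false proportion among
q < 0.3 calls at ≈ 0.30 (the nominal FDR level, within Monte-Carlo error)
and planted median r ≈ 0.99; the Edmonds–Karp value agrees with exhaustive
min-cut enumeration on 100% of 500 random graphs; the planted hub attains
rank 1 in 100% of 100 networks; repeated pipeline runs are byte-identical.

## Numerical and design notes

- Float output uses the `%.10g` format everywhere, which is what makes
  repeated runs byte-comparable.
- The regression direction (which cell line predicts which) and the choice
  of linear vs. log2 screen inputs are configuration, not hard-coded.
- `--restrict-to-screen` optionally prunes the network to screen-selected
  molecules plus sinks before the flow stage; the default flows over the
  full supplied network, since curated networks legitimately contain
  connector molecules that are not on the screen list.
- Degenerate inputs: source = sink is an error; a source or sink absent
  from the network yields flow 0 with a warning-level result rather than an
  error, so whitelist sweeps over partial networks do not abort.
- The pipeline aborts on the first stage error, naming the stage; warnings
  (dropped self-loops, collapsed duplicate edges, zero-variance antibodies)
  are counted and reported, never silently applied.

## Limitations

- The screen is per-protein simple linear regression; it models neither
  autocorrelation within a trajectory nor time-course shape, and the
  anchored baseline point makes nominal p-values slightly optimistic (the
  simulation-validated error rates above are the operative guarantees).
- Flow capacities are class-level integers; edge-specific confidences,
  signs (activation vs. inhibition) and min-cost or multi-commodity flow
  variants are out of scope.
- The credit-counting rule is one explicit operationalization of "how often
  is a molecule identified"; alternatives (e.g. per-run counting) change
  the ranking's character and are intentionally not blended.
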