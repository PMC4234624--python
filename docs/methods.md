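# Methods

`cohortnet` analyzes the early history of a social network: weekly directed
"A named B" graphs collected from a forming cohort (the motivating setting
is ~140–170 first-year students reporting whom they talked with about
problem solving, once a week over a seven-week course), together with a
per-student table of categorical attributes (gender, one of seven
pre-assigned recitation/lab *sections*, and an end-of-course grade on the
Danish 7-step scale). This note records the models, the parameter choices,
the numerical conventions, and the known limits of what the synthetic test
bed can show.

## Network preparation

A week's raw edge list may contain self-loops and duplicate ordered pairs;
`simplify` removes both and keeps the node set (a node whose only incident
link was a self-loop survives as an isolate, with a logged warning). Weeks
can be pooled with `merge_weeks` (edge-set union, then simplification) —
the standard preparation when early weeks are sparsely answered, and the
preparation the default pipeline mirrors by pooling weeks 1–2. A node
belongs to a week's network iff it appears as namer or named that week;
never-named, never-naming students are not represented.

## Link turnover

For the ordered weekly edge sets `E(t)`:

* `E_new(t) = |E(t) \ E(t-1)|` — links absent from the preceding week only
  (no memory of earlier weeks);
* `E_re(t) = |E(t) ∩ (E(1) ∪ … ∪ E(t-1))|` — re-established links;
* `f_new(t)` — fraction of `E(t)` never seen in any earlier week.

First-week convention: `E_new = E_tot`, `E_re = 0`. The two counts do not
partition `E_tot`: a link can be new relative to `t-1` yet re-established
relative to `t-2`. Degree summaries report the cumulative distribution
`P(K ≥ k)`, the moment-based standard deviation `sqrt(<k²> − <k>²)`, and —
because conventions differ on whether spread bars show the dispersion or
the uncertainty of the mean — also `sd/√n`. The diameter of a (possibly
disconnected) digraph is the maximum *finite* directed eccentricity;
unreachable ordered pairs are ignored, and a network with no edges has
diameter 0. Weekly density is `E_tot / (N(N−1))` with `N` that week's node
count.

## Map-equation community detection

Communities are found by minimizing the two-level map equation on the
directed graph. A walker follows a uniformly chosen out-link with
probability `1 − τ` and teleports to a uniform node with probability `τ`
(always, from a node without out-links); its stationary visit rates `p_i`
are computed by power iteration to an L1 fixed-point tolerance of 1e-12.
A partition M into modules with aggregate visit rates `p_k` and exit rates
`q_k` is scored in bits per step:

    L(M) = q·H(Q) + Σ_k (q_k + p_k)·H(P_k),

with `q = Σ q_k`, `H(Q)` the entropy of the normalized exit rates and
`H(P_k)` the entropy of module k's codebook (member visit rates plus the
exit rate, normalized). Exit rates include teleportation flow ("recorded"
teleportation), so a one-module partition has `q = 0` and `L` equal to the
entropy of the visit rates exactly. This accounting reproduces igraph's
`community_infomap` codelength to ~1e-13 on shared inputs, which the test
suite uses as an independent cross-check; the detector itself is our own.

Minimization is greedy and seeded: each run starts from singletons and
alternates randomized node-move sweeps (candidate targets: modules of in-
and out-neighbours, a fresh singleton, and — while at most 16 modules are
occupied — every module) with best-improving module merges, until `L` stops
decreasing; `L` is tracked incrementally so a candidate move costs
O(degree). The best of `n_runs` runs (default 100) is returned, ties broken
by the lexicographically smallest canonical labeling; labels are canonical
by decreasing size, then smallest member id. On every ≤8-node test digraph
the detector attains the exhaustive minimum over all set partitions
(Bell-number enumeration in the tests). τ defaults to 0.15, the
conventional teleportation rate. Directed modularity
`Q = (1/E) Σ_ij [A_ij − k_i^out k_j^in / E] δ(c_i,c_j)` is reported
alongside, and `run_stability` measures between-run variation of
information over consecutive single runs.

## Partition distances

Two partitions are compared on their overlapping nodes ("reduced
groupings"): the confusion matrix `N_kl` counts shared members between
module k of X and module l of Y, and

    VI(X,Y) = H(X) + H(Y) − 2·I(X;Y) = 2·H(XY) − H(X) − H(Y)

in bits (base-2 logs, `0·log 0 = 0`). VI is a metric bounded by
`log2(n_overlap)`; for overlaps between 102 and 160 nodes the bound runs
from 6.67 to 7.32 bits.

## Segregation

For a partition and a categorical attribute with week-specific global
distribution `p(a)` (computed from the partitioned nodes themselves), each
group's segregation is the KL divergence `D_k = Σ_a p_k(a) log2(p_k(a)/p(a))`
and the network's is the size-weighted total `S = Σ_k (n_k/n) D_k`. `S` is
0 when every group mirrors the cohort and equals the Shannon entropy of
`p(a)` under perfect segregation (each group pure) — both limits are
closed-form test anchors. Significance comes from a permutation null: the
observed attribute values are re-assigned uniformly at random to the
partitioned nodes (multiset preserved, network and partition fixed;
default 1000 permutations, vectorized), and `Z = (S_obs − mean_null)/sd_null`.
`|Z| > 1.96` is flagged, the same two-sided 5% convention at network and
group level. A degenerate null (zero spread, e.g. a constant attribute or
a single all-covering group) raises an explicit error at network level and
yields NaN per group. Grade is treated as unordered categories here; the
divergence uses category identity only.

## Alluvial diagrams and flow maps

The alluvial diagram assigns each week a column of community boxes with
height proportional to membership count (one scale factor for the whole
figure), ordered by decreasing size, and draws one streamline per nonzero
confusion-matrix entry between adjacent weeks, thickness proportional to
the student count and stacked by descending count. Boxes are colored by
per-group segregation significance: dark red (section), green (gender),
purple (both), gray otherwise. Flow maps summarize one week at community
level: node size is accumulated visit rate `Σ_{i∈C} p_i`, arrows the
inter-community per-step walk flow with teleportation included (the same
accounting as the map equation). SVG is the sole render target — geometry
carries `data-` attributes so every count and flow can be read back from
the file without a display.

## Synthetic cohort generator

The generator is the package's test bed and defines the conditions under
which the statistical claims are exercised. Defaults: 160 students, 7
sections (balanced within ±1), gender split 0.30 F, grades i.i.d. from a
7-step distribution independent of everything else, 7 weeks, participation
declining linearly 0.78 → 0.48, Poisson mean out-degree 5, persistence
0.85, section homophily weight 8, gender homophily weight 2. Each week
every student is active independently with that week's participation
probability; an active student emits Poisson(5) namings, each re-using a
uniformly chosen past out-partner with probability `persistence` and
otherwise drawing a new partner with probability proportional to
`8^[same section] · 2^[same gender]`; the week is then simplified.
Replicate k of an experiment uses seed `base + k`.

The persistence default was calibrated against the target regime the
generator is meant to emulate — roughly half of each week's links new
relative to the preceding week, a growing re-established fraction, and
~5% of the N(N−1) possible links ever used. At 0.85 the defaults give
~64% week-over-week new links, a completely-new fraction falling to ~0.17
by week 7, and ~1160 unique links (~4.6% saturation). The residual gap to
50% is structural: weekly activity is drawn i.i.d., so about
`1 − participation` of each week's links are "new" simply because the
namer was absent the week before, whereas real survey participation is
strongly autocorrelated.

What the generator does *not* emulate: reciprocity and transitivity.
Links are drawn independently per namer, so the graph lacks the tight
mutual clusters real collaboration networks have. A measured consequence
(confirmed against igraph's independent Infomap implementation, i.e. not
an optimizer artifact): at late-course densities (average out-degree ≈2.5)
the map-equation optimum on generated networks is genuinely a single
module, while real networks of similar density retain rich community
structure. Tests and experiments that need sustained community structure
therefore measure on the pooled weeks-1+2 network — the same pooling the
default pipeline applies — where the generator reliably yields 7–13
communities. Passing tests show the statistics behave correctly under the
generator's assumptions; they do not show that community detection on
sparse real networks will be equally stable.

## Experiment sizes and numerical conventions

* Exhaustive map-equation checks enumerate all partitions of ≤8 nodes.
* Null calibration: 1000 independent draws × 1000 permutations on a
  120-node, 8-group partition; the 5% level must reject in 5% ± 2%.
* Homophily recovery: 50 replicate cohorts, communities detected on the
  pooled first two weeks (3 seeded runs), 1000 permutations; section
  Z > 1.96 and grade |Z| ≤ 1.96 each required in ≥90% of replicates.
* Persistence monotonicity: grid {0, .25, .5, .75, .95} × 20 replicates,
  full participation, 4 weeks.
* All logarithms base 2; `0·log 0 = 0` throughout; greedy moves require an
  improvement larger than 1e-12 bits; visit rates sum to 1 within 1e-12.
* Detection run counts are reduced from the default 100 where experiments
  repeat detection across many replicates (3–10 runs there); partitions of
  the well-structured pooled week are insensitive to this in the seeds
  exercised.

## Known limitations

* The greedy minimizer guarantees a local optimum only; global optimality
  is verified exhaustively on small graphs, not at cohort size.
* VI between weeks ignores students present in only one of the two weeks.
* No analytic null for S (randomization only), no multiple-testing
  correction across weeks, and grade order is ignored by the divergence.
* The generator's missing reciprocity/transitivity and i.i.d. weekly
  participation are the two places its networks are known to be easier
  and harder, respectively, than real cohort data.
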