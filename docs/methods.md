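# Methods

## The graph-based open-ended survey model

A graph-based open-ended survey (GOS) is a hybrid of a multiple-choice and a
free-format survey.  Respondents arrive sequentially; each is shown a uniform
random sample of the current opinion pool (at least 8 items, up to 24),
supports any subset, and may author new opinions that immediately join the
pool for later respondents.  The result is a bipartite graph G = (V_o ∪ V_r,
E): opinion vertices, respondent vertices, and support edges.  `opinion_graph`
implements this container with strict invariants — bipartiteness, simple
edges, authored opinions connected to their author, monotone creation/arrival
indices — and lossless CSV/GraphML round-trips.  Respondent rows with zero
actions (no support, no authored opinion) never become vertices; they are
kept in a rejection log, because the generation rule only creates a
respondent vertex when a respondent acts.

## Synthetic surveys (`simulate`)

No public GOS response logs exist, so the simulator generates surveys with
planted structure:

* each respondent draws an *archetype* a ~ `archetype_weights`;
* each opinion carries a planted *group* g and a true annotation category;
* a displayed opinion of group g is supported independently with probability
  min(1, `support_intensity` · affinity[a, g] / E[display size]), where the
  affinity matrix has unit row sums.  The expected number of supports per
  turn is therefore `support_intensity` times the mean affinity of the
  displayed items;
* with probability `p_post` (default 0.08, the observed share of authoring
  respondents in four real survey rounds: 9.1%, 8.4%, 6.9%, 7.1%) the
  respondent authors one opinion whose group is drawn from their affinity
  row;
* a turn with neither support nor post is redrawn up to 10 times, then the
  arrival slot is logged as rejected;
* simulated annotators label each opinion independently: skip with
  probability `unannotated_frac` (default 0.1), otherwise report the true
  category with probability 1 − `annotator_error` (default error 0.1) and a
  uniformly random different category otherwise.

Identical configurations (including the seed) reproduce the survey bit for
bit.

### What the generator reproduces, and what it does not

It reproduces: sequential growth of the pool, the 8–24 uniform display rule,
realistic posting rates, block-structured support, a weakly-connected
"no concerns" block, and imperfect multi-annotator labels.  It does not
model: demographics or panel weighting, opinion text semantics (labels are
synthetic strings), respondent fatigue, or duplicate opinions.

### Arrival-time stratification and the preset pools

One genuine property of GOS data deserves emphasis: because the pool grows,
early respondents *cannot* support opinions that do not yet exist.  When the
pool grows by a large factor over the survey (e.g. 16 initial opinions
growing to ~180), this produces real arrival-time strata that a block model
correctly detects — planted archetypes are then not the dominant structure,
and recovery ARI drops to ~0.5–0.7.  The `two_block_no_concerns` and
`diffuse` presets therefore use a developed initial pool (200 opinions, the
scale a 2000-respondent survey's pool reaches anyway), in which block
structure dominates and the planted respondent bipartition is recovered with
ARI ≈ 0.95.  Users studying the cold-start transient can simply lower
`n_initial_opinions`.  Preset support intensities are set so a respondent
supports roughly 2–4 of the 8 displayed items, typical multi-select
behavior.

## Annotation priors (`annotations`)

Annotators are never fused: every distinct (annotator, category) pair is its
own dimension, so three annotators over ten categories span K ≤ 30 labels
(the realized label space is used; unused pairs are dropped).  Each opinion
vertex receives a K-vector prior: a vertex holding m ≥ 1 labels gets
η = `mass_on_labels`/m on each held label and ε = (1 − `mass_on_labels`)/(K − m)
elsewhere; unannotated vertices are uniform 1/K.  The single knob
`mass_on_labels` (default 0.99) fixes the one degree of freedom left by the
normalisation constraint, keeping η ≫ ε (η/ε ≥ 99·(K−m)/m).  A vertex
holding *all* labels degenerates to uniform and is flagged.  Inter-annotator
consistency is summarised by raw agreement and Cohen's kappa over jointly
annotated opinions.

## Clustering (`sbm`)

The clustering objective is a microcanonical description length (DL) for the
non-degree-corrected stochastic block model on a bipartite graph, with
groups constrained to one side (opinions and respondents never share a
group).  For group sizes n_r, block edge counts e_rs, E edges, and B1 × B2
groups:

* partition term, per side (N vertices, B groups):
  ln N + ln C(N−1, B−1) + ln(N!/∏_r n_r!);
* edge-count term: ln C(B1·B2 + E − 1, E);
* graph term: Σ_rs ln C(n_r·n_s, e_rs).

Minimising the total is Bayesian model selection: B is inferred, never
supplied.  With annotation priors, each opinion group is aligned to the
single label maximising its members' summed log-prior (equivalently the
majority held label under the η/ε construction), and the objective gains
−Σ_v log p_v(label of v's group); uniform-prior vertices contribute zero, so
a run with uniform priors is identical to a run with none.

Search: (1) multilevel agglomeration — every vertex starts in its own
group, the best sampled two-hop merge candidates are *forced* (shrink factor
1.5 per round) down to one group per side, each level is cheaply refined,
and the best-scoring level is restored.  Forcing is essential: the singleton
partition is a local DL minimum (it fits every edge perfectly), so
improvement-only merging cannot leave it.  (2) Annealed single-vertex
Metropolis–Hastings with same-side proposals, inverse temperature rising
geometrically 1 → 5 over the sweeps, with the proposal-count Hastings
correction; the chain at β = 1 provably targets exp(−DL) (verified against
exact enumeration on small state spaces).  (3) Zero-temperature polish:
best-improving single-vertex moves plus exhaustive pairwise merges until a
local minimum.  Best of `n_restarts` restarts (default 10) wins.  On graphs
of ≤ 8 vertices an exhaustive enumeration oracle is available, and the
default search budget attains its global optimum on random test graphs.

Numerical conventions: all terms in nats via `lgamma`; ties broken by
canonical (first-appearance) group order; every randomness source is an
explicit seeded generator.  A degree-corrected variant (Karrer–Newman block
entropy −Σ e_rs ln(e_rs/(d_r d_s))) is available behind
`degree_corrected=True`; it omits a degree-sequence prior and is provided
for exploration, not used by any headline result.

Known limitations: the non-degree-corrected likelihood can split groups by
degree when popularity within a planted group is strongly heterogeneous
(e.g. old versus freshly-authored opinions); on small sparse graphs the
parsimony terms dominate and true-but-thin structure is (correctly) not
reported — with 2 respondents per 2×2 block the single grouping wins, from 3
upward the planted blocks win.

## Summaries (`analysis`)

* Posting rate: respondents with ≥ 1 authored opinion, as a percentage
  rounded half-up to one decimal.
* Propensity matrix: e[i, j] = edges between opinion group i and respondent
  group j, normalised within each column; zero-edge columns are flagged, not
  NaN; optional zero-row padding aligns tables across surveys.
* Palette profiles: per respondent, the share of their edges in each opinion
  group (rows sum to 1); degree-0 respondents are excluded and listed.  The
  display order minimises total adjacent L1 dissimilarity via greedy
  nearest-neighbour construction plus best-improvement 2-opt (all starts are
  tried for n ≤ 12; the result is never worse than the input order, and on
  small instances it matches the factorial optimum in ≥ 8/10 random trials).
  The seriation objective and heuristic are this package's explicit,
  testable choice for the "optimal horizontal alignment" that palette
  diagrams require.

## Pipeline

`run_pipeline` chains simulate/load → annotations → priors → inference →
summaries → rendering, writing every intermediate table plus
`provenance.json` (config echo, seeds, per-stage counts).  Identical configs
give identical outputs; `compare_runs` reports partition ARIs and propensity
distances between two runs.

## Problem sizes used in the checks

The automated checks run: planted-recovery at the full preset size (2000
respondents, 5 seeds; inference with 15 sweeps × 3 restarts, which the
annealing experiments showed is past the point where results stop changing),
prior-gain at 1000 respondents (5 paired seeds), null-structure runs at
200+200 vertices (10 seeds), oracle equivalence on 20 random ≤ 8-vertex
graphs, and stationarity on an exactly enumerable 4-vertex state space.
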