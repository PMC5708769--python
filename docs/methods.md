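# Methods

`cytobn` infers discrete Bayesian networks over cytokine panels: per-subject
multiplex immunoassay concentrations (pg/ml) are discretised into three
relative-concentration states, a directed acyclic graph (DAG) is learned by
maximising a Bayesian Dirichlet equivalent (BDeu) score with Tabu search,
and non-parametric bootstrapping grades each edge's stability. This note
records the model, the tunable parameters, the numerical conventions, and
what the synthetic-data checks do and do not demonstrate.

## Model and score

Each analyte is a node taking states {low, intermediate, high}. For a
candidate DAG G, the marginal likelihood of the discretised data under
Dirichlet parameter priors with equivalent sample size (ESS) `s` is

    score(G) = Σ_i Σ_j [ lnΓ(α_ij) − lnΓ(α_ij + N_ij) ]
                       + Σ_k [ lnΓ(α_ijk + N_ijk) − lnΓ(α_ijk) ]

with `r = 3` states, `q_i = 3^|pa(i)|` parent configurations,
`α_ijk = s/(q_i r)`, `α_ij = s/q_i`, and `N_ijk` the count of node `i` in
state `k` under parent configuration `j`. The score decomposes over
node–parent families and is likelihood-equivalent: DAGs encoding the same
conditional-independence structure score identically under a uniform
structure prior (pinned to 1e-8 in the tests). Conditional probability
tables are reported as posterior means `(N_ijk + α_ijk)/(N_ij + α_ij)`;
unobserved parent configurations therefore yield the uniform row.

Which Dirichlet prior family the original analyses used is not recoverable;
BDeu with configurable ESS is implemented and the choice is recorded in the
run metadata. The default ESS 1.0 is a deliberately weak prior; larger
values admit more edges.

## Discretisation

Columns are z-scored (sample SD, ddof 1) and then allocated to three
equal-frequency bins. Equal-frequency binning is invariant under strictly
increasing transforms, so z-scoring cannot change bin membership; the step
is kept to make the pipeline's order of operations explicit, and a
regression test asserts the invariance rather than removing the step. Tied
raw values always share a bin (greedy distinct-value fill with re-targeted
capacities), which is deterministic and label-independent at the cost of
count imbalance for zero-inflated columns; the imbalance is logged.
Constant columns (e.g. an all-undetectable analyte) cannot be binned and
are excluded from learning with a warning. Cut points are reported per
analyte on the z-scale as the per-bin maxima, so re-applying them
reproduces the states exactly.

## Knowledge priors

Curated knowledge networks enter as tab-separated edge lists (optional
third column: weight in (0,1], default 1; knowledge-base and text-mining
lists are merged by union before use). The seeding prior is the undirected
intersection of both species' networks — direction is discarded before
intersecting. Feedback loops in directed inputs are broken by greedy
removal of the minimum-weight edge on each detected cycle, ties by
(parent, child) name order; exact minimum feedback arc set is deliberately
out of scope. The prior enters the search twice:

1. the initial structure is the prior skeleton oriented along analyte-name
   order (always acyclic), trimmed to the parent limit;
2. every modelled edge absent from the prior skeleton is penalised by
   −kappa (default 1.0) in the log score.

kappa = 0 recovers the uniform structure prior exactly, so data always can
overrule the seed. The relative weighting of knowledge-base vs text-mining
edges is unspecified upstream; both default to 1.0.

## Search

Moves are add / delete / reverse of one directed edge, enumerated
lexicographically by node name; the best admissible non-tabu move is taken
even when it worsens the score; a tabu list (length 10) of recently undone
moves blocks immediate backtracking, with aspiration for moves beating the
best structure seen. A run stops after 1000 moves or 50 moves without
improvement. Because a deterministic trajectory can cycle without ever
crossing the jointly-worsening moves needed to assemble a multi-parent
collider, the search restarts from seeded random DAGs (16 restarts by
default; restart 0 from the prior-seeded or supplied structure). Results
are bit-reproducible for fixed data, configuration and seed. On all 3-node
(25 DAGs) and 4-node (543 DAGs) instances exercised in the tests the
restarted search attains the exhaustive-enumeration optimum exactly.

The default parent limit is 3: with 3 states a 3-parent family already has
27 configurations, about the most ~20 subjects can inform; a warning is
appropriate whenever n < q_i·r. Exact global search beyond 4 nodes, MCMC
over structures, and Gaussian/dynamic networks are out of scope.

## Bootstrap confidence

Subjects (rows, never columns) are resampled with replacement B = 100
times; the learner re-runs per replicate and each directed edge's
confidence is its containing fraction. Because direction within a Markov
equivalence class is weakly identified at n ≈ 20, the undirected skeleton
confidence is reported alongside and always dominates the directed value.
The full-data point-estimate DAG is annotated per edge and dichotomised at
0.80: "grey" at or above, "red" below. Replicates reuse the full-data bin
cut points by default (equivalent to resampling discrete rows, and keeping
replicates comparable); per-replicate re-discretisation is switchable. At
n = 20 the BDeu optimum itself overfits multi-parent families on null data;
the bootstrap is what flags such edges — in the study-scale null check all
learned edges come out below the 0.80 threshold.

## Panel statistics

Compartment comparisons run per analyte: Shapiro–Wilk (alpha 0.05,
configurable; applied to the paired difference vector, or to each group for
unpaired designs) routes to a paired t-test or Wilcoxon signed-rank test
(unpaired: t-test — Welch's variant when a Levene test rejects equal
variances at 0.05 — or Mann–Whitney). Zeros are retained as true values;
zero-difference pairs use the Pratt rule; an all-zero difference vector is
flagged degenerate with p = 1. Holm's step-down correction is applied
across the full analyte family, and the higher group is flagged only when
the adjusted p is below 0.05. Dilution correction converts sample mass to
volume at unit density (1 g = 1 ml) — a documented stand-in, as the exact
upstream formula is not restated — giving
measured × (sample + diluent volume)/sample volume.

## Topology and colour annotation

Roles are functions of degree: orphan (degree 0), parent/root (in 0,
out ≥ 1), terminal (out 0, in ≥ 1), hub (non-terminal with total degree ≥ 3
or in ≥ 2 and out ≥ 1), else internal. The hub rule is an explicit,
configurable stand-in — published hub definitions vary — and raw degrees
are always exported so users can apply their own criterion. When several
sinks exist, all are listed as terminal.

Colours collapse each node's CPT with its parents fixed at their modal
states, resolved in topological order from the roots (how multi-parent
conditioning is collapsed for display is a design choice; this one is
deterministic and local). The modal probability p* sets hue — high → green,
low → red, intermediate → white — and intensity (p* − 1/3)/(2/3) ∈ [0, 1];
white nodes have intensity 0 by definition, and ties prefer intermediate,
then the lower state.

Cross-species abridgement drops the analytes not measured in the other
species and re-runs the entire pipeline on the reduced panel; the full
network is never edited in place. The built-in presets encode "analytes
absent from the other species' panel": {IL-18, IP-10, Leptin, VEGF} for rat
panels and {IL-3, IL-12 (p40), MIP-1beta} for mouse panels. Published
descriptions of which list attaches to which species are internally
inconsistent (the Methods-style listing omits IL-18 and MIP-1beta and maps
lists to the opposite species); the presets follow the reading above and
are plain configuration, so either convention can be supplied explicitly.

## Synthetic data

The generator draws discrete states by ancestral sampling along a known
DAG (topological order, name ties broken alphabetically) and emits
concentrations from per-(analyte, state) lognormal components — positive
and right-skewed like assay data, without claiming the study data followed
any particular distribution — optionally zeroed with per-analyte
probability to mimic "undetectable" readings, which are encoded as exact 0,
not missing. Calibration to published mean ± SEM tables moment-matches one
lognormal per analyte (target SD = SEM·√n), splits it into three tercile
components on the log scale, and shifts all locations in closed form so
the equal-weight mixture mean equals the target exactly; the SD is matched
approximately (within 15% in the tests). A zero mean with zero SEM becomes
an always-undetectable analyte. Calibrated models use an empty DAG with
uniform state marginals; dependency structure for recovery studies comes
from the separate 8-node / 8-edge benchmark model (two roots, maximum
in-degree 2, "noisy copy" CPTs of strength 0.8, emission locations
log 10/30/90 with scale 0.25).

What passing the synthetic checks shows — and does not. The generator's
three emission states align with the three discretisation bins, so
structure recovery is well-posed by construction; real assay data offer no
such guarantee. Plate effects, bead-count artefacts, standard-curve
nonlinearity, measurement correlation between analytes sharing a detection
channel, and inter-animal covariates are all unmodelled. Recovery scores
(skeleton F1 = 1.0 at n = 1000 with strong CPTs) therefore certify the
implementation, not expected performance at n = 20 on biological samples,
where the bootstrap tiering is the honest summary of stability.

## Problem sizes and numerics

Default checks use: 50 random 3-node and 10 random 4-node data sets (n=30)
for oracle equivalence; 100 random sets for likelihood equivalence (1e-8);
1000 random single-edge moves for incremental-vs-full rescoring (1e-8);
20 seeds × (1 + 100 bootstrap) learns at n = 1000 for recovery; 1000 null
simulations of a 24-analyte family for FWER and 100 seeds for power; and a
20-subject × 24-analyte calibrated panel for the end-to-end run. Score
comparisons use an absolute tolerance of 1e-12 for tie detection within the
search and 1e-9 against the enumeration oracle. CPT rows must sum to 1
within 1e-9. Degenerate inputs are defined behaviour: empty data score 0;
constant columns are excluded before learning; an empty prior intersection
runs unseeded with a warning.

## Known limitations

- Single time point, acyclic structure: feedback regulation appears only
  through its static signature; dynamic Bayesian networks are out of scope.
- Equal-frequency bins force near-uniform marginals, so parentless nodes
  are always coloured white — colour is informative only downstream of
  learned edges.
- The greedy feedback-arc heuristic is not minimal in the exact sense.
- Direction (as opposed to skeleton) recovery at n ≈ 20 is weak; directed
  confidences should be read with the skeleton confidence alongside.
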