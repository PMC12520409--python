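# Methods

This note records the model, the numerical choices, and the design
decisions behind `ffhrisk`, in the spirit of a statistical package's
methods documentation. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model

The object of study is a discrete Bayesian network over 21 binary nodes:
20 risk factors coded from construction accident reports (five core
categories — illegal practices A1–A3, safety-management failures B1–B8,
site/equipment hazards C1–C3, protection deficiencies D1–D3, worker
factors E1–E3) and one outcome node `FFHA` (a fall-from-height accident
occurs). Every node has states TRUE/FALSE. The joint distribution
factorizes as usual over the DAG, P(V) = Π P(v | parents(v)).

The structure is *hybrid*: edges originate from expert elicitation, are
screened by evidence fusion, and are then refined against report data by
conditional-independence testing. Parameters come entirely from the data.

### Evidence fusion

Each candidate edge is scored 0–10 by two panels. A panel's support mass
is the arithmetic mean of its scores divided by 10 — the simplest
estimator consistent with panel-level supports reported to two or three
decimals. Dempster's rule is applied on the two-element frame
{exists, not-exists} with *Bayesian* masses (no mass on the frame):

- conflict k = m₁(1−m₂) + (1−m₁)m₂,
- fused mass m = m₁m₂ / (1−k),
- Bel = Pl = m (equality holds exactly because no mass rests on the frame).

The Bayesian-mass convention is a deliberate modelling choice: the
bundled 25-row elicitation summary prints Bel = Pl on every row, which is
possible only under this convention, and the test suite verifies that all
25 rows reproduce to four decimals. Combination with m = 0.5 is the
identity on (0,1) (a maximally uncertain source is neutral); total
conflict (one source at 0, the other at 1) is an error, not a silent
result. Screening keeps an edge iff Bel ≥ 0.8 *and* Pl ≥ 0.8 *and*
k < 0.5; the ≥/< mix is consistent with every bundled surviving row
(minimum Bel 0.8439, maximum k 0.4228). Reported values are rounded
half-even to 4 decimals; internal computation is full precision.

Only the two-element frame is supported. General D-S combination over
arbitrary focal elements, and respondent-reliability weighting, are out of
scope.

### Structure refinement

d-separation on the screened DAG identifies *suspect* edges: X→Y such that
removing the edge still leaves a directed single-mediator path X→Z→Y. For
each suspect edge and mediator, the plug-in conditional mutual information

I(X;Y|Z) = Σ_{x,y,z} P̂(x,y,z) log [ P̂(x,y|z) / (P̂(x|z) P̂(y|z)) ]

is estimated from the incidence matrix with P̂(x,y,z) = N(x,y,z)/N and the
standard 0·log(·) := 0 convention for empty cells. The edge is removed
when I < 0.02 for *any* tested mediator (the laxer rule; a stricter
all-mediators rule would behave identically on all bundled cases, and the
choice is exposed as configuration by passing per-edge test triples).
Single-variable conditioners are auto-generated; arbitrary user triples
are first-class inputs because an analyst may wish to probe pairs without
a mediator path (the machinery warns, rather than errs, when a triple
names an absent edge).

The logarithm base defaults to 2 (bits) and is configurable to natural
log; the 0.02 threshold is a conventional independence cut-off whose
literature provenance does not pin the base, so both are runnable and the
sensitivity sweep over both bases is part of the test suite. d-separation
itself delegates to networkx's standard algorithm; tests cross-check it
against an independent path-enumeration oracle on random DAGs, and the CMI
estimator against a literal triple-loop oracle to 1e-12.

Constraint-based or score-based structure learning from data alone
(PC/GES) is a non-goal: structure always originates from elicited edges.

### Parameter estimation

With α > 0 the Laplace-smoothed estimators are

- priors: P(A=TRUE) = (X_A + α)/(N + 2α),
- CPT rows: P(A=TRUE|C) = (X_{A|C} + α)/(N_C + 2α),

which keep every probability strictly inside (0,1). α defaults to 1
(add-one smoothing) and is configuration — sensitivity runs over
α ∈ {0.5, 1} are one config field away.

**Unseen parent combinations.** When N_C = 0 the row falls back to the
single-parent conditionals p_i = P(A=TRUE | parent_i = c_i) (each
estimated pairwise with the same smoothing): with g_T and g_F the
geometric means of the p_i and (1−p_i), the row is g_T/(g_T+g_F). A bare
geometric mean of marginals would not produce complementary TRUE/FALSE
probabilities; the normalization is the minimal completion that restores a
valid distribution. Fallback rows are flagged (`provenance="fallback"`)
so downstream consumers can tell observed from imputed rows. A uniform
(0.5) fallback is available as configuration.

**The accident-only outcome.** Every report in the corpus is an accident,
so no data column exists for the outcome. The default treats the outcome
as an implicit all-TRUE column, giving (N_C+α)/(N_C+2α) for observed
parent combinations — necessarily above 1/2. This is an honest structural
limitation, not a bug: conditional accident probabilities well below 50%
cannot be derived from case-only data by these estimators, so any
published sub-50% scenario probabilities must involve additional
information (negative cases, expert priors, or tool defaults). The fitting
routine therefore also accepts an explicit outcome column (e.g. synthetic
controls) to exercise the full estimation path, and the synthetic
generator can retain the outcome column for exactly this purpose.

**Parent order.** CPT parents default to lexicographic (catalog) order;
`fit_parameters` accepts per-node overrides, and the bundled 21-node
topology pins the outcome's parents to the conventional scenario-table
column order (A2, D1, C3, E1, E2, E3, C1). Rows enumerate TRUE-first with
the leftmost parent most significant (all-TRUE is row 0).

### Exact inference

Queries are answered by variable elimination over dense binary factor
tables: evidence is sliced into the CPT factors, hidden variables are
summed out in min-fill order (deterministic lexicographic tie-break), and
the query factor is normalized. Exactness makes oracle testing trivial:
the suite checks elimination against full joint enumeration to 1e-10 on
200 random models (≤ 12 nodes) and on the full 21-node topology (2^21
enumeration), and checks invariance across random elimination orders.
Evidence with probability zero raises an error rather than returning a
silent 0/0. Approximate inference, multi-state (> 2) nodes and temporal
networks are non-goals.

Both reasoning directions use the same machinery: `posterior` for
predictive queries, `diagnostic_probabilities` (P(factor | outcome=TRUE))
for backward reasoning. Factor-importance rankings report *both* the
empty-evidence marginals and the diagnostic posteriors, because published
"risk probability" figures can be read either way; the two coincide only
for factors d-separated from the outcome.

### Scenario analysis

A risk scenario is a complete TRUE/FALSE assignment of the outcome's
parents; the table has exactly 2^|parents| rows (128 for the bundled
topology). Since the outcome is d-separated from all other nodes given its
parents, each scenario's P(outcome=TRUE) equals the corresponding CPT row
— the tests assert this identity, and also assert that the column of
scenario probabilities does *not* sum to 1 (they are conditionals, not a
distribution). Ranking ties break by canonical enumeration order, making
top-N reports deterministic. Partial scenarios are deliberately excluded
from the table (they are ordinary posterior queries); intervention
semantics (do-calculus) are a non-goal.

## Synthetic data: what it emulates and what it does not

The generator draws incidence matrices by ancestral sampling from a
ground-truth network and, when conditioned on the outcome, rejection-keeps
only outcome-TRUE rows and drops the outcome column — reproducing both the
accident-only selection effect (factor frequencies converge to
P(factor | accident), not the unconditional marginals; asserted against a
closed form on a 3-node fixture) and the 20-column layout with zero-padded
report IDs. Questionnaire scores are normal draws centred at 8.5/10 for
true edges and 2.0/10 for non-edges (sd configurable, default 1.5),
clipped to [0,10] and rounded half-even — half-even rounding keeps the
generators bit-reproducible across platforms.

The ground-truth CPTs of the bundled 21-node preset are *illustrative*
(seeded uniform draws in (0.05, 0.95)): the real corpus's co-occurrence
structure is only partially visible from the bundled 16-report excerpt, so
no calibration to real frequencies is attempted. Passing recovery tests
therefore demonstrate that the pipeline recovers structures and parameters
under realistic sample sizes and noise — not that the real corpus was
reproduced. Factor-misclassification noise (coding errors in the reports)
is not simulated.

## Benchmark and test sizing

- **Structure recovery** runs at the realistic study scale: corpus of 368
  outcome-conditioned reports, panels of 11 and 41 respondents, score sd
  1.5, candidate set = 24 true edges + 5–8 decoys, success = exact edge-set
  recovery in ≥ 8 of 10 seeds.
- **Parameter recovery** uses 50,000 samples from a hand-specified 6-node
  network whose parent-combination supports all land in the thousands.
  The design is a standard-error budget: a tolerance of 0.02 absolute on a
  CPT entry is ≈ 0.9 binomial standard errors at support 500 (a coin flip)
  but ≥ 2.8 standard errors at support ≥ 5,000, so the benchmark topology
  keeps all supports large; only rows with support ≥ 500 are checked, as
  below that the tolerance is uninformative.
- The 2^21 joint enumeration and the 200-model oracle sweep are sized to
  run in seconds on one CPU.

## Degenerate inputs and edge cases

- Non-binary cells, duplicate report IDs and off-catalog columns are
  format/validation errors naming the offending row/column.
- CMI on an empty matrix is an error; a variable constant in the data
  yields CMI 0 with a degenerate-margin warning.
- Fusion with totally conflicting degenerate sources raises; agreeing
  degenerate sources have k = 0.
- Pruning is idempotent and cannot create cycles (it only removes edges).
- An outcome with no parents has no scenario table (error), and top-N
  requests outside [1, rows] are rejected.

## Known limitations

- The accident-only outcome CPT (above) is the main interpretive caveat:
  absolute outcome probabilities from case-only data are upper-bounded
  away from small values, so scenario probabilities should be read as
  *relative* risk orderings unless control data are supplied.
- The candidate-edge list is an input; the package does not attempt to
  reconstruct which candidate edges an elicitation rejected before the
  published summary.
- Plug-in CMI is biased upward at small N (≈ df/(2N ln 2) bits under
  independence); at N = 368 this is ≈ 0.004 bits against a 0.02 threshold,
  acceptable, but thresholds should be revisited for much smaller corpora.
- Exact inference is exponential in treewidth; fine for 21 nodes, not for
  networks orders of magnitude larger.
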