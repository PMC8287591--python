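# Methods

## The cross-impact balance model

A CIB system consists of `n` factors, each with an ordered list of at
least two discrete states (the default configuration is binary
low/high).  The cross-impact matrix `C` assigns an integer judgment
score in [−2, +2] to every ordered combination (source factor, source
state, target factor, target state): +2 "strongly promoting", −2
"strongly restricting", 0 "no influence".  Diagonal blocks are
structurally zero — a factor does not judge itself.

Given a scenario `s` (one state per factor), the impact balance of
state `t` of factor `k` is the sum of incoming judgments from every
other factor's assigned state.  Each balance entry therefore lies in
[−2(n−1), +2(n−1)].  A scenario is *weakly consistent* when every
factor's assigned state has a balance at least as high as every
alternative state's, and *strictly consistent* when that maximum is
unique.  Weak consistency is the package default: a tied factor has no
net pressure to switch, and treating ties as consistent matches common
CIB practice.  Strict mode is exposed as an option; it always selects a
subset of the weak set and can be empty.

The *succession operator* maps a scenario to the per-factor argmax of
impact balances, retaining the current state when it is among the
maxima.  Its fixed points are exactly the weakly consistent scenarios,
which gives the solver an independently checkable characterisation; the
operator is single-step (trajectories and cycles are not followed) and
exists for verification, not as a solver.

An *inconsistency score* accompanies every consistency check: the
maximum over factors of (best alternative balance − chosen-state
balance), floored at zero.  It is zero exactly for weakly consistent
scenarios.  An integer *tolerance* option relaxes the consistency
condition — a factor passes when its balance deficit is ≤ tolerance
(weak) or < tolerance (strict), so tolerance 0 recovers the exact
definitions.  The default tolerance is 0: only fully consistent
scenarios are reported unless the user opts in.

## Enumeration

Scenario discovery is exhaustive: every candidate in the state space is
tested, in canonical lexicographic order (declared factor order, then
state index), so outputs are deterministic and diff-stable.  Candidates
are evaluated in vectorised blocks of 2^14; the balance tensor for a
block is accumulated per source factor, making the 2048-candidate
default system enumerable in milliseconds.  A hard guard refuses state
spaces above 2^24 candidates with an error carrying the exact count; no
heuristic or pruning search is implemented because the intended problem
sizes (10–20 binary factors) need none.

Interventions fix one factor state at a time.  The fixed factor is
exempted from the consistency condition — it is held in place by an
external stimulus, not by the system — but still contributes to every
other factor's balances.  Fixing therefore only removes constraints:
every baseline-consistent scenario with the factor already in the fixed
state remains consistent under the intervention (a property the test
suite checks on random instances).

## Elicitation encoding

Questionnaire responses record, per ordered factor pair, whether a
direct influence exists and, if so, which relationship shape best
describes it.  Shapes map to 2×2 judgment blocks (rows: source state
low/high; columns: target state low/high).  The default table:

| shape                  | low row  | high row |
|------------------------|----------|----------|
| linear_increasing      | +2 −2    | −2 +2    |
| linear_decreasing      | −2 +2    | +2 −2    |
| saturating_increasing  | +2 −2    | −1 +1    |
| saturating_decreasing  | −2 +2    | +1 −1    |
| threshold_increasing   | +1 −1    | −2 +2    |
| threshold_decreasing   | −1 +1    | +2 −2    |
| u_shaped               | −1 +1    | −1 +1    |
| inverted_u             | +1 −1    | +1 −1    |

Rationale: linear shapes carry full strength at both ends; saturating
shapes are strong where the curve is steep (low source values) and weak
where it flattens; threshold shapes are the mirror image; U-shaped and
inverted-U shapes push the target weakly toward one side from both
source states.  Every default block has zero-sum rows (promotion of one
target state is balanced by restriction of the other) and each
increasing/decreasing pair is a column swap of the other.  The table is
an explicit, overridable artifact choice — published studies do not
always print their graph-to-score mapping — and users can supply their
own table file; non-zero-sum custom rows are accepted with a warning
rather than an error.

One response per ordered pair is enforced (elicitation protocols of
this kind collect each relationship from a single expert);
multi-expert reconciliation is out of scope.

## Classification and metrics

The promoting map designates the health-promoting state of every factor
and the outcome subset (default: chronic disease prevalence — low,
physical activity — high, processed-food consumption — low).  Categories
follow the all/none/otherwise rule on outcome states; the salubrious
flag additionally requires at least `threshold` promoting factors,
default 8 = ⌊11·0.7⌋+1, the smallest count strictly exceeding 70 % of 11
factors (recomputed by `salubrious_threshold` for other factor counts).

The promoting state of *healthy food prices* is genuinely ambiguous
(low prices improve access; high prices can accompany thriving
healthy-food markets).  The default map designates **low** as promoting
and documents the choice; it is a configuration default, not a claim,
and is overridable in the factor config.

Pooling concatenates per-region scenario sets with provenance tags,
reporting both the total (with multiplicity) and the unique count.
Metrics are computed on the pooled-with-duplicates list by default — a
scenario found independently in two regions counts twice, reflecting
its double identification — with a dedup flag for sensitivity.

`pct_factors_promoting` counts every (scenario, factor) slot, including
the fixed factor's slot under an intervention (reading "across all
consistent scenarios" literally); an `include_fixed=False` flag excludes
it for sensitivity analysis.  Percentages are computed in full floating
precision and reported at one decimal place in files; the
healthy+mixed+unhealthy partition sums to 100 within 0.1.  Metrics on an
empty scenario set raise an explicit error rather than returning 0, and
intervention results with empty sets are surfaced as explicit entries —
strict mode can legitimately produce them.

## Synthetic data

The generators emulate the *published summary structure* of a
three-region elicitation round over the default 11-factor system:
Brazil 39, Peru 53 and Guatemala 60 elicited relationships out of the
110 possible ordered pairs, with nonlinear-shape fractions 0.87, 0.81
and 0.77 (linear = the two linear shapes; everything else nonlinear).
Pairs are sampled uniformly without replacement; shapes uniformly
within the linear/nonlinear class.  Each generator draws from a stream
derived from (seed, region name), so regions are independently
reproducible and the whole pipeline is byte-stable per seed.

What the fixtures do **not** emulate: the content of any real study's
matrices (which judgments connect which pairs), correlations between
relationships, or expert disagreement.  Scenario sets derived from the
fixtures are therefore plausible stand-ins whose counts and categories
vary with the seed; passing tests demonstrate the correctness of the
machinery on data with realistic density and shape statistics, not
agreement with any published scenario table.

Two further generators support verification: `generate_random_matrix`
(independent off-diagonal blocks, entries uniform on {−2,−1,1,2}) for
oracle comparisons, and `plant_consistent_scenario`, which builds a
matrix in which a chosen target scenario is strictly consistent by a
requested margin.  Planting writes, for each factor, judgment rows of
±2 from `ceil(margin/4)` designated source factors — only the rows for
the sources' target-scenario states; alternative-state rows stay zero,
so other scenarios may additionally be weakly consistent as all-zero
ties.  Margins above 4(n−1) are infeasible on the ±2 scale and rejected.

## Verification problem sizes

The solver is cross-checked against a pure-Python brute-force oracle
(per-scenario, per-factor score summation through the public accessors)
on 100 seeded random instances of 3–8 binary factors at densities
0.3–0.8, in both modes; the succession fixed-point equivalence is
checked over the full state space of the same instances; planted
recovery uses 100 instances of 6 factors with margins 1–8.  These sizes
make the full suite run in a few seconds while covering state spaces up
to 2^8 exhaustively.

## File formats and determinism

All formats are plain UTF-8 text (long-form CSV for matrices and
responses, YAML/JSON for configs and the encoding table).  Written
files begin with a comment line carrying the tool version and a digest
of the canonical body; readers skip comment lines, and write-after-read
is byte-identical for canonicalised inputs.  State labels are matched
case-insensitively after trimming; factor order is the declaration
order in the config.

## Known limitations

- Exhaustive enumeration only; systems beyond ~24 binary factors are
  refused rather than approximated.
- Binary factors are assumed by the shape-encoding layer (the core
  solver handles any state count).
- One expert per relationship; no reconciliation of conflicting
  judgments or inter-rater statistics.
- Reported proportions carry no statistical uncertainty: they describe
  the composition of a deterministic consistent-scenario set and have
  no probabilistic interpretation.
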