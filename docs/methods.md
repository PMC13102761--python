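# Methods

## Model

The package models p binary contributing-factor indicators coded from bed-fall
incident reports as a discrete Bayesian network: a DAG *G* plus, for every
node i, a conditional distribution of X_i given its parents Pa_i. The joint
factorizes as ∏_i P(X_i | Pa_i). Two modelling assumptions are inherited from
the coding scheme and matter for interpretation:

- A 0 cell means *not documented as contributing*, not "known absent". No
  missing-data mechanism is modelled; the network describes co-occurrence
  patterns inside reported falls, not population-level fall risk (the data
  contain no non-fall comparison group).
- Edges are conditional-dependence statements under the BIC-optimal
  factorization, not causal or temporal claims. BIC is score-equivalent, so
  any member of a Markov-equivalence class fits equally well; the direction
  of a reversible edge is fixed by the search's deterministic tie-break, and
  `to_cpdag` (v-structures + Meek rules R1–R3) exposes which directions are
  actually compelled.

## Structure search

Steepest-ascent hill climbing from the empty graph over single-edge moves
(add, delete, reverse), accepting the best move whose BIC improvement exceeds
ε = 1e-9, with natural-log BIC penalty (ln n)/2 per free parameter and the
conventions 0·ln 0 = 0 and "empty parent configurations contribute no
likelihood but full penalty". The in-degree cap (default 3) keeps structures
sparse at n ≈ 100. No tabu list or restarts: on 100 random 3-variable
problems the plain climber reaches the exhaustively-verified global optimum
in ≥ 95 cases (the remainder are genuine local optima, bounded in the test
suite). Candidate moves are enumerated in a fixed order — operation, then
(from, to) pairs lexicographically — so identical inputs give byte-identical
edge lists.

## Parameter estimation

BDeu prior with equivalent sample size 1.0: per-cell pseudo-count
α_ijk = ESS/(r·q) with r = 2 child states and q = 2^|Pa| parent
configurations, giving θ_ijk = (N_ijk + ESS/(r q)) / (N_ij + ESS/q). This
per-cell split is the standard BDeu convention; it is also the unique choice
that reproduces the published smoothed conditionals (0.003 = 0.25/83.5 etc.)
from integer joint counts, which is how the canonical fixtures were derived.
A never-observed parent configuration yields the uniform 0.5/0.5.
Probabilities are stored at full precision; rounding (3 d.p. probabilities,
1 d.p. percents) happens only at report rendering — computing the relative
change from rounded probabilities would give +19.6% where the correct value
is +19.4%, and the test suite pins this distinction.

## Bootstrap stability

Nonparametric bootstrap: B = 200 resamples of n rows with replacement,
structure learning repeated per resample with the same search configuration,
directed-edge frequencies = count/B (exact rationals). Replicate b's resample
stream is fully determined by (seed, b), so replicates are order-independent
and reproducible. The stable subnetwork keeps edges with frequency ≥ 0.5
(majority rule; any threshold between the published gap of ~0.10 and 0.51
selects the same edges) and refuses cyclic selections. A convergence check
reports per-edge frequency drift between replicate checkpoints; on
study-sized synthetic data the top edges drift ≤ 0.10 between B = 200 and
B = 400.

## Inference

Exact variable elimination over the CPT factors with a min-degree elimination
order (any order is exact; the heuristic only bounds intermediate factor
size). Scenario analysis contrasts the model-marginal baseline P(target = 1)
— the CPT-propagated marginal, not the raw sample frequency; the published
baselines match the model marginal to 3 d.p. and differ from the raw
frequencies — with the conditional under fixed evidence, reporting absolute
and relative change from unrounded values. Conditioning is observational
("what did reports with this condition look like"), not a do-intervention;
every report emits this caveat.

95% CIs use the percentile bootstrap: rows resampled with replacement, CPTs
refit on the *fixed* structure, the query statistic recomputed, B = 1000 by
default. This is the simplest method consistent with the degenerate interval
observed for P(G=1 | F=0): the zero joint cell (G=1, F=0) survives
essentially every resample, so the interval collapses onto the smoothing
floor ≈ [0.003, 0.003]. How the original study computed its intervals is not
stated anywhere we could find, so bootstrap-percentile is a package design
choice and CI agreement is qualitative only.

## Synthetic data: what it emulates and what it does not

The canonical fixtures are deterministic 102-record matrices whose marginal
counts (F 19, G 5, A 39, B 15, S 31, T 26, N 4, U 11 of 102) and pairwise
joint cells match the published tables exactly. The joint cells are not
guesses: θ = (N_11 + 1/4)/(N_+1 + 1/2) is strictly monotone in the integer
joint count, so each published smoothed conditional inverts to a unique
integer — (G=1, F=0) = 0, (A=1, F=1) = 1, (B=1, A=1) = 1, (T=1, S=1) = 0,
(U=1, N=1) = 4 (arithmetic documented in `synthetic.py`). Which rows carry
the overlaps is arbitrary (sufficient statistics are unaffected), so a fixed
canonical layout is used. Consequently every probability the pipeline
reproduces on these fixtures is an exact consequence of the published
counts — but the fixtures say nothing about cross-component joints (e.g. F
and S together), which the publication leaves unconstrained; components are
treated as independent.

`canonical_truth()` packages the five-edge stable structure with these exact
CPTs as simulation ground truth. `study_emulator()` forward-samples the 8
component columns at n = 102 and adds independent Bernoulli noise columns
for the remaining 14 codes at shipped synthetic rates (3–9 positives per
102; the publication prints no counts for those codes, so the rates are free
parameters chosen once as plausible sparse-report rates). Passing
recovery tests on this synthetic data therefore demonstrates correctness of
the algorithms under the stated generating process, not fidelity of the
emulator to the real reports' unprinted joint structure.

## Replication sizes and statistical reading of the stochastic checks

Recovery and stability checks are seeded simulations with sizes chosen to
give stable verdicts at interactive runtimes:

- Structure recovery: forward samples of n = 5,000, bootstrap frequencies
  pooled over 10 seeded runs (fresh sample and resample stream per seed),
  compared at the skeleton level. True adjacencies ≥ 0.9, false ≤ 0.2.
  Pooling is deliberate: a single generating sample can carry a borderline
  chance correlation (|r| ≈ 0.04 at n = 5,000 sits at the BIC acceptance
  threshold), making per-sample false-edge frequencies bimodal; the pooled
  frequency is the stable estimand of edge stability.
- Parameter recovery: the recovered value of each CPT entry is the mean
  refit over 10 seeded samples (±0.03 at n = 5,000, ±0.01 at n = 50,000).
  Rare parent configurations (the 4%-positive root N) leave only ~200
  effective observations per 5,000-record sample, so a single-sample
  estimate has σ ≈ 0.015 and cannot honestly carry a fixed ±0.03 band.
- CI coverage is spot-checked (30 seeded replications at the study's
  n = 102) rather than exhaustively, for runtime.

## Numerical and degenerate-input choices

- ε = 1e-9 acceptance threshold prevents cycling among score-equivalent
  structures; determinism everywhere is a hard contract (tested
  byte-identical).
- 2×2 rater agreement (Cohen's κ, pooled over all cells — only one aggregate
  value is conventionally reported) returns 1.0 when both codings are
  identical and constant (chance agreement p_e = 1).
- Constant columns are legal everywhere: BIC handles empty cells by the
  0·ln 0 convention, BDeu smoothing keeps probabilities in (0, 1), and
  zero-probability evidence is impossible for fitted nets with ESS > 0.
- Cyclic stable-edge selections raise with a remediation hint (raise the
  threshold) rather than silently dropping edges.

## Known limitations

- Hill climbing is a local search; the no-restart configuration can stop at
  local optima (bounded, not eliminated, by the acceptance checks).
- Bootstrap edge frequencies are reported for directed edges for table
  parity, but only adjacency/CPDAG-level statements are
  equivalence-invariant.
- The emulator's noise columns are independent by construction; real
  isolated factors may correlate weakly with component factors.
- CIs assume the fixed-structure bootstrap; structural uncertainty is
  reported separately (edge frequencies) and not propagated into the CIs.
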