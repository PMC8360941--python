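# Methods

## Setting

A bipartite network G = (V₁, V₂, E) links nodes across two disjoint sets
only. Link prediction ranks the nonexistent pairs E′ = U \ E (U the
|V₁|×|V₂| pair universe) by a similarity score; good scores put the truly
missing (or soon-to-appear) links on top. In the temporal variant every
link carries a diagnosis date and the task is forecasting each patient's
next diagnosis.

## Score definitions and conventions

Because linked cross-set nodes share no common neighbours, all indices are
built from quadrangles. For a candidate pair (x, y) define
side1 = Γ̂(x) ∩ Γ(y) ⊆ V₁ and side2 = Γ(x) ∩ Γ̂(y) ⊆ V₂; the sets are
disjoint and CN = |side1| + |side2|. LCL counts the links between Γ(y) and
Γ(x); for a non-adjacent pair these links are in bijection with the unique
length-3 paths x–d′–p′–y, an identity the test suite checks exhaustively
against the walk matrix B·Bᵀ·B.

The degree-weighted family (AA, RA) sums 1/log₂|Γ(z)| resp. 1/|Γ(z)| over
the CN set. Every counted node has degree ≥ 2 when (x, y) ∉ E (it touches
one endpoint and an internal path node), so the logarithm never vanishes
on any pair actually scored; the vectorised engine still zero-masks
degree-0/1 weights defensively.

The local-community family follows the Cannistraci/Daminelli conventions:
CAR = CN·LCL; CAA and CRA weight each CN-set node z by γ(z), its number of
incident local-community links; CJC divides CAR by the neighbourhood union
size |Γ̂(x) ∪ Γ(y)| + |Γ(x) ∪ Γ̂(y)| (the same denominator as the
intersection-over-union JC); CPA = e_x·e_y + (e_x + e_y)·CAR + CAR² with
e_x = |Γ(x) \ side2| the external degree. These bipartite forms are not
fixed by a single canonical reference; each lives in one small function so
an alternative convention is a one-line swap. Note that CPA, like PA,
retains a pure degree term and is therefore nonzero even without
quadrangles; all other CN-family scores are 0 then.

PRA weights each length-3 path by the reciprocal degree product of its two
internal nodes, so evidence routed through low-degree (specific)
intermediaries counts more. Each path term is ≤ 1, hence
0 ≤ PRA ≤ LCL.

## Temporal index

TPRA multiplies each path term by M(d′, d), the estimated probability that
a patient diagnosed with the intermediate disease d′ is later diagnosed
with the target disease d. Two estimators:

* **all_patients** — numerator: patients with d′ whose d-diagnosis is
  strictly later; denominator: all patients with d′. Conservative; absent
  follow-up deflates the probabilities.
* **both_diagnosed** — condition on patients carrying both diseases; then
  M(i,j) + M(j,i) = 1 in the absence of same-date ties, which the
  invariant tests assert.

Same-date diagnoses carry no ordering information: the default policy
counts them in the denominator only ("strict"); a "half" policy awards 0.5
to both directions. M(i,i) = 0 by convention (a diagonal term can never
occur in a path anyway, since d′ ∈ Γ(p) while d ∉ Γ(p)). No smoothing by
default; additive smoothing (num+s)/(den+2s) is available for sparse
disease pairs. During evaluation M is always re-estimated from the run's
training links — estimating it on the full network would leak the probe.

Two scoring routes exist: readable per-pair set/path functions and a
vectorised dense-matrix engine (the engine's entries are exact for every
pair not in E, which covers all pairs ever scored). Their agreement is a
standing property test.

## Evaluation protocol

Observed links split into training E^T and probe E^P. Static protocol:
uniform random partition with |E^P| = round(f·|E|), f = 0.1 by default.
Temporal protocol: patients with ≥ 2 diagnoses are drawn at random without
replacement, each contributing exactly its latest-dated link to the probe
until |E^P| reaches round(f·|E|); everything else trains. Ties for a
patient's latest date resolve to the lexicographically smallest disease
id, a reproducibility choice. Every index in a run is evaluated on the
same split.

AUC is the pairwise estimator (n′ + 0.5·n″)/n over probe-vs-nonexistent
score comparisons: exhaustive when |E^P|·|E′| ≤ 10⁷, otherwise 10⁶
sampled comparisons with a recorded seed. AUROC is computed independently
via scikit-learn's rank-based ROC area; with exhaustive comparisons and
midrank ties the two coincide (Mann–Whitney identity), which the suite
verifies on random score configurations. Precision/recall/F-score use a
top-k cut with k = |E^P| by default and a deterministic tie-break (score
descending, then pair id). Reports carry per-run detail, seeds, k and tie
policies.

The ranked-prediction analyses operate on one scored run: the degree-bias
analysis records, per disease, the position of its first correct
prediction against the disease's ascending-degree rank (hub-biased methods
fill early positions with high-degree diseases); unique-disease coverage
counts the distinct diseases among the top fraction (default 50%) of
correct predictions and the lowest degree rank reached.

### Null calibration

A scorer assigning i.i.d. random scores must sit at AUC 0.5. The
calibration check draws n independent comparisons with *fresh* i.i.d.
scores per comparison, so the estimate concentrates at 0.5 with standard
error 0.5/√n (≈ 5·10⁻⁴ at n = 10⁶). Re-using one realized score per
candidate would instead leave a residual spread of order 1/√(12·|E^P|)
however large n grows — with a small probe set that spread dwarfs the
tolerance a calibration check needs, which is why the fully independent
form is used.

## Synthetic cohorts

The cohort generator emulates filtered multimorbidity data: per patient
and time step, each undiagnosed disease j is acquired with probability
1 − (1 − baseline_j) · Π_{i∈current} (1 − T[i, j]) — a baseline hazard
plus independent promotion by every disease already carried. Acquisitions
are dated on consecutive days in acquisition order (a same-day mode
produces deliberate ties); patients ending below `min_conditions` (default
4) distinct diagnoses are dropped, and the realized ordered-pair
frequencies are logged with independent event-stream code so the
conditional-probability estimator can be validated against the generator.

Default parameterisation: 20 diseases; five "entry" conditions with
per-step baseline 0.05 and 0.01 for the rest; a planted transition chain
T[i, i+5] = 0.40; horizon 8 steps. This keeps the post-filter mean patient
degree in the 6–7 range typical of multimorbidity cohorts filtered to ≥ 4
conditions, so a 10% link probe draws only part of the patient pool and
repeated splits genuinely differ. What the generator does *not* model —
demographics, mortality, censoring, non-stationary hazards, miscoding —
bounds what green tests mean: they demonstrate correctness of the
machinery and the detectability of planted transition signal, not clinical
performance on real data.

## Problem sizes and numerical choices

The test and acceptance workloads use cohorts of 120–500 patients
(5000 for the probability-recovery check) and random graphs of ≤ 30 nodes
for exhaustive identity checks; at these sizes the dense matrix engine is
exact and fast, and every stochastic check runs with a fixed seed.
Deterministic ordering (sorted node ids, stable tie-breaks) makes repeated
runs bit-identical. Scores are plain float64 sums of at most a few
thousand terms; no tolerance beyond standard float comparison (~1e-9
relative in tests) is needed. Degenerate inputs — empty candidate lists,
edgeless graphs, zero denominators in JC/CJC, diseases with zero
denominator in M — all score 0 rather than raising, except where a
contract is violated (wrong-side nodes, uncovered diseases, empty score
sets), which raises a typed error.

## Known limitations

* The bipartite JC/CAR-family forms are one reasonable convention among
  several in the literature; results for those indices are
  convention-dependent.
* The all_patients estimator conflates "never develops j" with "not yet
  observed with j"; the both_diagnosed mode answers only the ordering
  question.
* TPRA assumes path evidence is additive and transition probabilities are
  patient-independent; comorbidity burden, age and sex are ignored.
* The dense engine scales as O(|V₁|·|V₂|) memory; networks with ~10⁵×10⁵
  pairs fit, but truly large systems would need a sparse rewrite.
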