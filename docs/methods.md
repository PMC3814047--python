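# Methods

## Data model

A protein is reduced to its **domain architecture**: the *set* of
structural-domain identifiers detected in it, with repeats ignored. This
set-semantics choice keeps the architecture space near-linear in the number
of domain types rather than exponential. All proteins sharing one
architecture merge into a single **entry** whose EC annotation is the union
of the members' EC numbers; the member accessions are retained. A
**universe** is a collection of entries with unique architectures, indexed
by domain (posting lists) and by architecture (exact lookup). Only fully
specified 4-block EC numbers are admitted; partial codes such as `2.7.11.-`
are rejected at parse time because the method models specific reactions, not
EC subclasses.

## Candidate measurements

For a candidate architecture `a`, the *included entries* are all entries
whose architecture is a (not necessarily proper) superset of `a`; the
*exact entry* is the unique entry equal to `a`, if any. Four measurements
are computed:

* **existence** `∈ {0, 1}` — whether the exact entry is present.
* **succinctness** `= |ECs_exact| / |ECs_included|`, with both numerator and
  denominator counting **distinct EC numbers** (not entry–EC pairs): the
  numerator over the exact entry (0 if absent), the denominator over all
  included entries. Undefined (and the candidate non-deducible) when no
  entry contains `a`.
* **consistency** — each included entry is split into single-reaction
  pseudo-entries; `n_i` counts included entries annotated with reaction
  `EC_i` (each entry contributes at most one pseudo-entry per EC),
  `N = Σ n_i`, `k` = number of distinct reactions, `n̄ = N/k`. Then
  `consistency = Σ_i (n_i/N)·((n_i − n̄)/N)`, algebraically
  `(Σ n_i² − N²/k)/N²`, hence ≥ 0 with equality iff all `n_i` are equal.
  The mean `n̄` is carried at full double precision and never rounded; the
  summation and closed forms agree to ≤ 1e−12 over random count vectors
  (property-tested).
* **simplicity** — `|a|`, the candidate's domain count.

## Prediction workflow

An exact architecture hit short-circuits enumeration. Otherwise all proper
non-empty subsets of the query (2^d − 2 of them; refused above 20 domains,
~10^6 subsets) plus the query itself are scored. The four "sequential"
measurements are realized as one lexicographic sort key with directions
(existence max, succinctness max, consistency min, simplicity min) and a
final deterministic tie-break on the canonical (sorted, comma-joined)
architecture string. Candidates that exist nowhere but are contained in
larger entries remain eligible with succinctness 0; a query fails only when
*no* candidate has any included entry.

The chosen architecture's reactions are ranked by **intensity**
`n̄ / n_i`, ascending: intensity < 1 ⇔ `n_i > n̄`, i.e. the reaction is
expressed above average among the candidate's included entries, and
`Σ_i 1/intensity(EC_i) = k` identically. Ties (equal counts) order
lexicographically by EC string so batch output is reproducible. The
reported protein list contains the members of the entry exactly matching
the chosen candidate (empty when the winner exists only inside larger
entries) — listing all included entries' proteins was the open alternative;
exact-match members are the ones whose annotation the prediction actually
restates. The full ranked reaction list (not a top-1 cut) is treated as the
prediction when scoring, since no cutoff is part of the model.

## Association-rule baseline

Each entry becomes one transaction whose items are its domains and ECs,
tagged by type. Frequent itemsets are mined levelwise (Apriori join +
subset pruning; supports counted via per-itemset transaction-id sets, which
is arithmetic-identical to a scan). Thresholds are **inclusive**:
support ≥ 3 transactions and confidence ≥ 0.6, so the stated threshold
values are attainable boundaries; both live in `ARConfig`. Every frequent
itemset containing at least one domain and one EC item admits exactly one
domain→EC split (the antecedent is its domain part, whose support is
frequent by anti-monotonicity), giving rules with multi-EC consequents
directly. Prediction unions the consequents of all rules whose antecedent
is a subset of the query; a best-rule-only mode (highest confidence, then
support) is available as an option. The transaction encoding is per merged
entry, not per protein, matching the per-entry evaluation unit.

## Cross-validation protocol

`run_cv` performs `runs` independent random repartitions into `n_folds`
near-equal folds (sizes differ by ≤ 1; 5,203 entries split 5 ways as
1,041/1,041/1,041/1,040/1,040). Each run–fold pair is one *simulation*:
both methods are trained on the training entries only and every test entry
is scored, stratified into single-EC and multiple-EC sets. Because
architectures are unique, a held-out entry can never take the exact-match
path — every test prediction exercises subset enumeration.

Per cell: **match** = the method produced any prediction; **hit** = match
and the predicted EC set equals the annotated set exactly (the strictest
reading of "predicted correctly"; an overlap criterion is available but not
the default); accuracy = hit/match, undefined (excluded from means, with a
count of defined simulations) when nothing matched. Rows `AR` and `ERP1`
use the full test stratum; `ERP2` re-scores the ERP predictions on exactly
the test entries AR matched, so `ERP2.testing = ERP2.match = AR.match` by
construction (any AR antecedent is a frequent domain set, hence deducible
for ERP). Aggregation reports mean ± sample standard deviation (ddof = 1;
0.0 below two samples) of per-simulation values — accuracies are averaged
as per-simulation ratios, not pooled counts. Run `r` seeds its partition
with `base_seed + r`; all randomness flows through one seeded generator per
run.

## Synthetic universes

The generator emulates the statistical shape of a real UniProtKB ×
SUPERFAMILY extraction without any download. Domains are partitioned into
disjoint *pools* of ~10; each pool carries a ground-truth EC set of size 1
or 2, with the share of 2-EC pools set by `multi_ec_fraction`. An entry
draws its multiplicity (multi with probability `multi_ec_fraction`, giving
an i.i.d. Bernoulli single:multiple split — 0.4 by default, the ~6:4 shape
of real data), picks a pool of that type, and samples its architecture
within the pool; `co_occurrence_strength` < 1 swaps each sampled domain out
of pool with probability 1 − strength, creating cross-pool architectures.
Defaults: 50 domains, 500 entries, 20 ECs, architecture sizes
{1: 0.2, 2: 0.3, 3: 0.3, 4: 0.2} (small fingerprints dominate real data),
`co_occurrence_strength = 1.0`, deterministic signal, seed 0.

In **deterministic** mode an entry's EC set is exactly the union of its
domains' ground-truth sets — even for cross-pool architectures. In
**noisy** mode each vocabulary EC additionally flips in or out of the label
with probability `noise_rate` (reverting if the label would become empty).
Architectures are deduplicated by rejection sampling with an attempt cap;
infeasible parameter combinations (more entries than distinct within-pool
architectures at strength 1) raise upfront.

What a green recovery test establishes — and what it does not: with pure
pools and no label noise, *any* deducible candidate of a held-out entry
predicts exactly the entry's EC set, so the 5-fold hit rate on test entries
whose singleton domains occur in training is 100%. This validates the
enumeration/ranking/scoring plumbing end to end, not the method's accuracy
on real data, where promiscuous domains, shared ECs across architectures
and annotation noise make included-EC unions strictly larger than the
truth. The generator does not model protein sequences, domain detection,
EC hierarchy structure, or per-protein (sub-entry) annotation conflicts.

The two worked-example fixtures are frozen constructions: a ten-entry
superset neighbourhood of {SSF56112, SSF57889} realizing the printed
constraints (10 included entries; pseudo-entry counts 2, 7, 6, 1, 1; exact
entry carrying 3 of the 5 reactions, succinctness 0.6) — the allocation of
reactions to the nine non-exact entries is one convenient realization,
documented in code, since only the aggregate constraints are pinned — and a
two-entry universe exercising the exact-match, subset-match and failure
report paths.

## Numerical and interface choices

* All set comparisons are on frozen sets; the canonical string form is used
  only for display and tie-breaks.
* Succinctness is an exact small-integer ratio in floating point; the
  consistency worked example is asserted to 1e−12.
* Entry order is insertion order everywhere, so every pipeline stage is
  deterministic given (inputs, seed); batch prediction is by contract
  order-independent across queries.
* Enumeration cap: 20 domains, a hard error rather than silent truncation.
* CLI exit codes: 0 success, 1 validation/usage error, 2 I/O or parse error
  (parse errors name the offending line).

## Known limitations

* Hit scoring demands exact EC-set equality; near-misses (correct reaction
  plus one spurious EC) count as matches but not hits.
* The predictor consults only the single best candidate; no evidence
  combination across candidates or confidence calibration is attempted.
* Partial (3-block) EC prediction and EC-class structure are out of scope.
* Apriori is the only mining algorithm provided; rule interestingness
  beyond support/confidence is not modelled.
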