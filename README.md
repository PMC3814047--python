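# erp — enzyme reaction prediction from domain architectures

`erp` annotates enzymes: given the *domain architecture* of a protein — the
set of structural-domain identifiers (SUPERFAMILY-style accessions such as
`SSF50729`) detected in its sequence — it predicts the enzyme reactions the
protein catalyzes, as 4-block EC numbers (`class.subclass.sub-subclass.serial`).
It is aimed at annotation pipelines where domain assignments are already
available (e.g. from InterPro/SUPERFAMILY cross-references) and sequence- or
structure-based EC predictors are too heavy or unavailable.

## The method

The reference data set (the *universe*) merges all proteins sharing one
architecture into a single **entry** carrying the union of their EC numbers.
A query architecture that matches an entry exactly is annotated directly.
Otherwise all 2^d − 2 proper sub-architectures (plus the query itself, which
may still occur inside larger entries) are scored with four measurements and
the best candidate is chosen:

1. **Existence** — 1 if some entry equals the candidate exactly, else 0.
2. **Succinctness** — `|ECs_exact| / |ECs_included|`: of the distinct
   reactions carried by entries *containing* the candidate, the fraction
   already carried by entries matching it *exactly*. Near 1 means the
   candidate catalyzes its reactions without auxiliary domains.
3. **Consistency** — split every entry containing the candidate into
   single-reaction pseudo-entries; with `n_i` pseudo-entries for reaction
   `EC_i`, `N = Σ n_i`, `k` reactions and mean `n̄ = N/k`,

   `Consistency = Σ_i (n_i/N) · ((n_i − n̄)/N)`

   This weighted dispersion is ≥ 0 and 0 exactly when every reaction is
   expressed equally — an unambiguous architecture/reaction relationship.
4. **Simplicity** — the candidate's domain count; fewer is better.

Candidates are ordered lexicographically by (existence ↓, succinctness ↓,
consistency ↑, simplicity ↑). The chosen architecture's reactions are then
ranked by **intensity** `n̄ / n_i`; values below 1 flag reactions expressed
above average, so low intensity ranks first.

For comparison the package ships an **association-rule baseline**: Apriori
frequent-itemset mining over entry transactions (items = domains + ECs) with
inclusive thresholds support ≥ 3 and confidence ≥ 0.6, predicting the union
of consequents of all firing `domains → ECs` rules. A repeated stratified
5-fold cross-validation harness scores both methods with Hit (exact EC-set
prediction) / Match (any prediction) accounting, separately for single-EC
and multiple-EC entries.

## Worked example

Build a two-entry universe ({SSF51110, SSF55486} → 3.4.24.21 and
{SSF54814} → 2.7.7.8) and query three architectures:

```sh
erp build -i entries.tsv -o model.json
# universe built: 2 entries, 3 domains, 2 EC numbers
erp predict -m model.json -q queries.txt
```

```
query: {SSF51110,SSF55486}
status: exact match
chosen architecture: {SSF51110,SSF55486}
succinctness: 1 (exact-match reactions 1 / included reactions 1)
consistency: 0
simplicity: 2 domain(s)
ranked reactions (intensity ascending, low preferred):
  EC 3.4.24.21  entries=1  intensity=1
proteins with the chosen architecture:
  F4KTN6 (F4KTN6_9SPHI)

query: {SSF54211,SSF54814}
status: subset match
chosen architecture: {SSF54814}
...
  EC 2.7.7.8  entries=1  intensity=1

query: {SSF54211,SSF54236}
status: failure
Enzyme reactions for the domain architecture {SSF54211,SSF54236} could not
be deduced from the universe data set.
```

The first query matches an entry exactly: succinctness 1 and consistency 0
say this architecture catalyzes 3.4.24.21 without auxiliary domains and is
associated with no other reaction; with a single reaction its intensity is
1\. The second query is unknown, but its subset {SSF54814} exists and wins
the ranking, yielding 2.7.7.8. The third query shares no domain with the
universe, so nothing can be deduced.

Other subcommands: `erp ar-train` / `erp ar-predict` (the association-rule
baseline), `erp eval` (repeated k-fold cross-validation tables) and
`erp simulate` (synthetic universes with a known domain → EC ground truth;
see `docs/methods.md`).

## Entry-table format

Plain TSV, one protein per line: accession, semicolon-joined domain
identifiers, semicolon-joined 4-block EC numbers, optional UniProt-style ID.
`#` lines are comments. Partial EC numbers (`2.7.11.-`) are rejected.

```
Q5VT25	SSF50729;SSF56112;SSF57889	2.7.11.1
Q9BZL6	SSF50729;SSF56112;SSF57889	2.7.11.13	Q9BZL6_HUMAN
```

## Reference values

`scripts/acceptance.py` rebuilds the worked-example fixtures and recomputes
the package's reference quantities (the succinctness and consistency worked
examples and the exact-match measurements of a lone single-reaction entry)
from scratch, writing them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
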