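"""Association-rule baseline: Apriori mining over entry transactions.

Each merged entry becomes one transaction whose items are its domains and
its EC numbers, tagged by type so that rule antecedents can be restricted to
domains and consequents to ECs.  Frequent itemsets are mined levelwise
(classic Apriori with candidate pruning); every frequent itemset mixing the
two item types yields one rule ``domains -> ECs`` kept when its confidence
clears the threshold.  Default thresholds are support 3 and confidence 0.6,
both inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

from .universe import DomainArchitecture, Universe

__all__ = [
    "DOMAIN_TAG",
    "EC_TAG",
    "ARConfig",
    "ARRule",
    "ARPrediction",
    "entries_to_transactions",
    "mine_frequent_itemsets",
    "generate_rules",
    "train_ar",
    "ar_predict",
    "rules_to_json",
    "rules_from_json",
]

DOMAIN_TAG = "D"
EC_TAG = "E"

Item = tuple[str, str]  # (tag, identifier)
Transaction = frozenset  # frozenset[Item]


@dataclass(frozen=True)
class ARConfig:
    """Mining thresholds; both are inclusive (>=)."""

    min_support: int = 3
    min_confidence: float = 0.6

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0 < self.min_confidence <= 1:
            raise ValueError("min_confidence must be in (0, 1]")


@dataclass(frozen=True)
class ARRule:
    """A mined rule: domain antecedent -> EC consequent."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: int
    confidence: float

    def to_dict(self) -> dict:
        return {
            "antecedent": sorted(self.antecedent),
            "consequent": sorted(self.consequent),
            "support": self.support,
            "confidence": self.confidence,
        }


@dataclass(frozen=True)
class ARPrediction:
    matched: bool
    ecs: frozenset[str]


def entries_to_transactions(universe: Universe) -> list[Transaction]:
    """One transaction per entry: tagged domain items plus tagged EC items."""
    return [
        frozenset(
            [(DOMAIN_TAG, d) for d in entry.architecture]
            + [(EC_TAG, ec) for ec in entry.ecs]
        )
        for entry in universe
    ]


def mine_frequent_itemsets(
    transactions: list[Transaction], config: ARConfig = ARConfig()
) -> dict[frozenset, int]:
    """Levelwise Apriori: all itemsets with support >= min_support.

    Supports are absolute transaction counts.  Candidate (k)-itemsets are
    joined from (k-1)-itemsets sharing a (k-2)-prefix and pruned when any
    (k-1)-subset is infrequent; supports are counted by intersecting
    per-itemset transaction-id sets, which is equivalent to a scan.
    """
    if not transactions:
        raise ValueError("transaction set must be non-empty")
    min_support = config.min_support

    # Level 1: transaction-id sets per single item.
    tidsets: dict[tuple, set[int]] = {}
    for tid, transaction in enumerate(transactions):
        for item in transaction:
            tidsets.setdefault((item,), set()).add(tid)
    level = {
        itemset: tids for itemset, tids in tidsets.items() if len(tids) >= min_support
    }
    frequent: dict[frozenset, int] = {
        frozenset(itemset): len(tids) for itemset, tids in level.items()
    }

    while level:
        prefixes = sorted(level)  # sorted tuples of items
        next_level: dict[tuple, set[int]] = {}
        frequent_keys = set(level)
        for i, left in enumerate(prefixes):
            for right in prefixes[i + 1 :]:
                if left[:-1] != right[:-1]:
                    break  # sorted order: no further shared prefix
                candidate = left + (right[-1],)
                # prune: every (k-1)-subset must be frequent
                if any(
                    candidate[:j] + candidate[j + 1 :] not in frequent_keys
                    for j in range(len(candidate) - 2)
                ):
                    continue
                tids = level[left] & level[right]
                if len(tids) >= min_support:
                    next_level[candidate] = tids
        for itemset, tids in next_level.items():
            frequent[frozenset(itemset)] = len(tids)
        level = next_level
    return frequent


def generate_rules(
    itemsets: dict[frozenset, int], config: ARConfig = ARConfig()
) -> list[ARRule]:
    """Rules X -> Y with X the domain items and Y the EC items of a frequent set.

    Since antecedents must be all-domain and consequents all-EC, each mixed
    frequent itemset admits exactly one split.  Confidence is
    support(X u Y) / support(X); kept when >= min_confidence (inclusive).
    Sorted by confidence desc, support desc, then canonical form.
    """
    rules: list[ARRule] = []
    for itemset, support in itemsets.items():
        domains = frozenset(name for tag, name in itemset if tag == DOMAIN_TAG)
        ecs = frozenset(name for tag, name in itemset if tag == EC_TAG)
        if not domains or not ecs:
            continue
        antecedent_key = frozenset((DOMAIN_TAG, d) for d in domains)
        antecedent_support = itemsets[antecedent_key]  # frequent by anti-monotonicity
        confidence = support / antecedent_support
        if confidence >= config.min_confidence:
            rules.append(
                ARRule(
                    antecedent=domains,
                    consequent=ecs,
                    support=support,
                    confidence=confidence,
                )
            )
    rules.sort(
        key=lambda r: (
            -r.confidence,
            -r.support,
            ",".join(sorted(r.antecedent)),
            ",".join(sorted(r.consequent)),
        )
    )
    return rules


def train_ar(universe: Universe, config: ARConfig = ARConfig()) -> list[ARRule]:
    """Mine frequent itemsets from a universe and derive the rule set."""
    transactions = entries_to_transactions(universe)
    if not transactions:
        return []
    itemsets = mine_frequent_itemsets(transactions, config)
    return generate_rules(itemsets, config)


def ar_predict(
    rules: Iterable[ARRule],
    query: DomainArchitecture,
    aggregate: str = "union",
) -> ARPrediction:
    """Apply the rule set to a query architecture.

    A rule fires when its antecedent is a subset of the query's domains.
    ``aggregate='union'`` (default) unions the consequents of all firing
    rules; ``'best'`` keeps only the highest-ranked firing rule's consequent.
    """
    if aggregate not in ("union", "best"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    query_set = frozenset(query)
    firing = [r for r in rules if r.antecedent <= query_set]
    if not firing:
        return ARPrediction(matched=False, ecs=frozenset())
    if aggregate == "best":
        return ARPrediction(matched=True, ecs=firing[0].consequent)
    ecs: set[str] = set()
    for rule in firing:
        ecs |= rule.consequent
    return ARPrediction(matched=True, ecs=frozenset(ecs))


def rules_to_json(rules: list[ARRule], config: ARConfig) -> str:
    return json.dumps(
        {
            "config": {
                "min_support": config.min_support,
                "min_confidence": config.min_confidence,
            },
            "rules": [r.to_dict() for r in rules],
        },
        indent=1,
    )


def rules_from_json(text: str) -> tuple[list[ARRule], ARConfig]:
    payload = json.loads(text)
    config = ARConfig(**payload["config"])
    rules = [
        ARRule(
            antecedent=frozenset(item["antecedent"]),
            consequent=frozenset(item["consequent"]),
            support=item["support"],
            confidence=item["confidence"],
        )
        for item in payload["rules"]
    ]
    return rules, config
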