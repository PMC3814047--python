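"""Synthetic universes and worked-example fixtures.

The random generator emulates the statistical shape of a real
UniProtKB x SUPERFAMILY extraction without any download: a few thousand
unique-architecture entries, a roughly 6:4 single-EC to multiple-EC split,
small architectures, and domains that co-occur preferentially.

Model: domains are partitioned into disjoint *pools*; each pool carries a
ground-truth EC set of size 1 (single pools) or 2 (multi pools).  An entry
draws its multiplicity (multi with probability ``multi_ec_fraction``), picks
a pool of that type, and samples its architecture from the pool's domains.
With ``co_occurrence_strength`` below 1, each sampled domain is swapped for
a random out-of-pool domain with probability ``1 - strength``, producing
cross-pool architectures.  In ``deterministic`` signal mode an entry's EC
set is exactly the union of its domains' ground-truth EC sets; ``noisy``
mode additionally flips each vocabulary EC in or out with probability
``noise_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .universe import DomainArchitecture, ProteinRecord, Universe, merge_into_entries

__all__ = [
    "SynthParams",
    "generate_universe",
    "worked_example_fig2",
    "worked_example_section3",
]


def _default_arch_sizes() -> dict[int, float]:
    # Small architectures dominate real SUPERFAMILY fingerprints; repeats of
    # a domain are ignored, so sizes rarely exceed a handful of domains.
    return {1: 0.2, 2: 0.3, 3: 0.3, 4: 0.2}


@dataclass
class SynthParams:
    """Generator parameters; defaults give a 500-entry, 50-domain universe
    with a 60:40 single:multiple EC split and noise-free pool structure."""

    n_domains: int = 50
    n_entries: int = 500
    n_ecs: int = 20
    arch_size_distribution: dict[int, float] = field(default_factory=_default_arch_sizes)
    multi_ec_fraction: float = 0.4
    co_occurrence_strength: float = 1.0
    signal_mode: str = "deterministic"
    noise_rate: float = 0.0
    pool_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.multi_ec_fraction <= 1:
            raise ValueError("multi_ec_fraction must be in [0, 1]")
        if not 0 <= self.co_occurrence_strength <= 1:
            raise ValueError("co_occurrence_strength must be in [0, 1]")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.signal_mode not in ("deterministic", "noisy"):
            raise ValueError("signal_mode must be 'deterministic' or 'noisy'")
        if self.n_domains < 2 or self.n_entries < 1 or self.n_ecs < 2:
            raise ValueError("need n_domains >= 2, n_entries >= 1, n_ecs >= 2")
        if self.pool_size < max(self.arch_size_distribution):
            raise ValueError("pool_size must cover the largest architecture size")
        total = sum(self.arch_size_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("arch_size_distribution probabilities must sum to 1")
        if any(s < 1 for s in self.arch_size_distribution):
            raise ValueError("architecture sizes must be >= 1")


def _capacity(params: SynthParams, pool_sizes: list[int]) -> int:
    """Distinct within-pool architectures available (a lower bound overall)."""
    sizes = list(params.arch_size_distribution)
    return sum(
        sum(math.comb(p, s) for s in sizes if s <= p) for p in pool_sizes
    )


def _ec_vocabulary(n_ecs: int) -> list[str]:
    # Valid 4-block EC strings cycling through the six NC-IUBMB classes.
    return [f"{i % 6 + 1}.{i // 6 + 1}.1.{i + 1}" for i in range(n_ecs)]


def generate_universe(params: SynthParams) -> tuple[Universe, dict[str, list[str]]]:
    """Generate a reproducible universe plus its ground-truth domain->EC map.

    Returns ``(universe, truth)`` where ``truth[domain]`` is the sorted list
    of ground-truth ECs of that domain's pool.  Raises ``ValueError`` when
    the architecture space cannot hold ``n_entries`` distinct entries.
    """
    rng = np.random.default_rng(params.seed)
    domains = [f"SSF9{i:04d}" for i in range(params.n_domains)]
    ec_vocab = _ec_vocabulary(params.n_ecs)

    # Partition domains into pools of ~pool_size.
    n_pools = max(2, params.n_domains // params.pool_size)
    pools: list[list[str]] = [list(chunk) for chunk in np.array_split(domains, n_pools)]
    pool_sizes = [len(p) for p in pools]

    if params.co_occurrence_strength == 1.0 and _capacity(params, pool_sizes) < params.n_entries:
        raise ValueError(
            f"architecture space ({_capacity(params, pool_sizes)} distinct "
            f"within-pool architectures) cannot hold {params.n_entries} entries"
        )

    # Assign pool types: ~multi_ec_fraction of pools carry 2-EC truth sets.
    n_multi_pools = round(n_pools * params.multi_ec_fraction)
    if params.multi_ec_fraction > 0:
        n_multi_pools = max(1, n_multi_pools)
    if params.multi_ec_fraction < 1:
        n_multi_pools = min(n_pools - 1, n_multi_pools)
    pool_types = [i < n_multi_pools for i in range(n_pools)]  # True = multi

    # Assign EC truth sets per pool, consuming the vocabulary cyclically.
    truth: dict[str, list[str]] = {}
    pool_ecs: list[frozenset[str]] = []
    cursor = 0
    for pool, is_multi in zip(pools, pool_types):
        want = 2 if is_multi else 1
        ecs = frozenset(ec_vocab[(cursor + j) % len(ec_vocab)] for j in range(want))
        cursor += want
        pool_ecs.append(ecs)
        for domain in pool:
            truth[domain] = sorted(ecs)

    sizes = np.array(sorted(params.arch_size_distribution))
    size_probs = np.array([params.arch_size_distribution[int(s)] for s in sizes])
    multi_pool_idx = [i for i, m in enumerate(pool_types) if m]
    single_pool_idx = [i for i, m in enumerate(pool_types) if not m]

    seen: set[frozenset] = set()
    records: list[ProteinRecord] = []
    attempts = 0
    max_attempts = 200 * params.n_entries
    while len(records) < params.n_entries:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place all entries with distinct architectures; "
                "parameters are infeasible"
            )
        is_multi = rng.random() < params.multi_ec_fraction
        candidates = multi_pool_idx if is_multi else single_pool_idx
        pool_idx = int(rng.choice(candidates)) if candidates else int(rng.integers(n_pools))
        pool = pools[pool_idx]
        size = int(rng.choice(sizes, p=size_probs))
        size = min(size, len(pool))
        members = list(rng.choice(pool, size=size, replace=False))
        if params.co_occurrence_strength < 1.0:
            for j in range(len(members)):
                if rng.random() < 1.0 - params.co_occurrence_strength:
                    members[j] = domains[int(rng.integers(params.n_domains))]
        arch = frozenset(members)
        if arch in seen:
            continue
        seen.add(arch)
        ecs: set[str] = set()
        for domain in arch:
            ecs |= set(truth[domain])
        if params.signal_mode == "noisy" and params.noise_rate > 0:
            flipped = set(ecs)
            for ec in ec_vocab:
                if rng.random() < params.noise_rate:
                    flipped.symmetric_difference_update({ec})
            if flipped:  # never leave an entry without reactions
                ecs = flipped
        idx = len(records)
        records.append(
            ProteinRecord(
                accession=f"P{idx:06d}",
                domains=DomainArchitecture(arch),
                ecs=frozenset(ecs),
                uniprot_id=f"P{idx:06d}_SYN",
            )
        )
    return merge_into_entries(records), truth


def worked_example_fig2() -> Universe:
    """A small universe realizing the printed two-domain worked example.

    Exactly 10 entries contain {SSF56112, SSF57889}; splitting them into
    single-reaction pseudo-entries yields counts {2.7.10.2: 2, 2.7.11.1: 7,
    2.7.11.13: 6, 2.7.1.107: 1, 1.3.1.74: 1} (N = 17, k = 5), and the
    exact-match entry carries exactly {2.7.10.2, 2.7.11.1, 2.7.11.13}, so
    the pair's succinctness is 3/5 = 0.6.  Only the printed constraints pin
    the fixture down; the particular allocation of reactions to the other
    nine superset entries is one convenient realization.

    The universe also contains entries for every other subset of
    {SSF50729, SSF56112, SSF57889}, each with one private reaction, so that
    all six sub-architectures of that query exist and {SSF56112, SSF57889}
    wins the ranking on succinctness.
    """
    pair = ["SSF56112", "SSF57889"]
    superset_ecs = [
        # one extra domain per entry; EC lists chosen so column sums match
        ("SSF50729", ["2.7.11.1", "2.7.11.13", "1.3.1.74"]),  # merged-entry example
        ("SSF10003", ["2.7.10.2", "2.7.11.1"]),
        ("SSF10004", ["2.7.11.1", "2.7.11.13"]),
        ("SSF10005", ["2.7.11.1", "2.7.11.13"]),
        ("SSF10006", ["2.7.11.1"]),
        ("SSF10007", ["2.7.11.1"]),
        ("SSF10008", ["2.7.11.13"]),
        ("SSF10009", ["2.7.11.13"]),
        ("SSF10010", ["2.7.1.107"]),
    ]
    records = [
        # The exact match of the pair.
        ProteinRecord("PEX001", DomainArchitecture(pair),
                      frozenset(["2.7.10.2", "2.7.11.1", "2.7.11.13"])),
    ]
    # Three proteins sharing the {SSF50729, SSF56112, SSF57889} architecture
    # merge into one entry with the union of their reactions.
    records += [
        ProteinRecord("Q5VT25", DomainArchitecture(pair + ["SSF50729"]),
                      frozenset(["2.7.11.1"])),
        ProteinRecord("Q9BZL6", DomainArchitecture(pair + ["SSF50729"]),
                      frozenset(["2.7.11.13"])),
        ProteinRecord("E0W264", DomainArchitecture(pair + ["SSF50729"]),
                      frozenset(["1.3.1.74", "2.7.11.13"])),
    ]
    for i, (extra, ecs) in enumerate(superset_ecs[1:], start=2):
        records.append(
            ProteinRecord(f"PSUP{i:03d}", DomainArchitecture(pair + [extra]),
                          frozenset(ecs))
        )
    # Entries making every other subset of the 3-domain query exist, each
    # with a private reaction so their succinctness stays low.
    extras = [
        (["SSF50729", "SSF56112"], "5.3.1.1"),
        (["SSF50729", "SSF57889"], "4.2.1.11"),
        (["SSF50729"], "6.3.2.6"),
        (["SSF56112"], "3.1.3.3"),
        (["SSF57889"], "1.1.1.27"),
    ]
    for i, (arch, ec) in enumerate(extras, start=1):
        records.append(
            ProteinRecord(f"PSUB{i:03d}", DomainArchitecture(arch), frozenset([ec]))
        )
    return merge_into_entries(records)


def worked_example_section3() -> Universe:
    """The two single-entry query scenarios used by the report examples.

    Contains {SSF51110, SSF55486} -> 3.4.24.21 (protein F4KTN6) and
    {SSF54814} -> 2.7.7.8 (protein D9PMT6); the domains SSF54211 and
    SSF54236 occur in no entry, so queries built only from them fail.
    """
    records = [
        ProteinRecord(
            "F4KTN6",
            DomainArchitecture(["SSF51110", "SSF55486"]),
            frozenset(["3.4.24.21"]),
            uniprot_id="F4KTN6_9SPHI",
        ),
        ProteinRecord(
            "D9PMT6",
            DomainArchitecture(["SSF54814"]),
            frozenset(["2.7.7.8"]),
            uniprot_id="D9PMT6_9ZZZZ",
        ),
    ]
    return merge_into_entries(records)
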