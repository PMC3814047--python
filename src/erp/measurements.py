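"""Priority measurements for candidate sub-architectures and EC ranking.

Four measurements prioritize candidate architectures during subset
enumeration:

* **existence** — 1 if some entry's architecture equals the candidate
  exactly, else 0; an exact structural witness outranks everything else.
* **succinctness** — ``|ECs_exact| / |ECs_included|``, the fraction of
  reactions reachable from entries *containing* the candidate that are
  already carried by entries matching it *exactly*.  A value near 1 means
  the candidate catalyzes its reactions without auxiliary domains.
* **consistency** — a weighted dispersion of per-reaction entry counts,
  ``sum_i (n_i/N) * ((n_i - N/k)/N)`` where ``n_i`` counts included entries
  annotated with reaction ``EC_i`` after splitting multi-reaction entries
  into single-reaction pseudo-entries, ``N = sum n_i`` and ``k`` is the
  number of distinct reactions.  Zero means every reaction is expressed
  equally, i.e. an unambiguous architecture/reaction relationship.
* **simplicity** — the candidate's domain count; fewer domains preferred
  when nothing else separates candidates.

Once an architecture is chosen, its reactions are ranked by **intensity**
``n_bar / n_i`` (mean pseudo-entry count over the reaction's count); values
below 1 flag reactions expressed above average, so low intensity ranks
first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .universe import DomainArchitecture, Entry, Universe

__all__ = [
    "NonDeducibleError",
    "SuccinctnessBreakdown",
    "ReactionCounts",
    "MeasurementVector",
    "included_entries",
    "existence",
    "succinctness",
    "reaction_counts",
    "consistency",
    "intensity",
    "measurement_vector",
]


class NonDeducibleError(LookupError):
    """No entry's architecture contains the candidate: nothing to measure."""

    def __init__(self, arch: DomainArchitecture):
        super().__init__(
            f"architecture {{{arch.canonical}}} is contained in no entry; "
            "its measurements are undefined"
        )
        self.architecture = arch


def included_entries(universe: Universe, arch: DomainArchitecture) -> list[Entry]:
    """Entries whose architecture is a superset (not necessarily proper) of *arch*.

    Uses the per-domain index: only entries containing the rarest domain of
    the candidate are scanned.  Order follows universe entry order.
    """
    if not arch:
        raise ValueError("architecture must be non-empty")
    postings = []
    for domain in arch:
        entries = universe.by_domain.get(domain)
        if not entries:
            return []
        postings.append(entries)
    smallest = min(postings, key=len)
    target = frozenset(arch)
    return [e for e in smallest if target <= e.architecture]


def existence(universe: Universe, arch: DomainArchitecture) -> int:
    """1 iff an entry with exactly this architecture exists, else 0."""
    return 1 if frozenset(arch) in universe.by_architecture else 0


@dataclass(frozen=True)
class SuccinctnessBreakdown:
    """The two EC sets behind a succinctness ratio."""

    ecs_exact: frozenset[str]
    ecs_included: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ecs_included:
            raise ValueError("succinctness is undefined without included entries")
        if not self.ecs_exact <= self.ecs_included:
            raise ValueError("exact-match ECs must be a subset of included ECs")

    @property
    def value(self) -> float:
        return len(self.ecs_exact) / len(self.ecs_included)


def succinctness(universe: Universe, arch: DomainArchitecture) -> SuccinctnessBreakdown:
    """Ratio of distinct exact-match reactions to distinct included reactions.

    Raises :class:`NonDeducibleError` when no entry contains the candidate.
    """
    included = included_entries(universe, arch)
    if not included:
        raise NonDeducibleError(arch)
    ecs_included: set[str] = set()
    for entry in included:
        ecs_included |= entry.ecs
    exact = universe.by_architecture.get(frozenset(arch))
    ecs_exact = frozenset(exact.ecs) if exact is not None else frozenset()
    return SuccinctnessBreakdown(ecs_exact=ecs_exact, ecs_included=frozenset(ecs_included))


@dataclass(frozen=True)
class ReactionCounts:
    """Per-reaction pseudo-entry counts for one candidate architecture.

    Splitting every included multi-reaction entry into single-reaction
    pseudo-entries, ``counts[EC_i] = n_i`` is the number of included entries
    annotated with ``EC_i`` (each entry contributes at most 1 per EC),
    ``N = sum n_i`` and ``k`` is the number of distinct reactions.
    """

    counts: dict[str, int]
    N: int
    k: int

    def __post_init__(self) -> None:
        if self.k != len(self.counts):
            raise ValueError("k must equal the number of distinct ECs")
        if self.N != sum(self.counts.values()):
            raise ValueError("N must equal the sum of per-EC counts")
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("every per-EC count must be >= 1")

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "ReactionCounts":
        ordered = dict(sorted(counts.items()))
        return cls(counts=ordered, N=sum(ordered.values()), k=len(ordered))

    @property
    def mean(self) -> float:
        """Mean pseudo-entry count n_bar = N / k, kept at full precision."""
        return self.N / self.k


def reaction_counts(universe: Universe, arch: DomainArchitecture) -> ReactionCounts:
    """Pseudo-entry counts over the candidate's included entries."""
    included = included_entries(universe, arch)
    if not included:
        raise NonDeducibleError(arch)
    counts: dict[str, int] = {}
    for entry in included:
        for ec in entry.ecs:
            counts[ec] = counts.get(ec, 0) + 1
    return ReactionCounts.from_counts(counts)


def consistency(counts: ReactionCounts) -> float:
    """Weighted dispersion sum_i (n_i/N) * ((n_i - n_bar)/N).

    Always >= 0 (it equals ``(sum n_i^2 - N^2/k) / N^2``) and 0 exactly when
    all counts are equal.
    """
    N = counts.N
    mean = counts.mean
    return sum((n / N) * ((n - mean) / N) for n in counts.counts.values())


def intensity(counts: ReactionCounts) -> dict[str, float]:
    """Intensity n_bar / n_i per reaction, sorted ascending (low preferred).

    Ties (equal counts) break lexicographically on the EC string so batch
    output is deterministic.
    """
    mean = counts.mean
    items = sorted(counts.counts.items(), key=lambda kv: (mean / kv[1], kv[0]))
    return {ec: mean / n for ec, n in items}


@dataclass(frozen=True)
class MeasurementVector:
    """The four prioritization measurements for one candidate architecture."""

    architecture: DomainArchitecture
    existence: int
    succinctness: SuccinctnessBreakdown
    consistency: float
    simplicity: int

    @property
    def sort_key(self) -> tuple:
        """Lexicographic priority key: existence desc, succinctness desc,
        consistency asc, simplicity asc, canonical form asc."""
        return (
            -self.existence,
            -self.succinctness.value,
            self.consistency,
            self.simplicity,
            self.architecture.canonical,
        )

    def to_dict(self) -> dict:
        return {
            "architecture": sorted(self.architecture),
            "existence": self.existence,
            "succinctness": self.succinctness.value,
            "ecs_exact": sorted(self.succinctness.ecs_exact),
            "ecs_included": sorted(self.succinctness.ecs_included),
            "consistency": self.consistency,
            "simplicity": self.simplicity,
        }


def measurement_vector(universe: Universe, arch: DomainArchitecture) -> MeasurementVector:
    """Bundle existence, succinctness, consistency and simplicity for *arch*.

    Raises :class:`NonDeducibleError` when the candidate is contained in no
    entry (all measurements undefined).
    """
    breakdown = succinctness(universe, arch)  # raises NonDeducibleError if empty
    counts = reaction_counts(universe, arch)
    return MeasurementVector(
        architecture=DomainArchitecture(arch),
        existence=existence(universe, arch),
        succinctness=breakdown,
        consistency=consistency(counts),
        simplicity=len(arch),
    )
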