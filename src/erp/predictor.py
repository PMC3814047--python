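"""Query workflow: subset enumeration, candidate ranking, prediction reports.

Given a query architecture, the predictor first looks for an entry with the
exact same architecture.  If none exists, all proper non-empty subsets of the
query (plus the query itself, which may still be contained in larger
entries) are scored with the four measurements and the best candidate under
the lexicographic priority key is chosen.  The chosen architecture's
reactions are then ranked by intensity.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .measurements import (
    MeasurementVector,
    NonDeducibleError,
    intensity,
    measurement_vector,
    reaction_counts,
)
from .universe import DomainArchitecture, Universe

__all__ = [
    "MAX_ENUMERATION_DOMAINS",
    "ArchitectureTooLargeError",
    "RankedEC",
    "PredictionResult",
    "enumerate_subarchitectures",
    "rank_candidates",
    "predict",
    "predict_batch",
    "format_report",
    "parse_query_line",
    "parse_query_file",
]

#: Queries above this domain count would enumerate > 2^20 subsets; refuse.
MAX_ENUMERATION_DOMAINS = 20

FAILURE = "failure"
EXACT_MATCH = "exact_match"
SUBSET_MATCH = "subset_match"


class ArchitectureTooLargeError(ValueError):
    def __init__(self, arch: DomainArchitecture, cap: int):
        super().__init__(
            f"architecture with {len(arch)} domains exceeds the enumeration "
            f"cap of {cap} (would enumerate 2^{len(arch)} - 2 subsets)"
        )


class RankedEC(NamedTuple):
    ec: str
    count: int
    intensity: float


@dataclass
class PredictionResult:
    """Outcome of one query: status, chosen candidate, ranked reactions."""

    query: DomainArchitecture
    status: str
    chosen: MeasurementVector | None = None
    ranked_ecs: list[RankedEC] = field(default_factory=list)
    proteins: list[tuple[str, str | None]] = field(default_factory=list)
    error: str | None = None

    @property
    def ecs(self) -> frozenset[str]:
        return frozenset(r.ec for r in self.ranked_ecs)

    def to_dict(self) -> dict:
        return {
            "query": sorted(self.query),
            "status": self.status,
            "chosen": self.chosen.to_dict() if self.chosen else None,
            "ranked_ecs": [
                {"ec": r.ec, "count": r.count, "intensity": r.intensity}
                for r in self.ranked_ecs
            ],
            "proteins": [[acc, uid] for acc, uid in self.proteins],
            "error": self.error,
        }


def enumerate_subarchitectures(
    arch: DomainArchitecture, cap: int = MAX_ENUMERATION_DOMAINS
) -> list[DomainArchitecture]:
    """All proper non-empty subsets of *arch* (2^d - 2 of them).

    Ordered by decreasing size, then by canonical (sorted, comma-joined)
    form, so larger — more specific — candidates are considered first.
    """
    if len(arch) > cap:
        raise ArchitectureTooLargeError(arch, cap)
    domains = sorted(arch)
    subsets: list[DomainArchitecture] = []
    for size in range(len(domains) - 1, 0, -1):
        for combo in itertools.combinations(domains, size):
            subsets.append(DomainArchitecture(combo))
    return subsets


def rank_candidates(
    universe: Universe, candidates: Iterable[DomainArchitecture]
) -> list[MeasurementVector]:
    """Score candidates and sort best-first under the priority key.

    Non-deducible candidates (contained in no entry) are dropped; duplicates
    keep their first occurrence.  The key orders by existence (desc),
    succinctness (desc), consistency (asc), simplicity (asc), with a final
    tie-break on the canonical architecture string.
    """
    vectors: list[MeasurementVector] = []
    seen: set[frozenset] = set()
    for arch in candidates:
        key = frozenset(arch)
        if key in seen:
            continue
        seen.add(key)
        try:
            vectors.append(measurement_vector(universe, arch))
        except NonDeducibleError:
            continue
    vectors.sort(key=lambda v: v.sort_key)
    return vectors


def _ranked_ecs(universe: Universe, arch: DomainArchitecture) -> list[RankedEC]:
    counts = reaction_counts(universe, arch)
    return [
        RankedEC(ec=ec, count=counts.counts[ec], intensity=value)
        for ec, value in intensity(counts).items()
    ]


def _exact_proteins(universe: Universe, arch: DomainArchitecture) -> list:
    entry = universe.by_architecture.get(frozenset(arch))
    return list(entry.proteins) if entry is not None else []


def predict(
    universe: Universe,
    query: DomainArchitecture,
    cap: int = MAX_ENUMERATION_DOMAINS,
) -> PredictionResult:
    """Predict the enzyme reactions catalyzed by a query architecture.

    Exact-architecture hits short-circuit enumeration.  Otherwise every
    proper subset plus the query itself competes; if none is deducible the
    result is a failure.
    """
    query = DomainArchitecture(query)
    if frozenset(query) in universe.by_architecture:
        chosen = measurement_vector(universe, query)
        return PredictionResult(
            query=query,
            status=EXACT_MATCH,
            chosen=chosen,
            ranked_ecs=_ranked_ecs(universe, query),
            proteins=_exact_proteins(universe, query),
        )
    candidates = enumerate_subarchitectures(query, cap=cap) + [query]
    ranking = rank_candidates(universe, candidates)
    if not ranking:
        return PredictionResult(query=query, status=FAILURE)
    chosen = ranking[0]
    return PredictionResult(
        query=query,
        status=SUBSET_MATCH,
        chosen=chosen,
        ranked_ecs=_ranked_ecs(universe, chosen.architecture),
        proteins=_exact_proteins(universe, chosen.architecture),
    )


def predict_batch(
    universe: Universe, queries: Iterable[DomainArchitecture]
) -> list[PredictionResult]:
    """Predict every query independently, preserving input order.

    Per-query errors (e.g. an over-cap architecture) are recorded in that
    query's result and the batch continues.
    """
    results: list[PredictionResult] = []
    for query in queries:
        try:
            results.append(predict(universe, query))
        except (ArchitectureTooLargeError, ValueError) as exc:
            results.append(
                PredictionResult(
                    query=DomainArchitecture(query) if query else query,
                    status=FAILURE,
                    error=str(exc),
                )
            )
    return results


def format_report(result: PredictionResult) -> str:
    """Render a human-readable report for one prediction."""
    lines = [f"query: {{{result.query.canonical}}}"]
    if result.status == FAILURE:
        lines.append("status: failure")
        if result.error:
            lines.append(f"error: {result.error}")
        lines.append(
            f"Enzyme reactions for the domain architecture "
            f"{{{result.query.canonical}}} could not be deduced from the "
            f"universe data set."
        )
        return "\n".join(lines) + "\n"
    label = "exact match" if result.status == EXACT_MATCH else "subset match"
    chosen = result.chosen
    lines.append(f"status: {label}")
    lines.append(f"chosen architecture: {{{chosen.architecture.canonical}}}")
    b = chosen.succinctness
    lines.append(
        f"succinctness: {b.value:g} "
        f"(exact-match reactions {len(b.ecs_exact)} / included reactions {len(b.ecs_included)})"
    )
    lines.append(f"consistency: {chosen.consistency:g}")
    lines.append(f"simplicity: {chosen.simplicity} domain(s)")
    lines.append("ranked reactions (intensity ascending, low preferred):")
    for r in result.ranked_ecs:
        lines.append(f"  EC {r.ec}  entries={r.count}  intensity={r.intensity:g}")
    if result.proteins:
        lines.append("proteins with the chosen architecture:")
        for accession, uniprot_id in result.proteins:
            suffix = f" ({uniprot_id})" if uniprot_id else ""
            lines.append(f"  {accession}{suffix}")
    return "\n".join(lines) + "\n"


_STATUS_RE = re.compile(r"^status: (failure|exact match|subset match)$", re.M)
_CHOSEN_RE = re.compile(r"^chosen architecture: \{([^}]*)\}$", re.M)
_EC_RE = re.compile(r"^  EC (\S+) ", re.M)


def parse_report(text: str) -> tuple[str, DomainArchitecture | None, str | None]:
    """Extract (status, chosen architecture, top EC) back out of a report."""
    m = _STATUS_RE.search(text)
    if not m:
        raise ValueError("no status line found")
    status = m.group(1).replace(" ", "_")
    chosen_m = _CHOSEN_RE.search(text)
    chosen = DomainArchitecture.from_string(chosen_m.group(1)) if chosen_m else None
    ec_m = _EC_RE.search(text)
    return status, chosen, ec_m.group(1) if ec_m else None


def parse_query_line(line: str) -> DomainArchitecture:
    """Parse one query architecture; domains comma- or space-delimited."""
    return DomainArchitecture.from_string(line)


def parse_query_file(stream: Iterable[str]) -> list[DomainArchitecture]:
    queries = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        queries.append(parse_query_line(line))
    return queries
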