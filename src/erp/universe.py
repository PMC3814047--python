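"""Entry/universe data model for domain-architecture -> EC-number mapping.

A protein is represented by its *domain architecture*: the set of structural
domain identifiers (SUPERFAMILY-style accessions, e.g. ``SSF50729``) detected
in its sequence, with repetitions ignored.  All proteins sharing one
architecture are merged into a single *entry* that carries the union of their
EC-number annotations.  The collection of entries, together with lookup
indexes by domain and by architecture, forms the *universe* against which
queries are evaluated.

The on-disk entry table is plain TSV: one protein per line with at least
three tab-separated fields — accession, semicolon-joined domain identifiers,
semicolon-joined 4-block EC numbers — and an optional fourth field holding a
UniProt-style ID.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "EC_PATTERN",
    "EntryTableError",
    "DomainArchitecture",
    "ProteinRecord",
    "Entry",
    "Universe",
    "parse_entry_table",
    "merge_into_entries",
    "split_single_multi",
    "write_entry_table",
]

#: A complete EC number: four dot-separated numeric blocks.  Partial ECs such
#: as ``2.7.11.-`` are rejected; only fully specified reactions are modelled.
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


class EntryTableError(ValueError):
    """Raised when an entry-table line cannot be parsed or validated."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DomainArchitecture(frozenset):
    """An unordered, duplicate-free set of domain identifiers.

    Equality and hashing are inherited from :class:`frozenset`, so
    architectures compare order-insensitively and interoperate with plain
    frozensets.  The canonical text form is the lexicographically sorted,
    comma-joined domain list.
    """

    __slots__ = ()

    def __new__(cls, domains: Iterable[str]) -> "DomainArchitecture":
        arch = super().__new__(cls, domains)
        if not arch:
            raise ValueError("a domain architecture must contain at least one domain")
        if not all(isinstance(d, str) and d.strip() for d in arch):
            raise ValueError("domain identifiers must be non-empty strings")
        return arch

    @classmethod
    def from_string(cls, text: str) -> "DomainArchitecture":
        """Parse a comma- or whitespace-delimited list of domain identifiers."""
        tokens = [t for t in re.split(r"[,\s;]+", text.strip()) if t]
        if not tokens:
            raise ValueError(f"no domain identifiers found in {text!r}")
        return cls(tokens)

    @property
    def canonical(self) -> str:
        return ",".join(sorted(self))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DomainArchitecture({{{self.canonical}}})"


def _validate_ecs(ecs: Iterable[str], line_number: int | None = None) -> frozenset[str]:
    ecs = frozenset(ecs)
    if not ecs:
        raise EntryTableError("empty EC field", line_number)
    for ec in ecs:
        if not EC_PATTERN.match(ec):
            raise EntryTableError(
                f"invalid EC number {ec!r} (need four numeric blocks a.b.c.d)",
                line_number,
            )
    return ecs


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, its domain set, and its EC annotations."""

    accession: str
    domains: DomainArchitecture
    ecs: frozenset[str]
    uniprot_id: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.domains, DomainArchitecture):
            object.__setattr__(self, "domains", DomainArchitecture(self.domains))
        object.__setattr__(self, "ecs", _validate_ecs(self.ecs))


@dataclass(frozen=True)
class Entry:
    """A unique architecture with the union of ECs of all member proteins."""

    architecture: DomainArchitecture
    ecs: frozenset[str]
    proteins: tuple[tuple[str, str | None], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not isinstance(self.architecture, DomainArchitecture):
            object.__setattr__(self, "architecture", DomainArchitecture(self.architecture))
        object.__setattr__(self, "ecs", _validate_ecs(self.ecs))
        object.__setattr__(self, "proteins", tuple(tuple(p) for p in self.proteins))

    @property
    def is_single_ec(self) -> bool:
        return len(self.ecs) == 1


class Universe:
    """An indexed collection of entries with unique architectures."""

    def __init__(self, entries: Iterable[Entry]):
        self.entries: list[Entry] = list(entries)
        self.by_architecture: dict[frozenset, Entry] = {}
        self.by_domain: dict[str, list[Entry]] = {}
        for entry in self.entries:
            if entry.architecture in self.by_architecture:
                raise ValueError(
                    f"duplicate architecture {entry.architecture.canonical!r}; "
                    "merge proteins into entries first"
                )
            self.by_architecture[entry.architecture] = entry
            for domain in entry.architecture:
                self.by_domain.setdefault(domain, []).append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Entry]:
        return iter(self.entries)

    def __contains__(self, architecture) -> bool:
        return frozenset(architecture) in self.by_architecture

    @property
    def domains(self) -> set[str]:
        return set(self.by_domain)

    @property
    def ecs(self) -> set[str]:
        out: set[str] = set()
        for entry in self.entries:
            out |= entry.ecs
        return out

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "Universe":
        return merge_into_entries(records)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "architecture": sorted(e.architecture),
                    "ecs": sorted(e.ecs),
                    "proteins": [[acc, uid] for acc, uid in e.proteins],
                }
                for e in self.entries
            ],
            "metadata": {
                "n_entries": len(self.entries),
                "n_domains": len(self.by_domain),
                "n_ecs": len(self.ecs),
            },
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "Universe":
        entries = [
            Entry(
                architecture=DomainArchitecture(item["architecture"]),
                ecs=frozenset(item["ecs"]),
                proteins=tuple((acc, uid) for acc, uid in item.get("proteins", [])),
            )
            for item in payload["entries"]
        ]
        return cls(entries)

    @classmethod
    def from_json(cls, text: str) -> "Universe":
        return cls.from_dict(json.loads(text))


def parse_entry_table(stream: Iterable[str]) -> list[ProteinRecord]:
    """Parse a TSV entry table into protein records.

    Each non-comment line needs >= 3 tab-separated fields: accession,
    semicolon-joined domains, semicolon-joined ECs, optionally a UniProt ID.
    Duplicated domains or ECs within a line collapse (set semantics).
    Raises :class:`EntryTableError` naming the offending line number.
    """
    records: list[ProteinRecord] = []
    for line_number, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise EntryTableError(
                f"expected >= 3 tab-separated fields, got {len(fields)}", line_number
            )
        accession = fields[0].strip()
        if not accession:
            raise EntryTableError("empty accession field", line_number)
        domains = [d.strip() for d in fields[1].split(";") if d.strip()]
        if not domains:
            raise EntryTableError("empty domain field", line_number)
        ecs = [e.strip() for e in fields[2].split(";") if e.strip()]
        ecs = _validate_ecs(ecs, line_number)
        uniprot_id = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
        records.append(
            ProteinRecord(
                accession=accession,
                domains=DomainArchitecture(domains),
                ecs=frozenset(ecs),
                uniprot_id=uniprot_id,
            )
        )
    return records


def merge_into_entries(records: Iterable[ProteinRecord]) -> Universe:
    """Merge proteins sharing a domain architecture into single entries.

    The resulting entry carries the union of its member proteins' EC numbers
    and the full member list; entry order follows first appearance.
    """
    grouped: dict[frozenset, dict] = {}
    for rec in records:
        slot = grouped.setdefault(
            rec.domains, {"arch": rec.domains, "ecs": set(), "proteins": []}
        )
        slot["ecs"] |= rec.ecs
        slot["proteins"].append((rec.accession, rec.uniprot_id))
    entries = [
        Entry(
            architecture=slot["arch"],
            ecs=frozenset(slot["ecs"]),
            proteins=tuple(slot["proteins"]),
        )
        for slot in grouped.values()
    ]
    return Universe(entries)


def split_single_multi(universe: Universe) -> tuple[list[Entry], list[Entry]]:
    """Partition entries into (single-EC, multiple-EC) lists."""
    single = [e for e in universe if e.is_single_ec]
    multi = [e for e in universe if not e.is_single_ec]
    return single, multi


def write_entry_table(universe: Universe, handle: IO[str]) -> None:
    """Write a universe back to entry-table TSV, one line per protein.

    Per-protein EC attribution is not retained after merging, so every
    protein of an entry is written with the entry's full EC union; the
    round trip is lossless at the entry level.
    """
    handle.write("# accession\tdomains\tecs\tuniprot_id\n")
    for entry in universe:
        domains = ";".join(sorted(entry.architecture))
        ecs = ";".join(sorted(entry.ecs))
        for accession, uniprot_id in entry.proteins:
            handle.write(f"{accession}\t{domains}\t{ecs}\t{uniprot_id or ''}\n")
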