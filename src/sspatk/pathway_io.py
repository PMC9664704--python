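"""Pathway collections: parsing, coverage filtering, and set-overlap statistics.

A pathway is represented by the set of metabolite identifiers annotated
to it.  Collections are ordered (source-file order matters for the
greedy non-redundant construction) and can be read from GMT files or
from the Reactome ``ChEBI2Reactome_All_Levels.txt`` flat file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "PathwayCollection",
    "CoverageView",
    "parse_gmt",
    "write_gmt",
    "parse_reactome_chebi",
    "filter_by_coverage",
    "overlap_coefficient",
    "build_nonredundant_set",
]


def _normalize_id(identifier: str) -> str:
    """Trim whitespace; uppercase a leading ``chebi:`` prefix."""
    identifier = identifier.strip()
    if identifier.lower().startswith("chebi:"):
        identifier = "CHEBI:" + identifier[6:]
    return identifier


@dataclass
class PathwayCollection:
    """Ordered, named sets of metabolite identifiers.

    ``entries`` maps pathway_id -> (display name, frozenset of member
    identifiers); insertion order is preserved and meaningful.
    """

    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    source: str = "gmt"
    species: str = ""

    def __post_init__(self) -> None:
        for pid, (_, members) in self.entries.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.entries)

    def name(self, pathway_id: str) -> str:
        return self.entries[pathway_id][0]

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.entries[pathway_id][1]

    def all_members(self) -> frozenset[str]:
        """Union of all member sets."""
        out: set[str] = set()
        for _, members in self.entries.values():
            out |= members
        return frozenset(out)

    def subset(self, pathway_ids: Iterable[str]) -> "PathwayCollection":
        return PathwayCollection(
            entries={pid: self.entries[pid] for pid in pathway_ids},
            source=self.source,
            species=self.species,
        )

    @classmethod
    def from_dict(
        cls,
        sets: dict[str, Iterable[str]],
        source: str = "synthetic",
        names: dict[str, str] | None = None,
        species: str = "",
    ) -> "PathwayCollection":
        entries = {
            pid: ((names or {}).get(pid, pid), frozenset(members))
            for pid, members in sets.items()
        }
        return cls(entries=entries, source=source, species=species)


@dataclass(frozen=True)
class CoverageView:
    """Measured coverage of one pathway within a given abundance matrix."""

    pathway_id: str
    full_size: int
    measured_members: frozenset[str]

    @property
    def coverage(self) -> int:
        return len(self.measured_members)


class GMTParseError(ValueError):
    pass


def parse_gmt(path) -> PathwayCollection:
    """Parse a GMT file (one set per line: id, description, members...).

    Duplicate member identifiers within a line collapse to one; a line
    with fewer than three fields or a repeated pathway id is an error.
    """
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *raw_members = fields
            if pid in entries:
                raise GMTParseError(f"line {lineno}: duplicate pathway id {pid!r}")
            members = frozenset(
                _normalize_id(m) for m in raw_members if m.strip()
            )
            if not members:
                raise GMTParseError(f"line {lineno}: pathway {pid!r} has no members")
            entries[pid] = (desc, members)
    return PathwayCollection(entries=entries, source="gmt")


def write_gmt(collection: PathwayCollection, path) -> None:
    """Write a collection in GMT format (members in sorted order)."""
    with open(path, "w") as fh:
        for pid in collection:
            members = sorted(collection.members(pid))
            fh.write("\t".join([pid, collection.name(pid), *members]) + "\n")


def parse_reactome_chebi(path, species: str = "Homo sapiens") -> PathwayCollection:
    """Parse the Reactome ChEBI-to-pathway flat file, one species only.

    Expected columns (tab-separated, no header): ChEBI id, pathway
    stable id, URL, pathway name, evidence code, species.  Member ids
    are normalised to ``CHEBI:<digits>`` form.
    """
    entries: dict[str, tuple[str, set[str]]] = {}
    species_seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                continue
            chebi, pid, _url, name, _evidence, row_species = fields[:6]
            species_seen.add(row_species)
            if row_species != species:
                continue
            member = _normalize_id(chebi)
            if not member.startswith("CHEBI:"):
                member = "CHEBI:" + member
            if pid not in entries:
                entries[pid] = (name, set())
            entries[pid][1].add(member)
    if not entries:
        raise ValueError(
            f"no pathways for species {species!r}; species seen: "
            f"{sorted(species_seen)}"
        )
    return PathwayCollection(
        entries={pid: (name, frozenset(m)) for pid, (name, m) in entries.items()},
        source="reactome",
        species=species,
    )


def overlap_coefficient(A: Iterable[str], B: Iterable[str]) -> float:
    """Szymkiewicz-Simpson overlap coefficient |A∩B| / min(|A|, |B|).

    0 means no overlap; 1 means the smaller set is contained in the
    larger one.  Undefined (raises) for empty sets.
    """
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(A & B) / min(len(A), len(B))


def filter_by_coverage(
    collection: PathwayCollection,
    matrix,
    min_coverage: int = 2,
) -> tuple[PathwayCollection, list[CoverageView]]:
    """Keep pathways with >= ``min_coverage`` members measured in ``matrix``.

    The returned collection's member sets are the *measured* subsets
    (scoring operates on measured members only); the CoverageView list
    reports full and measured sizes for every retained pathway.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    measured = frozenset(matrix.metabolite_ids)
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    views: list[CoverageView] = []
    for pid in collection:
        full = collection.members(pid)
        present = full & measured
        if len(present) >= min_coverage:
            entries[pid] = (collection.name(pid), present)
            views.append(
                CoverageView(
                    pathway_id=pid, full_size=len(full), measured_members=present
                )
            )
    if not entries:
        raise ValueError(
            "no pathway has sufficient measured coverage; check that the "
            "matrix column identifiers and the pathway member identifiers "
            "use the same namespace (e.g. CHEBI:<digits>)"
        )
    out = PathwayCollection(
        entries=entries, source=collection.source, species=collection.species
    )
    return out, views


def build_nonredundant_set(collection: PathwayCollection) -> PathwayCollection:
    """Greedy construction of a pairwise-disjoint pathway subset.

    Scans pathways in collection order and accepts a pathway iff its
    member set shares no identifier with the union of all previously
    accepted pathways.  Every pair in the result therefore has overlap
    coefficient 0.
    """
    accepted: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    for pid in collection:
        members = collection.members(pid)
        if not (members & union):
            accepted[pid] = collection.entries[pid]
            union |= members
    return PathwayCollection(
        entries=accepted, source=collection.source, species=collection.species
    )
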