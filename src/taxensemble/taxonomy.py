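"""Minimal taxonomy handling: load a rank/parent table and resolve any
taxon identifier to its species-level ancestor.

Read classifiers frequently place reads above the species rank (the LCA
algorithm stops at a genus or family when reference matches disagree) or
below it (strain and subspecies nodes in the NCBI taxonomy).  Downstream
species-level analysis keeps only assignments that resolve to a node of
rank ``species``: sub-species nodes are promoted to their species
ancestor, while genus-and-above assignments are treated as not assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping


class _NotAssigned:
    """Singleton sentinel for a read with no species-level assignment."""

    __slots__ = ()
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NA"

    def __bool__(self) -> bool:
        return False


#: The "not assigned" value (Kraken2 status U, taxid 0, a read missing
#: from a MEGAN r2c file, or any assignment with no species ancestor).
NOT_ASSIGNED = _NotAssigned()

SPECIES_RANK = "species"


class TaxonomyError(ValueError):
    """Malformed taxonomy table: duplicate taxid, dangling parent or cycle."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


class Taxonomy:
    """A validated taxid -> (parent, rank, name) table.

    Invariants enforced at construction: taxids are unique and positive,
    every parent exists, and every parent chain terminates at a root
    (a node whose parent is itself, or taxid 1).
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid <= 0:
                raise TaxonomyError(f"non-positive taxid {node.taxid}")
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        self._validate()

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent not in self._nodes and not self._is_root(node):
                raise TaxonomyError(
                    f"unknown parent {node.parent} for taxid {node.taxid}"
                )
        # Walk every chain once; a chain longer than the node count is a cycle.
        limit = len(self._nodes) + 1
        for node in self._nodes.values():
            current, steps = node, 0
            while not self._is_root(current):
                current = self._nodes[current.parent]
                steps += 1
                if steps > limit:
                    raise TaxonomyError(
                        f"cycle in parent chain starting at taxid {node.taxid}"
                    )

    @staticmethod
    def _is_root(node: TaxonNode) -> bool:
        return node.parent == node.taxid or node.taxid == 1

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, taxid: int) -> TaxonNode:
        return self._nodes[taxid]

    def rank(self, taxid: int) -> str:
        return self._nodes[taxid].rank

    def name(self, taxid: int) -> str:
        return self._nodes[taxid].name

    def name_to_taxid(self) -> Mapping[str, int]:
        """Name -> taxid lookup; later duplicates of a name are ignored."""
        out: dict[str, int] = {}
        for node in self._nodes.values():
            out.setdefault(node.name, node.taxid)
        return out

    def resolve_to_species(self, taxid) -> int | _NotAssigned:
        """Resolve ``taxid`` to its species-level node, or ``NOT_ASSIGNED``.

        A species-rank node resolves to itself; a node below species rank
        is promoted to the nearest species ancestor; anything else
        (genus and above, ``no rank`` with no species ancestor, taxid 0,
        or a taxid absent from the table) is ``NOT_ASSIGNED``.  Species
        identity is tracked by taxid, never by name.
        """
        if taxid is NOT_ASSIGNED or taxid == 0 or taxid not in self._nodes:
            return NOT_ASSIGNED
        current = self._nodes[taxid]
        while True:
            if current.rank == SPECIES_RANK:
                return current.taxid
            if self._is_root(current):
                return NOT_ASSIGNED
            current = self._nodes[current.parent]


def resolve_to_species(taxid, taxonomy: Taxonomy) -> int | _NotAssigned:
    """Functional alias for :meth:`Taxonomy.resolve_to_species`."""
    return taxonomy.resolve_to_species(taxid)


def load_taxonomy(source: IO[str]) -> Taxonomy:
    """Load a 4-column tab-delimited taxonomy table.

    Columns: taxid, parent_taxid, rank, name.  A header line is detected
    by a non-numeric first field and skipped.
    """
    nodes = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise TaxonomyError(
                f"line {lineno}: expected 4 tab-delimited fields, got {len(fields)}"
            )
        if lineno == 1 and not fields[0].strip().lstrip("-").isdigit():
            continue  # header
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError as exc:
            raise TaxonomyError(f"line {lineno}: non-integer taxid field") from exc
        nodes.append(TaxonNode(taxid, parent, fields[2].strip(), fields[3].strip()))
    return Taxonomy(nodes)


def load_ncbi_dmp(nodes_source: IO[str], names_source: IO[str] | None = None) -> Taxonomy:
    """Load the NCBI ``nodes.dmp`` / ``names.dmp`` dialect.

    Fields are separated by ``\\t|\\t`` and lines end with ``\\t|``.
    Only the taxid, parent and rank columns of nodes.dmp are used; names
    come from the ``scientific name`` class of names.dmp when given.
    """
    names: dict[int, str] = {}
    if names_source is not None:
        for raw in names_source:
            parts = [p.strip() for p in raw.rstrip("\n").rstrip("|").split("\t|\t")]
            if len(parts) >= 4 and parts[3].rstrip("\t|").strip() == "scientific name":
                names[int(parts[0])] = parts[1]
            elif len(parts) >= 2 and int(parts[0]) not in names:
                names.setdefault(int(parts[0]), parts[1])
    nodes = []
    for raw in nodes_source:
        parts = [p.strip() for p in raw.rstrip("\n").rstrip("|").split("\t|\t")]
        if len(parts) < 3:
            raise TaxonomyError("malformed nodes.dmp line")
        taxid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
        nodes.append(TaxonNode(taxid, parent, rank, names.get(taxid, str(taxid))))
    return Taxonomy(nodes)
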