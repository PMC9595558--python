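"""Parsers and writers for the classifier output dialects.

Supported inputs:

* Kraken2 per-read output — 5 tab-separated columns: status (``C``/``U``),
  read id, taxid, read length, LCA k-mer breakdown.
* Kraken2 summary report — 6 columns: percent, clade count, direct count,
  rank code, taxid, name; species rows carry rank code ``S``.
* MEGAN6 ``rma2info -r2c Taxonomy`` — 2 columns: read id, taxid.  Reads
  the LCA left unassigned are omitted from the file entirely.
* MEGAN6 ``rma2info -c2c Taxonomy`` — 2 columns: taxid (or scientific
  name), read count.
* The canonical assignment dialect written by this package — 2 columns
  with a ``read_id\\ttaxid`` header and the literal ``NA`` for reads
  without a species-level assignment.

All assignment parsers push every taxid through species-level resolution
(:func:`taxensemble.taxonomy.resolve_to_species`), so a table coming out
of a parser only ever contains species taxids or ``NOT_ASSIGNED``.
Parsers are strict: a malformed line or duplicate read id raises
:class:`ParseError` with its line number rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterator, Mapping

from taxensemble.taxonomy import NOT_ASSIGNED, Taxonomy, _NotAssigned

Assignment = int | _NotAssigned


class ParseError(ValueError):
    """Malformed classifier output; message carries the 1-based line number."""


@dataclass
class ReadAssignmentTable:
    """Per-read species assignments of one classifier on one sample.

    ``assignments`` maps read id to a species taxid or ``NOT_ASSIGNED``.
    A read id absent from the mapping is also treated as not assigned
    (``get`` returns ``NOT_ASSIGNED``): MEGAN's r2c output omits
    unassigned reads while Kraken2 lists them with status ``U``, and both
    classifiers saw the same input reads.
    """

    sample_id: str
    classifier_id: str
    assignments: dict[str, Assignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for read_id, value in self.assignments.items():
            if value is not NOT_ASSIGNED and (not isinstance(value, int) or value <= 0):
                raise ValueError(
                    f"read {read_id!r}: assignment must be a positive taxid or NA"
                )

    def get(self, read_id: str) -> Assignment:
        return self.assignments.get(read_id, NOT_ASSIGNED)

    def read_ids(self) -> set[str]:
        return set(self.assignments)

    def assigned_items(self) -> Iterator[tuple[str, int]]:
        for read_id, value in self.assignments.items():
            if value is not NOT_ASSIGNED:
                yield read_id, value

    def n_assigned(self) -> int:
        return sum(1 for _ in self.assigned_items())

    def species_counts(self) -> "SpeciesCountTable":
        counts: dict[int, int] = {}
        for _, taxid in self.assigned_items():
            counts[taxid] = counts.get(taxid, 0) + 1
        return SpeciesCountTable(sample_id=self.sample_id, counts=counts)

    def species_set(self) -> set[int]:
        return {taxid for _, taxid in self.assigned_items()}


@dataclass
class SpeciesCountTable:
    """Read counts per species taxid for one sample."""

    sample_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxid, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative count for taxid {taxid}")

    def total(self) -> int:
        return sum(self.counts.values())


def _parse_taxid(text: str, lineno: int) -> int:
    try:
        taxid = int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer taxid {text!r}") from None
    if taxid < 0:
        raise ParseError(f"line {lineno}: negative taxid {taxid}")
    return taxid


def parse_kraken2_assignments(
    source: IO[str],
    taxonomy: Taxonomy,
    sample_id: str = "",
    classifier_id: str = "kraken2",
) -> ReadAssignmentTable:
    """Parse Kraken2 standard per-read output into a species-resolved table.

    Status ``U`` lines and taxids without a species-level resolution map
    to ``NOT_ASSIGNED``; every input line yields exactly one entry.
    """
    assignments: dict[str, Assignment] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        status, read_id, taxid_text = fields[0], fields[1], fields[2]
        if status not in ("C", "U"):
            raise ParseError(f"line {lineno}: unknown status {status!r}")
        if read_id in assignments:
            raise ParseError(f"line {lineno}: duplicate read id {read_id!r}")
        if status == "U":
            assignments[read_id] = NOT_ASSIGNED
        else:
            taxid = _parse_taxid(taxid_text, lineno)
            assignments[read_id] = taxonomy.resolve_to_species(taxid)
    return ReadAssignmentTable(sample_id, classifier_id, assignments)


def parse_megan_r2c(
    source: IO[str],
    taxonomy: Taxonomy,
    sample_id: str = "",
    classifier_id: str = "megan",
) -> ReadAssignmentTable:
    """Parse MEGAN6 ``rma2info -r2c Taxonomy`` output (read id, taxid).

    Unassigned reads do not appear in this format; they are simply absent
    from the returned table.
    """
    assignments: dict[str, Assignment] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        read_id, taxid_text = fields
        if read_id in assignments:
            raise ParseError(f"line {lineno}: duplicate read id {read_id!r}")
        assignments[read_id] = taxonomy.resolve_to_species(
            _parse_taxid(taxid_text, lineno)
        )
    return ReadAssignmentTable(sample_id, classifier_id, assignments)


def parse_canonical_assignments(
    source: IO[str],
    taxonomy: Taxonomy | None = None,
    sample_id: str = "",
    classifier_id: str = "canonical",
) -> ReadAssignmentTable:
    """Parse the canonical 2-column dialect (header ``read_id\\ttaxid``,
    literal ``NA`` for unassigned reads).

    With ``taxonomy=None`` taxids pass through unresolved, which makes
    write-then-parse an exact round trip for species-resolved tables.
    """
    assignments: dict[str, Assignment] = {}
    first = True
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        if first and fields == ["read_id", "taxid"]:
            first = False
            continue
        first = False
        read_id, taxid_text = fields
        if read_id in assignments:
            raise ParseError(f"line {lineno}: duplicate read id {read_id!r}")
        if taxid_text == "NA":
            assignments[read_id] = NOT_ASSIGNED
        else:
            taxid = _parse_taxid(taxid_text, lineno)
            if taxid == 0:
                assignments[read_id] = NOT_ASSIGNED
            elif taxonomy is not None:
                assignments[read_id] = taxonomy.resolve_to_species(taxid)
            else:
                assignments[read_id] = taxid
    return ReadAssignmentTable(sample_id, classifier_id, assignments)


def write_canonical_assignments(table: ReadAssignmentTable, sink: IO[str]) -> None:
    """Write the canonical 2-column dialect; reads sorted for stable diffs."""
    sink.write("read_id\ttaxid\n")
    for read_id in sorted(table.assignments):
        value = table.assignments[read_id]
        sink.write(f"{read_id}\t{'NA' if value is NOT_ASSIGNED else value}\n")


def parse_species_counts(
    source: IO[str],
    dialect: str,
    taxonomy: Taxonomy,
    sample_id: str = "",
) -> SpeciesCountTable:
    """Parse per-species read counts, retaining only species-level rows.

    ``dialect='megan_c2c'``: 2 columns (taxid or scientific name, count).
    ``dialect='kraken2_report'``: the standard 6-column report; rows with
    rank code ``S`` are taken with their *direct* (not clade) counts.
    """
    if dialect not in ("megan_c2c", "kraken2_report"):
        raise ValueError(f"unknown dialect {dialect!r}")
    counts: dict[int, int] = {}
    name_map: Mapping[str, int] | None = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if dialect == "megan_c2c":
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            key, count_text = fields
            key = key.strip()
            if key.lstrip("-").isdigit():
                taxid = _parse_taxid(key, lineno)
            else:
                if name_map is None:
                    name_map = taxonomy.name_to_taxid()
                if key not in name_map:
                    raise ParseError(f"line {lineno}: unknown taxon name {key!r}")
                taxid = name_map[key]
            try:
                count = int(count_text)
            except ValueError:
                # MEGAN c2c counts can be fractional under weighted LCA
                try:
                    count = math.floor(float(count_text) + 0.5)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric count {count_text!r}"
                    ) from None
        else:
            if len(fields) != 6:
                raise ParseError(
                    f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            rank_code = fields[3].strip()
            if rank_code != "S":
                continue
            taxid = _parse_taxid(fields[4].strip(), lineno)
            try:
                count = int(fields[2])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer direct count {fields[2]!r}"
                ) from None
        species = taxonomy.resolve_to_species(taxid)
        if species is NOT_ASSIGNED or species != taxid:
            continue  # keep species-level rows only
        counts[taxid] = counts.get(taxid, 0) + count
    return SpeciesCountTable(sample_id=sample_id, counts=counts)


def write_profile(profile, sink: IO[str], taxonomy: Taxonomy | None = None) -> None:
    """Write a species profile as TSV.

    Columns: species taxid, name (empty without a taxonomy), read count,
    relative abundance at 6 significant digits.  Rows are ordered by
    descending count with ascending taxid as tie-break, so output is
    deterministic and diff-friendly.
    """
    sink.write("species_taxid\tname\tcount\trelative_abundance\n")
    order = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for taxid, count in order:
        name = ""
        if taxonomy is not None and taxid in taxonomy:
            name = taxonomy.name(taxid)
        abundance = count / profile.total_reads
        sink.write(f"{taxid}\t{name}\t{count}\t{abundance:.6g}\n")
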