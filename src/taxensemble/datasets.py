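"""Bundled reference benchmark: intersection false positives on 21
single-species insect libraries.

A published mitochondrial-metagenomics benchmark sequenced 21 libraries,
each containing one known insect species, and classified the reads with
BLASTn+MEGAN6 and Kraken2 against a database of 1934 insect
mitogenomes.  Under the intersection merge, 11 of the 21 libraries had
no false-positive species at all; this module encodes, for the other 10,
the reported false-positive species with their per-species RPIR
(relative abundance over total QC-passed reads) and whether each is
congeneric to the library's focal species.

Species are identified by name in the source listing, so the taxids
produced by :func:`library_profile` are **synthetic placeholders**
assigned deterministically from the species names; they are internally
consistent but are not NCBI taxids.  Abundances reported only as a
bound ("below 0.0001") are encoded as :data:`BELOW_DETECTION` — any
value strictly below 0.0001 yields the same filtering behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

from taxensemble.profiling import SpeciesProfile

#: Encoding for abundances reported only as "< 0.0001" (midpoint of the bound).
BELOW_DETECTION = 0.00005

#: Denominator used to materialise the reported abundances as integer read
#: counts; every reported value is a multiple of 1e-5, so counts are exact.
DEFAULT_TOTAL_READS = 100_000

#: Nominal focal-species abundance used when materialising a profile; the
#: focal species always sits far above every detection limit considered.
FOCAL_ABUNDANCE = 0.005


@dataclass(frozen=True)
class FalsePositive:
    name: str
    rpir: float
    congener: bool


@dataclass(frozen=True)
class LibraryRecord:
    library_id: str
    focal_name: str
    focal_order: str
    n_congeners_in_db: int
    false_positives: tuple[FalsePositive, ...]


_LIBRARIES: tuple[LibraryRecord, ...] = (
    LibraryRecord("1-1", "Papilio machaon", "Lepidoptera", 14, ()),
    LibraryRecord("1-3", "Drosophila melanogaster", "Diptera", 20, ()),
    LibraryRecord("1-4", "Drosophila mojavensis", "Diptera", 20, ()),
    LibraryRecord("1-6", "Linepithema humile", "Hymenoptera", 0, ()),
    LibraryRecord("1-9", "Acyrthosiphon pisum", "Hemiptera", 0, ()),
    LibraryRecord("2-1", "Atta colombica", "Hymenoptera", 0, ()),
    LibraryRecord("2-4", "Drosophila melanogaster", "Diptera", 20, ()),
    LibraryRecord("2-5", "Drosophila mojavensis", "Diptera", 20, ()),
    LibraryRecord("2-7", "Drosophila suzukii", "Diptera", 20, ()),
    LibraryRecord("2-8", "Linepithema humile", "Hymenoptera", 0, ()),
    LibraryRecord("2-11", "Vollenhovia emeryi", "Hymenoptera", 0, ()),
    LibraryRecord(
        "1-2", "Drosophila virilis", "Diptera", 20,
        (
            FalsePositive("Drosophila littoralis", 0.0008, True),
            FalsePositive("Drosophila incompta", BELOW_DETECTION, True),
        ),
    ),
    LibraryRecord(
        "1-5", "Bactrocera oleae", "Diptera", 14,
        (FalsePositive("Bactrocera biguttula", 0.0018, True),),
    ),
    LibraryRecord(
        "1-7", "Bombus terrestris", "Hymenoptera", 3,
        (
            FalsePositive("Bombus hypocrita", 0.0035, True),
            FalsePositive("Bombus waltoni", 0.0023, True),
            FalsePositive("Bombus ignitus", 0.0015, True),
        ),
    ),
    LibraryRecord(
        "1-8", "Apis mellifera", "Hymenoptera", 7,
        (
            FalsePositive("Apis nigrocincta", 0.0011, True),
            FalsePositive("Apis florea", 0.0006, True),
            FalsePositive("Apis laboriosa", 0.0002, True),
            FalsePositive("Apis nuluensis", 0.0002, True),
            FalsePositive("Apis andreniformis", BELOW_DETECTION, True),
            FalsePositive("Apis cerana", BELOW_DETECTION, True),
            FalsePositive("Apis dorsata", BELOW_DETECTION, True),
        ),
    ),
    LibraryRecord(
        "2-3", "Cimex lectularius", "Hemiptera", 0,
        (
            FalsePositive("Reduvius tenebrosus", 0.0009, False),
            FalsePositive("Aquatica wuhana", 0.0001, False),
        ),
    ),
    LibraryRecord(
        "2-9", "Plutella xylostella", "Lepidoptera", 1,
        (FalsePositive("Prismognathus prossi", 0.0002, False),),
    ),
    LibraryRecord(
        "2-12", "Wasmannia auropunctata", "Hymenoptera", 0,
        (
            FalsePositive("Vespa orientalis", 0.0028, False),
            FalsePositive("Eriogyna pyretorum", 0.0013, False),
            FalsePositive("Pristomyrmex punctatus", 0.001, False),
            FalsePositive("Allocarsidara bakeri", 0.0001, False),
        ),
    ),
    LibraryRecord(
        "2-2", "Bemisia tabaci", "Hemiptera", 1,
        (
            FalsePositive("Bemisia afer", 0.0008, True),
            FalsePositive("Barca bicolor", 0.0004, False),
            FalsePositive("Trialeurodes vaporariorum", 0.0004, False),
        ),
    ),
    LibraryRecord(
        "2-6", "Drosophila virilis", "Diptera", 20,
        (
            FalsePositive("Drosophila littoralis", 0.0003, True),
            FalsePositive("Pachycerina decemlineata", 0.0002, False),
        ),
    ),
    LibraryRecord(
        "2-10", "Solenopsis invicta", "Hymenoptera", 2,
        (
            FalsePositive("Solenopsis richteri", 0.0183, True),
            FalsePositive("Solenopsis geminata", 0.0039, True),
            FalsePositive("Myrmica scabrinodis", 0.0013, False),
        ),
    ),
)


def library_records() -> tuple[LibraryRecord, ...]:
    """All 21 benchmark libraries, zero-false-positive ones first."""
    return _LIBRARIES


def species_taxids() -> dict[str, int]:
    """Deterministic synthetic taxid per species name (placeholder ids)."""
    names = sorted(
        {rec.focal_name for rec in _LIBRARIES}
        | {fp.name for rec in _LIBRARIES for fp in rec.false_positives}
    )
    return {name: 100_001 + i for i, name in enumerate(names)}


def library_profile(
    record: LibraryRecord, total_reads: int = DEFAULT_TOTAL_READS
) -> tuple[SpeciesProfile, int]:
    """Materialise a library's intersection species profile.

    Reported abundances become integer counts over ``total_reads`` (the
    default makes every reported value exact); the focal species is
    added at :data:`FOCAL_ABUNDANCE`.  Returns the profile and the focal
    species' (synthetic) taxid.
    """
    taxids = species_taxids()
    focal = taxids[record.focal_name]
    counts = {focal: round(FOCAL_ABUNDANCE * total_reads)}
    for fp in record.false_positives:
        counts[taxids[fp.name]] = round(fp.rpir * total_reads)
    return (
        SpeciesProfile(
            sample_id=record.library_id, total_reads=total_reads, counts=counts
        ),
        focal,
    )
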