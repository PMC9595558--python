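"""Per-sample species profiles and the analytic detection limit.

A species profile holds, for one sample, the number of reads assigned to
each species plus the total number of QC-passed reads in the sample.
The per-species relative abundance is count / total_reads — the same
denominator as the sample-level RPIR (relative proportion of informative
reads), so a species' abundance is directly its per-species RPIR.

The analytic detection limit drops species whose relative abundance
falls below a threshold ε: false-positive species typically carry very
few reads, so a small ε removes many of them while losing few reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from taxensemble.io_formats import ReadAssignmentTable


@dataclass(frozen=True)
class DetectionLimit:
    """Relative-abundance threshold ε in [0, 1].

    A species is retained when its abundance is **greater than or equal
    to** ε.  The inclusive comparison means a species sitting exactly at
    the threshold (e.g. abundance 0.001 at ε = 0.001) stays in the list.
    """

    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")


@dataclass
class SpeciesProfile:
    """Species read counts and relative abundances for one sample.

    ``total_reads`` is the number of QC-passed reads in the sample, the
    denominator for both per-species abundance and sample RPIR.  Species
    with zero assigned reads are not listed.
    """

    sample_id: str
    total_reads: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for taxid, count in self.counts.items():
            if count < 1:
                raise ValueError(f"taxid {taxid}: counts must be >= 1")
        if sum(self.counts.values()) > self.total_reads:
            raise ValueError("assigned reads exceed total_reads")

    @property
    def assigned_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        """Number of distinct species in the profile."""
        return len(self.counts)

    @property
    def rpir(self) -> float:
        """Relative proportion of informative reads: assigned / total."""
        return self.assigned_reads / self.total_reads

    def abundance(self, taxid: int) -> float:
        return self.counts.get(taxid, 0) / self.total_reads

    @property
    def abundances(self) -> dict[int, float]:
        return {taxid: count / self.total_reads for taxid, count in self.counts.items()}


def build_profile(
    assignments: ReadAssignmentTable, total_reads: int
) -> SpeciesProfile:
    """Aggregate a read-assignment table into a species profile.

    Raises ``ValueError`` when ``total_reads`` is smaller than the number
    of assigned reads: the denominator is the whole sample, of which the
    assigned reads are a subset.
    """
    counts = assignments.species_counts().counts
    if total_reads < sum(counts.values()):
        raise ValueError(
            f"total_reads ({total_reads}) < assigned reads ({sum(counts.values())})"
        )
    return SpeciesProfile(
        sample_id=assignments.sample_id, total_reads=total_reads, counts=dict(counts)
    )


def apply_detection_limit(
    profile: SpeciesProfile,
    limit: DetectionLimit,
    denominator: str = "total",
) -> SpeciesProfile:
    """Drop species whose relative abundance is below the detection limit.

    Retained species keep their counts and the profile keeps its
    ``total_reads``, so the operation is idempotent at a fixed ε and
    monotone in ε (a larger ε never retains a species a smaller ε
    dropped).

    ``denominator`` selects the abundance denominator: ``"total"``
    (default) uses the sample's total QC-passed reads, matching the
    per-species RPIR convention; ``"assigned"`` uses the assigned-read
    count of the unfiltered profile instead.
    """
    if denominator not in ("total", "assigned"):
        raise ValueError(f"unknown denominator {denominator!r}")
    denom = profile.total_reads if denominator == "total" else profile.assigned_reads
    if denom == 0:  # empty profile under "assigned": nothing to filter
        return SpeciesProfile(profile.sample_id, profile.total_reads, {})
    kept = {
        taxid: count
        for taxid, count in profile.counts.items()
        if count / denom >= limit.epsilon
    }
    return SpeciesProfile(
        sample_id=profile.sample_id, total_reads=profile.total_reads, counts=kept
    )
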