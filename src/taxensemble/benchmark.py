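"""Read-level benchmarking of classifiers and their combinations on
single-species samples.

Each benchmark library contains DNA of exactly one known insect species
(the *focal* species), so every read's true origin is known.  Reads are
labelled:

* **TP** — assigned to the focal species (and surviving the detection
  limit);
* **FP** — assigned to any other surviving species;
* **FN** — not assigned by the assessed method, but assigned to the
  focal species by at least one of the two base classifiers.  Most reads
  are nuclear DNA that cannot map onto a mitogenome reference, so "all
  unassigned reads" would be a meaningless FN denominator; the union of
  focal-assigned reads across both base classifiers is the set of reads
  demonstrably recoverable by some tool.

True negatives are not computed: an unassigned read may be exogenous
DNA, a sequencing artefact, or simply absent from the database, and
these cannot be told apart.

Derived metrics per method and sample: richness (species count of the
filtered profile), RPIR = (TP+FP)/total reads, precision = TP/(TP+FP),
recall = TP/(TP+FN); the latter two are undefined (``None``) when their
denominator is zero.  Known contaminant species (cross-contamination in
the lab or field) are excluded before any counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from taxensemble.io_formats import ReadAssignmentTable, SpeciesCountTable
from taxensemble.profiling import DetectionLimit, apply_detection_limit, build_profile
from taxensemble.taxonomy import NOT_ASSIGNED, Taxonomy


@dataclass
class BenchmarkContext:
    """Everything needed to score one method on one sample.

    ``base_tables`` are the two individual classifiers' (contaminant-free,
    species-resolved) assignment tables; they define the FN denominator
    for every method, base and merged alike.
    """

    focal_species: int
    contaminants: frozenset[int]
    total_reads: int
    base_tables: tuple[ReadAssignmentTable, ReadAssignmentTable]
    taxonomy: Taxonomy | None = None

    def __post_init__(self) -> None:
        self.contaminants = frozenset(self.contaminants)
        if self.focal_species in self.contaminants:
            raise ValueError("focal species cannot be a contaminant")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.taxonomy is not None and self.focal_species not in self.taxonomy:
            raise ValueError(
                f"focal species {self.focal_species} absent from taxonomy"
            )


@dataclass
class BenchmarkResult:
    """TP/FP/FN read counts and derived metrics for one method on one sample."""

    method_id: str
    tp: int
    fp: int
    fn: int
    richness: int
    rpir: float

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else None

    def metrics(self) -> dict[str, float | int | None]:
        return {
            "richness": self.richness,
            "rpir": self.rpir,
            "precision": self.precision,
            "recall": self.recall,
        }


def exclude_contaminants(
    assignments: ReadAssignmentTable, contaminants: Iterable[int]
) -> tuple[ReadAssignmentTable, SpeciesCountTable]:
    """Remove reads assigned to known contaminant species.

    Returns the cleaned table (contaminant reads absent, everything else
    untouched) and a per-species tally of what was removed.
    """
    contaminants = frozenset(contaminants)
    clean: dict = {}
    removed: dict[int, int] = {}
    for read_id, value in assignments.assignments.items():
        if value is not NOT_ASSIGNED and value in contaminants:
            removed[value] = removed.get(value, 0) + 1
        else:
            clean[read_id] = value
    return (
        ReadAssignmentTable(assignments.sample_id, assignments.classifier_id, clean),
        SpeciesCountTable(sample_id=assignments.sample_id, counts=removed),
    )


def focal_read_union(
    base_tables: Sequence[ReadAssignmentTable], focal_species: int
) -> set[str]:
    """Reads assigned to the focal species by at least one base classifier."""
    union: set[str] = set()
    for table in base_tables:
        union.update(r for r, t in table.assigned_items() if t == focal_species)
    return union


def evaluate_method(
    method_assignments: ReadAssignmentTable,
    context: BenchmarkContext,
    limit: DetectionLimit = DetectionLimit(0.0),
) -> BenchmarkResult:
    """Score one method (a base classifier or a merged table) on one sample.

    Pipeline: build the species profile, apply the detection limit, then
    count TP (focal-species reads of surviving species), FP (reads of
    any other surviving species) and FN = |U| - TP where U is the set of
    reads assigned to the focal species by either base classifier
    (floored at zero; a method cannot have negative misses).  The
    detection limit is applied *before* counting, so reads of filtered
    species count neither as TP nor FP.
    """
    profile = build_profile(method_assignments, context.total_reads)
    filtered = apply_detection_limit(profile, limit)
    surviving = set(filtered.counts)
    tp = filtered.counts.get(context.focal_species, 0)
    fp = sum(
        count for taxid, count in filtered.counts.items()
        if taxid != context.focal_species
    )
    union = focal_read_union(context.base_tables, context.focal_species)
    fn = max(len(union) - tp, 0)
    assert tp + fp == filtered.assigned_reads  # conservation
    return BenchmarkResult(
        method_id=method_assignments.classifier_id,
        tp=tp,
        fp=fp,
        fn=fn,
        richness=len(surviving),
        rpir=(tp + fp) / context.total_reads,
    )


#: Display precision per metric, matching the conventional reporting
#: style: 1 decimal for richness, 4 for RPIR, 3 for precision/recall.
METRIC_DECIMALS = {"richness": 1, "rpir": 4, "precision": 3, "recall": 3}


def aggregate_over_samples(
    results: Sequence[BenchmarkResult],
) -> dict[str, dict[str, float]]:
    """Mean and sample standard deviation (n-1) of each metric.

    Undefined (``None``) metric values are excluded pairwise with a
    warning.  Values are returned at full precision; use
    :func:`format_summary` for display rounding.
    """
    if not results:
        raise ValueError("no results to aggregate")
    summary: dict[str, dict[str, float]] = {}
    for metric in ("richness", "rpir", "precision", "recall"):
        values = [r.metrics()[metric] for r in results]
        defined = [v for v in values if v is not None]
        if len(defined) < len(values):
            warnings.warn(
                f"{len(values) - len(defined)} undefined {metric} value(s) "
                "excluded from aggregation",
                stacklevel=2,
            )
        if not defined:
            summary[metric] = {"mean": math.nan, "sd": math.nan, "n": 0}
            continue
        n = len(defined)
        mean = sum(defined) / n
        sd = (
            math.sqrt(sum((v - mean) ** 2 for v in defined) / (n - 1))
            if n > 1
            else 0.0
        )
        summary[metric] = {"mean": mean, "sd": sd, "n": n}
    return summary


def format_summary(summary: dict[str, dict[str, float]]) -> dict[str, str]:
    """Render a summary as ``mean ± sd`` strings at display precision."""
    out = {}
    for metric, stats in summary.items():
        d = METRIC_DECIMALS.get(metric, 3)
        out[metric] = f"{stats['mean']:.{d}f} ± {stats['sd']:.{d}f}"
    return out
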