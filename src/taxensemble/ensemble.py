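"""Pairwise merging of two classifiers' read assignments.

For each read the two classifiers either agree on a species, disagree,
or one (or both) of them leaves the read unassigned.  The two merge
policies resolve these cases as follows:

==========  ==========  =======  ============
p           q           union    intersection
==========  ==========  =======  ============
NA          NA          NA       NA
species s   NA          s        NA
NA          species s   s        NA
species s   species n   NA       NA
species s   species s   s        s
==========  ==========  =======  ============

Union extracts as many informative reads as possible; intersection keeps
only reads whose species both classifiers confirm, which is what
suppresses classifier-specific false positives.  The method is strictly
pairwise — no voting, no confidence weighting.
"""

from __future__ import annotations

import enum

from taxensemble.io_formats import Assignment, ReadAssignmentTable
from taxensemble.taxonomy import NOT_ASSIGNED


class MergePolicy(enum.Enum):
    """How to combine two classifiers' assignments for one read."""

    UNION = "union"
    INTERSECTION = "intersection"


def _merge_one(a_p: Assignment, a_q: Assignment, policy: MergePolicy) -> Assignment:
    if a_p is NOT_ASSIGNED and a_q is NOT_ASSIGNED:
        return NOT_ASSIGNED
    if a_p is NOT_ASSIGNED or a_q is NOT_ASSIGNED:
        if policy is MergePolicy.UNION:
            return a_q if a_p is NOT_ASSIGNED else a_p
        return NOT_ASSIGNED
    if a_p != a_q:
        return NOT_ASSIGNED  # conflicting species: discarded by both policies
    return a_p


def merge_assignments(
    table_p: ReadAssignmentTable,
    table_q: ReadAssignmentTable,
    policy: MergePolicy,
) -> ReadAssignmentTable:
    """Merge two species-resolved assignment tables for the same sample.

    The read universe is the union of the two tables' read ids; a read
    missing from one table counts as ``NOT_ASSIGNED`` for that
    classifier.  Raises ``ValueError`` when the sample ids differ, which
    guards against merging tables from different samples.
    """
    if table_p.sample_id != table_q.sample_id:
        raise ValueError(
            f"sample_id mismatch: {table_p.sample_id!r} != {table_q.sample_id!r}"
        )
    if not isinstance(policy, MergePolicy):
        policy = MergePolicy(policy)
    merged: dict[str, Assignment] = {}
    for read_id in table_p.read_ids() | table_q.read_ids():
        merged[read_id] = _merge_one(table_p.get(read_id), table_q.get(read_id), policy)
    out = ReadAssignmentTable(
        sample_id=table_p.sample_id,
        classifier_id=(
            f"{policy.value}({table_p.classifier_id},{table_q.classifier_id})"
        ),
        assignments=merged,
    )
    # The merge can never invent a species absent from both inputs.
    assert out.species_set() <= table_p.species_set() | table_q.species_set()
    return out
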