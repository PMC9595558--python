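"""Synthetic two-classifier outputs for single-species samples.

The simulator emulates the *assignment* behaviour of two read-level
taxonomic classifiers run on a sample containing one known species — no
sequences, k-mers or alignments are modelled.  Per read and per
classifier:

1. with probability ``assign_prob`` the read is assigned at all (the
   remainder stays unassigned, emulating nuclear reads that cannot map
   onto a mitogenome reference);
2. an assigned read is correct (the focal species) with probability
   ``1 - error_prob``, otherwise it goes to a wrong species drawn from a
   fixed pool in which congeners of the focal species carry
   ``congener_weight`` times the weight of non-congeners — misassigned
   reads land preferentially on close relatives;
3. when *both* classifiers err on the same read, with probability
   ``error_correlation`` they err to the *same* wrong species (drawn
   from the average of the two classifiers' weight distributions),
   otherwise their wrong draws are independent.

Independent wrong draws are what makes the intersection policy
effective: two classifiers with uncorrelated error processes almost
never agree on the same wrong species.

Each classifier consumes its own random substream spawned from the seed,
so adding or reconfiguring one classifier does not perturb the other's
draws, and identical seeds reproduce identical samples byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from taxensemble.io_formats import Assignment, ReadAssignmentTable
from taxensemble.taxonomy import NOT_ASSIGNED


@dataclass(frozen=True)
class ClassifierModel:
    """Error model of one simulated classifier.

    assign_prob
        Probability that a read is assigned at all.  Realistic values in
        mitochondrial metagenomics are small (~0.007): only reads of
        mitochondrial origin can match the reference.
    error_prob
        Probability that an assigned read goes to a wrong species.
    congener_weight
        Relative weight of congeneric vs non-congeneric species among
        wrong-assignment targets (default 10: misassignments mostly hit
        species of the focal genus).
    """

    assign_prob: float
    error_prob: float
    congener_weight: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.assign_prob <= 1.0:
            raise ValueError("assign_prob must be in [0, 1]")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError("error_prob must be in [0, 1]")
        if self.congener_weight <= 0:
            raise ValueError("congener_weight must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic single-species sample.

    ``species_pool`` lists the wrong-assignment targets as
    ``(taxid, is_congener)`` pairs; it must not contain the focal
    species.  ``error_correlation`` is the probability that, given both
    classifiers err on a read, they err to the same species.
    """

    n_reads: int
    focal_species: int
    species_pool: tuple[tuple[int, bool], ...]
    classifier_p: ClassifierModel
    classifier_q: ClassifierModel
    error_correlation: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_pool", tuple(
            (int(t), bool(c)) for t, c in self.species_pool
        ))
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.error_correlation <= 1.0:
            raise ValueError("error_correlation must be in [0, 1]")
        if any(t == self.focal_species for t, _ in self.species_pool):
            raise ValueError("species_pool must not contain the focal species")
        if len(set(t for t, _ in self.species_pool)) != len(self.species_pool):
            raise ValueError("duplicate taxid in species_pool")
        if not self.species_pool and (
            self.classifier_p.error_prob > 0 or self.classifier_q.error_prob > 0
        ):
            raise ValueError("empty species_pool requires error_prob = 0")


@dataclass
class SyntheticSample:
    """Ground truth plus the two simulated classifier outputs."""

    truth: dict[str, int]
    table_p: ReadAssignmentTable
    table_q: ReadAssignmentTable
    total_reads: int
    config: SimulationConfig = field(repr=False, default=None)


def _pool_weights(pool: Sequence[tuple[int, bool]], congener_weight: float) -> np.ndarray:
    raw = np.array(
        [congener_weight if is_cong else 1.0 for _, is_cong in pool], dtype=float
    )
    return raw / raw.sum()


def _simulate_classifier(
    rng: np.random.Generator,
    n: int,
    model: ClassifierModel,
    n_pool: int,
    weights: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (assigned, erred, wrong-target index) vectors for one classifier.

    Wrong-target indices are drawn for every read regardless of use, so
    the stream consumed by one classifier is a fixed function of (n,
    model, pool) and never depends on the other classifier.
    """
    assigned = rng.random(n) < model.assign_prob
    erred = rng.random(n) < model.error_prob
    if n_pool > 0:
        wrong_idx = rng.choice(n_pool, size=n, p=weights)
    else:
        wrong_idx = np.zeros(n, dtype=int)
    return assigned, erred, wrong_idx


def simulate_sample(config: SimulationConfig) -> SyntheticSample:
    """Generate one synthetic sample with two classifier outputs.

    Deterministic: the same config (including seed) yields byte-for-byte
    identical tables.
    """
    n = config.n_reads
    pool_taxids = np.array([t for t, _ in config.species_pool], dtype=np.int64)
    n_pool = len(pool_taxids)

    ss_p, ss_q, ss_shared = np.random.SeedSequence(config.seed).spawn(3)
    rng_p = np.random.default_rng(ss_p)
    rng_q = np.random.default_rng(ss_q)
    rng_shared = np.random.default_rng(ss_shared)

    w_p = _pool_weights(config.species_pool, config.classifier_p.congener_weight) if n_pool else None
    w_q = _pool_weights(config.species_pool, config.classifier_q.congener_weight) if n_pool else None

    a_p, e_p, idx_p = _simulate_classifier(rng_p, n, config.classifier_p, n_pool, w_p)
    a_q, e_q, idx_q = _simulate_classifier(rng_q, n, config.classifier_q, n_pool, w_q)

    # Correlated errors: where both classifiers err, a Bernoulli(error_
    # correlation) coin decides whether they share one wrong draw, taken
    # from the average of the two weight distributions (symmetric in p,q).
    if n_pool > 0 and config.error_correlation > 0:
        share = rng_shared.random(n) < config.error_correlation
        w_shared = (w_p + w_q) / 2.0
        shared_idx = rng_shared.choice(n_pool, size=n, p=w_shared)
        both_wrong = a_p & e_p & a_q & e_q
        joint = both_wrong & share
        idx_p = np.where(joint, shared_idx, idx_p)
        idx_q = np.where(joint, shared_idx, idx_q)

    width = max(6, len(str(n - 1)))
    read_ids = [f"read{i:0{width}d}" for i in range(n)]
    truth = {rid: config.focal_species for rid in read_ids}

    def build_table(a, e, idx, classifier_id) -> ReadAssignmentTable:
        assignments: dict[str, Assignment] = {}
        for i, rid in enumerate(read_ids):
            if not a[i]:
                assignments[rid] = NOT_ASSIGNED
            elif e[i]:
                assignments[rid] = int(pool_taxids[idx[i]])
            else:
                assignments[rid] = config.focal_species
        return ReadAssignmentTable(config.sample_id, classifier_id, assignments)

    return SyntheticSample(
        truth=truth,
        table_p=build_table(a_p, e_p, idx_p, "sim_p"),
        table_q=build_table(a_q, e_q, idx_q, "sim_q"),
        total_reads=n,
        config=config,
    )


def expected_intersection_fp_reads(config: SimulationConfig) -> float:
    """Closed-form expected number of intersection false-positive reads.

    A read is an intersection FP iff both classifiers assign it, both
    err, and both land on the same wrong species:

        E[FP] = n * a_p * a_q * e_p * e_q * (c + (1 - c) * sum_s w_p(s) w_q(s))

    where c is the error correlation and w_p, w_q the wrong-target
    weight distributions.
    """
    p, q = config.classifier_p, config.classifier_q
    if not config.species_pool:
        return 0.0
    w_p = _pool_weights(config.species_pool, p.congener_weight)
    w_q = _pool_weights(config.species_pool, q.congener_weight)
    collide = float(np.dot(w_p, w_q))
    c = config.error_correlation
    return (
        config.n_reads
        * p.assign_prob * q.assign_prob
        * p.error_prob * q.error_prob
        * (c + (1.0 - c) * collide)
    )
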