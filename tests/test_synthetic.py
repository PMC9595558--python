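import math
import random

import pytest

from taxensemble import (
    NOT_ASSIGNED,
    BenchmarkContext,
    ClassifierModel,
    MergePolicy,
    SimulationConfig,
    evaluate_method,
    merge_assignments,
    simulate_sample,
)
from taxensemble.synthetic import expected_intersection_fp_reads

FOCAL = 50_000


def make_config(**overrides):
    defaults = dict(
        n_reads=5000,
        focal_species=FOCAL,
        species_pool=tuple((60_000 + i, i < 5) for i in range(20)),
        classifier_p=ClassifierModel(assign_prob=0.3, error_prob=0.02),
        classifier_q=ClassifierModel(assign_prob=0.35, error_prob=0.10),
        error_correlation=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _evaluate_all(sample, epsilon=0.0):
    from taxensemble import DetectionLimit

    ctx = BenchmarkContext(
        focal_species=sample.config.focal_species,
        contaminants=frozenset(),
        total_reads=sample.total_reads,
        base_tables=(sample.table_p, sample.table_q),
    )
    limit = DetectionLimit(epsilon)
    out = {}
    for name, table in (
        ("p", sample.table_p),
        ("q", sample.table_q),
        ("union", merge_assignments(sample.table_p, sample.table_q, MergePolicy.UNION)),
        ("intersection", merge_assignments(sample.table_p, sample.table_q, MergePolicy.INTERSECTION)),
    ):
        out[name] = evaluate_method(table, ctx, limit)
    return out


def test_seed_determinism_is_byte_for_byte():
    a = simulate_sample(make_config())
    b = simulate_sample(make_config())
    assert a.table_p.assignments == b.table_p.assignments
    assert a.table_q.assignments == b.table_q.assignments
    assert a.truth == b.truth
    # a different seed perturbs the output
    c = simulate_sample(make_config(seed=12))
    assert c.table_p.assignments != a.table_p.assignments


def test_no_errors_means_no_false_positives():
    config = make_config(
        classifier_p=ClassifierModel(assign_prob=0.3, error_prob=0.0),
        classifier_q=ClassifierModel(assign_prob=0.35, error_prob=0.0),
    )
    results = _evaluate_all(simulate_sample(config))
    assert results["intersection"].fp == 0
    assert results["intersection"].precision == 1.0
    assert results["p"].fp == 0 and results["q"].fp == 0


def test_degenerate_classifier_with_zero_assign_prob():
    config = make_config(
        classifier_q=ClassifierModel(assign_prob=0.0, error_prob=0.1)
    )
    sample = simulate_sample(config)
    inter = merge_assignments(sample.table_p, sample.table_q, MergePolicy.INTERSECTION)
    union = merge_assignments(sample.table_p, sample.table_q, MergePolicy.UNION)
    assert inter.n_assigned() == 0
    assert {r: v for r, v in union.assignments.items()} == sample.table_p.assignments


def test_empty_pool_with_errors_rejected():
    with pytest.raises(ValueError, match="empty species_pool"):
        make_config(species_pool=())


def test_pool_must_exclude_focal():
    with pytest.raises(ValueError, match="focal"):
        make_config(species_pool=((FOCAL, False),))


def test_species_set_containment_holds_on_every_replicate():
    """Intersection's species list is contained in both base lists and in
    the union's; the union never reports a species unseen by both bases.

    Note union richness can dip *below* a base classifier's richness:
    a species supported only by reads on which the other classifier
    chose a different species loses those reads to the conflict rule.
    """
    for seed in range(10):
        sample = simulate_sample(make_config(seed=seed, n_reads=2000))
        sp_p = sample.table_p.species_set()
        sp_q = sample.table_q.species_set()
        union = merge_assignments(sample.table_p, sample.table_q, MergePolicy.UNION)
        inter = merge_assignments(sample.table_p, sample.table_q, MergePolicy.INTERSECTION)
        assert inter.species_set() <= sp_p & sp_q
        assert inter.species_set() <= union.species_set()
        assert union.species_set() <= sp_p | sp_q
        assert len(inter.species_set()) <= min(len(sp_p), len(sp_q))


def test_intersection_suppresses_false_positive_species_on_average():
    """With uncorrelated errors over a uniform pool, the intersection's
    mean false-positive species count sits below either base classifier's."""
    pool = tuple((60_000 + i, False) for i in range(10))
    fp_counts = {"p": [], "q": [], "intersection": []}
    for seed in range(50):
        config = make_config(
            seed=seed, n_reads=2000, species_pool=pool,
            classifier_p=ClassifierModel(assign_prob=0.3, error_prob=0.05),
            classifier_q=ClassifierModel(assign_prob=0.3, error_prob=0.15),
        )
        sample = simulate_sample(config)
        inter = merge_assignments(sample.table_p, sample.table_q, MergePolicy.INTERSECTION)
        for name, table in (("p", sample.table_p), ("q", sample.table_q),
                            ("intersection", inter)):
            fp_counts[name].append(len(table.species_set() - {FOCAL}))
    mean = lambda xs: sum(xs) / len(xs)
    assert mean(fp_counts["intersection"]) < mean(fp_counts["p"])
    assert mean(fp_counts["intersection"]) < mean(fp_counts["q"])


def test_intersection_fp_reads_match_closed_form_over_replicates():
    """Summed intersection FP reads over 50 seeded replicates fall
    within 3 sigma of the closed-form expectation, and an independent
    per-read rejection simulator lands in the same band."""
    pool = tuple((60_000 + i, False) for i in range(10))
    config_proto = dict(
        n_reads=20_000, species_pool=pool,
        classifier_p=ClassifierModel(assign_prob=0.5, error_prob=0.3),
        classifier_q=ClassifierModel(assign_prob=0.5, error_prob=0.3),
    )
    per_replicate = expected_intersection_fp_reads(make_config(**config_proto))
    n_rep = 50
    expected = n_rep * per_replicate
    # each read is an intersection FP independently with prob per_rep/n
    p_fp = per_replicate / config_proto["n_reads"]
    sigma = math.sqrt(n_rep * config_proto["n_reads"] * p_fp * (1 - p_fp))

    observed = 0
    for seed in range(n_rep):
        sample = simulate_sample(make_config(seed=seed, **config_proto))
        inter = merge_assignments(sample.table_p, sample.table_q, MergePolicy.INTERSECTION)
        observed += sum(
            1 for v in inter.assignments.values()
            if v is not NOT_ASSIGNED and v != FOCAL
        )
    assert abs(observed - expected) <= 3 * sigma

    # independent oracle: naive per-read loop with Python's RNG
    rng = random.Random(1234)
    taxids = [t for t, _ in pool]
    oracle = 0
    n_oracle = 200_000
    m_p, m_q = config_proto["classifier_p"], config_proto["classifier_q"]
    for _ in range(n_oracle):
        a_p = rng.random() < m_p.assign_prob and rng.random() < m_p.error_prob
        a_q = rng.random() < m_q.assign_prob and rng.random() < m_q.error_prob
        if a_p and a_q and rng.choice(taxids) == rng.choice(taxids):
            oracle += 1
    sigma_oracle = math.sqrt(n_oracle * p_fp * (1 - p_fp))
    assert abs(oracle - n_oracle * p_fp) <= 3 * sigma_oracle


def test_correlated_errors_raise_intersection_fp_rate():
    pool = tuple((60_000 + i, False) for i in range(10))
    base = dict(
        n_reads=50_000, species_pool=pool,
        classifier_p=ClassifierModel(assign_prob=0.5, error_prob=0.3),
        classifier_q=ClassifierModel(assign_prob=0.5, error_prob=0.3),
    )
    assert expected_intersection_fp_reads(
        make_config(error_correlation=0.8, **base)
    ) > expected_intersection_fp_reads(make_config(error_correlation=0.0, **base))

    def observed_fp(correlation, seed=3):
        sample = simulate_sample(
            make_config(error_correlation=correlation, seed=seed, **base)
        )
        inter = merge_assignments(
            sample.table_p, sample.table_q, MergePolicy.INTERSECTION
        )
        return sum(
            1 for v in inter.assignments.values()
            if v is not NOT_ASSIGNED and v != FOCAL
        )

    assert observed_fp(0.8) > observed_fp(0.0)


def test_base_precision_recovers_one_minus_error_prob():
    """Estimated precision of a base classifier converges to
    1 - error_prob (within a 3-sigma binomial band)."""
    error_prob = 0.1
    config = make_config(
        n_reads=50_000,
        classifier_p=ClassifierModel(assign_prob=0.2, error_prob=error_prob),
        seed=5,
    )
    sample = simulate_sample(config)
    results = _evaluate_all(sample)
    n_assigned = results["p"].tp + results["p"].fp
    sigma = math.sqrt(error_prob * (1 - error_prob) / n_assigned)
    assert results["p"].precision == pytest.approx(1 - error_prob, abs=3 * sigma)
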