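import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytochunk import (
    ClassDistribution,
    ClassScheme,
    LabeledPointCloud,
    SamplingPlan,
    allocate_anchors_dependent,
    allocate_anchors_independent,
    build_training_set,
    extract_chunk,
    largest_remainder_round,
    sample_anchor_points,
)

PRINTED_FRACTIONS = [0.027, 0.015, 0.789, 0.00475, 0.00475, 0.00475, 0.00475, 0.150]


def brute_force_largest_remainder(raw, total):
    """Independent oracle: explicit floor + remainder ranking with index ties."""
    floors = [int(np.floor(x)) for x in raw]
    remainders = [(-(x - f), i) for i, (x, f) in enumerate(zip(raw, floors))]
    for _, i in sorted(remainders)[: total - sum(floors)]:
        floors[i] += 1
    return floors


class TestLargestRemainder:
    @given(raw=st.lists(st.floats(0, 50), min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_sums(self, raw):
        total = int(round(np.sum(raw)))
        result = largest_remainder_round(np.array(raw), total)
        assert result.sum() == total
        assert result.tolist() == brute_force_largest_remainder(raw, total)

    def test_raw_exceeding_total_raises(self):
        with pytest.raises(ValueError):
            largest_remainder_round(np.array([2.0, 3.0]), 4)


class TestAllocation:
    def test_uniform_symmetry(self):
        dist = ClassDistribution(np.full(8, 100))
        for allocate in (allocate_anchors_independent, allocate_anchors_dependent):
            plan = allocate(dist, 80)
            np.testing.assert_array_equal(plan.a_c, 10)

    def test_independent_on_printed_distribution(self):
        # oracle result for raw percentages (2.7, 1.5, 78.9, 0.475 x 4, 15.0)
        dist = ClassDistribution.from_fractions(PRINTED_FRACTIONS, n=200_000)
        plan = allocate_anchors_independent(dist, 100)
        expected = brute_force_largest_remainder(np.array(PRINTED_FRACTIONS) * 100, 100)
        assert plan.a_c.tolist() == expected == [3, 2, 79, 1, 0, 0, 0, 15]
        assert plan.a_c.sum() == 100

    def test_dependent_on_printed_distribution(self):
        dist = ClassDistribution.from_fractions(PRINTED_FRACTIONS, n=200_000)
        plan = allocate_anchors_dependent(dist, 100)
        fr = np.array(PRINTED_FRACTIONS)
        raw = (1 - fr) / (1 - fr).sum() * 100
        assert plan.a_c.tolist() == brute_force_largest_remainder(raw, 100)
        assert plan.a_c.sum() == 100
        # the dominant class receives the fewest anchors
        assert np.argmin(plan.a_c) == ClassScheme().index("leaf")

    def test_single_class_independent_takes_all(self):
        counts = np.zeros(8, dtype=int)
        counts[4] = 500
        plan = allocate_anchors_independent(ClassDistribution(counts), 100)
        assert plan.a_c[4] == 100 and plan.a_c.sum() == 100

    def test_single_class_dependent_raises(self):
        counts = np.zeros(8, dtype=int)
        counts[4] = 500
        with pytest.raises(ValueError, match="2 present classes"):
            allocate_anchors_dependent(ClassDistribution(counts), 100)

    def test_absent_classes_get_zero_anchors(self):
        counts = np.array([10, 90, 0, 0, 0, 0, 0, 0])
        plan = allocate_anchors_dependent(ClassDistribution(counts), 100)
        assert np.all(plan.a_c[2:] == 0)
        # two present classes with fractions (0.1, 0.9): inverses (0.9, 0.1)
        assert plan.a_c.tolist()[:2] == [90, 10]

    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=8, max_size=8).filter(
            lambda c: sum(1 for x in c if x > 0) >= 2
        ),
        a=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_allocations_always_sum_to_a(self, counts, a):
        dist = ClassDistribution(np.array(counts))
        for allocate in (allocate_anchors_independent, allocate_anchors_dependent):
            plan = allocate(dist, a)
            assert plan.a_c.sum() == a
            assert np.all(plan.a_c[np.array(counts) == 0] == 0)

    @given(present=st.integers(2, 8), a=st.integers(1, 300))
    @settings(max_examples=100, deadline=None)
    def test_strategies_coincide_on_uniform(self, present, a):
        counts = np.zeros(8, dtype=int)
        counts[:present] = 977  # equal counts for every present class
        dist = ClassDistribution(counts)
        ind = allocate_anchors_independent(dist, a)
        dep = allocate_anchors_dependent(dist, a)
        np.testing.assert_array_equal(ind.a_c, dep.a_c)


def _single_class_cloud(n, label=2):
    rng = np.random.default_rng(0)
    return LabeledPointCloud(
        positions=rng.normal(0, 10, (n, 3)),
        colours=np.zeros((n, 3), dtype=int),
        labels=np.full(n, label),
    )


class TestAnchorSampling:
    def test_exhaustive_draw_returns_all_points(self, small_plant):
        from phytochunk import class_distribution

        dist = class_distribution(small_plant)
        plan = SamplingPlan("class_independent", dist.n, dist.counts.copy(), k=8)
        anchors = sample_anchor_points(small_plant, plan, np.random.default_rng(0))
        assert sorted(i for i, _ in anchors) == list(range(small_plant.n_points))

    def test_determinism_under_fixed_seed(self, small_plant):
        from phytochunk import class_distribution, allocate_anchors_dependent

        plan = allocate_anchors_dependent(class_distribution(small_plant), 30)
        a1 = sample_anchor_points(small_plant, plan, np.random.default_rng(11))
        a2 = sample_anchor_points(small_plant, plan, np.random.default_rng(11))
        assert a1 == a2

    def test_uniformity_over_seeded_repetitions(self):
        """Each of 10 points drawn with frequency 0.1 +- 0.01 over 10,000 draws."""
        cloud = _single_class_cloud(10)
        a_c = np.zeros(8, dtype=int)
        a_c[2] = 1
        plan = SamplingPlan("class_independent", 1, a_c, k=1)
        rng = np.random.default_rng(2024)
        freq = np.zeros(10)
        reps = 10_000
        for _ in range(reps):
            (idx, _), = sample_anchor_points(cloud, plan, rng)
            freq[idx] += 1
        np.testing.assert_allclose(freq / reps, 0.1, atol=0.01)

    def test_oversampling_falls_back_to_replacement(self, caplog):
        cloud = _single_class_cloud(5)
        a_c = np.zeros(8, dtype=int)
        a_c[2] = 12
        plan = SamplingPlan("class_independent", 12, a_c, k=1)
        with caplog.at_level("WARNING"):
            anchors = sample_anchor_points(cloud, plan, np.random.default_rng(0))
        assert len(anchors) == 12
        assert "replacement" in caplog.text

    def test_absent_class_with_anchors_raises(self):
        cloud = _single_class_cloud(5, label=0)
        a_c = np.zeros(8, dtype=int)
        a_c[3] = 1
        plan = SamplingPlan("class_independent", 1, a_c, k=1)
        with pytest.raises(ValueError, match="absent"):
            sample_anchor_points(cloud, plan, np.random.default_rng(0))


class TestExtractChunk:
    def test_k_at_least_n_returns_whole_cloud(self, random_cloud):
        chunk = extract_chunk(random_cloud, 0, k=10_000)
        assert sorted(chunk.member_indices) == list(range(random_cloud.n_points))

    def test_collinear_tie_break_by_index(self):
        cloud = LabeledPointCloud(
            positions=[[x, 0, 0] for x in range(5)],
            colours=np.zeros((5, 3), dtype=int),
            labels=np.zeros(5, dtype=int),
        )
        chunk = extract_chunk(cloud, 2, k=3)
        # distances {0,1,1,2,2}: anchor first, then the distance-1 pair by index
        assert chunk.member_indices.tolist() == [2, 1, 3]
        # the k-boundary tie at distance 2 resolves to the lower index
        chunk4 = extract_chunk(cloud, 2, k=4)
        assert chunk4.member_indices.tolist() == [2, 1, 3, 0]

    def test_anchor_is_first_member(self, random_cloud):
        chunk = extract_chunk(random_cloud, 77, k=13)
        assert chunk.member_indices[0] == 77
        assert len(chunk) == 13

    def test_matches_brute_force_sort_oracle(self):
        """k-NN membership equals a full distance sort on 200 random instances."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(20, 2_000))
            k = int(rng.integers(1, n + 1))
            positions = rng.uniform(-50, 50, (n, 3))
            cloud = LabeledPointCloud(
                positions=positions,
                colours=np.zeros((n, 3), dtype=int),
                labels=np.zeros(n, dtype=int),
            )
            anchor = int(rng.integers(0, n))
            chunk = extract_chunk(cloud, anchor, k)
            d = np.linalg.norm(positions - positions[anchor], axis=1)
            expected = np.lexsort((np.arange(n), d))[:k]
            np.testing.assert_array_equal(chunk.member_indices, expected)

    def test_invalid_k_raises(self, random_cloud):
        with pytest.raises(ValueError):
            extract_chunk(random_cloud, 0, k=0)


class TestBuildTrainingSet:
    def test_single_anchor_yields_single_chunk(self, small_plant):
        ts = build_training_set([small_plant], "class_independent", a=1, k=16, seed=0)
        assert ts.n_chunks == 1

    def test_chunk_count_is_clouds_times_anchors(self):
        from phytochunk import PlantParams, generate_dataset

        plants = generate_dataset(3, PlantParams(n_points=2_000), master_seed=1)
        ts = build_training_set(plants, "class_dependent", a=10, k=32, seed=0)
        assert ts.n_chunks == 30

    def test_adding_a_cloud_does_not_perturb_existing_chunks(self, small_plant, medium_plant):
        one = build_training_set([small_plant], "class_dependent", a=10, k=32, seed=4)
        two = build_training_set(
            [small_plant, medium_plant], "class_dependent", a=10, k=32, seed=4
        )
        for c1, c2 in zip(one.chunk_sets[0], two.chunk_sets[0]):
            np.testing.assert_array_equal(c1.member_indices, c2.member_indices)

    def test_unknown_strategy_raises(self, small_plant):
        with pytest.raises(ValueError, match="strategy"):
            build_training_set([small_plant], "balanced", a=1, k=8, seed=0)

    def test_dependent_entropy_exceeds_independent_across_seeds(self):
        """Balance gain holds on every imbalanced plant over many seeds."""
        from phytochunk import PlantParams, generate_plant

        for seed in range(20):
            plant = generate_plant(PlantParams(n_points=4_000, seed=seed))
            dep = build_training_set([plant], "class_dependent", a=16, k=64, seed=seed)
            ind = build_training_set([plant], "class_independent", a=16, k=64, seed=seed)
            assert dep.entropy_bits >= ind.entropy_bits

    def test_entropy_non_increasing_in_k_trend(self, medium_plant):
        """Smaller chunks keep the inverse-sampled balance; larger ones dilute it."""
        entropies = [
            build_training_set([medium_plant], "class_dependent", a=30, k=k, seed=2).entropy_bits
            for k in (128, 512, 2048)
        ]
        assert entropies[0] > entropies[-1]
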