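import numpy as np
import pytest

from tailatlas.core import CorrespondenceMap, PointCloud
from tailatlas.composite import (
    CompositeMap,
    build_composite,
    identify_nmps,
    impute_channel,
    probability_map,
    threshold_rescale,
)
from tailatlas.registration import RegistrationConfig
from tailatlas.synthetic import TailbudScenario, perturb, rotation_about, simulate_tailbud
from tailatlas.core import RigidTransform


def _grid_target(n=10):
    pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    return PointCloud(pts, {"sox2": np.linspace(0, 1, n)})


class TestImputeChannel:
    def test_unique_mapping_copies_value(self):
        target = _grid_target(2)
        cm = CorrespondenceMap(np.array([[0, 0], [1, 1]]), 2, 2)
        vals, pol = impute_channel(cm, np.array([0.42, 0.9]), target)
        assert vals[0] == pytest.approx(0.42)
        assert pol[0] == "unique"

    def test_multi_mapping_median_and_mean(self):
        target = _grid_target(1)
        cm = CorrespondenceMap(np.array([[0, 0], [1, 0], [2, 0]]), 3, 1)
        src = np.array([0.2, 0.4, 0.9])
        vals, pol = impute_channel(cm, src, target, multi_policy="median")
        assert vals[0] == pytest.approx(0.4)
        assert pol[0] == "multi"
        vals, _ = impute_channel(cm, src, target, multi_policy="mean")
        assert vals[0] == pytest.approx(0.5)

    def test_knn_mean_of_assigned_neighbors(self):
        # targets 0..5 on a line; 0..4 uniquely mapped, 5 unmapped
        target = _grid_target(6)
        pairs = np.column_stack([np.arange(5), np.arange(5)])
        cm = CorrespondenceMap(pairs, 5, 6)
        src = np.array([0.0, 0.5, 1.0, 0.5, 0.5])
        vals, pol = impute_channel(cm, src, target, unmapped_policy="knn", k=5)
        assert pol[5] == "knn"
        assert vals[5] == pytest.approx(np.mean([0, 0.5, 1, 0.5, 0.5]))

    def test_null_and_complete_policies(self):
        target = _grid_target(3)
        cm = CorrespondenceMap(np.array([[0, 0]]), 1, 3)
        vals, pol = impute_channel(cm, np.array([0.7]), target, unmapped_policy="null")
        assert vals[1] == 0.0 and pol[1] == "null"
        existing = np.array([0.1, 0.2, 0.3])
        vals, pol = impute_channel(
            cm, np.array([0.7]), target, unmapped_policy="complete", existing=existing
        )
        assert vals[2] == pytest.approx(0.3)
        assert pol[2] == "complete"

    def test_parameter_errors(self):
        target = _grid_target(2)
        cm = CorrespondenceMap(np.array([[0, 0]]), 1, 2)
        with pytest.raises(ValueError, match="k must"):
            impute_channel(cm, np.array([0.5]), target, k=0)
        with pytest.raises(ValueError, match="existing"):
            impute_channel(cm, np.array([0.5]), target, unmapped_policy="complete")
        empty = CorrespondenceMap(np.empty((0, 2)), 1, 2)
        with pytest.raises(ValueError, match="no target point"):
            impute_channel(empty, np.array([0.5]), target, unmapped_policy="knn")

    def test_imputed_values_stay_in_source_range(self):
        rng = np.random.default_rng(0)
        target = _grid_target(8)
        pairs = np.column_stack([np.arange(6), rng.integers(0, 5, size=6)])
        cm = CorrespondenceMap(pairs, 6, 8)
        src = rng.uniform(0.2, 0.8, size=6)
        vals, _ = impute_channel(cm, src, target)
        assert vals.min() >= src.min() - 1e-12
        assert vals.max() <= src.max() + 1e-12


class TestThresholdRescale:
    def test_linear_grid_example(self):
        out = threshold_rescale(np.arange(0, 1.0, 0.1), q=0.7)
        assert np.allclose(out[:7], 0.0)
        assert np.allclose(out[7:], [0.7 / 0.9, 0.8 / 0.9, 1.0])

    def test_q_zero_is_pure_rescale(self):
        v = np.array([2.0, 4.0, 6.0])
        assert np.allclose(threshold_rescale(v, q=0.0), [0, 0.5, 1])

    def test_binary_vector_unchanged(self):
        v = np.array([0.0, 1.0, 0.0, 1.0])
        assert np.allclose(threshold_rescale(v, q=0.4), v)

    def test_idempotent_and_unit_range(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=50)
        once = threshold_rescale(v, 0.7)
        assert once.min() == 0.0 and once.max() == 1.0
        assert np.allclose(threshold_rescale(once, 0.7), once)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            threshold_rescale(np.ones(5))


class TestBuildComposite:
    def test_zero_sources_returns_target(self, tailbud):
        cmap = build_composite(tailbud, [])
        assert cmap.channel_names == list(tailbud.channels)
        assert cmap.provenance == {}

    def test_copy_source_is_lossless(self, tailbud):
        extra = np.linspace(0, 1, tailbud.n_points)
        source = tailbud.with_channel("cdh6", extra)
        source.sample_id = "copy"
        cmap = build_composite(
            tailbud, [source], config=RegistrationConfig(seed=1)
        )
        assert np.abs(cmap.target.channels["cdh6"] - extra).max() == pytest.approx(0.0)
        assert cmap.provenance["cdh6"]["policy_counts"] == {"unique": tailbud.n_points}

    def test_five_sources_make_eight_channels(self, tailbud):
        genes = [["cdh6", "hes6"], ["sp5l"], ["tagln3b"], ["tcf"], ["znf703"]]
        sources = []
        for i, group in enumerate(genes):
            sc = TailbudScenario(
                n_points=tailbud.n_points, seed=1,
                extra_channels={g: ("sox2", 0.5) for g in group},
            )
            cl = simulate_tailbud(sc)
            cl = PointCloud(
                cl.points,
                {k: v for k, v in cl.channels.items() if k != "tbxta"},
                sample_id=f"src{i}",
            )
            t = RigidTransform.from_rotation_translation(
                rotation_about([0, 1, 0.2], np.deg2rad(8 + 2 * i)), [3.0 * i, 1.0, -2.0]
            )
            sources.append(perturb(cl, transform=t, pos_sd=0.5, seed=30 + i))
        cmap = build_composite(tailbud, sources, config=RegistrationConfig(seed=2))
        assert sorted(cmap.channel_names) == sorted(
            ["sox2", "tbxta", "cdh6", "hes6", "sp5l", "tagln3b", "tcf", "znf703"]
        )
        assert not cmap.rejected_sources

    def test_low_fitness_source_rejected(self, tailbud):
        scrambled = perturb(tailbud.with_channel("cdh6", tailbud.channels["sox2"]),
                            pos_sd=60.0, seed=3)
        scrambled.sample_id = "scrambled"
        with pytest.warns(UserWarning, match="rejected"):
            cmap = build_composite(
                tailbud, [scrambled], config=RegistrationConfig(seed=1), min_fitness=0.99
            )
        assert "cdh6" not in cmap.channel_names
        assert cmap.rejected_sources[0]["sample_id"] == "scrambled"


class TestIdentifyNmps:
    def _map(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        cloud = PointCloud(
            pts,
            {"sox2": np.array([0.5, 0.0, 0.4, 0.8]), "tbxta": np.array([0.5, 0.9, 0.7, 0.0])},
        )
        return CompositeMap(target=cloud)

    def test_region_and_positivity_rules(self):
        cmap = self._map()
        region = np.array([True, True, False, True])
        nmps, excluded = identify_nmps(cmap, region)
        assert list(nmps) == [0]          # double-positive inside region
        assert list(excluded) == [2]      # double-positive outside region
        # sox2 = 0 (cell 1) and tbxta = 0 (cell 3) are never NMps
        assert 1 not in nmps and 3 not in nmps

    def test_box_regions(self):
        cmap = self._map()
        nmps, _ = identify_nmps(cmap, [{"x": (-0.5, 0.5)}])
        assert list(nmps) == [0]

    def test_missing_channel_raises(self):
        cloud = PointCloud(np.zeros((1, 3)), {"sox2": np.array([1.0])})
        with pytest.raises(KeyError, match="tbxta"):
            identify_nmps(CompositeMap(target=cloud), np.array([True]))


class TestProbabilityMap:
    def test_counting_and_display_threshold(self):
        target = _grid_target(4)
        hits = [np.array([1]), np.array([1, 2]), np.array([1])]
        pm = probability_map(target, hits, min_count=2)
        assert list(pm.counts) == [0, 3, 1, 0]
        assert list(pm.display_set) == [1]

    def test_single_source_empty_display(self):
        target = _grid_target(3)
        pm = probability_map(target, [np.array([0, 1])], min_count=2)
        assert pm.display_set.size == 0

    def test_min_count_one_is_union(self):
        target = _grid_target(4)
        pm = probability_map(target, [np.array([0]), np.array([2])], min_count=1)
        assert list(pm.display_set) == [0, 2]

    def test_counts_sum_equals_total_hits(self):
        rng = np.random.default_rng(0)
        target = _grid_target(20)
        hits = [np.unique(rng.integers(0, 20, size=7)) for _ in range(4)]
        pm = probability_map(target, hits)
        assert pm.counts.sum() == sum(h.size for h in hits)
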