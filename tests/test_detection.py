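"""Thresholding, labeling, densities and size classes."""

import numpy as np
import pytest

import synquery as sq
from synquery.query_engine import MarkerSpec
from synquery.synthetic_data import _render_punctum
from tests.conftest import make_geometry


def pv(data, name="q"):
    return sq.ProbabilityVolume(name, np.asarray(data, float),
                                make_geometry(*data.shape))


class TestThresholdAndLabel:
    def test_empty_map_gives_no_detections(self):
        assert sq.threshold_and_label(pv(np.zeros((3, 8, 8)))) == []

    def test_two_disjoint_blobs_give_two_records(self):
        data = np.zeros((3, 20, 20))
        data[1, 2:4, 2:4] = 0.95
        data[1, 14:16, 14:16] = 0.95
        dets = sq.threshold_and_label(pv(data))
        assert len(dets) == 2
        assert dets[0].centroid_px < dets[1].centroid_px  # deterministic order

    def test_centroids_in_micrometres(self):
        data = np.zeros((3, 10, 10))
        data[2, 5, 6] = 1.0
        d, = sq.threshold_and_label(pv(data))
        assert d.centroid_um == pytest.approx((2 * 0.07, 0.5, 0.6))

    def test_raising_threshold_never_adds_detections(self, sparse_probs,
                                                     queries):
        """Over the operating range, a stricter threshold only removes calls.

        (Exactly at saturation a supra-threshold region can pinch apart into
        two cores, so the guarantee is stated for thresholds up to the 0.9
        default.)
        """
        for qname in ("Glutamatergic VGluT1", "GABAergic"):
            pm = sq.evaluate_query(sparse_probs, queries[qname])
            counts = [len(sq.threshold_and_label(pm, thr))
                      for thr in (0.3, 0.5, 0.7, 0.9)]
            assert counts == sorted(counts, reverse=True)

    def test_detection_accuracy_on_default_scene(self, sparse_scene,
                                                 sparse_probs, queries):
        """Recall and precision >= 0.9 against ground truth at 0.3 um."""
        from synquery.experiments import ELIGIBLE_TYPES
        _, _, truth, _ = sparse_scene
        matched = n_det = n_truth = 0
        for qname, types in ELIGIBLE_TYPES.items():
            dets = sq.detect(sparse_probs, queries[qname], with_spans=False)
            m, nd, nt = sq.match_to_truth(
                dets, [t for t in truth if t.type in types], radius_um=0.3)
            matched += m; n_det += nd; n_truth += nt
        assert matched / n_truth >= 0.9
        assert matched / n_det >= 0.9


class TestSizeBinnedDensities:
    def test_subtraction_arithmetic(self, sparse_probs, queries, sparse_scene):
        cfg, _, _, _ = sparse_scene
        v = cfg.geometry.total_volume_um3
        d = sq.size_binned_densities(sparse_probs,
                                     queries["Glutamatergic VGluT1"], v)
        assert d["small"] + d["medium"] + d["large"] == pytest.approx(d["all"],
                                                                      rel=1e-12)
        assert all(x >= 0 for x in d.values())

    def test_single_slice_scene_has_no_medium_or_large(self):
        cfg = sq.SimulationConfig(
            seed=13, geometry=sq.AcquisitionGeometry(10, 80, 80),
            densities={"VGluT1": 0.15}, nuclei_fraction=0.0,
            span_log_mu=np.log(1.0), span_log_sigma=1e-6)
        channels, truth, _ = sq.generate_volume(cfg)
        assert all(t.span == 1 for t in truth)
        probs = sq.channel_probabilities(
            {n: channels[n] for n in ("synapsin", "VGluT1", "PSD95")})
        d = sq.size_binned_densities(
            probs, sq.standard_queries()["Glutamatergic VGluT1"],
            cfg.geometry.total_volume_um3)
        assert d["medium"] == 0 and d["large"] == 0
        assert d["small"] == d["all"] > 0

    def test_size_class_proportions_recovered(self):
        """Detected small/medium/large shares track the log-normal truth."""
        cfg = sq.SimulationConfig(
            seed=21, geometry=sq.AcquisitionGeometry(30, 200, 200))
        cfg = cfg.with_density_scale(0.2)
        channels, truth, _ = sq.generate_volume(cfg)
        probs = sq.channel_probabilities(
            {n: c for n, c in channels.items() if n != "DAPI"})
        npil = sq.nuclei_mask(channels["DAPI"])
        d = sq.size_binned_densities(
            probs, sq.standard_queries()["Glutamatergic VGluT1"],
            npil.neuropil_volume_um3)
        elig = [t for t in truth if t.type in ("VGluT1", "VGluT1/2")]
        for cls in ("small", "medium", "large"):
            truth_prop = np.mean([t.size_class == cls for t in elig])
            assert d[cls] / d["all"] == pytest.approx(truth_prop, rel=0.10)

    def test_zero_volume_rejected(self, sparse_probs, queries):
        with pytest.raises(ValueError):
            sq.size_binned_densities(sparse_probs, queries["GABAergic"], 0.0)


class TestSingleMarkerDensity:
    def test_empty_channel_all_zero(self):
        g = make_geometry(4, 20, 20)
        empty = sq.ProbabilityVolume("GS", np.zeros(g.shape), g)
        d = sq.single_marker_puncta_density(empty, MarkerSpec("GS"), 10.0)
        assert set(d.values()) == {0.0}

    def test_ten_single_slice_puncta_counted_exactly(self):
        g = sq.AcquisitionGeometry(10, 100, 100)
        clean = np.zeros(g.shape)
        positions = [(1 + (k % 8), 15 + 20 * (k % 4), 15 + 20 * (k // 4))
                     for k in range(10)]  # well separated
        for z, r, c in positions:
            _render_punctum(clean, z, 1, float(r), float(c), 2.0, 50.0)
        prob = sq.ProbabilityVolume("GS", np.clip(clean, 0, 1), g)
        v = g.total_volume_um3
        d = sq.single_marker_puncta_density(prob, MarkerSpec("GS"), v)
        assert d["all"] == pytest.approx(10 / v)
        assert d["medium"] == 0 and d["large"] == 0
        assert d["small"] + d["medium"] + d["large"] == pytest.approx(d["all"])


class TestAssignLayers:
    def test_counts_conserved_and_boundary_convention(self):
        g = make_geometry(2, 30, 10)
        partition = sq.LayerPartition(("L1", "L2/3", "L4"), (10, 20), 30)
        rng = np.random.default_rng(0)
        dets = []
        for i in range(40):
            r = rng.uniform(0, 30)
            dets.append(sq.DetectionRecord(
                id=i, query_name="q", voxels=(np.array([0]), np.array([0]),
                                              np.array([0])),
                centroid_px=(0.0, r, 0.0), centroid_um=(0.0, r * 0.1, 0.0)))
        sq.assign_layers(dets, partition)
        by_layer = {n: sum(d.layer == n for d in dets) for n in partition.names}
        assert sum(by_layer.values()) == 40
        # row exactly on a boundary belongs to the layer starting there
        boundary = sq.DetectionRecord(
            id=99, query_name="q",
            voxels=(np.array([0]), np.array([0]), np.array([0])),
            centroid_px=(0.0, 10.0, 0.0), centroid_um=(0.0, 1.0, 0.0))
        sq.assign_layers([boundary], partition)
        assert boundary.layer == "L2/3"


class TestSpanDistribution:
    def test_counts_nonincreasing_in_span(self, sparse_probs, queries):
        dist = sq.postsynaptic_span_distribution(
            sparse_probs, queries["Glutamatergic VGluT1"],
            span_values=(1, 2, 3, 4))
        assert all(v >= 0 for v in dist.values())

    def test_postsynaptic_span_distribution_tracks_truth(self):
        cfg = sq.SimulationConfig(
            seed=21, geometry=sq.AcquisitionGeometry(30, 250, 250),
            densities={"VGluT1": 0.25}, nuclei_fraction=0.0)
        channels, truth, _ = sq.generate_volume(cfg)
        probs = sq.channel_probabilities(
            {n: channels[n] for n in ("synapsin", "VGluT1", "PSD95")})
        dist = sq.postsynaptic_span_distribution(
            probs, sq.standard_queries()["Glutamatergic VGluT1"])
        total = sum(dist.values())
        truth_counts = {}
        for t in truth:
            key = f"{t.span}" if t.span < 6 else "6+"
            truth_counts[key] = truth_counts.get(key, 0) + 1
        for key, n in truth_counts.items():
            det_prop = dist.get(key, 0) / total
            assert det_prop == pytest.approx(n / len(truth), abs=0.10)

    def test_concentrated_spans_land_in_one_class(self):
        cfg = sq.SimulationConfig(
            seed=14, geometry=sq.AcquisitionGeometry(12, 80, 80),
            densities={"VGluT1": 0.12}, nuclei_fraction=0.0,
            span_log_mu=np.log(2.0), span_log_sigma=1e-6)
        channels, truth, _ = sq.generate_volume(cfg)
        assert all(t.span == 2 for t in truth)
        probs = sq.channel_probabilities(
            {n: channels[n] for n in ("synapsin", "VGluT1", "PSD95")})
        dist = sq.postsynaptic_span_distribution(
            probs, sq.standard_queries()["Glutamatergic VGluT1"],
            span_values=(1, 2, 3))
        assert dist["2"] >= 0.9 * sum(dist.values())


class TestTripartiteOrdering:
    def test_tripartite_counts_never_exceed_bipartite(self, sparse_probs,
                                                      queries):
        for bi, tri in sq.TRIPARTITE_OF.items():
            nb = len(sq.detect(sparse_probs, queries[bi], with_spans=False))
            nt = len(sq.detect(sparse_probs, queries[tri], with_spans=False))
            assert nt <= nb
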