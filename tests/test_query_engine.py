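"""Query evaluation: punctum evidence, colocalization, adjacency."""

import numpy as np
import pytest

import synquery as sq
from synquery.query_engine import MarkerSpec, Query, QueryParams
from tests.conftest import make_geometry, random_prob_channels


def pv(data, name="x"):
    data = np.asarray(data, float)
    return sq.ProbabilityVolume(name, data, make_geometry(*data.shape))


class TestPunctumProbability:
    def test_certainty_is_preserved(self):
        vol = pv(np.ones((4, 8, 8)))
        out = sq.punctum_probability(vol, MarkerSpec("x", 2, 2))
        assert np.allclose(out.data, 1.0)

    def test_single_slice_box_mean(self):
        data = np.zeros((1, 9, 9))
        data[0, 4:6, 4:6] = 1.0  # 2x2 block of certain foreground
        out = sq.punctum_probability(pv(data), MarkerSpec("x", 2, 1))
        assert out.data.max() == pytest.approx(1.0)
        assert (out.data == 1.0).sum() == 1  # only the aligned window
        assert out.data[0, 0, 0] == 0.0

    def test_slice_span_window_products(self):
        """Hand evaluation on a block present on slices 4 and 5 of 8."""
        data = np.zeros((8, 9, 9))
        data[4:6, 4:6, 4:6] = 1.0
        out2 = sq.punctum_probability(pv(data), MarkerSpec("x", 2, 2))
        # the two-slice window {4,5} has product 1 at the aligned position
        assert out2.data[4].max() == pytest.approx(1.0)
        assert out2.data[5].max() == pytest.approx(1.0)
        assert out2.data[3].max() < 1.0  # windows containing slice 3 include a zero slice
        out3 = sq.punctum_probability(pv(data), MarkerSpec("x", 2, 3))
        assert out3.data.max() < 1.0  # no three consecutive slices are filled

    def test_requirement_deeper_than_stack_is_empty(self):
        data = np.ones((2, 4, 4))
        out = sq.punctum_probability(pv(data), MarkerSpec("x", 2, 5))
        assert not out.data.any()


class TestCombine:
    def test_single_marker_identity_up_to_dilation(self):
        vol = pv(np.ones((2, 5, 5)))
        out = sq.combine_colocalized([vol])
        assert np.allclose(out.data, 1.0)

    def test_colocalization_tolerates_one_pixel_offset(self):
        a = np.zeros((1, 9, 9))
        b = np.zeros((1, 9, 9))
        a[0, 4, 4] = 1.0
        b[0, 4, 5] = 1.0  # offset by 1 px
        out = sq.combine_colocalized([pv(a), pv(b)], r_coloc=1)
        assert out.data.max() == pytest.approx(1.0)
        b5 = np.zeros((1, 9, 9))
        b5[0, 4, 8] = 1.0  # offset by 4 px: outside the dilation
        far = sq.combine_colocalized([pv(a), pv(b5)], r_coloc=1)
        assert far.data.max() == 0.0

    def test_empty_subclass_rejected(self):
        with pytest.raises(ValueError):
            sq.combine_colocalized([])

    def test_adjacency_reaches_two_pixels(self):
        pre = np.zeros((3, 9, 9))
        post = np.zeros((3, 9, 9))
        pre[1, 4, 4] = 1.0
        post[1, 4, 6] = 1.0  # 2 px away
        q = sq.combine_adjacent(pv(pre), pv(post), a_xy=2, a_z=1)
        assert q.data[1, 4, 4] == pytest.approx(1.0)
        post_far = np.zeros((3, 9, 9))
        post_far[1, 4, 8] = 1.0  # 4 px away, beyond the +-2 px search
        q_far = sq.combine_adjacent(pv(pre), pv(post_far), a_xy=2, a_z=1)
        assert q_far.data[1, 4, 4] == 0.0

    def test_zero_offset_adjacency_allowed(self):
        both = np.zeros((1, 5, 5))
        both[0, 2, 2] = 1.0
        q = sq.combine_adjacent(pv(both), pv(both.copy()))
        assert q.data[0, 2, 2] == pytest.approx(1.0)

    def test_absent_astro_channel_annihilates(self):
        ones = pv(np.ones((2, 5, 5)))
        zeros = pv(np.zeros((2, 5, 5)))
        q = sq.combine_adjacent(ones, pv(np.ones((2, 5, 5))), zeros)
        assert not q.data.any()


class TestEvaluateQuery:
    def test_missing_channel_named_in_error(self, small_geometry):
        chans = random_prob_channels(0, small_geometry, names=("A", "B"))
        query = Query("q", (MarkerSpec("A"),), (MarkerSpec("Z"),))
        with pytest.raises(KeyError, match="Z"):
            sq.evaluate_query(chans, query)

    def test_all_zero_channels_give_zero_map(self, small_geometry):
        zeros = {n: sq.ProbabilityVolume(n, np.zeros(small_geometry.shape),
                                         small_geometry) for n in "AB"}
        query = Query("q", (MarkerSpec("A"),), (MarkerSpec("B"),))
        out = sq.evaluate_query(zeros, query)
        assert not out.data.any()

    def test_noise_free_synapse_is_certain(self, queries):
        """An ideal rendered synapse scores >= 0.9; empty background < 0.1."""
        cfg = sq.SimulationConfig(
            seed=5, geometry=sq.AcquisitionGeometry(12, 40, 40),
            densities={}, nuclei_fraction=0.0, vglut2_speckle_rate=0.0,
            background_std=0.0)
        channels, _, _ = sq.generate_volume(cfg)
        # paint one ideal VGluT1 synapse by hand at the center
        from synquery.synthetic_data import _render_punctum
        for name in ("synapsin", "VGluT1"):
            arr = channels[name].data
            _render_punctum(arr, 6, 2, 20.0, 20.0, 2.0, 1000.0)
        _render_punctum(channels["PSD95"].data, 6, 2, 20.0, 22.0, 2.0, 1000.0)
        probs = sq.channel_probabilities(
            {n: c for n, c in channels.items() if n != "DAPI"},
            scope="volume")
        out = sq.evaluate_query(probs, queries["Glutamatergic VGluT1"])
        assert out.data[6, 19:22, 19:22].max() >= 0.9
        far = out.data[:, :10, :10]
        assert far.max() < 0.1

    def test_bipartite_synapse_fails_tripartite_query(self, queries):
        cfg = sq.SimulationConfig(
            seed=6, geometry=sq.AcquisitionGeometry(12, 60, 60),
            astro_association={k: 0.0 for k in ("VGluT1", "VGluT2",
                                                "VGluT1/2", "GABAergic")})
        cfg = cfg.with_density_scale(0.05)
        channels, truth, _ = sq.generate_volume(cfg)
        probs = sq.channel_probabilities(
            {n: c for n, c in channels.items() if n != "DAPI"})
        tri = sq.evaluate_query(probs,
                                queries["Glutamatergic VGluT1 adjacent to astrocyte"])
        for t in truth:
            if t.type not in ("VGluT1", "VGluT1/2"):
                continue
            z, r, c = (int(round(x)) for x in t.centroid_px)
            win = tri.data[max(0, z - 2):z + 3, max(0, r - 3):r + 4,
                           max(0, c - 3):c + 4]
            assert win.max() < 0.9

    def test_marker_order_within_subclass_irrelevant(self, small_geometry):
        chans = random_prob_channels(7, small_geometry)
        q1 = Query("q", (MarkerSpec("A"), MarkerSpec("B")), (MarkerSpec("C"),))
        q2 = Query("q", (MarkerSpec("B"), MarkerSpec("A")), (MarkerSpec("C"),))
        assert np.array_equal(sq.evaluate_query(chans, q1).data,
                              sq.evaluate_query(chans, q2).data)

    @pytest.mark.parametrize("seed", range(5))
    def test_requirements_are_anti_monotone(self, seed, small_geometry):
        """More markers or longer spans never raise any voxel's probability."""
        chans = random_prob_channels(seed, small_geometry)
        base = Query("q", (MarkerSpec("A"),), (MarkerSpec("B"),))
        more = Query("q", (MarkerSpec("A"), MarkerSpec("C")), (MarkerSpec("B"),))
        longer = base.with_required_span(2)
        out = sq.evaluate_query(chans, base).data
        tol = 1e-12
        assert np.all(sq.evaluate_query(chans, more).data <= out + tol)
        assert np.all(sq.evaluate_query(chans, longer).data <= out + tol)

    def test_deterministic(self, small_geometry):
        chans = random_prob_channels(9, small_geometry)
        q = Query("q", (MarkerSpec("A"),), (MarkerSpec("B"),))
        assert np.array_equal(sq.evaluate_query(chans, q).data,
                              sq.evaluate_query(chans, q).data)
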