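"""Simulator ground truth, determinism, and statistical fidelity."""

import numpy as np
import pytest
from scipy import stats

import synquery as sq
from synquery.synthetic_data import (SYNAPSE_TYPES, TYPE_MARKERS,
                                     span_class_probabilities)


class TestGenerateVolume:
    def test_zero_density_pure_background(self):
        cfg = sq.SimulationConfig(seed=0, densities={}, nuclei_fraction=0.0,
                                  vglut2_speckle_rate=0.0)
        channels, truth, nuclei = sq.generate_volume(cfg)
        assert truth == []
        assert not nuclei.any()
        syn = channels["synapsin"].data
        assert syn.mean() == pytest.approx(cfg.background_mean, rel=0.01)
        assert syn.std() == pytest.approx(cfg.background_std, rel=0.05)

    def test_same_seed_bit_identical(self):
        cfg = sq.SimulationConfig(seed=42).with_density_scale(0.1)
        ch1, t1, n1 = sq.generate_volume(cfg)
        ch2, t2, n2 = sq.generate_volume(cfg)
        assert t1 == t2
        assert np.array_equal(n1, n2)
        for name in ch1:
            assert np.array_equal(ch1[name].data, ch2[name].data)

    def test_count_matches_poisson_oracle(self):
        cfg = sq.SimulationConfig(seed=1, nuclei_fraction=0.0,
                                  min_spacing_um=0.0)
        channels, truth, _ = sq.generate_volume(cfg)
        lam = sum(cfg.densities.values()) * cfg.geometry.total_volume_um3
        assert abs(len(truth) - lam) <= 3 * np.sqrt(lam)

    def test_marker_co_occurrence_respects_types(self):
        """No PSD-95 signal at GABAergic sites, no gephyrin at glutamatergic."""
        for stype, (pre, post) in TYPE_MARKERS.items():
            assert "synapsin" in pre
        cfg = sq.SimulationConfig(
            seed=2, geometry=sq.AcquisitionGeometry(12, 80, 80),
            densities={"GABAergic": 0.15}, nuclei_fraction=0.0,
            background_std=0.0, vglut2_speckle_rate=0.0)
        channels, truth, _ = sq.generate_volume(cfg)
        assert len(truth) > 0
        assert np.all(channels["PSD95"].data == cfg.background_mean)
        assert np.all(channels["VGluT1"].data == cfg.background_mean)
        assert channels["gephyrin"].data.max() > cfg.background_mean

    def test_vglut2_rendered_spans_at_least_two(self):
        cfg = sq.SimulationConfig(
            seed=3, geometry=sq.AcquisitionGeometry(12, 80, 80),
            densities={"VGluT2": 0.2}, nuclei_fraction=0.0,
            background_std=0.0, vglut2_speckle_rate=0.0)
        channels, truth, _ = sq.generate_volume(cfg)
        above = channels["VGluT2"].data > cfg.background_mean
        per_slice = above.any(axis=(1, 2))
        # every synapse contributes at least two consecutive labeled sections
        for t in truth:
            z = int(t.centroid_px[0])
            assert per_slice[z] or per_slice[z + 1]

    def test_nuclei_fraction_close_to_target(self):
        cfg = sq.SimulationConfig(seed=4,
                                  geometry=sq.AcquisitionGeometry(30, 200, 200))
        _, _, nuclei = sq.generate_volume(cfg)
        assert nuclei.mean() == pytest.approx(cfg.nuclei_fraction, abs=0.02)

    def test_synapses_avoid_nuclei(self):
        cfg = sq.SimulationConfig(seed=5).with_density_scale(0.3)
        _, truth, nuclei = sq.generate_volume(cfg)
        for t in truth:
            z, r, c = (int(x) for x in t.centroid_px)
            assert not nuclei[z, r, c]

    def test_excessive_nuclei_fraction_rejected(self):
        with pytest.raises(ValueError):
            sq.generate_volume(sq.SimulationConfig(nuclei_fraction=1.0))


class TestSpanStatistics:
    def test_span_sampling_matches_lognormal(self):
        """KS distance of sampled spans to the rounded log-normal < 0.1."""
        rng = np.random.default_rng(6)
        mu, sigma = np.log(2.0), 0.5
        spans = sq.sample_spans(rng, mu, sigma, 1000)
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        grid = np.arange(1, spans.max() + 1)
        emp = np.array([(spans <= g).mean() for g in grid])
        theo = dist.cdf(grid + 0.5)
        assert np.max(np.abs(emp - theo)) < 0.1

    def test_class_probabilities_sum_to_one(self):
        p = span_class_probabilities(np.log(2.0), 0.5)
        assert sum(p) == pytest.approx(1.0)
        assert all(x > 0 for x in p)

    def test_astro_fraction_within_binomial_error(self):
        cfg = sq.SimulationConfig(seed=7,
                                  geometry=sq.AcquisitionGeometry(30, 200, 200))
        cfg = cfg.with_density_scale(0.5)
        _, truth, _ = sq.generate_volume(cfg)
        glut = [t for t in truth if t.type != "GABAergic"]
        frac = np.mean([t.astro_associated for t in glut])
        p = cfg.astro_association["VGluT1"]
        se = np.sqrt(p * (1 - p) / len(glut))
        assert abs(frac - p) <= 4 * se


class TestCohort:
    def test_cohort_shapes_and_labels(self):
        base = sq.SimulationConfig(
            geometry=sq.AcquisitionGeometry(8, 40, 40),
            nuclei_fraction=0.0).with_density_scale(0.05)
        samples = sq.generate_cohort(base, base, n_wt=3, n_ko=4)
        assert [s.group for s in samples] == ["WT"] * 3 + ["KO"] * 4
        assert len({s.sample_id for s in samples}) == 7

    def test_duplicate_seeds_rejected(self):
        base = sq.SimulationConfig(geometry=sq.AcquisitionGeometry(4, 20, 20))
        with pytest.raises(ValueError):
            sq.generate_cohort(base, base, 2, 2, seeds=[1, 1, 2, 3])

    def test_ko_density_multiplier_shifts_truth(self):
        from dataclasses import replace
        base = sq.SimulationConfig(
            geometry=sq.AcquisitionGeometry(20, 120, 120),
            densities={"VGluT2": 0.4}, nuclei_fraction=0.0)
        ko = replace(base, densities={"VGluT2": 0.3})
        wt_counts, ko_counts = [], []
        for i in range(10):
            _, t_wt, _ = sq.generate_volume(replace(base, seed=50 + i))
            _, t_ko, _ = sq.generate_volume(replace(ko, seed=150 + i))
            wt_counts.append(len(t_wt))
            ko_counts.append(len(t_ko))
        change = (np.mean(ko_counts) - np.mean(wt_counts)) / np.mean(wt_counts)
        assert change == pytest.approx(-0.25, abs=0.08)


class TestTruthIO:
    def test_round_trip(self, tmp_path, sparse_scene):
        _, _, truth, _ = sparse_scene
        path = tmp_path / "truth.csv"
        sq.write_ground_truth(truth, path)
        back = sq.read_ground_truth(path)
        assert back == truth

    def test_empty_truth_header_only(self, tmp_path):
        path = tmp_path / "truth.csv"
        sq.write_ground_truth([], path)
        assert sq.read_ground_truth(path) == []
        assert path.read_text().startswith("id,type,")
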