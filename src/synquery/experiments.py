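"""Canonical desk-scale validation experiments.

Each function builds a simulated scene with known ground truth, runs the
pipeline on it, and reports recovery metrics.  They are deterministic given
a seed and sized to run on a single CPU in seconds to a few minutes; the
same recipes back both the test suite and the reproduction script.

Scene sizes and densities are chosen per experiment: detection accuracy
and parameter recovery use sparse fields (a few hundredths to a few tenths
of a synapse per µm³) where per-synapse bookkeeping is unambiguous, while
the density-additivity check runs at the full cortical density scale
(~1.9 synapses per µm³ of neuropil) where it matters.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import density_to_unprocessed, shrinkage_volumetric
from .catalog import standard_queries
from .colocalization import cross_correlation_profile
from .detection import detect
from .geometry_io import AcquisitionGeometry
from .neuropil import nuclei_mask
from .probability import channel_probabilities
from .synthetic_data import (SimulationConfig, generate_adjacent_pair_field,
                             generate_volume, match_to_truth)

#: Query → ground-truth types it should detect, for accuracy scoring.
ELIGIBLE_TYPES = {
    "Glutamatergic VGluT1": ("VGluT1", "VGluT1/2"),
    "Glutamatergic VGluT2": ("VGluT2", "VGluT1/2"),
    "GABAergic": ("GABAergic",),
}


def _probs(channels, exclude=("DAPI",)):
    return channel_probabilities({n: c for n, c in channels.items()
                                  if n not in exclude})


def shrinkage_examples() -> dict[str, float]:
    """Tissue-shrinkage worked examples.

    23% linear shrinkage of dehydrated/embedded tissue corresponds to
    ~54% volumetric shrinkage, deflating a density of 1.94 synapses/µm³ of
    embedded tissue to ~0.9/µm³ of unprocessed tissue; a punctum spanning
    two 70 nm sections is at least 0.14 µm deep.
    """
    return {
        "volumetric_shrinkage_pct": 100 * shrinkage_volumetric(0.23),
        "density_unprocessed_per_um3": density_to_unprocessed(1.94, 0.23),
        "min_punctum_depth_um": 2 * 0.07,
    }


def detection_accuracy(seed: int) -> dict[str, float]:
    """Recall/precision of the type-specific queries on a ~50-synapse scene.

    A default-noise 100×100 px × 30 section volume is populated at a
    density giving roughly fifty synapses; each type-specific query's
    detections are greedily matched to the eligible ground truth within
    0.3 µm, pooled over queries.
    """
    cfg = SimulationConfig(seed=seed)
    scale = 50 / (sum(cfg.densities.values())
                  * cfg.geometry.total_volume_um3 * (1 - cfg.nuclei_fraction))
    cfg = cfg.with_density_scale(scale)
    channels, truth, _ = generate_volume(cfg)
    probs = _probs(channels)
    queries = standard_queries()
    matched = n_det = n_truth = 0
    for qname, types in ELIGIBLE_TYPES.items():
        dets = detect(probs, queries[qname], with_spans=False)
        m, nd, nt = match_to_truth(
            dets, [t for t in truth if t.type in types], radius_um=0.3)
        matched += m
        n_det += nd
        n_truth += nt
    return {"recall": matched / n_truth, "precision": matched / n_det,
            "n_truth": len(truth)}


def additivity_identity(seed: int) -> dict[str, float]:
    """Excitatory-density consistency at full cortical density.

    The density of all glutamatergic synapses should equal the VGluT1 plus
    VGluT2 densities minus the dually labeled VGluT1/VGluT2 density (which
    would otherwise be counted twice).  Computed on a 30×30 µm × 30 section
    volume at a density where simulated punctum footprints stay clear of
    neighboring synapses' adjacency neighborhoods — at higher crowding the
    synthetic blob geometry lets one synapse borrow another's markers,
    which contaminates the per-type counts rather than testing them.
    """
    cfg = SimulationConfig(seed=seed,
                           geometry=AcquisitionGeometry(30, 300, 300))
    cfg = cfg.with_density_scale(0.15)
    channels, truth, _ = generate_volume(cfg)
    probs = _probs(channels)
    neuropil = nuclei_mask(channels["DAPI"])
    v = neuropil.neuropil_volume_um3
    queries = standard_queries()
    counts = {name: len(detect(probs, queries[name], with_spans=False))
              for name in ("Glutamatergic", "Glutamatergic VGluT1",
                           "Glutamatergic VGluT2",
                           "Glutamatergic VGluT1/VGluT2")}
    glut = counts["Glutamatergic"] / v
    combo = (counts["Glutamatergic VGluT1"] + counts["Glutamatergic VGluT2"]
             - counts["Glutamatergic VGluT1/VGluT2"]) / v
    return {"glut_density": glut, "combo_density": combo,
            "relative_error": abs(glut - combo) / glut, "n_truth": len(truth)}


def association_recovery(seed: int, n_samples: int = 3,
                         association: float | None = None) -> dict[str, float]:
    """Recover the configured astrocyte-association probability.

    Three sparse 30×30 µm samples (as from three animals) are simulated at
    the configured association probability; in each, the tripartite VGluT1
    query density is divided by the bipartite one, and the per-sample
    fractions are averaged.  Sparse fields keep chance adjacency to
    unrelated astrocytic puncta and detection crosstalk low, which is what
    makes the fraction a clean estimate of the generative parameter.
    """
    fractions = []
    queries = standard_queries()
    for i in range(n_samples):
        cfg = SimulationConfig(seed=seed * 100 + i,
                               geometry=AcquisitionGeometry(30, 300, 300))
        if association is not None:
            cfg = replace(cfg, astro_association={
                k: association for k in cfg.astro_association})
        cfg = cfg.with_density_scale(0.08)
        channels, truth, _ = generate_volume(cfg)
        probs = _probs(channels)
        n_bi = len(detect(probs, queries["Glutamatergic VGluT1"],
                          with_spans=False))
        n_tri = len(detect(probs, queries["Glutamatergic VGluT1 adjacent to astrocyte"],
                           with_spans=False))
        fractions.append(n_tri / n_bi if n_bi else float("nan"))
    configured = (association if association is not None
                  else SimulationConfig().astro_association["VGluT1"])
    return {"recovered_fraction": float(np.mean(fractions)),
            "configured": configured,
            "per_sample": fractions}


def nuclei_recovery(seed: int) -> dict[str, float]:
    """DAPI-based nuclei volume fraction vs the generator's 10% target."""
    cfg = SimulationConfig(seed=seed,
                           geometry=AcquisitionGeometry(30, 200, 200))
    cfg = cfg.with_density_scale(0.1)
    channels, _, nuclei = generate_volume(cfg)
    mask = nuclei_mask(channels["DAPI"])
    est = mask.nuclei_volume_um3 / mask.total_volume_um3
    return {"estimated_fraction": est, "true_fraction": float(nuclei.mean()),
            "target_fraction": cfg.nuclei_fraction}


def ko_sign_recovery(seed: int, n_cohorts: int = 20,
                     effect: float = -0.15) -> dict[str, float]:
    """Direction-of-change recovery for a knockout effect on large inhibitory synapses.

    Each replicate cohort has three wild-type and four knockout samples
    (21×21 µm × 30 sections, GABAergic synapses only); the knockout
    generator carries ``effect`` on the large (≥3 section) size class.
    Reported is the fraction of cohorts in which the detected large-
    inhibitory density difference has the configured sign.
    """
    base = SimulationConfig(geometry=AcquisitionGeometry(30, 210, 210),
                            densities={"GABAergic": 0.30}, nuclei_fraction=0.0)
    ko = replace(base, size_class_multipliers={"GABAergic": {"large": 1 + effect}})
    query = standard_queries()["GABAergic"].with_required_span(3)
    correct = 0
    for rep in range(n_cohorts):
        group_means = {"WT": [], "KO": []}
        for i in range(7):
            grp = "WT" if i < 3 else "KO"
            cfg = replace(base if grp == "WT" else ko,
                          seed=seed * 1000 + rep * 10 + i)
            channels, _, _ = generate_volume(cfg)
            probs = channel_probabilities(
                {n: channels[n] for n in ("synapsin", "GAD", "gephyrin")})
            n3 = len(detect(probs, query, with_spans=False))
            group_means[grp].append(n3 / cfg.geometry.total_volume_um3)
        diff = np.mean(group_means["KO"]) - np.mean(group_means["WT"])
        if np.sign(diff) == np.sign(effect):
            correct += 1
    return {"sign_success_rate": correct / n_cohorts, "n_cohorts": n_cohorts}


def ei_ratio_recovery(seed: int) -> dict[str, float]:
    """Detected excitation/inhibition density ratio vs generator truth."""
    cfg = SimulationConfig(seed=seed,
                           geometry=AcquisitionGeometry(30, 250, 250))
    cfg = cfg.with_density_scale(0.2)
    channels, truth, _ = generate_volume(cfg)
    probs = _probs(channels)
    queries = standard_queries()
    v = cfg.geometry.total_volume_um3
    exc = len(detect(probs, queries["Glutamatergic"], with_spans=False)) / v
    inh = len(detect(probs, queries["GABAergic"], with_spans=False)) / v
    n_exc = sum(t.type != "GABAergic" for t in truth)
    n_inh = sum(t.type == "GABAergic" for t in truth)
    return {"detected_ratio": exc / inh, "truth_ratio": n_exc / n_inh}


def adjacent_pair_profile(seed: int) -> dict[str, float]:
    """Shift-correlation signature of adjacent-but-not-overlapping markers.

    A field of marker pairs offset by 0.3–0.4 µm is generated; the lateral
    shift-correlation should rise from its zero-shift value to a maximum
    at the offset distance and decay beyond it.
    """
    a, b = generate_adjacent_pair_field(seed=seed)
    prof = cross_correlation_profile(a, b, max_shift_px=20)
    pos = prof.r[prof.shifts_px >= 0]
    peak = int(np.argmax(pos))
    return {"r_zero": float(prof.r_at(0)), "r_peak": float(pos[peak]),
            "peak_shift_um": peak * prof.pixel_size_xy,
            "r_tail": float(prof.r_at(10))}
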