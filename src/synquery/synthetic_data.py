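"""Synthetic multi-channel array-tomography volumes with ground truth.

The generator emulates the acquisition this pipeline targets: ribbons of
70 nm physical sections imaged at ~0.1 µm lateral pixel pitch, one
grayscale stack per immunofluorescent channel (synapsin, PSD-95, VGluT1,
VGluT2, GAD, gephyrin, GS, DAPI).  Synapses of four disjoint types are
placed uniformly in the neuropil (never inside nuclei):

========== ============================== ==============
type       presynaptic markers            postsynaptic
========== ============================== ==============
VGluT1     synapsin, VGluT1               PSD95
VGluT2     synapsin, VGluT2               PSD95
VGluT1/2   synapsin, VGluT1, VGluT2       PSD95
GABAergic  synapsin, GAD                  gephyrin
========== ============================== ==============

Presynaptic markers are co-centered; the postsynaptic punctum is displaced
by a synaptic-cleft offset (0.15–0.25 µm) in a random lateral direction;
when a synapse is astrocyte-associated a glutamine-synthetase (GS) punctum
is placed adjacent to the pair.  Each punctum is a Gaussian blob laterally
and spans a number of consecutive sections drawn from a log-normal size
distribution (VGluT2 puncta at real synapses always span at least two
sections).  Channels carry per-channel Gaussian background noise; the
VGluT2 channel additionally carries randomly scattered single-section
speckle puncta, emulating that antibody's higher nonspecific background.
DAPI contains ellipsoidal nuclei occupying a target volume fraction.

Every random draw flows from one seeded generator, so identical configs
and seeds give bit-identical volumes, and every synapse is recorded in a
ground-truth table for recall/precision and parameter-recovery testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geometry_io import AcquisitionGeometry, ChannelVolume

SYNAPSE_TYPES = ("VGluT1", "VGluT2", "VGluT1/2", "GABAergic")
CHANNEL_NAMES = ("synapsin", "PSD95", "VGluT1", "VGluT2", "GAD",
                 "gephyrin", "GS", "DAPI")

#: Marker layout per synapse type: (presynaptic channels, postsynaptic channel)
TYPE_MARKERS: dict[str, tuple[tuple[str, ...], str]] = {
    "VGluT1": (("synapsin", "VGluT1"), "PSD95"),
    "VGluT2": (("synapsin", "VGluT2"), "PSD95"),
    "VGluT1/2": (("synapsin", "VGluT1", "VGluT2"), "PSD95"),
    "GABAergic": (("synapsin", "GAD"), "gephyrin"),
}

SIZE_CLASS_NAMES = ("small", "medium", "large")


@dataclass(frozen=True)
class GroundTruthSynapse:
    """Simulator-side truth record for one synapse."""

    id: int
    type: str
    centroid_um: tuple[float, float, float]
    centroid_px: tuple[float, float, float]
    span: int                     # sections spanned by the synaptic markers
    radius_um: float              # lateral punctum radius
    amplitude: float              # peak intensity above background
    astro_associated: bool
    layer: str | None = None

    @property
    def size_class(self) -> str:
        return "small" if self.span == 1 else ("medium" if self.span == 2 else "large")


@dataclass(frozen=True)
class SimulationConfig:
    """Scene parameters of one simulated sample.

    Defaults reproduce the conditions of adult mouse somatosensory cortex
    as this kind of experiment reports them: a total synapse density near
    1.9 per µm³ of neuropil split into the four types, an inhibitory
    fraction near 16%, astrocytic association of ~72% for excitatory and
    ~29% for inhibitory synapses, log-normal punctum sizes with median two
    sections, cleft offsets of 0.15–0.25 µm, and nuclei occupying ~10% of
    the imaged volume.
    """

    geometry: AcquisitionGeometry = AcquisitionGeometry(
        n_slices=30, height_px=100, width_px=100)
    #: synapses per µm³ of neuropil, per (disjoint) type
    densities: dict[str, float] = field(default_factory=lambda: {
        "VGluT1": 1.30, "VGluT2": 0.20, "VGluT1/2": 0.12, "GABAergic": 0.30})
    #: probability that a synapse of each type is astrocyte-associated
    astro_association: dict[str, float] = field(default_factory=lambda: {
        "VGluT1": 0.72, "VGluT2": 0.72, "VGluT1/2": 0.72, "GABAergic": 0.29})
    #: per-type multipliers on the small/medium/large sub-densities,
    #: for encoding cohort effect sizes (e.g. −15% large inhibitory)
    size_class_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    #: log-normal span parameters (of log section count)
    span_log_mu: float = float(np.log(2.0))
    span_log_sigma: float = 0.5
    #: synaptic cleft pre→post offset range, µm (lateral)
    cleft_offset_um: tuple[float, float] = (0.15, 0.25)
    #: GS punctum offset from the synapse, µm (lateral)
    astro_offset_um: float = 0.25
    #: punctum lateral radius range, µm
    punctum_radius_um: tuple[float, float] = (0.1, 0.3)
    #: GS punctum lateral radius range, µm — peripheral astrocytic processes
    #: are fine (below-resolution) structures, so their puncta are smaller
    #: than synaptic ones
    astro_radius_um: tuple[float, float] = (0.08, 0.15)
    #: optical blur folded into rendered lateral width, µm
    psf_sigma_um: float = 0.1
    #: Gaussian background per channel
    background_mean: float = 100.0
    background_std: float = 10.0
    #: punctum peak amplitude over background, in background SDs
    peak_snr: float = 8.0
    #: single-section VGluT2 speckle puncta per µm³
    vglut2_speckle_rate: float = 1.0
    #: minimum centroid separation between synapses, µm
    min_spacing_um: float = 0.6
    #: nuclei: target volume fraction and semi-axis ranges (µm)
    nuclei_fraction: float = 0.10
    nucleus_rxy_um: tuple[float, float] = (1.0, 2.0)
    nucleus_rz_um: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def with_density_scale(self, factor: float) -> "SimulationConfig":
        """Uniformly rescale every type density (desk-scale runs)."""
        return replace(self, densities={k: v * factor
                                        for k, v in self.densities.items()})


def _amplitude(cfg: SimulationConfig) -> float:
    """Punctum peak over background: ``peak_snr`` background SDs (or an
    absolute ``peak_snr`` units in a noise-free scene)."""
    return cfg.peak_snr * (cfg.background_std if cfg.background_std > 0 else 1.0)


def span_class_probabilities(log_mu: float, log_sigma: float
                             ) -> tuple[float, float, float]:
    """P(span = 1), P(span = 2), P(span ≥ 3) under the rounded log-normal."""
    dist = stats.lognorm(s=log_sigma, scale=np.exp(log_mu))
    p1 = float(dist.cdf(1.5))
    p2 = float(dist.cdf(2.5) - dist.cdf(1.5))
    return p1, p2, 1.0 - p1 - p2


def sample_spans(rng: np.random.Generator, log_mu: float, log_sigma: float,
                 n: int, minimum: int = 1) -> np.ndarray:
    """Draw section spans: round a log-normal variate, floor at ``minimum``."""
    x = rng.lognormal(mean=log_mu, sigma=log_sigma, size=n)
    return np.maximum(np.rint(x).astype(int), minimum)


def _sample_span_in_class(rng: np.random.Generator, cfg: SimulationConfig,
                          size_class: str) -> int:
    if size_class == "small":
        return 1
    if size_class == "medium":
        return 2
    while True:  # truncated draw for the open-ended large class
        s = int(sample_spans(rng, cfg.span_log_mu, cfg.span_log_sigma, 1)[0])
        if s >= 3:
            return s


#: Radial cutoff of rendered puncta, in units of the lateral sigma.
#: Real immunofluorescent puncta are compact spots; an untruncated Gaussian
#: leaves faint skirts that are not part of the punctum.
_BLOB_TRUNCATION_SIGMA = 2.0


def _render_punctum(data: np.ndarray, z_center: int, span: int,
                    row: float, col: float, sigma_px: float, amp: float) -> None:
    """Add a punctum: truncated Gaussian laterally, flat across ``span`` sections."""
    nz, h, w = data.shape
    z0 = z_center - (span - 1) // 2
    z1 = z0 + span
    z0, z1 = max(0, z0), min(nz, z1)
    half = max(1, int(np.ceil(_BLOB_TRUNCATION_SIGMA * sigma_px)))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1 or z0 >= z1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    blob = amp * np.exp(-d2 / (2 * sigma_px**2))
    blob[d2 > (_BLOB_TRUNCATION_SIGMA * sigma_px) ** 2] = 0.0
    data[z0:z1, r0:r1, c0:c1] += blob[None]


def _generate_nuclei(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Ellipsoidal nuclei mask at the target volume fraction."""
    if cfg.nuclei_fraction >= 1:
        raise ValueError("nuclei fraction must be < 1")
    geom = cfg.geometry
    nz, h, w = geom.shape
    mask = np.zeros(geom.shape, dtype=bool)
    if cfg.nuclei_fraction <= 0:
        return mask
    target = cfg.nuclei_fraction * mask.size
    zz = np.arange(nz)[:, None, None] * geom.slice_thickness
    rr = np.arange(h)[None, :, None] * geom.pixel_size_xy
    cc = np.arange(w)[None, None, :] * geom.pixel_size_xy
    for _ in range(1000):
        current = int(mask.sum())
        if current >= target:
            break
        rxy = rng.uniform(*cfg.nucleus_rxy_um)
        rz = rng.uniform(*cfg.nucleus_rz_um)
        cz = rng.uniform(0, nz * geom.slice_thickness)
        cr = rng.uniform(0, h * geom.pixel_size_xy)
        cc_ = rng.uniform(0, w * geom.pixel_size_xy)
        ell = (((zz - cz) / rz) ** 2 + ((rr - cr) / rxy) ** 2
               + ((cc - cc_) / rxy) ** 2) <= 1.0
        grown = int((mask | ell).sum())
        # stop at whichever side of the target is closer
        if grown - target > target - current:
            break
        mask |= ell
    return mask


def _place_synapses(rng: np.random.Generator, cfg: SimulationConfig,
                    nuclei: np.ndarray,
                    counts: dict[tuple[str, str], int]) -> list[GroundTruthSynapse]:
    geom = cfg.geometry
    nz, h, w = geom.shape
    min_spacing_px = cfg.min_spacing_um / geom.pixel_size_xy
    placed: list[tuple[float, float, float]] = []  # (z_um, r_um, c_um)
    truth: list[GroundTruthSynapse] = []
    margin_xy = 4  # px, keeps puncta and their offsets inside the field
    sid = 0
    items = sorted(counts.items())
    for (stype, size_class), n in items:
        for _ in range(n):
            span = _sample_span_in_class(rng, cfg, size_class)
            z_half = (span - 1) // 2 + 1
            for _try in range(200):
                z = int(rng.integers(z_half, max(z_half + 1, nz - z_half - (span - 1) % 2)))
                r = rng.uniform(margin_xy, h - margin_xy)
                c = rng.uniform(margin_xy, w - margin_xy)
                if nuclei[z, int(r), int(c)]:
                    continue
                z_um, r_um, c_um = (z * geom.slice_thickness,
                                    r * geom.pixel_size_xy, c * geom.pixel_size_xy)
                ok = True
                for (pz, pr, pc) in placed:
                    if (abs(pz - z_um) < cfg.min_spacing_um
                            and (pr - r_um) ** 2 + (pc - c_um) ** 2
                            < cfg.min_spacing_um**2):
                        ok = False
                        break
                if ok:
                    break
            else:
                continue  # could not place; drop (dense scenes only)
            placed.append((z_um, r_um, c_um))
            radius = rng.uniform(*cfg.punctum_radius_um)
            astro_p = cfg.astro_association.get(stype, 0.0)
            truth.append(GroundTruthSynapse(
                id=sid, type=stype,
                centroid_um=(z_um, r_um, c_um), centroid_px=(float(z), r, c),
                span=span, radius_um=radius,
                amplitude=_amplitude(cfg),
                astro_associated=bool(rng.random() < astro_p)))
            sid += 1
    return truth


def generate_volume(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, ChannelVolume],
                               list[GroundTruthSynapse], np.ndarray]:
    """Simulate one sample: channel volumes, ground truth, true nuclei mask.

    Synapse counts per type and size class are Poisson with mean
    density · class probability · neuropil volume (after any per-class
    effect multipliers); placement is uniform over the neuropil with a
    minimum spacing.  Identical configs and seeds give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    nuclei = _generate_nuclei(rng, cfg)
    neuropil_um3 = (nuclei.size - nuclei.sum()) * geom.voxel_volume_um3

    class_p = dict(zip(SIZE_CLASS_NAMES,
                       span_class_probabilities(cfg.span_log_mu, cfg.span_log_sigma)))
    counts: dict[tuple[str, str], int] = {}
    for stype, dens in sorted(cfg.densities.items()):
        mult = cfg.size_class_multipliers.get(stype, {})
        for size_class in SIZE_CLASS_NAMES:
            lam = dens * class_p[size_class] * mult.get(size_class, 1.0) * neuropil_um3
            counts[(stype, size_class)] = int(rng.poisson(lam)) if lam > 0 else 0

    truth = _place_synapses(rng, cfg, nuclei, counts)

    stacks = {name: np.zeros(geom.shape, dtype=float) for name in CHANNEL_NAMES}
    amp = _amplitude(cfg)
    px = geom.pixel_size_xy
    for syn in truth:
        z, r, c = syn.centroid_px
        sigma_px = np.sqrt(syn.radius_um**2 + cfg.psf_sigma_um**2) / px
        pre_channels, post_channel = TYPE_MARKERS[syn.type]
        theta = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(*cfg.cleft_offset_um) / px
        post_r, post_c = r + off * np.cos(theta), c + off * np.sin(theta)
        for ch in pre_channels:
            span = syn.span
            if ch == "VGluT2":
                span = max(span, 2)  # real VGluT2 label always spans >= 2 sections
            _render_punctum(stacks[ch], int(z), span, r, c, sigma_px, amp)
        _render_punctum(stacks[post_channel], int(z), syn.span,
                        post_r, post_c, sigma_px, amp)
        if syn.astro_associated:
            phi = theta + np.pi / 2 + rng.uniform(-0.5, 0.5)
            a_off = cfg.astro_offset_um / px
            a_sigma = np.sqrt(rng.uniform(*cfg.astro_radius_um) ** 2
                              + cfg.psf_sigma_um**2) / px
            # astrocytic processes are extended sheets: always >= 2 sections
            _render_punctum(stacks["GS"], int(z), 2,
                            r + a_off * np.cos(phi), c + a_off * np.sin(phi),
                            a_sigma, amp)

    # VGluT2 antibody speckle: bright single-section blobs everywhere
    n_speckle = int(rng.poisson(cfg.vglut2_speckle_rate * geom.total_volume_um3))
    for _ in range(n_speckle):
        z = int(rng.integers(0, geom.n_slices))
        r = rng.uniform(0, geom.height_px)
        c = rng.uniform(0, geom.width_px)
        _render_punctum(stacks["VGluT2"], z, 1, r, c,
                        cfg.psf_sigma_um / px * 1.5, amp)

    stacks["DAPI"][nuclei] = amp

    channels: dict[str, ChannelVolume] = {}
    for name in CHANNEL_NAMES:
        noisy = stacks[name] + rng.normal(cfg.background_mean, cfg.background_std,
                                          size=geom.shape)
        channels[name] = ChannelVolume(name=name, data=np.clip(noisy, 0, None),
                                       geometry=geom)
    return channels, truth, nuclei


@dataclass
class CohortSample:
    sample_id: str
    group: str
    channels: dict[str, ChannelVolume]
    truth: list[GroundTruthSynapse]
    nuclei: np.ndarray


def generate_cohort(config_wt: SimulationConfig, config_ko: SimulationConfig,
                    n_wt: int = 3, n_ko: int = 4,
                    seeds: list[int] | None = None) -> list[CohortSample]:
    """Independent WT and KO samples; the KO config encodes the effect sizes.

    Defaults mirror the common design of three wild-type and four knockout
    animals.  ``seeds`` must be distinct, one per sample; by default they
    are derived from the two configs' seeds.
    """
    n = n_wt + n_ko
    if seeds is None:
        seeds = [config_wt.seed * 1000 + i for i in range(n)]
    if len(seeds) != n or len(set(seeds)) != n:
        raise ValueError("need one distinct seed per sample")
    samples = []
    for i in range(n):
        group = "WT" if i < n_wt else "KO"
        cfg = replace(config_wt if group == "WT" else config_ko, seed=seeds[i])
        channels, truth, nuclei = generate_volume(cfg)
        samples.append(CohortSample(sample_id=f"{group.lower()}{i}", group=group,
                                    channels=channels, truth=truth, nuclei=nuclei))
    return samples


def generate_adjacent_pair_field(seed: int = 0,
                                 offset_um: tuple[float, float] = (0.3, 0.4),
                                 blob_sigma_um: float = 0.12,
                                 n_pairs: int = 1200,
                                 shape: tuple[int, int, int] = (10, 400, 300),
                                 background_mean: float = 100.0,
                                 background_std: float = 10.0,
                                 amplitude: float = 80.0
                                 ) -> tuple[ChannelVolume, ChannelVolume]:
    """Two channels of paired puncta that are adjacent but never overlap.

    Each pair consists of one punctum per channel, displaced by a random
    lateral direction and a distance drawn from ``offset_um`` — the
    geometry of an astrocytic process beside a postsynaptic density.  The
    shift-correlation profile of such a field rises with lateral shift up
    to the offset distance and falls beyond it, the signature of adjacency
    without overlap.
    """
    rng = np.random.default_rng(seed)
    geom = AcquisitionGeometry(*shape)
    a = np.zeros(shape)
    b = np.zeros(shape)
    sigma_px = blob_sigma_um / geom.pixel_size_xy
    margin = 8
    for _ in range(n_pairs):
        z = int(rng.integers(1, shape[0] - 1))
        r = rng.uniform(margin, shape[1] - margin)
        c = rng.uniform(margin, shape[2] - margin)
        theta = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(*offset_um) / geom.pixel_size_xy
        _render_punctum(a, z, 2, r, c, sigma_px, amplitude)
        _render_punctum(b, z, 2, r + d * np.cos(theta), c + d * np.sin(theta),
                        sigma_px, amplitude)
    noise = rng.normal(background_mean, background_std, size=(2, *shape))
    return (ChannelVolume("pair_a", np.clip(a + noise[0], 0, None), geom),
            ChannelVolume("pair_b", np.clip(b + noise[1], 0, None), geom))


# ---------------------------------------------------------------------------
# Ground-truth I/O
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["id", "type", "z_um", "row_um", "col_um", "z_px", "row_px",
                 "col_px", "span", "radius_um", "amplitude",
                 "astro_associated", "layer"]


def truth_to_frame(truth: list[GroundTruthSynapse]) -> pd.DataFrame:
    rows = [{
        "id": s.id, "type": s.type,
        "z_um": s.centroid_um[0], "row_um": s.centroid_um[1],
        "col_um": s.centroid_um[2],
        "z_px": s.centroid_px[0], "row_px": s.centroid_px[1],
        "col_px": s.centroid_px[2],
        "span": s.span, "radius_um": s.radius_um, "amplitude": s.amplitude,
        "astro_associated": s.astro_associated,
        "layer": s.layer if s.layer is not None else "",
    } for s in truth]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_ground_truth(truth: list[GroundTruthSynapse],
                       path: str | os.PathLike) -> None:
    truth_to_frame(truth).to_csv(path, index=False, float_format="%.17g")


def read_ground_truth(path: str | os.PathLike) -> list[GroundTruthSynapse]:
    frame = pd.read_csv(path, keep_default_na=False,
                        float_precision="round_trip")
    out = []
    for _, row in frame.iterrows():
        out.append(GroundTruthSynapse(
            id=int(row["id"]), type=str(row["type"]),
            centroid_um=(float(row["z_um"]), float(row["row_um"]),
                         float(row["col_um"])),
            centroid_px=(float(row["z_px"]), float(row["row_px"]),
                         float(row["col_px"])),
            span=int(row["span"]), radius_um=float(row["radius_um"]),
            amplitude=float(row["amplitude"]),
            astro_associated=(str(row["astro_associated"]) == "True"
                              if not isinstance(row["astro_associated"], (bool, np.bool_))
                              else bool(row["astro_associated"])),
            layer=(str(row["layer"]) or None)))
    return out


def match_to_truth(detections, truth: list[GroundTruthSynapse],
                   radius_um: float = 0.3) -> tuple[int, int, int]:
    """Greedy one-to-one centroid matching of detections to ground truth.

    Pairs are considered in order of increasing centroid distance; each
    detection and each true synapse is used at most once.  Returns
    (matched, n_detections, n_truth) from which recall and precision follow.
    """
    if not detections or not truth:
        return 0, len(detections), len(truth)
    det = np.array([d.centroid_um for d in detections])
    tru = np.array([t.centroid_um for t in truth])
    diff = det[:, None, :] - tru[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    pairs = [(dist[i, j], i, j) for i in range(len(det)) for j in range(len(tru))
             if dist[i, j] <= radius_um]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return matched, len(detections), len(truth)
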