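"""Thresholding query maps into discrete synapse detections and densities.

A query probability map is thresholded (default 0.9) and supra-threshold
voxels are grouped into 26-connected 3-D components, one detection per
component.  Densities are detections per µm³ of neuropil.  Size classes
(small / medium / large) are obtained by *query subtraction*: the same
query is run requiring marker spans of ≥1, ≥2 and ≥3 consecutive sections,
and the per-class counts are successive differences of the resulting
detection counts — small synapses have at least one marker on a single
section only, large synapses have every marker on three or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .geometry_io import (DEFAULT_PROBABILITY_THRESHOLD, AcquisitionGeometry,
                          LayerPartition)
from .probability import ProbabilityVolume
from .query_engine import (MarkerSpec, Query, QueryParams, punctum_probability,
                           evaluate_query)

#: 26-connectivity structuring element for 3-D component labeling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

SIZE_CLASSES = ("small", "medium", "large", "all")


@dataclass
class DetectionRecord:
    """One called synapse."""

    id: int
    query_name: str
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (z, r, c) index arrays
    centroid_px: tuple[float, float, float]
    centroid_um: tuple[float, float, float]
    marker_spans: dict[str, int] = field(default_factory=dict)
    layer: str | None = None
    astrocyte_associated: bool = False

    @property
    def n_voxels(self) -> int:
        return len(self.voxels[0])


def _marker_span(thresholded_marker: np.ndarray, component_mask_2d: np.ndarray,
                 z_range: tuple[int, int], a_xy: int, a_z: int) -> int:
    """Consecutive slices on which the marker punctum is present near a component.

    ``component_mask_2d`` is the detection's lateral footprint, dilated by
    the adjacency radius; a slice counts when any voxel of the thresholded
    marker map falls inside that footprint.  The span is the longest run of
    consecutive such slices overlapping the component's (padded) z extent.
    """
    present = thresholded_marker[:, component_mask_2d].any(axis=1)
    z0 = max(0, z_range[0] - a_z)
    z1 = min(len(present) - 1, z_range[1] + a_z)
    best = 0
    run_start = None
    for z in range(len(present)):
        if present[z]:
            if run_start is None:
                run_start = z
        if not present[z] or z == len(present) - 1:
            if run_start is not None:
                run_end = z - 1 if not present[z] else z
                if run_end >= z0 and run_start <= z1:
                    best = max(best, run_end - run_start + 1)
                run_start = None
    return best


def _split_touching(mask: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Separate merged detections by a distance-transform watershed.

    At realistic synapse densities the supra-threshold regions of adjacent
    synapses can touch, welding several synapses into one 26-connected
    component and displacing its centroid.  The distance transform is
    computed per slice in 2-D (sections are thin relative to lateral blob
    extent, so a 3-D transform is capped by the stack faces and loses the
    lateral structure); each connected plateau of its local maxima seeds
    one watershed basin.  Components with a single seed region come out
    exactly as plain connected-component labeling would give them.
    """
    if not mask.any():
        return labels
    dist = np.empty(mask.shape, dtype=float)
    for z in range(mask.shape[0]):
        dist[z] = ndimage.distance_transform_edt(mask[z])
    local_max = (dist >= ndimage.maximum_filter(dist, size=(3, 5, 5))) & mask
    # noise-ragged borders fragment a blob's maximum plateau; bridge pieces
    # closer than the minimum punctum footprint so one core yields one seed
    local_max = ndimage.binary_dilation(local_max, np.ones((3, 5, 5), bool)) & mask
    seeds, n_seeds = ndimage.label(local_max, structure=_STRUCT_26)
    if n_seeds <= labels.max():
        return labels
    return watershed(-dist, markers=seeds, mask=mask)


def threshold_and_label(prob_map: ProbabilityVolume,
                        threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
                        query: Query | None = None,
                        prob_channels: dict[str, ProbabilityVolume] | None = None,
                        params: QueryParams = QueryParams(),
                        split_touching: bool = True) -> list[DetectionRecord]:
    """Threshold a query map into per-component detections.

    Voxels with probability ≥ ``threshold`` are grouped into 26-connected
    components (split where distinct cores merely touch, unless
    ``split_touching`` is disabled); each becomes one
    :class:`DetectionRecord` with centroid in pixels and µm.  When the
    originating ``query`` and the per-channel foreground probabilities are
    supplied, each marker's slice span at the detection is measured from
    its single-slice punctum evidence; the astrocyte flag records whether
    the query included an astrocyte marker.  Ordering is deterministic: by
    centroid (slice, row, col).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    geometry = prob_map.geometry
    mask = prob_map.data >= threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if split_touching and n:
        labels = _split_touching(mask, labels)

    marker_maps: dict[str, np.ndarray] = {}
    if query is not None and prob_channels is not None:
        for m in query.markers:
            if m.channel not in marker_maps:
                single = punctum_probability(prob_channels[m.channel],
                                             MarkerSpec(m.channel, m.min_xy_px,
                                                        min_slices=1))
                marker_maps[m.channel] = single.data >= threshold

    records: list[DetectionRecord] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        voxels = np.nonzero(labels[slc] == lab)
        zs = voxels[0] + slc[0].start
        rs = voxels[1] + slc[1].start
        cs = voxels[2] + slc[2].start
        centroid = (float(zs.mean()), float(rs.mean()), float(cs.mean()))
        spans: dict[str, int] = {}
        if marker_maps:
            foot = np.zeros((geometry.height_px, geometry.width_px), dtype=bool)
            foot[rs, cs] = True
            foot = ndimage.binary_dilation(
                foot, structure=np.ones((2 * params.a_xy + 1,) * 2, dtype=bool))
            zr = (int(zs.min()), int(zs.max()))
            for m in query.markers:
                spans[m.channel] = _marker_span(marker_maps[m.channel], foot, zr,
                                                params.a_xy, params.a_z)
        records.append(DetectionRecord(
            id=0, query_name=prob_map.name,
            voxels=(zs, rs, cs), centroid_px=centroid,
            centroid_um=geometry.px_to_um(centroid),
            marker_spans=spans,
            astrocyte_associated=bool(query.astrocyte) if query else False))
    records.sort(key=lambda d: d.centroid_px)
    for i, rec in enumerate(records):
        rec.id = i
    return records


def detect(prob_channels: dict[str, ProbabilityVolume], query: Query,
           threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
           params: QueryParams = QueryParams(),
           with_spans: bool = True) -> list[DetectionRecord]:
    """Evaluate a query and threshold it in one call."""
    prob_map = evaluate_query(prob_channels, query, params)
    return threshold_and_label(prob_map, threshold,
                               query=query if with_spans else None,
                               prob_channels=prob_channels if with_spans else None,
                               params=params)


def _count(prob_channels, query, span, threshold, params) -> int:
    q = query.with_required_span(span)
    return len(detect(prob_channels, q, threshold, params, with_spans=False))


def size_binned_densities(prob_channels: dict[str, ProbabilityVolume],
                          query: Query, neuropil_volume_um3: float,
                          threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
                          params: QueryParams = QueryParams()) -> dict[str, float]:
    """Densities per µm³ by size class via query subtraction.

    The query is run at span requirements 1, 2 and 3 giving counts N1 ≥ N2
    ≥ N3; then small = (N1−N2)/V, medium = (N2−N3)/V, large = N3/V and
    all = N1/V, which sum exactly.
    """
    if neuropil_volume_um3 <= 0:
        raise ValueError("neuropil volume must be > 0")
    n1, n2, n3 = (_count(prob_channels, query, s, threshold, params)
                  for s in (1, 2, 3))
    assert n1 >= n2 >= n3, "span anti-monotonicity violated"
    v = neuropil_volume_um3
    return {"small": (n1 - n2) / v, "medium": (n2 - n3) / v,
            "large": n3 / v, "all": n1 / v}


def single_marker_puncta_density(prob_channel: ProbabilityVolume,
                                 spec: MarkerSpec, neuropil_volume_um3: float,
                                 threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
                                 ) -> dict[str, float]:
    """Size-binned punctum density of a single channel (no adjacency).

    The same span-subtraction scheme applied directly to the channel's
    punctum-probability maps: small puncta span one section, medium two,
    large three or more.
    """
    if neuropil_volume_um3 <= 0:
        raise ValueError("neuropil volume must be > 0")
    counts = []
    for s in (1, 2, 3):
        pm = punctum_probability(prob_channel, spec, min_slices=s)
        labels, n = ndimage.label(pm.data >= threshold, structure=_STRUCT_26)
        counts.append(n)
    n1, n2, n3 = counts
    assert n1 >= n2 >= n3, "span anti-monotonicity violated"
    v = neuropil_volume_um3
    return {"small": (n1 - n2) / v, "medium": (n2 - n3) / v,
            "large": n3 / v, "all": n1 / v}


def assign_layers(detections: list[DetectionRecord],
                  partition: LayerPartition) -> list[DetectionRecord]:
    """Label each detection with the layer containing its centroid row."""
    for d in detections:
        d.layer = partition.layer_of_row(d.centroid_px[1])
    return detections


def postsynaptic_span_distribution(prob_channels: dict[str, ProbabilityVolume],
                                   base_query: Query,
                                   span_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                                   threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
                                   params: QueryParams = QueryParams()
                                   ) -> dict[str, int]:
    """Distribution of the postsynaptic punctum span among detected synapses.

    The base query is run with the postsynaptic marker's span floor set to
    each value of ``span_values`` (ascending); successive differences of the
    nonincreasing counts give the number of synapses whose postsynaptic
    punctum spans exactly k sections, with the final class open-ended
    ("k+").  Keys are e.g. ``"1", "2", ..., "6+"``.
    """
    spans = sorted(span_values)
    counts = []
    for s in spans:
        q = base_query.with_postsynaptic_span(s)
        counts.append(len(detect(prob_channels, q, threshold, params,
                                 with_spans=False)))
    assert all(a >= b for a, b in zip(counts, counts[1:])), \
        "span anti-monotonicity violated"
    out: dict[str, int] = {}
    for i, s in enumerate(spans[:-1]):
        out[str(s)] = counts[i] - counts[i + 1]
    out[f"{spans[-1]}+"] = counts[-1]
    return out
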