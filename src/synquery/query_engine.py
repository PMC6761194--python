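"""Declarative synapse-type queries over foreground-probability channels.

A *query* describes what one synapse type looks like: which immunofluorescent
markers must be present, whether each is presynaptic, postsynaptic or
astrocytic, the minimum lateral footprint of each punctum (default
2 px × 2 px = 0.2 µm × 0.2 µm) and the number of consecutive 70 nm sections
it must span.  Markers within one subclass (e.g. synapsin with VGluT1) are
expected to *colocalize* — occupy the same 3-D space — while the pre, post
and astrocyte groups are expected to be *adjacent*: juxtaposed, occupying
immediately neighboring voxels rather than the same ones.

Evaluating a query turns per-channel foreground probabilities into a single
map whose value at each voxel is the probability that a synapse matching
the description is centered there.  The concrete operators are:

``punctum_probability``
    lateral box-mean over the marker's minimum footprint on each slice,
    then, for the slice-span requirement *m*, the max over all windows of
    *m* consecutive slices containing the voxel of the product of the
    windowed per-slice values.
``combine_colocalized``
    voxelwise product of the subclass's punctum maps after a small lateral
    max-dilation (radius ``r_coloc``) of each, accommodating puncta that
    share only a small proportion of pixels.
``combine_adjacent``
    product of the presynaptic map with the neighborhood-max (±``a_xy`` px
    laterally, ±``a_z`` slices) of the postsynaptic and, when present,
    astrocytic maps.

All operators map [0,1] volumes to [0,1] volumes, are monotone in their
inputs, and are anti-monotone in the requirements: adding a marker or
raising a slice-span requirement can never raise the probability anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry_io import DEFAULT_MIN_XY_PX
from .probability import ProbabilityVolume

logger = logging.getLogger("synquery")


@dataclass(frozen=True)
class MarkerSpec:
    """One required marker within a query.

    ``min_slices`` of ``None`` means "use the query-level required span";
    an explicit value acts as a floor on that span (the VGluT2 rule: its
    punctum must span at least two adjacent sections regardless of the
    span the query is being run at, because the antibody also produces
    single-slice speckle background).
    """

    channel: str
    min_xy_px: int = DEFAULT_MIN_XY_PX
    min_slices: int | None = None

    def __post_init__(self) -> None:
        if self.min_xy_px < 1:
            raise ValueError("min_xy_px must be >= 1")
        if self.min_slices is not None and self.min_slices < 1:
            raise ValueError("min_slices must be >= 1")

    def effective_min_slices(self, required_span: int) -> int:
        if self.min_slices is None:
            return required_span
        return max(self.min_slices, required_span)


@dataclass(frozen=True)
class Query:
    """A synapse-type definition: marker sets plus size requirements."""

    name: str
    presynaptic: tuple[MarkerSpec, ...]
    postsynaptic: tuple[MarkerSpec, ...]
    astrocyte: MarkerSpec | None = None
    required_span: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "presynaptic", tuple(self.presynaptic))
        object.__setattr__(self, "postsynaptic", tuple(self.postsynaptic))
        if not self.presynaptic or not self.postsynaptic:
            raise ValueError(
                f"query {self.name!r} needs at least one presynaptic and one "
                f"postsynaptic marker")
        if self.required_span < 1:
            raise ValueError("required_span must be >= 1")

    @property
    def markers(self) -> tuple[MarkerSpec, ...]:
        extra = (self.astrocyte,) if self.astrocyte else ()
        return self.presynaptic + self.postsynaptic + extra

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(m.channel for m in self.markers)

    def with_required_span(self, span: int) -> "Query":
        """Same query at a different slice-span requirement."""
        return replace(self, required_span=span)

    def with_postsynaptic_span(self, span: int) -> "Query":
        """Pin every postsynaptic marker's span floor to ``span``."""
        post = tuple(replace(m, min_slices=span) for m in self.postsynaptic)
        return replace(self, postsynaptic=post)


@dataclass(frozen=True)
class QueryParams:
    """Window radii of the query operators, in grid units.

    Lateral and axial scales are parameterized separately because the grid
    is anisotropic (0.1 µm pixels vs 0.07 µm sections).
    """

    r_coloc: int = 1   # lateral max-dilation radius for within-subclass overlap, px
    a_xy: int = 2      # lateral adjacency search radius, px
    a_z: int = 1       # axial adjacency search radius, slices
    lateral_mode: str = "joint"  # punctum window evidence: 'joint' | 'mean'


#: Floor avoiding log(0) in the joint-probability window evidence.
_LOG_FLOOR = 1e-30


def _lateral_box_evidence(data: np.ndarray, size: int,
                          mode: str = "joint") -> np.ndarray:
    """Per-slice lateral punctum evidence over a ``size`` × ``size`` window.

    ``"joint"`` (default) takes the product of the per-pixel foreground
    probabilities — the probability that the whole minimum footprint is
    foreground, treating pixels as independent.  ``"mean"`` takes the
    arithmetic box mean instead; it is kept for comparison but its heavy
    noise tail at high thresholds admits far more spurious puncta (the
    chance that four independent uniform background probabilities average
    above 0.9 is ~10⁻³, their product exceeds 0.9 only ~5·10⁻⁶ of the
    time).  Border windows are edge-replicated; an exact zero anywhere in
    the window forces the joint evidence to exactly zero.
    """
    if size == 1:
        return data.astype(float, copy=True)
    out = np.empty(data.shape, dtype=float)
    if mode == "mean":
        for z in range(data.shape[0]):
            ndimage.uniform_filter(data[z].astype(float), size=size,
                                   mode="nearest", output=out[z])
        return out
    if mode != "joint":
        raise ValueError("lateral evidence mode must be 'joint' or 'mean'")
    n_px = size * size
    for z in range(data.shape[0]):
        plane = data[z].astype(float)
        logp = np.log(np.clip(plane, _LOG_FLOOR, None))
        ndimage.uniform_filter(logp, size=size, mode="nearest", output=logp)
        out[z] = np.exp(n_px * logp)
        zero_hit = ndimage.minimum_filter(plane, size=size, mode="nearest") == 0.0
        out[z][zero_hit] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    return out


def punctum_probability(prob_volume: ProbabilityVolume,
                        spec: MarkerSpec,
                        min_slices: int | None = None,
                        lateral_mode: str = "joint") -> ProbabilityVolume:
    """Probability that a punctum of the required size is present at a voxel.

    The lateral evidence combines the foreground probabilities over the
    ``min_xy_px`` window on each slice (joint probability by default, see
    :func:`_lateral_box_evidence`); the axial requirement of *m*
    consecutive slices takes, at voxel depth z, the maximum over the
    windows of *m* consecutive slices containing z of the product of the
    windowed slice values.  A requirement deeper than the stack yields an
    all-zero map with a warning.
    """
    m = spec.effective_min_slices(min_slices) if min_slices is not None else (
        spec.min_slices or 1)
    data = prob_volume.data
    nz = data.shape[0]
    if m > nz:
        logger.warning("punctum requirement of %d slices exceeds stack depth %d; "
                       "returning empty map", m, nz)
        return ProbabilityVolume(name=prob_volume.name,
                                 data=np.zeros_like(data, dtype=float),
                                 geometry=prob_volume.geometry)
    lateral = _lateral_box_evidence(data, spec.min_xy_px, mode=lateral_mode)
    if m == 1:
        return ProbabilityVolume(name=prob_volume.name, data=lateral,
                                 geometry=prob_volume.geometry)
    # products over each window of m consecutive slices
    n_win = nz - m + 1
    win_prod = lateral[:n_win].copy()
    for k in range(1, m):
        win_prod *= lateral[k:k + n_win]
    out = np.empty_like(lateral)
    for z in range(nz):
        s0 = max(0, z - m + 1)
        s1 = min(z, n_win - 1)
        out[z] = win_prod[s0:s1 + 1].max(axis=0)
    return ProbabilityVolume(name=prob_volume.name, data=out,
                             geometry=prob_volume.geometry)


def _dilate(data: np.ndarray, dz: int, dxy: int) -> np.ndarray:
    if dz == 0 and dxy == 0:
        return data
    return ndimage.maximum_filter(data, size=(2 * dz + 1, 2 * dxy + 1, 2 * dxy + 1),
                                  mode="constant", cval=0.0)


def combine_colocalized(punctum_probs: Sequence[ProbabilityVolume],
                        r_coloc: int = QueryParams.r_coloc) -> ProbabilityVolume:
    """Joint probability that all markers of one subclass co-occupy a site.

    Each punctum map is max-dilated laterally by ``r_coloc`` px before the
    voxelwise product, so puncta that merely share a border still count as
    colocalized.  A single marker passes through unchanged up to dilation.
    """
    if not punctum_probs:
        raise ValueError("combine_colocalized requires at least one punctum map")
    geometry = punctum_probs[0].geometry
    out = np.ones(geometry.shape, dtype=float)
    for pv in punctum_probs:
        if pv.geometry.shape != geometry.shape:
            raise ValueError("punctum maps must share one grid")
        out *= _dilate(pv.data, 0, r_coloc)
    name = "+".join(pv.name for pv in punctum_probs)
    return ProbabilityVolume(name=name, data=out, geometry=geometry)


def combine_adjacent(pre: ProbabilityVolume, post: ProbabilityVolume,
                     astro: ProbabilityVolume | None = None,
                     a_xy: int = QueryParams.a_xy,
                     a_z: int = QueryParams.a_z) -> ProbabilityVolume:
    """Synapse probability from juxtaposed subclass maps.

    q(x) = pre(x) · maxN(post)(x) [· maxN(astro)(x)] where maxN is the max
    over the adjacency neighborhood (±a_xy px laterally, ±a_z slices).
    Zero offset is allowed — puncta may share a small proportion of pixels.
    """
    q = pre.data * _dilate(post.data, a_z, a_xy)
    name = f"{pre.name}|{post.name}"
    if astro is not None:
        q = q * _dilate(astro.data, a_z, a_xy)
        name += f"|{astro.name}"
    return ProbabilityVolume(name=name, data=q, geometry=pre.geometry)


def evaluate_query(prob_channels: dict[str, ProbabilityVolume], query: Query,
                   params: QueryParams = QueryParams()) -> ProbabilityVolume:
    """Evaluate a full query: punctum evidence → colocalization → adjacency.

    ``prob_channels`` maps channel names to foreground-probability volumes.
    The output lives on the same grid with values in [0, 1]; the value at a
    voxel is the probability a synapse matching the query is centered there.
    """
    missing = [c for c in query.channels if c not in prob_channels]
    if missing:
        raise KeyError(f"query {query.name!r} needs channels not provided: {missing}")

    def subclass_map(specs: Sequence[MarkerSpec]) -> ProbabilityVolume:
        puncta = [punctum_probability(prob_channels[m.channel], m,
                                      min_slices=query.required_span,
                                      lateral_mode=params.lateral_mode)
                  for m in specs]
        return combine_colocalized(puncta, r_coloc=params.r_coloc)

    pre = subclass_map(query.presynaptic)
    post = subclass_map(query.postsynaptic)
    astro = subclass_map([query.astrocyte]) if query.astrocyte else None
    result = combine_adjacent(pre, post, astro, a_xy=params.a_xy, a_z=params.a_z)
    return ProbabilityVolume(name=query.name, data=result.data,
                             geometry=result.geometry)
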