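"""Calibrated serial-section volumes and file I/O.

Array tomography produces, for each immunofluorescent channel, a stack of
images of ultrathin (here 70 nm) physical sections.  Stacks from all
channels live on one voxel grid, indexed ``(slice, row, col)`` with 0-based
indices; physical coordinates are voxel-center micrometres.  This module
holds the calibration data model plus readers and writers for image stacks
(TIFF), the pipeline configuration (YAML), and detection tables (CSV).
Registration and alignment across staining rounds are assumed done
upstream; readers only validate congruent shapes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("synquery")

#: Default lateral pixel pitch, µm per pixel.
DEFAULT_PIXEL_SIZE_XY = 0.1
#: Default physical section thickness, µm.
DEFAULT_SLICE_THICKNESS = 0.07
#: Default probability threshold applied to query output maps.
DEFAULT_PROBABILITY_THRESHOLD = 0.9
#: Default threshold on DAPI foreground probability for nuclei.
DEFAULT_DAPI_THRESHOLD = 0.6
#: Default minimum lateral punctum footprint, pixels per side.
DEFAULT_MIN_XY_PX = 2


class FormatError(ValueError):
    """Raised when an input stack or table violates the expected format."""


class ConfigError(ValueError):
    """Raised when the configuration file is inconsistent."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical calibration of a serial-section volume.

    Parameters
    ----------
    n_slices, height_px, width_px
        Grid extents: number of physical sections, image rows and columns.
    pixel_size_xy
        Lateral pixel pitch in µm (isotropic in-plane).
    slice_thickness
        Physical section thickness in µm.
    """

    n_slices: int
    height_px: int
    width_px: int
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_XY
    slice_thickness: float = DEFAULT_SLICE_THICKNESS

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size_xy and slice_thickness must be > 0")
        if min(self.n_slices, self.height_px, self.width_px) < 1:
            raise ValueError("all grid extents must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.height_px, self.width_px)

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        return self.pixel_size_xy**2 * self.slice_thickness

    @property
    def total_volume_um3(self) -> float:
        """Physical volume of the full grid in µm³."""
        return float(np.prod(self.shape)) * self.voxel_volume_um3

    def px_to_um(self, zrc: Sequence[float]) -> tuple[float, float, float]:
        """Convert a (slice, row, col) position to voxel-center µm."""
        z, r, c = zrc
        return (
            float(z) * self.slice_thickness,
            float(r) * self.pixel_size_xy,
            float(c) * self.pixel_size_xy,
        )


@dataclass
class ChannelVolume:
    """One immunofluorescent channel on the common grid.

    ``data`` is a 3-D array of nonnegative intensities indexed
    ``(slice, row, col)``; ``geometry`` carries the physical calibration.
    """

    name: str
    data: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"channel {self.name!r}: data must be 3-D")
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"channel {self.name!r}: data shape {self.data.shape} does not "
                f"match geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError(f"channel {self.name!r}: intensities must be finite and >= 0")


@dataclass(frozen=True)
class LayerPartition:
    """Split of the image rows into named cortical-layer subvolumes.

    ``boundaries`` are strictly increasing interior row offsets; layer *i*
    owns rows ``[b_{i-1}, b_i)`` (half-open), with ``b_-1 = 0`` and
    ``b_last = height_px``.  Layer assignment of anatomical boundaries is a
    user decision; the partition is supplied, not inferred.
    """

    names: tuple[str, ...]
    boundaries: tuple[int, ...]
    height_px: int

    def __post_init__(self) -> None:
        if len(self.names) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more layer name than boundaries")
        b = list(self.boundaries)
        if b != sorted(set(b)):
            raise ValueError("boundaries must be strictly increasing")
        if b and (b[0] <= 0 or b[-1] >= self.height_px):
            raise ValueError("boundaries must lie strictly inside the image height")

    @property
    def edges(self) -> tuple[int, ...]:
        return (0, *self.boundaries, self.height_px)

    def layer_of_row(self, row: float) -> str:
        idx = int(np.searchsorted(self.boundaries, row, side="right"))
        return self.names[idx]

    def row_slices(self) -> dict[str, slice]:
        e = self.edges
        return {n: slice(e[i], e[i + 1]) for i, n in enumerate(self.names)}


# ---------------------------------------------------------------------------
# Image stack I/O
# ---------------------------------------------------------------------------

def read_channel_stack(path: str | os.PathLike, name: str,
                       geometry: AcquisitionGeometry | None = None,
                       pixel_size_xy: float = DEFAULT_PIXEL_SIZE_XY,
                       slice_thickness: float = DEFAULT_SLICE_THICKNESS) -> ChannelVolume:
    """Read one channel from a multi-page TIFF or a directory of slice TIFFs.

    A directory is read in lexicographic filename order, which must equal
    slice order.  All slices must share one shape; intensities are preserved
    bit-exact.  If ``geometry`` is omitted it is built from the stack shape
    and the supplied calibration.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF slices found in directory {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"slice shapes differ in {path}: {sorted(shapes)}")
        if any(s.ndim != 2 for s in slices):
            raise FormatError(f"per-slice TIFFs in {path} must be 2-D grayscale")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a grayscale stack, got shape {data.shape}")
    if geometry is None:
        geometry = AcquisitionGeometry(
            n_slices=data.shape[0], height_px=data.shape[1], width_px=data.shape[2],
            pixel_size_xy=pixel_size_xy, slice_thickness=slice_thickness)
    elif data.shape != geometry.shape:
        raise FormatError(
            f"{path}: stack shape {data.shape} does not match declared geometry "
            f"{geometry.shape}")
    return ChannelVolume(name=name, data=data, geometry=geometry)


def write_channel_stack(channel: ChannelVolume, path: str | os.PathLike) -> None:
    """Write a channel as a multi-page grayscale TIFF (bit-exact round trip)."""
    tifffile.imwrite(Path(path), channel.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything ``load_config`` resolves from one YAML file."""

    geometry: AcquisitionGeometry
    channel_paths: dict[str, str]
    queries: list  # list[Query]; type lives in query_engine to avoid a cycle
    layers: LayerPartition | None
    probability_threshold: float = DEFAULT_PROBABILITY_THRESHOLD
    dapi_threshold: float = DEFAULT_DAPI_THRESHOLD
    min_xy_px: int = DEFAULT_MIN_XY_PX
    stats: dict = field(default_factory=dict)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse and validate a pipeline YAML configuration.

    The file declares channels (name → stack path), acquisition geometry,
    the synapse-type queries (mirroring the catalog's column names:
    presynaptic / postsynaptic / astrocyte markers, per-marker minimum
    slice spans and lateral footprint), optional layer boundaries, and
    thresholds.  Missing thresholds fall back to the defaults (probability
    0.9, DAPI 0.6, minimum footprint 2×2 px), which are echoed to the log.
    """
    from .query_engine import MarkerSpec, Query  # late import, avoids cycle

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    geo = raw.get("geometry", {})
    try:
        geometry = AcquisitionGeometry(
            n_slices=int(geo["n_slices"]),
            height_px=int(geo["height_px"]),
            width_px=int(geo["width_px"]),
            pixel_size_xy=float(geo.get("pixel_size_xy", DEFAULT_PIXEL_SIZE_XY)),
            slice_thickness=float(geo.get("slice_thickness", DEFAULT_SLICE_THICKNESS)),
        )
    except KeyError as exc:
        raise ConfigError(f"geometry section missing key {exc}") from None

    channels = dict(raw.get("channels", {}))
    if not channels:
        raise ConfigError("config declares no channels")

    thresholds = raw.get("thresholds", {})
    prob_thr = float(thresholds.get("probability", DEFAULT_PROBABILITY_THRESHOLD))
    dapi_thr = float(thresholds.get("dapi", DEFAULT_DAPI_THRESHOLD))
    min_xy = int(thresholds.get("min_xy_px", DEFAULT_MIN_XY_PX))

    def _specs(names, spans: Mapping[str, int], default_span: int) -> list[MarkerSpec]:
        return [MarkerSpec(channel=n, min_xy_px=min_xy,
                           min_slices=spans.get(n)) for n in names]

    queries = []
    for q in raw.get("queries", []):
        name = q["name"]
        spans = q.get("min_slices", {}) or {}
        pre = q.get("presynaptic", [])
        post = q.get("postsynaptic", [])
        astro_name = q.get("astrocyte")
        for marker in [*pre, *post, *([astro_name] if astro_name else [])]:
            if marker not in channels:
                raise ConfigError(
                    f"query {name!r} references channel {marker!r} which is not "
                    f"declared under 'channels'")
        required_span = int(q.get("required_span", 1))
        query = Query(
            name=name,
            presynaptic=_specs(pre, spans, required_span),
            postsynaptic=_specs(post, spans, required_span),
            astrocyte=(_specs([astro_name], spans, required_span)[0]
                       if astro_name else None),
            required_span=required_span,
        )
        queries.append(query)

    layers = None
    if "layers" in raw and raw["layers"]:
        lr = raw["layers"]
        layers = LayerPartition(names=tuple(lr["names"]),
                                boundaries=tuple(int(b) for b in lr.get("boundaries", [])),
                                height_px=geometry.height_px)

    cfg = PipelineConfig(geometry=geometry, channel_paths=channels,
                         queries=queries, layers=layers,
                         probability_threshold=prob_thr, dapi_threshold=dapi_thr,
                         min_xy_px=min_xy, stats=dict(raw.get("stats", {})))
    logger.info(
        "loaded config %s: %d channels, %d queries, probability threshold %.2f, "
        "DAPI threshold %.2f, min punctum %dx%d px",
        path, len(channels), len(queries), prob_thr, dapi_thr, min_xy, min_xy)
    return cfg


# ---------------------------------------------------------------------------
# Detection tables
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = [
    "id", "query", "z_px", "row_px", "col_px", "z_um", "row_um", "col_um",
    "n_voxels", "marker_spans", "layer", "astrocyte_associated",
]


def detections_to_frame(detections: Sequence) -> pd.DataFrame:
    """Tabulate DetectionRecords, ordered by centroid (slice, row, col)."""
    rows = []
    for d in detections:
        z, r, c = d.centroid_px
        zu, ru, cu = d.centroid_um
        spans = ";".join(f"{k}={v}" for k, v in sorted(d.marker_spans.items()))
        rows.append({
            "id": d.id, "query": d.query_name,
            "z_px": z, "row_px": r, "col_px": c,
            "z_um": zu, "row_um": ru, "col_um": cu,
            "n_voxels": d.n_voxels, "marker_spans": spans,
            "layer": d.layer if d.layer is not None else "",
            "astrocyte_associated": bool(d.astrocyte_associated),
        })
    frame = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["z_px", "row_px", "col_px"], kind="stable")
        frame = frame.reset_index(drop=True)
    return frame


def write_detection_table(detections: Sequence, path: str | os.PathLike) -> None:
    """Write detections as CSV: one row per called synapse, header always."""
    detections_to_frame(detections).to_csv(path, index=False)


def read_detection_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, dtype={"layer": str},
                       float_precision="round_trip",
                       converters={"astrocyte_associated": lambda s: s == "True"})
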