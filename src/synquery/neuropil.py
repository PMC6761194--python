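"""Neuropil volume from DAPI nuclei exclusion.

Synapse densities use the neuropil — the imaged tissue minus cell nuclei —
as denominator, since nuclear volume varies between fields and contains no
synapses.  The DAPI channel is converted to foreground probability,
thresholded (t = 0.6 by default), and cleaned by a short morphological
sequence: per-slice binary closing and hole filling, then removal of small
3-D components.  The neuropil volume is the total imaged volume minus the
nuclear volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .geometry_io import DEFAULT_DAPI_THRESHOLD, ChannelVolume
from .probability import estimate_background, foreground_probability

logger = logging.getLogger("synquery")


@dataclass
class NeuropilMask:
    """Binary neuropil mask plus the associated volumes (µm³)."""

    mask: np.ndarray  # True = neuropil
    nuclei_volume_um3: float
    neuropil_volume_um3: float
    total_volume_um3: float

    def __post_init__(self) -> None:
        if self.nuclei_volume_um3 < 0 or self.neuropil_volume_um3 < 0:
            raise ValueError("volumes must be >= 0")


def nuclei_mask(dapi: ChannelVolume, threshold: float = DEFAULT_DAPI_THRESHOLD,
                closing_radius: int = 2, min_size_voxels: int = 200,
                scope: str = "slice", robust: bool = True) -> NeuropilMask:
    """Segment DAPI nuclei and report neuropil / nuclear volumes.

    Steps: foreground probability of the DAPI channel; threshold at
    ``threshold``; per-slice morphological cleanup with a disk of
    ``closing_radius`` px — opening (the low threshold admits isolated
    supra-threshold background pixels, which opening erases while the
    solid nuclei survive), then closing and hole filling — and removal of
    3-D components smaller than ``min_size_voxels``.  Because the
    probability map is built from a background model re-estimated from the
    data, the mask is invariant to uniform intensity offsets.
    """
    data = dapi.data
    if data.max() == data.min():
        # exactly constant channel: a dark frame has no nuclei, a saturated
        # one is all nuclei — foreground probability cannot tell them apart
        if data.max() > 0:
            logger.warning("DAPI channel is saturated; neuropil volume is 0")
            nuclei = np.ones(data.shape, dtype=bool)
        else:
            nuclei = np.zeros(data.shape, dtype=bool)
        total = dapi.geometry.total_volume_um3
        nuc = float(nuclei.sum()) * dapi.geometry.voxel_volume_um3
        return NeuropilMask(mask=~nuclei, nuclei_volume_um3=nuc,
                            neuropil_volume_um3=total - nuc,
                            total_volume_um3=total)
    prob = foreground_probability(dapi, estimate_background(dapi, scope, robust))
    nuclei = prob.data >= threshold
    if closing_radius > 0:
        disk = morphology.disk(closing_radius)
        for z in range(nuclei.shape[0]):
            plane = ndimage.binary_opening(nuclei[z], structure=disk)
            plane = ndimage.binary_closing(plane, structure=disk)
            nuclei[z] = ndimage.binary_fill_holes(plane)
    if min_size_voxels > 0 and nuclei.any():
        labels, _ = ndimage.label(nuclei, structure=np.ones((3, 3, 3), bool))
        counts = np.bincount(labels.ravel())
        counts[0] = min_size_voxels  # background is never removed by size
        nuclei &= (counts >= min_size_voxels)[labels]
    voxel = dapi.geometry.voxel_volume_um3
    total = dapi.geometry.total_volume_um3
    nuc_vol = float(nuclei.sum()) * voxel
    neuropil_vol = total - nuc_vol
    if neuropil_vol <= 0:
        logger.warning("DAPI mask covers the entire volume; neuropil volume is 0")
    return NeuropilMask(mask=~nuclei, nuclei_volume_um3=nuc_vol,
                        neuropil_volume_um3=neuropil_vol, total_volume_um3=total)
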