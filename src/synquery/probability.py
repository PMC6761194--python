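"""Foreground-probability maps under a Gaussian background model.

Immunofluorescent array-tomography channels are mostly unlabeled background
whose intensity is well described by a Gaussian; puncta are sparse bright
outliers.  Each channel is converted to probability space by estimating the
background mean and spread from the data itself and mapping every voxel
intensity I to p_fg = Φ((I − µ)/σ), the standard normal CDF — one minus the
probability that the voxel belongs to the background's upper tail.  The map
is monotone in intensity and bounded in [0, 1].

Background statistics default to robust estimates (median and scaled MAD)
so that the sparse bright foreground does not inflate the scale; plain
moments are available for comparison.  Scope is per-slice by default since
staining efficiency varies from section to section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .geometry_io import AcquisitionGeometry, ChannelVolume

#: Consistency factor making the MAD of a normal sample estimate sigma.
_MAD_TO_SIGMA = 1.4826022185056018


@dataclass(frozen=True)
class BackgroundModel:
    """Gaussian background fit for one channel.

    ``mean`` and ``std`` have one entry per slice when ``scope`` is
    ``"slice"``, or length 1 when ``scope`` is ``"volume"``.
    """

    mean: np.ndarray
    std: np.ndarray
    scope: str  # "slice" | "volume"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        object.__setattr__(self, "std", np.atleast_1d(np.asarray(self.std, float)))
        if self.scope not in ("slice", "volume"):
            raise ValueError("scope must be 'slice' or 'volume'")
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have equal length")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.std))):
            raise ValueError("background estimates must be finite")
        if np.any(self.std < 0):
            raise ValueError("std must be >= 0")

    def per_slice(self, n_slices: int) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast to one (mean, std) pair per slice."""
        if self.scope == "volume":
            return (np.full(n_slices, self.mean[0]), np.full(n_slices, self.std[0]))
        if len(self.mean) != n_slices:
            raise ValueError("per-slice model length does not match stack depth")
        return self.mean, self.std


@dataclass
class ProbabilityVolume:
    """Per-voxel foreground (or query) probability on the channel grid."""

    name: str
    data: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"probability volume {self.name!r}: shape {self.data.shape} does "
                f"not match geometry {self.geometry.shape}")
        if self.data.size and (self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12):
            raise ValueError(f"probability volume {self.name!r}: values outside [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)


def _estimate_one(values: np.ndarray, robust: bool) -> tuple[float, float]:
    if robust:
        med = float(np.median(values))
        mad = float(stats.median_abs_deviation(values, axis=None, scale=1.0))
        return med, _MAD_TO_SIGMA * mad
    return float(np.mean(values)), float(np.std(values))


def estimate_background(channel: ChannelVolume, scope: str = "slice",
                        robust: bool = True) -> BackgroundModel:
    """Estimate the Gaussian background of one channel.

    Parameters
    ----------
    scope
        ``"slice"`` fits one (mean, std) per section, absorbing
        section-to-section staining variability; ``"volume"`` fits a single
        pair from all voxels.
    robust
        Use median / scaled MAD (default) so sparse bright puncta do not
        bias the fit; ``False`` uses plain sample moments.

    An all-constant slice yields std 0, a sentinel handled by
    :func:`foreground_probability`.
    """
    data = channel.data
    if data.size == 0:
        raise ValueError("channel is empty")
    if scope == "volume":
        mean, std = _estimate_one(data, robust)
        return BackgroundModel(mean=[mean], std=[std], scope="volume")
    if scope != "slice":
        raise ValueError("scope must be 'slice' or 'volume'")
    pairs = [_estimate_one(data[z], robust) for z in range(data.shape[0])]
    means, stds = zip(*pairs)
    return BackgroundModel(mean=list(means), std=list(stds), scope="slice")


def foreground_probability(channel: ChannelVolume,
                           background: BackgroundModel) -> ProbabilityVolume:
    """Map intensities to foreground probability p = Φ((I − µ)/σ).

    With σ = 0 (degenerate background) the rule collapses to a hard
    threshold: p = 1 where I > µ, else 0.
    """
    nz = channel.geometry.n_slices
    means, stds = background.per_slice(nz)
    out = np.empty(channel.data.shape, dtype=float)
    for z in range(nz):
        plane = channel.data[z].astype(float)
        if stds[z] == 0.0:
            out[z] = (plane > means[z]).astype(float)
        else:
            out[z] = special.ndtr((plane - means[z]) / stds[z])
    return ProbabilityVolume(name=channel.name, data=out, geometry=channel.geometry)


def channel_probabilities(channels: dict[str, ChannelVolume], scope: str = "slice",
                          robust: bool = True) -> dict[str, ProbabilityVolume]:
    """Convenience: foreground probability for every channel in a mapping."""
    return {name: foreground_probability(ch, estimate_background(ch, scope, robust))
            for name, ch in channels.items()}
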