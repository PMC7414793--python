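"""Marker-channel masking and compartment partition.

Microglia carry a genetically encoded (CX3CR1-GFP) or immunolabel
(Iba1 / AlexaFluor 594) marker imaged in a separate channel that is
co-registered with the NADH FLIM acquisition.  The marker intensity
image is thresholded into a microglial mask; the remaining pixels are
split into non-microglial cells (NADH-bright but marker-dark) and
background, so FLIM parameters can be averaged per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components
from skimage.morphology import disk

from .decay_model import DomainError, GridMismatchError

__all__ = [
    "MarkerImage",
    "CompartmentMask",
    "DegenerateMarkerError",
    "BACKGROUND",
    "NON_MICROGLIA",
    "MICROGLIA",
    "mask_from_marker",
    "build_compartments",
]

# Label codes, shared with the 8-bit TIFF mask format.
BACKGROUND = 0
NON_MICROGLIA = 1
MICROGLIA = 2


class DegenerateMarkerError(ValueError):
    """Otsu thresholding is undefined on a constant marker image."""


@dataclass(frozen=True)
class MarkerImage:
    """Co-registered marker-intensity image identifying microglia."""

    intensity: np.ndarray
    channel_label: str = "GFP"  # {"GFP", "A594", "other"}

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.ndim != 2:
            raise DomainError("marker image must be two-dimensional")
        if np.any(intensity < 0):
            raise DomainError("marker intensity must be non-negative")
        object.__setattr__(self, "intensity", intensity)
        if self.channel_label not in ("GFP", "A594", "other"):
            raise DomainError(f"unknown channel label {self.channel_label!r}")


@dataclass(frozen=True)
class CompartmentMask:
    """Per-pixel partition into microglia / non-microglia / background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise DomainError("compartment labels must be two-dimensional")
        if not np.isin(labels, (BACKGROUND, NON_MICROGLIA, MICROGLIA)).all():
            raise DomainError("labels must be 0 (background), 1 (non-microglia) or 2 (microglia)")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def microglia(self) -> np.ndarray:
        return self.labels == MICROGLIA

    @property
    def non_microglia(self) -> np.ndarray:
        return self.labels == NON_MICROGLIA

    @property
    def background(self) -> np.ndarray:
        return self.labels == BACKGROUND


def mask_from_marker(
    marker: MarkerImage | np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_region_px: int = 20,
    dilate_px: int = 0,
) -> np.ndarray:
    """Boolean microglia mask from the marker-intensity image.

    ``method='otsu'`` picks the threshold automatically (parameter-free
    and reproducible); ``method='fixed'`` uses ``fixed_threshold``.
    Connected components smaller than ``min_region_px`` are removed as
    noise specks.  ``dilate_px`` optionally grows the mask by that radius
    (off by default).
    """
    intensity = marker.intensity if isinstance(marker, MarkerImage) else np.asarray(marker, dtype=float)
    if intensity.size == 0:
        raise DomainError("marker image is empty")
    if method == "otsu":
        if np.ptp(intensity) == 0:
            raise DegenerateMarkerError(
                "marker image is constant; Otsu threshold undefined — "
                "use method='fixed' with an explicit threshold"
            )
        threshold = threshold_otsu(intensity)
    elif method == "fixed":
        if fixed_threshold is None:
            raise DomainError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise DomainError(f"unknown masking method {method!r}")
    mask = intensity > threshold
    if min_region_px > 1 and mask.any():
        comps = label_components(mask, connectivity=2)
        sizes = np.bincount(comps.ravel())
        keep = sizes >= min_region_px
        keep[0] = False
        mask = keep[comps]
    if dilate_px > 0:
        mask = binary_dilation(mask, disk(dilate_px))
    return mask


def build_compartments(
    microglia_mask: np.ndarray,
    nadh_photons: np.ndarray,
    cell_threshold: float,
) -> CompartmentMask:
    """Partition the image into the three analysis compartments.

    Microglia are the marker mask; non-microglia are NADH-bright cellular
    pixels lacking the marker (``nadh_photons >= cell_threshold``); the
    remainder is background.  ``nadh_photons`` should be the (unbinned)
    NADH intensity image so that spill-over from spatial binning does not
    recruit background pixels into the cellular compartments.
    """
    microglia_mask = np.asarray(microglia_mask, dtype=bool)
    nadh_photons = np.asarray(nadh_photons, dtype=float)
    if microglia_mask.shape != nadh_photons.shape:
        raise GridMismatchError(
            f"mask shape {microglia_mask.shape} != photon image shape {nadh_photons.shape}"
        )
    labels = np.zeros(microglia_mask.shape, dtype=np.uint8)
    labels[(~microglia_mask) & (nadh_photons >= cell_threshold)] = NON_MICROGLIA
    labels[microglia_mask] = MICROGLIA
    return CompartmentMask(labels=labels)
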