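"""3D FISH image quantification.

Implements the measurements behind chromosome-paint FISH: intensity-threshold
masks, percent nuclear volume occupied by a chromosome territory (territory
voxels divided by DAPI-mask voxels), connected-component spot detection, and
closest-pair 3D distances between two probe channels in physical micrometres.

Conventions
-----------
* Image data are ``(C, Z, Y, X)`` arrays; ``voxel_size`` is µm per axis in
  ``(z, y, x)`` order and may be anisotropic.
* A mask is "voxels strictly above the threshold"; the threshold used is
  recorded on the mask for provenance.
* Physical coordinates are voxel-center based: voxel index ``i`` sits at
  ``(i + 0.5) * voxel_size``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

ThresholdMethod = "otsu | ('fixed', value) | ('fraction_of_max', f)"


@dataclass
class ImageStack:
    """Multi-channel anisotropic 3D stack with physical voxel size."""

    data: np.ndarray  # (C, Z, Y, X) float32
    voxel_size: tuple[float, float, float]  # µm, (z, y, x)
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("number of channel names must match data")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel size {self.voxel_size}")
        self.channels = tuple(self.channels)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None
        return self.data[idx]

    # -- IO (multi-page TIFF; metadata in the image description) -----------

    def save_tiff(self, path) -> None:
        import tifffile

        meta = {"voxel_size_zyx_um": list(self.voxel_size), "channels": list(self.channels)}
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            description=json.dumps(meta),
            photometric="minisblack",
        )

    @classmethod
    def load_tiff(cls, path, voxel_size=None, channels=None) -> "ImageStack":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if data.ndim == 3:
            data = data[None]
        vs = tuple(voxel_size or meta.get("voxel_size_zyx_um", (1.0, 1.0, 1.0)))
        ch = tuple(channels or meta.get("channels", [f"ch{i}" for i in range(data.shape[0])]))
        return cls(data=np.asarray(data, dtype=np.float32), voxel_size=vs, channels=ch)


@dataclass
class VoxelMask:
    """Boolean 3D mask with the threshold that produced it."""

    mask: np.ndarray
    channel: str
    threshold: float
    voxel_size: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _resolve_threshold(values: np.ndarray, method) -> float:
    if method == "otsu" or method == ("otsu",):
        if np.ptp(values) == 0:
            # degenerate flat histogram: put the threshold just below the value
            return float(values.flat[0]) - 1.0
        return float(threshold_otsu(values))
    if isinstance(method, (tuple, list)) and len(method) == 2:
        kind, arg = method
        if kind == "fixed":
            if not np.isfinite(arg):
                raise ValueError(f"fixed threshold must be finite, got {arg}")
            return float(arg)
        if kind == "fraction_of_max":
            if not 0 < arg < 1:
                raise ValueError(f"fraction_of_max must be in (0,1), got {arg}")
            return float(arg) * float(values.max())
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_mask(stack: ImageStack, channel: str, method="otsu", within: VoxelMask | None = None) -> VoxelMask:
    """Mask of voxels strictly above an intensity threshold.

    ``within`` restricts the histogram used to *derive* the threshold (e.g.
    Otsu on the paint channel inside the DAPI mask); the mask itself is
    evaluated on the full grid.  An empty result is a warning, not an error.
    """
    img = stack.channel(channel)
    values = img[within.mask] if within is not None else img.ravel()
    if values.size == 0:
        raise ValueError("threshold region is empty")
    thr = _resolve_threshold(values, method)
    mask = img > thr
    if not mask.any():
        log.warning("threshold_mask: empty mask for channel %r (threshold %.4g)", channel, thr)
    return VoxelMask(mask=mask, channel=channel, threshold=thr, voxel_size=stack.voxel_size)


def percent_volume(territory: VoxelMask, nucleus: VoxelMask) -> float:
    """Percent of nucleus voxels covered by the territory mask.

    The territory is intersected with the nucleus mask, which keeps the ratio
    at or below 100% even if paint signal bleeds outside the DAPI mask.
    """
    if territory.mask.shape != nucleus.mask.shape:
        raise ValueError("territory and nucleus masks must share a grid")
    if territory.voxel_size != nucleus.voxel_size:
        raise ValueError("territory and nucleus masks must share a voxel size")
    n = nucleus.n_voxels
    if n == 0:
        raise ValueError("nucleus mask is empty")
    overlap = int(np.logical_and(territory.mask, nucleus.mask).sum())
    return 100.0 * overlap / n


def summarize_volumes(measurements: pd.DataFrame, group_by="group") -> pd.DataFrame:
    """Per-group mean / sd / n of percent nuclear volume.

    ``measurements`` needs a ``percent`` column plus the grouping columns.
    Sample standard deviation (ddof=1); a single measurement reports sd 0.
    When grouping by embryo with a ``stage`` column present, rows come back
    ordered by cell stage, giving the embryo time-course series.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if measurements.empty:
        raise ValueError("no measurements to summarize")
    grouped = measurements.groupby(list(group_by), sort=True)["percent"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
    out = out.reset_index()
    if "stage" in measurements.columns and "stage" not in group_by:
        stage = measurements.groupby(list(group_by), sort=True)["stage"].first().reset_index(drop=True)
        out = out.assign(stage=stage).sort_values("stage", kind="stable").reset_index(drop=True)
    return out


# -- spots -----------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def detect_spots(stack: ImageStack, channel: str, method=("fraction_of_max", 0.25), min_voxels: int = 2) -> np.ndarray:
    """Intensity-weighted centroids (µm, (z,y,x)) of above-threshold components.

    Connected components use 26-connectivity; components smaller than
    ``min_voxels`` are treated as noise and dropped.  Returns an (n, 3) array;
    empty when nothing is found (logged).
    """
    img = stack.channel(channel)
    mask = threshold_mask(stack, channel, method).mask
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        log.info("detect_spots: no spots in channel %r", channel)
        return np.empty((0, 3))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    if keep.size == 0:
        log.info("detect_spots: all %d components below %d voxels", n, min_voxels)
        return np.empty((0, 3))
    coms = ndimage.center_of_mass(img, labels, index=keep)
    vs = np.asarray(stack.voxel_size)
    return (np.asarray(coms) + 0.5) * vs


def pair_spot_distances(spots_a: np.ndarray, spots_b: np.ndarray, nucleus_id=None) -> pd.DataFrame:
    """Closest-pair matching of two spot sets (µm coordinates).

    Pairs each A spot with a distinct B spot by minimum-total-distance
    assignment (equivalently: each probe signal with the separate spot closest
    to it, resolved globally when several homolog pairs are present).  In
    tetraploid nuclei the two homolog pairs therefore each contribute their
    within-pair distance.  Unmatched leftovers are logged.
    """
    from scipy.optimize import linear_sum_assignment

    a = np.atleast_2d(np.asarray(spots_a, dtype=float))
    b = np.atleast_2d(np.asarray(spots_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both spot lists must be non-empty")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    ai, bj = linear_sum_assignment(d)
    rows = [
        {
            "nucleus_id": nucleus_id,
            "a_index": int(i),
            "b_index": int(j),
            "distance_um": float(d[i, j]),
        }
        for i, j in zip(ai, bj)
    ]
    leftover = abs(len(a) - len(b))
    if leftover:
        log.info("pair_spot_distances: %d unmatched spot(s)", leftover)
    return pd.DataFrame(rows)
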