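"""Per-frame 3D chromatin segmentation from the histone channel.

Pipeline: 3D median filter → 3D Gaussian filter → locally adaptive
(local-mean) threshold → border/size cleanup → 26-connected labeling.
Filtering is for detection only; downstream quantification reads raw
voxels through the resulting label volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import regionprops


def preprocess_volume(volume: np.ndarray, median_size=3, gauss_sigma=1.0) -> np.ndarray:
    """Median then Gaussian filter a single-channel 3D volume.

    ``median_size`` is the median window in voxels per axis (scalar or
    3-tuple); ``gauss_sigma`` the Gaussian SD in voxels per axis.
    Boundaries are handled by reflection. Shape is preserved.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    out = ndimage.median_filter(volume, size=median_size, mode="reflect")
    out = ndimage.gaussian_filter(out, sigma=gauss_sigma, mode="reflect")
    return out


def adaptive_threshold(volume: np.ndarray, block_size=15, offset: float = 0.0) -> np.ndarray:
    """Locally adaptive threshold: foreground iff intensity exceeds the
    local mean over an odd ``block_size`` window by more than ``offset``.

    A positive offset suppresses flat background (a constant volume maps
    to all-background), and increasing it only removes foreground voxels.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    block = np.broadcast_to(np.asarray(block_size), (3,)).astype(int)
    if np.any(block < 3) or np.any(block % 2 == 0):
        raise ValueError("block_size must be odd and >= 3 on every axis")
    if np.any(block > np.asarray(volume.shape)):
        raise ValueError("block_size exceeds volume shape")
    local_mean = ndimage.uniform_filter(volume, size=tuple(block), mode="reflect")
    return volume > (local_mean + offset)


def clean_mask(mask: np.ndarray, min_size: int = 0, max_size: int | None = None,
               clear_border: tuple[str, ...] = ("y", "x")) -> np.ndarray:
    """Remove border-touching components and size outliers.

    Components touching any border named in ``clear_border`` (subset of
    ``{"z", "y", "x"}``; by default only the lateral borders, since z
    truncation is physical) are removed, then components with volume
    outside ``[min_size, max_size]`` voxels are removed. Idempotent.
    """
    mask = np.asarray(mask).astype(bool)
    if max_size is None:
        max_size = mask.size
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    axis_index = {"z": 0, "y": 1, "x": 2} if mask.ndim == 3 else {"y": 0, "x": 1}
    bad = set(clear_border) - set(axis_index)
    if bad:
        raise ValueError(f"unknown border axes {sorted(bad)} for ndim={mask.ndim}")
    connectivity = mask.ndim  # 26-connectivity in 3D, 8 in 2D
    lab = sk_label(mask, connectivity=connectivity)
    keep = np.ones(lab.max() + 1, dtype=bool)
    keep[0] = False
    for ax_name in clear_border:
        ax = axis_index[ax_name]
        for side in (0, -1):
            face = np.take(lab, side, axis=ax)
            keep[np.unique(face[face > 0])] = False
    counts = np.bincount(lab.ravel(), minlength=lab.max() + 1)
    keep &= (counts >= min_size) & (counts <= max_size)
    return keep[lab]


@dataclass
class LabelVolume:
    """Integer label volume for one frame (0 = background), with physical
    calibration so centroids can be reported in µm."""

    labels: np.ndarray
    voxel_size: tuple[float, ...]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def properties(self, intensity: np.ndarray | None = None) -> pd.DataFrame:
        """Per-object table: label, centroid (µm), volume (voxels), and the
        mean of ``intensity`` under each label if given."""
        props = regionprops(self.labels, intensity_image=intensity)
        rows = []
        axis_names = ("z", "y", "x")[-self.labels.ndim:]
        for p in props:
            row = {"label": p.label, "volume_voxels": int(p.area)}
            for name, c, v in zip(axis_names, p.centroid, self.voxel_size):
                row[f"centroid_{name}_um"] = c * v
            if intensity is not None:
                row["mean_intensity"] = float(p.intensity_mean)
            rows.append(row)
        return pd.DataFrame(rows)

    def centroids_um(self) -> np.ndarray:
        """(n_objects, ndim) physical centroids ordered by label."""
        df = self.properties()
        if df.empty:
            return np.zeros((0, self.labels.ndim))
        cols = [f"centroid_{n}_um" for n in ("z", "y", "x")[-self.labels.ndim:]]
        return df.sort_values("label")[cols].to_numpy()


def label_volume(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Label 26-connected (3D) / 8-connected (2D) components 1..K."""
    mask = np.asarray(mask).astype(bool)
    labels = sk_label(mask, connectivity=mask.ndim)
    return LabelVolume(labels=labels.astype(np.int32),
                       voxel_size=tuple(voxel_size[-mask.ndim:]))


def segment_frame(volume: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
                  median_size=3, gauss_sigma=1.0, block_size=15,
                  offset: float = 0.0, min_size: int = 0,
                  max_size: int | None = None,
                  clear_border=("y", "x")) -> LabelVolume:
    """Full per-frame pipeline: filter → threshold → cleanup → label."""
    filtered = preprocess_volume(volume, median_size=median_size,
                                 gauss_sigma=gauss_sigma)
    mask = adaptive_threshold(filtered, block_size=block_size, offset=offset)
    mask = clean_mask(mask, min_size=min_size, max_size=max_size,
                      clear_border=clear_border)
    return label_volume(mask, voxel_size=voxel_size)
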