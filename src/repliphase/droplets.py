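"""Condensate image quantitation, depletion assays, and phase diagrams.

Droplet ROIs are auto-thresholded from the DNA channel; a partner
channel's partition is summarized as the enrichment ratio
``E = mean(inside) / mean(outside)`` with a guard band separating the
two pools (PSF bleed would otherwise bias the outside mean). Depletion
assays reduce gel band intensities to the depleted fraction
``D = 1 − supernatant/load`` and the optional pellet enrichment, and a
(protein, salt) grid of droplet counts assembles into a boolean phase
diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .projection import auto_threshold
from .segment import label_volume


def droplet_rois(dna_image: np.ndarray, method: str = "isodata",
                 min_area: int = 4) -> np.ndarray:
    """Label droplets in a single-channel frame.

    Automatic global threshold (same engine as the chromatin ROI) →
    8-connected components of at least ``min_area`` pixels. A blank
    image yields an empty label set, not an error.
    """
    dna_image = np.asarray(dna_image, dtype=np.float64)
    if dna_image.ndim != 2:
        raise ValueError("expected a single-channel 2D frame")
    if np.ptp(dna_image) == 0:
        return np.zeros(dna_image.shape, dtype=np.int32)
    thr = auto_threshold(dna_image, method=method)
    lv = label_volume(dna_image >= thr, voxel_size=(1.0, 1.0))
    labels = lv.labels
    counts = np.bincount(labels.ravel())
    ok = np.flatnonzero(counts >= min_area)
    ok = ok[ok > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ok, start=1):
        out[labels == old] = new
    return out


@dataclass
class PartitionResult:
    """Inside/outside partition statistics of the partner channel."""

    droplet_count: int
    per_droplet_mean: np.ndarray
    inside_mean: float | None
    outside_mean: float | None
    enrichment: float | None        # E = inside / outside
    enrichment_sd: float            # dispersion of per-droplet ratios (n−1)


def partition_ratio(partner_image: np.ndarray, droplet_labels: np.ndarray,
                    guard_band: int = 2) -> PartitionResult:
    """Partner-channel enrichment inside droplets relative to the bulk.

    ``inside`` pools all labeled pixels; ``outside`` pools unlabeled
    pixels beyond a ``guard_band``-pixel dilation of the labels. With no
    droplets, E is undefined and a count of 0 is returned.
    """
    partner_image = np.asarray(partner_image, dtype=np.float64)
    droplet_labels = np.asarray(droplet_labels)
    if partner_image.shape != droplet_labels.shape:
        raise ValueError("image and labels must share shape")
    n = int(droplet_labels.max())
    if n == 0:
        return PartitionResult(0, np.array([]), None, None, None, 0.0)
    inside_sel = droplet_labels > 0
    excluded = binary_dilation(inside_sel, iterations=guard_band) if guard_band > 0 else inside_sel
    outside_sel = ~excluded
    if not outside_sel.any():
        raise ValueError("no outside pixels beyond the guard band")
    inside_mean = float(partner_image[inside_sel].mean())
    outside_mean = float(partner_image[outside_sel].mean())
    per = np.array([partner_image[droplet_labels == i].mean() for i in range(1, n + 1)])
    ratios = per / outside_mean
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    return PartitionResult(droplet_count=n, per_droplet_mean=per,
                           inside_mean=inside_mean, outside_mean=outside_mean,
                           enrichment=inside_mean / outside_mean,
                           enrichment_sd=sd)


@dataclass
class DepletionResult:
    load: float
    supernatant: float
    depleted_fraction: float        # D = 1 − supernatant/load
    pellet_enrichment: float | None  # pellet / supernatant


def depletion_fraction(load: float, supernatant: float,
                       pellet: float | None = None) -> DepletionResult:
    """Reduce band intensities to depletion statistics.

    D is dimensionless, hence invariant to gel-wide exposure scaling.
    """
    if load <= 0:
        raise ValueError("load intensity must be > 0")
    if supernatant < 0 or (pellet is not None and pellet < 0):
        raise ValueError("intensities must be >= 0")
    d = 1.0 - supernatant / load
    enr = None
    if pellet is not None:
        enr = float("inf") if supernatant == 0 else pellet / supernatant
    return DepletionResult(load=load, supernatant=supernatant,
                           depleted_fraction=d, pellet_enrichment=enr)


@dataclass
class PhaseDiagram:
    """(protein, salt) grid of droplet counts and the phase-separated calls."""

    protein_nM: np.ndarray          # strictly increasing axis
    salt_mM: np.ndarray             # strictly increasing axis
    droplet_counts: np.ndarray      # shape (len(protein), len(salt))
    phase_separated: np.ndarray     # boolean, same shape
    cutoff: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phase_separated,
                            index=pd.Index(self.protein_nM, name="protein_nM"),
                            columns=pd.Index(self.salt_mM, name="salt_mM"))


def build_phase_diagram(conditions, droplet_count_cutoff: int = 1,
                        method: str = "isodata", min_area: int = 4) -> PhaseDiagram:
    """Assemble a phase diagram from a rectangular grid of conditions.

    ``conditions`` is an iterable of ``(protein_nM, salt_mM, value)`` where
    ``value`` is either a droplet count or a DNA-channel image to count
    droplets in. The grid must cover the full rectangle with no duplicate
    condition. ``phase_separated = count >= cutoff``.
    """
    entries = {}
    for protein, salt, value in conditions:
        key = (float(protein), float(salt))
        if key in entries:
            raise ValueError(f"duplicate condition {key}")
        if np.ndim(value) == 2:
            count = int(droplet_rois(value, method=method, min_area=min_area).max())
        else:
            count = int(value)
        entries[key] = count
    proteins = np.array(sorted({p for p, _ in entries}))
    salts = np.array(sorted({s for _, s in entries}))
    counts = np.zeros((len(proteins), len(salts)), dtype=int)
    for i, p in enumerate(proteins):
        for j, s in enumerate(salts):
            if (p, s) not in entries:
                raise ValueError(f"grid is not rectangular: missing ({p}, {s})")
            counts[i, j] = entries[(p, s)]
    return PhaseDiagram(protein_nM=proteins, salt_mM=salts,
                        droplet_counts=counts,
                        phase_separated=counts >= droplet_count_cutoff,
                        cutoff=int(droplet_count_cutoff))
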