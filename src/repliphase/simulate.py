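"""Ground-truth-annotated synthetic inputs for every downstream stage.

Four generators emulate the data the quantification pipelines consume:

* :func:`simulate_mitosis_movie` — two-channel mitosis movies (chromatin
  histone channel + a recruitment channel whose chromosomal enrichment
  factor follows the mitotic phase), with Gaussian PSF blur and
  Poisson + Gaussian camera noise over a calibrated voxel grid.
* :func:`simulate_droplet_field` — two-channel condensate images where a
  DNA channel defines droplets and a partner channel is enriched inside
  them by a known factor.
* :func:`simulate_titration` — Hill-model binding curves.
* :func:`random_sequence` — composition-controlled random sequences.

Each generator returns the rendered data together with a
:class:`GroundTruth` record holding the masks, identities, and true
parameters the pipelines are expected to recover, and is bit-reproducible
for a fixed (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import ImageStack

PHASES = ("metaphase", "anaphase", "telophase", "late_telophase", "interphase")

#: Default per-phase true chromosomal enrichment of the recruitment channel.
#: Loading begins in anaphase and peaks in late telophase.
DEFAULT_ENRICHMENT = {
    "metaphase": 1.0,
    "anaphase": 1.8,
    "telophase": 2.5,
    "late_telophase": 2.7,
    "interphase": 1.5,
}

#: Default mitotic phase schedule in seconds (embryo-like cadence).
DEFAULT_SCHEDULE = [
    ("metaphase", 34.0),
    ("anaphase", 45.0),
    ("telophase", 45.0),
    ("late_telophase", 45.0),
    ("interphase", 57.0),
]


@dataclass
class NoiseModel:
    """Camera noise: Poisson shot noise on expected counts, then additive
    Gaussian read noise. ``enabled=False`` renders the noiseless truth."""

    enabled: bool = True
    poisson_gain: float = 1.0   # photons per count; Poisson applied on counts*gain
    gaussian_sd: float = 2.0    # read-noise SD in counts

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.enabled:
            return expected
        g = self.poisson_gain
        out = rng.poisson(np.clip(expected, 0, None) * g).astype(np.float64) / g
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass
class MovieConfig:
    """Acquisition geometry and biological truth of a synthetic movie.

    Spatial defaults follow lattice-light-sheet-style volumetric
    acquisition: 0.250 µm z-steps over a 25 µm range and 5.67 s between
    stacks. ``enrichment_profile`` maps each phase to the true recruitment
    factor ``f`` (recruitment-channel level inside chromatin = background
    × f) that the downstream pipelines must recover.
    """

    n_nuclei: int = 10
    frame_interval: float = 5.67          # s
    z_step: float = 0.250                 # µm
    z_range: float = 25.0                 # µm
    xy_pixel: float = 0.25                # µm
    shape_xy: tuple[int, int] = (256, 256)
    phase_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [tuple(p) for p in DEFAULT_SCHEDULE])
    enrichment_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENT))
    background_level: float = 100.0       # counts; free parameter (not reported)
    chromatin_amplitude: float = 300.0    # chromatin channel: bg + amp inside mask
    nucleus_radius: float = 2.5           # µm
    cell_radius: float | None = None      # µm; None = cytoplasm fills the field
    dark_level: float = 2.0               # counts outside the cell (camera offset)
    chromatin_z_extent: float | None = None  # µm; override body z semi-axis
    psf_sigma: tuple[float, float, float] = (0.6, 0.25, 0.25)  # µm (z, y, x)
    noise: NoiseModel = field(default_factory=NoiseModel)
    drift: tuple[float, float] = (0.0, 0.0)  # µm/frame (y, x)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not self.phase_schedule:
            raise ValueError("phase_schedule must not be empty")
        for name, dur in self.phase_schedule:
            if name not in PHASES:
                raise ValueError(f"unknown phase {name!r}; expected one of {PHASES}")
            if dur <= 0:
                raise ValueError("phase durations must be > 0")
        for name, f in self.enrichment_profile.items():
            if name not in PHASES:
                raise ValueError(f"unknown phase {name!r} in enrichment_profile")
            if f < 0:
                raise ValueError("enrichment factors must be >= 0")
        if self.z_range / self.z_step < 3:
            raise ValueError("z_range/z_step must yield at least 3 planes")
        if self.frame_interval <= 0 or self.xy_pixel <= 0 or self.z_step <= 0:
            raise ValueError("physical calibration values must be positive")

    @property
    def n_planes(self) -> int:
        return int(round(self.z_range / self.z_step))

    @property
    def n_frames(self) -> int:
        total = sum(d for _, d in self.phase_schedule)
        return max(1, int(round(total / self.frame_interval)))

    def phase_of_time(self, t_seconds: float) -> tuple[str, float]:
        """Phase name and fractional progress in [0, 1) at a given time."""
        acc = 0.0
        for name, dur in self.phase_schedule:
            if t_seconds < acc + dur:
                return name, (t_seconds - acc) / dur
            acc += dur
        name, dur = self.phase_schedule[-1]
        return name, 1.0


@dataclass
class GroundTruth:
    """Truth record accompanying a synthetic image: per-frame masks labeled
    by nucleus identity, the true enrichment factor per (frame, nucleus),
    and the true background level."""

    masks: np.ndarray              # (t, z, y, x) or (t, y, x) integer labels
    true_f: pd.DataFrame           # columns: frame, nucleus_id, true_f
    background: float
    phase_of_frame: list[str] = field(default_factory=list)

    def mask_for(self, frame: int, nucleus_id: int) -> np.ndarray:
        return self.masks[frame] == nucleus_id

    def save(self, directory) -> None:
        """Write masks as integer TIFF plus the truth table as TSV."""
        import tifffile
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / "truth_masks.tif",
                         self.masks.astype(np.uint16), compression="zlib")
        self.true_f.to_csv(d / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# mitosis movies
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, voxel_size, center, semi, axis_angle=0.0):
    """Boolean mask of an ellipsoid whose two in-plane semi-axes are rotated
    by ``axis_angle`` (radians) in the xy plane.

    ``center`` and ``semi`` are (z, y, x) in µm; ``semi`` is ordered
    (z, along-axis, across-axis).
    """
    nz, ny, nx = shape
    dz_vox = max(1, int(math.ceil(semi[0] / voxel_size[0])) + 1)
    r_xy = max(semi[1], semi[2])
    dy_vox = max(1, int(math.ceil(r_xy / voxel_size[1])) + 1)
    dx_vox = max(1, int(math.ceil(r_xy / voxel_size[2])) + 1)
    cz = int(round(center[0] / voxel_size[0]))
    cy = int(round(center[1] / voxel_size[1]))
    cx = int(round(center[2] / voxel_size[2]))
    z0, z1 = max(0, cz - dz_vox), min(nz, cz + dz_vox + 1)
    y0, y1 = max(0, cy - dy_vox), min(ny, cy + dy_vox + 1)
    x0, x1 = max(0, cx - dx_vox), min(nx, cx + dx_vox + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return None, None
    zz = (np.arange(z0, z1) * voxel_size[0] - center[0])[:, None, None]
    yy = (np.arange(y0, y1) * voxel_size[1] - center[1])[None, :, None]
    xx = (np.arange(x0, x1) * voxel_size[2] - center[2])[None, None, :]
    ca, sa = math.cos(axis_angle), math.sin(axis_angle)
    u = ca * xx + sa * yy          # along the division axis
    v = -sa * xx + ca * yy         # across it
    m = (zz / semi[0]) ** 2 + (u / semi[1]) ** 2 + (v / semi[2]) ** 2 <= 1.0
    return m, (slice(z0, z1), slice(y0, y1), slice(x0, x1))


def _nucleus_bodies(phase, progress, radius, angle):
    """Centers (µm offsets along the division axis) and semi-axes
    (z, along-axis, across-axis) of the chromatin bodies in a given phase.

    Metaphase renders one oblate plate (short along the division axis);
    anaphase splits it into two prolate masses that separate; telophase
    and late telophase compact them; interphase decondenses.
    """
    r = radius
    sep_max = 3.0 * r
    if phase == "metaphase":
        return [(0.0, (0.8 * r, 0.45 * r, r))]
    if phase == "anaphase":
        d = (0.3 + 0.7 * progress) * sep_max
        semi = (0.65 * r, 0.75 * r, 0.55 * r)
        return [(-d / 2, semi), (d / 2, semi)]
    if phase == "telophase":
        semi = (0.62 * r, 0.62 * r, 0.62 * r)
        return [(-sep_max / 2, semi), (sep_max / 2, semi)]
    if phase == "late_telophase":
        semi = (0.58 * r, 0.58 * r, 0.58 * r)
        return [(-sep_max / 2, semi), (sep_max / 2, semi)]
    # interphase: decondensed daughters
    semi = (0.85 * r, 0.85 * r, 0.85 * r)
    return [(-sep_max / 2, semi), (sep_max / 2, semi)]


def _place_centers(config: MovieConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus centers inside the field.

    Raises if the requested nuclei cannot fit within the field of view.
    """
    ny, nx = config.shape_xy
    fy, fx = ny * config.xy_pixel, nx * config.xy_pixel
    fz = config.z_range
    r = config.nucleus_radius
    margin = 2.4 * r  # room for anaphase separation and the mask itself
    if fy <= 2 * margin or fx <= 2 * margin:
        raise ValueError("field of view too small for the configured nuclei")
    if fz <= 1.8 * r:
        raise ValueError("z range too small for the configured nuclei")
    min_dist = 4.8 * r
    centers = []
    for _ in range(config.n_nuclei):
        for attempt in range(2000):
            c = np.array([
                fz / 2 + rng.uniform(-0.15, 0.15) * fz,
                rng.uniform(margin, fy - margin),
                rng.uniform(margin, fx - margin),
            ])
            if all(np.hypot(c[1] - o[1], c[2] - o[2]) >= min_dist for o in centers):
                centers.append(c)
                break
        else:
            break
    if len(centers) == config.n_nuclei:
        return centers
    # Dense fields: fall back to a regular lattice with z jitter, the
    # quasi-regular packing of a syncytial blastoderm surface.
    n_y = int((fy - 2 * margin) // min_dist) + 1
    n_x = int((fx - 2 * margin) // min_dist) + 1
    if n_y * n_x < config.n_nuclei:
        raise ValueError(
            f"could not place {config.n_nuclei} non-overlapping nuclei "
            "in the configured field of view")
    sites = [(margin + iy * min_dist, margin + ix * min_dist)
             for iy in range(n_y) for ix in range(n_x)]
    order = rng.permutation(len(sites))[:config.n_nuclei]
    return [np.array([fz / 2 + rng.uniform(-0.15, 0.15) * fz, sites[k][0], sites[k][1]])
            for k in order]


def simulate_mitosis_movie(config: MovieConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel mitosis movie plus its ground truth.

    Channel 0 is the chromatin (histone) channel; channel 1 is the
    recruitment channel, equal to ``background_level × f`` inside the
    chromatin mask and ``background_level`` outside, where ``f`` is the
    phase-dependent enrichment factor. The expected image is blurred by a
    separable Gaussian PSF and then subjected to Poisson and Gaussian
    noise.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    place_rng = np.random.default_rng(master.spawn(1)[0])
    noise_rng = np.random.default_rng(master.spawn(1)[0])
    per_nucleus = [np.random.default_rng(s) for s in master.spawn(max(config.n_nuclei, 1))]

    centers = _place_centers(config, place_rng)
    angles = [per_nucleus[i].uniform(0, 2 * math.pi) for i in range(config.n_nuclei)]

    nz = config.n_planes
    ny, nx = config.shape_xy
    nt = config.n_frames
    voxel = (config.z_step, config.xy_pixel, config.xy_pixel)

    masks = np.zeros((nt, nz, ny, nx), dtype=np.int32)
    data = np.zeros((nt, 2, nz, ny, nx), dtype=np.float64)
    rows = []
    phases = []

    sigma_vox = tuple(s / v for s, v in zip(config.psf_sigma, voxel))
    for t in range(nt):
        phase, progress = config.phase_of_time(t * config.frame_interval)
        phases.append(phase)
        f = float(config.enrichment_profile.get(phase, 1.0))
        frame_mask = masks[t]
        for i, (c0, ang) in enumerate(zip(centers, angles)):
            drift = np.array([0.0, config.drift[0] * t, config.drift[1] * t])
            c = c0 + drift
            for offset, semi in _nucleus_bodies(phase, progress,
                                                config.nucleus_radius, ang):
                if config.chromatin_z_extent is not None:
                    semi = (config.chromatin_z_extent, semi[1], semi[2])
                center = (c[0],
                          c[1] + offset * math.sin(ang),
                          c[2] + offset * math.cos(ang))
                m, sl = _ellipsoid_mask((nz, ny, nx), voxel, center, semi, ang)
                if m is not None:
                    frame_mask[sl][m] = i + 1
            rows.append({"frame": t, "nucleus_id": i + 1, "true_f": f})
        inside = frame_mask > 0
        if config.cell_radius is None:
            # syncytial-embryo-like: cytoplasm fills the field of view
            chrom = config.background_level + config.chromatin_amplitude * inside
            gfp = config.background_level * np.where(inside, f, 1.0)
        else:
            # single cells on a dark field: recruitment channel is cytosolic
            # inside the cell, × f on chromatin, camera offset outside
            yy = (np.arange(ny) * voxel[1])[:, None]
            xx = (np.arange(nx) * voxel[2])[None, :]
            in_cell2d = np.zeros((ny, nx), dtype=bool)
            for i2, _ in enumerate(centers):
                cyx = centers[i2] + np.array([0.0, config.drift[0] * t,
                                              config.drift[1] * t])
                in_cell2d |= ((yy - cyx[1]) ** 2 + (xx - cyx[2]) ** 2
                              <= config.cell_radius ** 2)
            in_cell = np.broadcast_to(in_cell2d, (nz, ny, nx))
            chrom = (config.dark_level
                     + config.chromatin_amplitude * inside)
            gfp = np.where(in_cell,
                           config.background_level * np.where(inside, f, 1.0),
                           config.dark_level)
        if any(s > 0 for s in sigma_vox):
            chrom = gaussian_filter(chrom, sigma_vox, mode="reflect")
            gfp = gaussian_filter(gfp, sigma_vox, mode="reflect")
        data[t, 0] = config.noise.apply(chrom, noise_rng)
        data[t, 1] = config.noise.apply(gfp, noise_rng)

    stack = ImageStack(data=data, voxel_size=voxel,
                       channel_names=["chromatin", "recruitment"],
                       frame_interval=config.frame_interval)
    truth = GroundTruth(masks=masks,
                        true_f=pd.DataFrame(rows, columns=["frame", "nucleus_id", "true_f"]),
                        background=config.background_level,
                        phase_of_frame=phases)
    return stack, truth


def embryo_movie_config(f_late: float = 2.7, **overrides) -> MovieConfig:
    """Preset emulating syncytial-embryo volumetric acquisition: a field of
    nuclei dividing in synchrony, recruitment rising through anaphase to a
    late-telophase maximum ``f_late`` and partially decaying in interphase.

    The z sampling is coarser and the field smaller than the full
    acquisition geometry so a movie renders in seconds; the optics scale
    (nucleus size vs PSF) is preserved.
    """
    rel = {"metaphase": 0.0, "anaphase": 0.32, "telophase": 0.86,
           "late_telophase": 1.0, "interphase": 0.3}
    cfg = MovieConfig(
        n_nuclei=10,
        shape_xy=(160, 200),
        xy_pixel=0.3,
        z_range=6.4,
        z_step=0.4,
        nucleus_radius=3.0,
        psf_sigma=(0.2, 0.12, 0.12),
        enrichment_profile={p: 1.0 + r * (f_late - 1.0) for p, r in rel.items()},
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def s2_movie_config(**overrides) -> MovieConfig:
    """Preset emulating confocal S2-cell acquisition: one mitotic cell,
    1 µm z-steps over the cell volume, 90 s between stacks."""
    cfg = MovieConfig(
        n_nuclei=1,
        frame_interval=90.0,
        z_step=1.0,
        z_range=6.0,
        xy_pixel=0.2,
        shape_xy=(128, 128),
        nucleus_radius=3.0,
        cell_radius=8.0,
        chromatin_z_extent=30.0,  # chromatin spans the whole (thin) stack
        phase_schedule=[("metaphase", 180.0), ("anaphase", 270.0),
                        ("telophase", 270.0)],
        enrichment_profile={"metaphase": 1.0, "anaphase": 1.8,
                            "telophase": 2.5},
        psf_sigma=(0.0, 0.15, 0.15),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# droplet fields
# ---------------------------------------------------------------------------

def simulate_droplet_field(
    n_droplets: int,
    radius_range: tuple[float, float] = (1.0, 2.0),
    partner_enrichment: float = 10.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel: float = 0.2,
    background: float = 100.0,
    dna_amplitude: float = 500.0,
    psf_sigma: float = 0.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel 2D condensate field plus its ground truth.

    Channel 0 (DNA) defines the droplets; channel 1 (partner) equals
    ``background × partner_enrichment`` inside droplets and ``background``
    outside. Droplets are non-overlapping disks with radii drawn uniformly
    from ``radius_range`` (µm).
    """
    if n_droplets < 0:
        raise ValueError("n_droplets must be >= 0")
    lo, hi = radius_range
    if lo <= 0 or hi < lo:
        raise ValueError("radius_range must be positive and ordered")
    if partner_enrichment < 0:
        raise ValueError("partner_enrichment must be >= 0")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    ny, nx = shape
    fy, fx = ny * pixel, nx * pixel
    labels = np.zeros((ny, nx), dtype=np.int32)
    yy = (np.arange(ny) + 0.5) * pixel
    xx = (np.arange(nx) + 0.5) * pixel
    placed: list[tuple[float, float, float]] = []
    for i in range(n_droplets):
        r = rng.uniform(lo, hi)
        for attempt in range(5000):
            cy = rng.uniform(r, fy - r)
            cx = rng.uniform(r, fx - r)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + pixel) ** 2
                   for py, px, pr in placed):
                placed.append((cy, cx, r))
                m = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2 <= r ** 2
                labels[m] = i + 1
                break
        else:
            raise ValueError("could not place non-overlapping droplets; "
                             "reduce n_droplets or radii")
    inside = labels > 0
    dna = background + dna_amplitude * inside
    partner = background * np.where(inside, partner_enrichment, 1.0)
    if psf_sigma > 0:
        s = psf_sigma / pixel
        dna = gaussian_filter(dna, s, mode="reflect")
        partner = gaussian_filter(partner, s, mode="reflect")
    data = np.stack([noise.apply(dna, rng), noise.apply(partner, rng)])[None]
    stack = ImageStack(data=data, voxel_size=(pixel, pixel),
                       channel_names=["dna", "partner"], frame_interval=1.0)
    rows = [{"frame": 0, "nucleus_id": i + 1, "true_f": partner_enrichment}
            for i in range(n_droplets)]
    truth = GroundTruth(masks=labels[None],
                        true_f=pd.DataFrame(rows, columns=["frame", "nucleus_id", "true_f"]),
                        background=background)
    return stack, truth


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def simulate_titration(kd: float, hill_n: float, a0: float, amax: float,
                       concentrations, noise_sd: float = 0.0, seed: int = 0):
    """Hill-model titration: A(c) = A0 + (Amax−A0)·cⁿ/(Kdⁿ + cⁿ) + noise."""
    from .fitting import TitrationCurve, hill_model

    conc = np.asarray(concentrations, dtype=np.float64)
    if kd <= 0 or hill_n <= 0:
        raise ValueError("kd and hill_n must be > 0")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    signal = hill_model(conc, a0, amax, kd, hill_n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return TitrationCurve(concentrations=conc, signal=signal)


# ---------------------------------------------------------------------------
# random sequences
# ---------------------------------------------------------------------------

def random_sequence(length: int, alphabet: str = "protein",
                    weights: dict[str, float] | None = None, seed: int = 0):
    """I.i.d. random sequence over the protein or DNA alphabet.

    ``weights`` maps symbols to (unnormalized) probabilities; missing
    symbols get weight 0; unknown symbols raise.
    """
    from .seqfeat import DNA_ALPHABET, PROTEIN_ALPHABET, SequenceRecord

    if length < 0:
        raise ValueError("length must be >= 0")
    letters = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    if alphabet not in ("protein", "dna"):
        raise ValueError("alphabet must be 'protein' or 'dna'")
    if weights is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        unknown = set(weights) - set(letters)
        if unknown:
            raise ValueError(f"unknown symbols in weights: {sorted(unknown)}")
        w = np.array([float(weights.get(ch, 0.0)) for ch in letters])
        if w.sum() <= 0 or np.any(w < 0):
            raise ValueError("weights must be non-negative and normalizable")
        probs = w / w.sum()
    rng = np.random.default_rng(seed)
    chars = rng.choice(list(letters), size=length, p=probs)
    return SequenceRecord(id=f"random_{alphabet}_{seed}",
                          residues="".join(chars), molecule=alphabet)
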