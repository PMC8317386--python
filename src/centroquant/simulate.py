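"""Synthetic microscopy data with known ground truth.

Three generators cover the three kinds of input the analysis consumes:

* :func:`simulate_if_stack` — multichannel 3D immunofluorescence Z-stacks:
  ellipsoidal nuclei with a DNA-stain channel and marker channels carrying
  a handful of bright intranuclear foci, blurred by a Gaussian PSF and
  degraded by shot + read noise.
* :func:`simulate_smlm` — single-molecule blinking localizations in
  disc-shaped clusters, with linear stage drift and fiducial beads; can also
  rasterize raw camera frames for the Gaussian-fitting path.
* :func:`simulate_ploidy_population` — per-nucleus chromosome copy-number
  tables with a tetraploid baseline, a controllable instability fraction,
  an S/G2 (8-copy) subpopulation and volume outliers.

Every generator takes an explicit seed and is bit-reproducible. The returned
:class:`GroundTruth` is index-aligned with the observable output so recovery
tests can score any downstream stage.

Default geometry is desk-scale (30×256×256 voxel stacks, 2000 frames);
acquisition-scale sizes (60×1344×1024, 20000 frames) are reachable purely
through configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PlacementError
from .image_io import DEFAULT_VOXEL_SIZE, LOC_COLUMNS, VoxelGrid, write_json

__all__ = [
    "StackSimConfig", "SmlmSimConfig", "PloidySimConfig", "GroundTruth",
    "simulate_if_stack", "simulate_smlm", "simulate_ploidy_population",
    "render_raw_frames",
]


# --------------------------------------------------------------------------
# configs


@dataclass
class StackSimConfig:
    """Parameters of the immunofluorescence Z-stack generator.

    Intensities are arbitrary camera units (a.u.). The marker channel inside
    a nucleus sits at ``marker_baseline``; each focus adds a truncated 3D
    Gaussian of peak amplitude ``enrichment × baseline`` on top, so the peak
    excess over background is ``enrichment``-fold. In the treated group the
    per-focus enrichment is scaled by ``(1 - delta)``.
    """

    shape: tuple[int, int, int] = (30, 256, 256)          # (Z, Y, X) voxels
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE  # µm
    n_nuclei: int = 4
    semiaxes_z_um: tuple[float, float] = (1.2, 1.7)        # axial semi-axis range
    semiaxes_xy_um: tuple[float, float] = (2.2, 3.2)       # lateral semi-axis range
    foci_per_nucleus: int = 4          # near-tetraploid: one focus per homolog
    focus_sigma_um: float = 0.22       # isotropic blob sigma, truncated at 3 sigma
    # pairwise centre separation within a nucleus; > 2 x (3 sigma) so the
    # truncated blobs never overlap and each focus has closed-form truth
    focus_min_sep_um: float = 1.4
    enrichment: float = 3.0            # peak marker excess, fold over baseline
    delta: float = 0.0                 # fractional enrichment loss in treated group
    group: str = "control"             # "control" | "treated"
    n_marker_channels: int = 1
    dna_level: float = 120.0           # nuclear DNA-stain intensity (a.u.)
    marker_baseline: float = 60.0      # intranuclear marker background (a.u.)
    background: float = 8.0            # extranuclear background (a.u.)
    texture_amp: float = 0.15          # low-frequency multiplicative texture
    psf_sigma_um: tuple[float, float] = (0.25, 0.11)  # (axial, lateral)
    poisson_gain: float = 1.0          # photons per a.u.; 0 disables shot noise
    read_sigma: float = 2.0            # Gaussian read noise sd (a.u.); 0 disables
    seed: int = 0

    def validate(self) -> None:
        if min(self.shape) < 1 or self.n_nuclei < 0 or self.foci_per_nucleus < 0:
            raise ValueError("dimensions and counts must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.enrichment <= 0:
            raise ValueError("enrichment must be > 0")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must be in [0, 1)")
        if self.group not in ("control", "treated"):
            raise ValueError(f"unknown group {self.group!r}")
        for lo, hi in (self.semiaxes_z_um, self.semiaxes_xy_um):
            if not 0 < lo <= hi:
                raise ValueError("semi-axis ranges must be positive and ordered")


@dataclass
class SmlmSimConfig:
    """Parameters of the single-molecule blinking simulator.

    Lengths in nm, one frame = one camera exposure. Defaults are a
    scaled-down acquisition (2000 frames vs 20000 in a full experiment) on a
    128×128 px camera region at 144 nm/px.
    """

    n_frames: int = 2000
    frame_shape: tuple[int, int] = (128, 128)   # (rows, cols) px
    pixel_nm: float = 144.0
    n_clusters: int = 4
    cluster_radius_nm: float = 60.0
    emitters_per_cluster: int = 120
    mean_streak_len: float = 3.0       # consecutive-frame on-time (geometric)
    sigma_loc_nm: float = 20.0         # per-detection localization noise
    drift_nm_per_frame: tuple[float, float] = (0.05, 0.03)  # (dx, dy)
    n_fiducials: int = 3
    fiducial_noise_nm: float = 1.0     # beads are bright, localize well
    mean_photons: float = 1000.0
    psf_sigma_nm: float = 190.0        # ~1.3 px at 144 nm/px
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma_loc_nm < 0 or self.fiducial_noise_nm < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.mean_streak_len < 1:
            raise ValueError("mean_streak_len must be >= 1")
        if min(self.frame_shape) < 4 or self.pixel_nm <= 0:
            raise ValueError("invalid frame geometry")


@dataclass
class PloidySimConfig:
    """Parameters of the chromosome copy-number population generator.

    ``instability`` is the probability that a nucleus carries an aberrant
    copy number of the target chromosome; ``s_g2_fraction`` the probability
    of an S/G2 nucleus that has doubled its genome (count 8 for both
    chromosomes, inflated volume). Aberrant counts default to mostly single
    losses with rarer single/double gains, the pattern seen in near-tetraploid
    osteosarcoma cells.
    """

    n_nuclei: int = 1200
    euploid: int = 4
    instability: float = 0.039
    instability_control_chrom: float = 0.0   # aberration rate of chromosome 11
    aberrant_weights: dict[int, float] = field(
        default_factory=lambda: {3: 0.76, 5: 0.20, 6: 0.04}
    )
    s_g2_fraction: float = 0.05
    volume_median_um3: float = 700.0
    volume_sigma_log: float = 0.25     # sd of log-volume
    s_g2_volume_factor: float = 1.6    # S/G2 nuclei are larger
    volume_outlier_fraction: float = 0.01
    volume_outlier_factor: float = 2.5
    group: str = "uninduced"           # "induced" | "uninduced"
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0 or self.euploid < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.instability <= 1 or not 0 <= self.s_g2_fraction <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.instability + self.s_g2_fraction > 1:
            raise ValueError("instability + s_g2_fraction must be <= 1")
        w = sum(self.aberrant_weights.values())
        if self.aberrant_weights and abs(w - 1.0) > 1e-9:
            raise ValueError(f"aberrant_weights must sum to 1, got {w}")
        if self.volume_median_um3 <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class GroundTruth:
    """Truth tables index-aligned with a generator's observable output.

    Only the fields relevant to the generator that produced it are set.
    """

    nuclei: pd.DataFrame | None = None     # label, centroid, semi-axes, volume
    foci: pd.DataFrame | None = None       # nucleus label, centroid, enrichment
    emitters: pd.DataFrame | None = None   # emitter id, cluster, x, y (nm)
    drift: pd.DataFrame | None = None      # frame, dx, dy (nm)
    fiducials: pd.DataFrame | None = None  # fiducial id, x0, y0 (nm)
    counts: pd.DataFrame | None = None     # per-nucleus true category
    labels: np.ndarray | None = None       # nucleus label map (stack sims)

    def to_json(self, path: str | Path) -> None:
        """Serialize the tabular truth (label map excluded) as JSON."""
        payload = {
            k: v for k, v in asdict(self).items()
            if k != "labels" and v is not None
        }
        write_json(payload, path)


# --------------------------------------------------------------------------
# immunofluorescence stacks


def _place_nuclei(cfg: StackSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample non-overlapping ellipsoid centres/semi-axes; bounded retries."""
    dz, dy, dx = cfg.voxel_size
    extent = (cfg.shape[0] * dz, cfg.shape[1] * dy, cfg.shape[2] * dx)
    placed: list[dict] = []
    for i in range(cfg.n_nuclei):
        for _ in range(200):
            az = rng.uniform(*cfg.semiaxes_z_um)
            ay = rng.uniform(*cfg.semiaxes_xy_um)
            ax = rng.uniform(*cfg.semiaxes_xy_um)
            semi = np.array([az, ay, ax])
            if np.any(2 * semi >= extent):
                continue
            lo = semi * 1.02
            hi = np.array(extent) - semi * 1.02
            if np.any(hi <= lo):
                continue
            c = rng.uniform(lo, hi)
            # centre-distance overlap test against bounding spheres
            ok = True
            for p in placed:
                r_sum = max(semi[1:]) + max(p["semi"][1:])
                z_sum = semi[0] + p["semi"][0]
                d = c - p["centroid"]
                if (d[1] ** 2 + d[2] ** 2) < r_sum ** 2 and abs(d[0]) < z_sum:
                    ok = False
                    break
            if ok:
                placed.append({"centroid": c, "semi": semi})
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{cfg.n_nuclei} without overlap"
            )
    rows = []
    for lab, p in enumerate(placed, start=1):
        cz, cy, cx = p["centroid"]
        az, ay, ax = p["semi"]
        rows.append({
            "label": lab, "cz_um": cz, "cy_um": cy, "cx_um": cx,
            "az_um": az, "ay_um": ay, "ax_um": ax,
            "volume_um3": 4.0 / 3.0 * np.pi * az * ay * ax,
        })
    return pd.DataFrame(
        rows,
        columns=["label", "cz_um", "cy_um", "cx_um", "az_um", "ay_um", "ax_um",
                 "volume_um3"],
    )


def _coord_axes(shape, voxel_size):
    """Physical coordinate (µm) of each voxel centre along each axis."""
    return [
        (np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size)
    ]


def simulate_if_stack(cfg: StackSimConfig) -> tuple[VoxelGrid, GroundTruth]:
    """Generate a multichannel IF Z-stack plus aligned ground truth.

    Channel 0 is the DNA stain; channels 1..n are marker channels, each with
    ``foci_per_nucleus`` Gaussian foci per nucleus. With ``poisson_gain=0``,
    ``read_sigma=0`` and ``psf_sigma_um=(0, 0)`` the output is the exact
    noiseless model, which recovery tests exploit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nuclei = _place_nuclei(cfg, rng)

    zc, yc, xc = _coord_axes(cfg.shape, cfg.voxel_size)
    labels = np.zeros(cfg.shape, dtype=np.int32)
    dna = np.zeros(cfg.shape)
    n_ch = 1 + cfg.n_marker_channels
    channels = [dna] + [np.zeros(cfg.shape) for _ in range(cfg.n_marker_channels)]

    eff_enrich = cfg.enrichment * (1.0 - cfg.delta if cfg.group == "treated" else 1.0)
    foci_rows = []

    for rec in nuclei.itertuples(index=False):
        c = np.array([rec.cz_um, rec.cy_um, rec.cx_um])
        semi = np.array([rec.az_um, rec.ay_um, rec.ax_um])
        # normalized ellipsoid distance on the voxel grid (broadcasted)
        nz = (zc - c[0]) / semi[0]
        ny = (yc - c[1]) / semi[1]
        nx = (xc - c[2]) / semi[2]
        inside = (nz[:, None, None] ** 2 + ny[None, :, None] ** 2
                  + nx[None, None, :] ** 2) <= 1.0
        labels[inside] = rec.label
        # smooth multiplicative texture: few random low-frequency cosines
        texture = np.ones(cfg.shape)
        if cfg.texture_amp > 0:
            for _ in range(3):
                k = rng.uniform(0.2, 0.8, size=3)   # cycles per nucleus diameter
                phase = rng.uniform(0, 2 * np.pi)
                wave = np.cos(
                    2 * np.pi * (k[0] * nz[:, None, None]
                                 + k[1] * ny[None, :, None]
                                 + k[2] * nx[None, None, :]) + phase
                )
                texture += cfg.texture_amp / 3.0 * wave
        dna[inside] += (cfg.dna_level * texture)[inside]
        for ch in range(1, n_ch):
            channels[ch][inside] += (cfg.marker_baseline * texture)[inside]

        # foci: centres uniform inside the shrunken ellipsoid so the 3-sigma
        # support stays within the nucleus
        margin = 3.0 * cfg.focus_sigma_um
        inner = np.maximum(semi - margin, 0.3 * semi)
        for ch in range(1, n_ch):
            placed_foci: list[np.ndarray] = []
            for _ in range(cfg.foci_per_nucleus):
                fc = None
                for _ in range(500):
                    u = rng.uniform(-1, 1, size=3)
                    if u @ u > 1.0:
                        continue
                    cand_fc = c + u * inner
                    if all(np.linalg.norm(cand_fc - p) >= cfg.focus_min_sep_um
                           for p in placed_foci):
                        fc = cand_fc
                        break
                if fc is None:
                    raise PlacementError(
                        f"cannot place {cfg.foci_per_nucleus} foci at "
                        f"separation {cfg.focus_min_sep_um} µm in nucleus {rec.label}"
                    )
                placed_foci.append(fc)
                amp = eff_enrich * cfg.marker_baseline
                _add_blob(channels[ch], fc, cfg.focus_sigma_um, amp,
                          cfg.voxel_size, (zc, yc, xc))
                foci_rows.append({
                    "nucleus_label": rec.label, "channel": ch,
                    "cz_um": fc[0], "cy_um": fc[1], "cx_um": fc[2],
                    "enrichment": eff_enrich, "group": cfg.group,
                })

    data = np.stack(channels, axis=-1)
    data += cfg.background

    sz, sxy = cfg.psf_sigma_um
    if sz > 0 or sxy > 0:
        sig_vox = (sz / cfg.voxel_size[0], sxy / cfg.voxel_size[1],
                   sxy / cfg.voxel_size[2], 0)
        data = ndimage.gaussian_filter(data, sigma=sig_vox)
    if cfg.poisson_gain > 0:
        data = rng.poisson(data * cfg.poisson_gain) / cfg.poisson_gain
    if cfg.read_sigma > 0:
        data = data + rng.normal(0, cfg.read_sigma, size=data.shape)
    data = np.clip(data, 0, None)

    names = ["dna"] + [f"marker{i}" for i in range(1, n_ch)]
    grid = VoxelGrid(data, cfg.voxel_size, names)
    foci_cols = ["nucleus_label", "channel", "cz_um", "cy_um", "cx_um",
                 "enrichment", "group"]
    truth = GroundTruth(
        nuclei=nuclei,
        foci=pd.DataFrame(foci_rows, columns=foci_cols),
        labels=labels,
    )
    return grid, truth


def _add_blob(vol, centre_um, sigma_um, amplitude, voxel_size, axes):
    """Add an isotropic 3D Gaussian truncated at 3 sigma, in place."""
    zc, yc, xc = axes
    r = 3.0 * sigma_um
    sl = []
    for ax_coords, c, d in zip(axes, centre_um, voxel_size):
        lo = max(int(np.floor((c - r) / d)), 0)
        hi = min(int(np.ceil((c + r) / d)) + 1, ax_coords.size)
        sl.append(slice(lo, hi))
    zz = zc[sl[0]] - centre_um[0]
    yy = yc[sl[1]] - centre_um[1]
    xx = xc[sl[2]] - centre_um[2]
    d2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
          + xx[None, None, :] ** 2)
    blob = amplitude * np.exp(-d2 / (2 * sigma_um ** 2))
    blob[d2 > r ** 2] = 0.0
    vol[sl[0], sl[1], sl[2]] += blob


# --------------------------------------------------------------------------
# SMLM


def simulate_smlm(cfg: SmlmSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a blinking-emitter localization table with drift and fiducials.

    Emitters live in disc-shaped clusters; each emits once, on a streak of
    consecutive frames with geometric length (mean ``mean_streak_len``).
    Observed position = true + cumulative drift + isotropic noise. Fiducial
    beads appear in every frame and carry ``fiducial_noise_nm`` noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h_nm = cfg.frame_shape[0] * cfg.pixel_nm
    w_nm = cfg.frame_shape[1] * cfg.pixel_nm

    frames = np.arange(cfg.n_frames)
    drift = np.column_stack([
        frames * cfg.drift_nm_per_frame[0],
        frames * cfg.drift_nm_per_frame[1],
    ])  # (n_frames, 2): cumulative (dx, dy) relative to frame 0

    margin = max(4 * cfg.cluster_radius_nm, 0.1 * min(h_nm, w_nm))
    centres = np.column_stack([
        rng.uniform(margin, w_nm - margin, cfg.n_clusters),
        rng.uniform(margin, h_nm - margin, cfg.n_clusters),
    ])

    em_rows, obs_rows = [], []
    eid = 0
    for ci in range(cfg.n_clusters):
        for _ in range(cfg.emitters_per_cluster):
            # uniform in disc
            theta = rng.uniform(0, 2 * np.pi)
            rad = cfg.cluster_radius_nm * np.sqrt(rng.uniform())
            ex = centres[ci, 0] + rad * np.cos(theta)
            ey = centres[ci, 1] + rad * np.sin(theta)
            em_rows.append({"emitter": eid, "cluster": ci, "x": ex, "y": ey})
            start = rng.integers(0, cfg.n_frames)
            # geometric on-time, support >= 1, mean = mean_streak_len
            streak = int(rng.geometric(1.0 / cfg.mean_streak_len))
            for f in range(start, min(start + streak, cfg.n_frames)):
                noise = rng.normal(0, cfg.sigma_loc_nm, 2) \
                    if cfg.sigma_loc_nm > 0 else np.zeros(2)
                obs_rows.append({
                    "frame": f,
                    "x": ex + drift[f, 0] + noise[0],
                    "y": ey + drift[f, 1] + noise[1],
                    "uncertainty": cfg.sigma_loc_nm,
                    "sigma_psf": cfg.psf_sigma_nm,
                    "photons": rng.exponential(cfg.mean_photons),
                    "merged_id": np.nan,
                    "is_fiducial": False,
                    "emitter": eid,
                })
            eid += 1

    fid_rows = []
    fid_margin = 0.05 * min(h_nm, w_nm)
    for fi in range(cfg.n_fiducials):
        fx = rng.uniform(fid_margin, w_nm - fid_margin)
        fy = rng.uniform(fid_margin, h_nm - fid_margin)
        fid_rows.append({"fiducial": fi, "x0": fx, "y0": fy})
        noise = (rng.normal(0, cfg.fiducial_noise_nm, (cfg.n_frames, 2))
                 if cfg.fiducial_noise_nm > 0 else np.zeros((cfg.n_frames, 2)))
        for f in frames:
            obs_rows.append({
                "frame": int(f),
                "x": fx + drift[f, 0] + noise[f, 0],
                "y": fy + drift[f, 1] + noise[f, 1],
                "uncertainty": cfg.fiducial_noise_nm,
                "sigma_psf": cfg.psf_sigma_nm,
                "photons": 20 * cfg.mean_photons,
                "merged_id": np.nan,
                "is_fiducial": True,
                "emitter": -1 - fi,
            })

    obs = pd.DataFrame(obs_rows, columns=LOC_COLUMNS + ["emitter"])
    obs = obs.sort_values(["frame", "is_fiducial", "emitter"],
                          kind="stable").reset_index(drop=True)
    truth = GroundTruth(
        emitters=pd.DataFrame(em_rows, columns=["emitter", "cluster", "x", "y"]),
        drift=pd.DataFrame({"frame": frames, "dx": drift[:, 0], "dy": drift[:, 1]}),
        fiducials=pd.DataFrame(fid_rows, columns=["fiducial", "x0", "y0"]),
    )
    return obs, truth


def render_raw_frames(
    locs: pd.DataFrame,
    frame_shape: tuple[int, int],
    pixel_nm: float,
    psf_sigma_nm: float = 190.0,
    background: float = 10.0,
    read_sigma: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Rasterize a localization table into noisy raw camera frames.

    Each record becomes a 2D Gaussian PSF whose integral equals its photon
    count, on a constant background with shot and read noise — the input the
    Gaussian-fitting stage expects. Returns ``(n_frames, H, W)``.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(locs["frame"].max()) + 1 if len(locs) else 1
    stack = np.full((n_frames, *frame_shape), float(background))
    s_px = psf_sigma_nm / pixel_nm
    half = int(np.ceil(4 * s_px))
    for rec in locs.itertuples(index=False):
        # pixel-centre convention: physical x = (col + 0.5) * pixel_nm
        cx = rec.x / pixel_nm - 0.5
        cy = rec.y / pixel_nm - 0.5
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, frame_shape[1])
        y0, y1 = max(y0, 0), min(y1, frame_shape[0])
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * s_px ** 2))
        amp = rec.photons / (2 * np.pi * s_px ** 2)
        stack[int(rec.frame), y0:y1, x0:x1] += amp * g
    stack = rng.poisson(stack).astype(float)
    if read_sigma > 0:
        stack += rng.normal(0, read_sigma, stack.shape)
    return np.clip(stack, 0, None)


# --------------------------------------------------------------------------
# ploidy populations


def simulate_ploidy_population(cfg: PloidySimConfig) -> pd.DataFrame:
    """Draw a per-nucleus chromosome-count table.

    Returns columns ``nucleus_id, count_ch7, count_ch11, volume_um3, group,
    category`` where ``category`` is the truth label
    (``euploid | aberrant | s_g2``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nuclei

    u = rng.uniform(size=n)
    cat = np.where(u < cfg.s_g2_fraction, "s_g2",
                   np.where(u < cfg.s_g2_fraction + cfg.instability,
                            "aberrant", "euploid"))

    count7 = np.full(n, cfg.euploid, dtype=int)
    count11 = np.full(n, cfg.euploid, dtype=int)
    ab = cat == "aberrant"
    if ab.any() and cfg.aberrant_weights:
        vals = np.array(sorted(cfg.aberrant_weights))
        probs = np.array([cfg.aberrant_weights[v] for v in vals], dtype=float)
        count7[ab] = rng.choice(vals, size=int(ab.sum()), p=probs / probs.sum())
    if cfg.instability_control_chrom > 0 and cfg.aberrant_weights:
        ab11 = (rng.uniform(size=n) < cfg.instability_control_chrom) & (cat == "euploid")
        vals = np.array(sorted(cfg.aberrant_weights))
        probs = np.array([cfg.aberrant_weights[v] for v in vals], dtype=float)
        count11[ab11] = rng.choice(vals, size=int(ab11.sum()), p=probs / probs.sum())
    sg2 = cat == "s_g2"
    count7[sg2] = 2 * cfg.euploid
    count11[sg2] = 2 * cfg.euploid

    vol = cfg.volume_median_um3 * np.exp(
        rng.normal(0, cfg.volume_sigma_log, size=n))
    vol[sg2] *= cfg.s_g2_volume_factor
    if cfg.volume_outlier_fraction > 0:
        out = (rng.uniform(size=n) < cfg.volume_outlier_fraction) & ~sg2
        vol[out] *= cfg.volume_outlier_factor

    return pd.DataFrame({
        "nucleus_id": np.arange(n),
        "count_ch7": count7,
        "count_ch11": count11,
        "volume_um3": vol,
        "group": cfg.group,
        "category": cat,
    })
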