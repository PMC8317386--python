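"""Single-molecule localization microscopy pipeline.

Stages, in acquisition order: Gaussian PSF fitting of raw frames
(:func:`fit_events`), fiducial-based drift correction
(:func:`correct_drift`), merging of consecutive detections of the same
molecule (:func:`merge_consecutive`), super-resolved rendering as a sum of
unit-amplitude Gaussians (:func:`render`) and cluster-area measurement on
max-normalized ROIs (:func:`cluster_area`).

All positions are nm in raw-frame coordinates (origin at the top-left
corner of pixel (0, 0); the centre of pixel ``(i, j)`` is at
``((j + 0.5)·a, (i + 0.5)·a)`` for pixel size ``a``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from .errors import DomainError, SchemaError, UndefinedValueError
from .image_io import LOC_COLUMNS

__all__ = [
    "SuperResImage", "ClusterMeasurement", "DriftTrajectory",
    "fit_events", "correct_drift", "merge_consecutive", "render",
    "cluster_area", "object_pixel_nm", "thompson_uncertainty",
]


@dataclass
class SuperResImage:
    """Rendered super-resolution canvas, origin aligned to the raw frame."""

    data: np.ndarray       # 2D, intensities >= 0
    pixel_nm: float        # canvas pixel = raw pixel / upsample

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")


@dataclass
class ClusterMeasurement:
    roi_nm: tuple[float, float, float, float]  # (x0, x1, y0, y1), half-open
    threshold: float
    area_um2: float
    n_pixels: int


@dataclass
class DriftTrajectory:
    """Per-frame stage displacement (nm) relative to frame 0."""

    frames: np.ndarray
    dx: np.ndarray
    dy: np.ndarray

    def at(self, frame_idx) -> np.ndarray:
        """Displacement (dx, dy) for an array of frame indices."""
        idx = np.clip(np.asarray(frame_idx, dtype=int), 0, len(self.frames) - 1)
        return np.column_stack([self.dx[idx], self.dy[idx]])


def object_pixel_nm(camera_pixel_um: float = 16.0, magnification: float = 111.0) -> float:
    """Object-plane pixel size in nm: camera pixel / total magnification.

    A 16 µm camera pixel behind a 111× optical train maps to ≈ 144 nm in
    the sample plane.
    """
    if camera_pixel_um <= 0 or magnification <= 0:
        raise DomainError("camera pixel and magnification must be positive")
    return camera_pixel_um * 1000.0 / magnification


def thompson_uncertainty(
    sigma_psf_nm: float, photons: float, pixel_nm: float, bg_noise: float
) -> float:
    """Photon-statistics localization precision (Thompson-style).

    σ_loc² = (s² + a²/12)/N + 8π s⁴ b² / (a² N²), with PSF width ``s`` and
    pixel size ``a`` in nm, ``N`` photons and background noise ``b``
    (photons/pixel rms).
    """
    if photons <= 0:
        return np.inf
    s2 = sigma_psf_nm ** 2
    var = (s2 + pixel_nm ** 2 / 12.0) / photons \
        + 8.0 * np.pi * s2 ** 2 * bg_noise ** 2 / (pixel_nm ** 2 * photons ** 2)
    return float(np.sqrt(var))


# --------------------------------------------------------------------------
# event fitting


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    yy, xx = coords
    return (amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2))
            + offset).ravel()


def fit_events(
    frames: np.ndarray,
    pixel_nm: float,
    threshold_k: float = 5.0,
    fit_radius_px: int = 4,
    psf_sigma_guess_px: float = 1.3,
    min_distance_px: int = 4,
) -> pd.DataFrame:
    """Detect and fit single-molecule events in raw frames.

    Per frame: difference-of-Gaussians band-pass → local maxima above
    ``threshold_k`` robust noise sigmas → least-squares fit of a symmetric
    2D Gaussian (amplitude, x, y, σ_psf, offset) in a
    ``(2·fit_radius+1)²`` window. Photons are the fitted Gaussian integral;
    the uncertainty column is the Thompson precision. Fits that fail to
    converge, run out of the window or land on another peak are discarded.

    Returns a canonical localization table (nm units, 0-based frames).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise SchemaError(f"expected (n_frames, H, W) raw frames, got ndim={frames.ndim}")

    rows = []
    win = fit_radius_px
    for f_idx, img in enumerate(frames):
        bg = np.median(img)
        noise = 1.4826 * np.median(np.abs(img - bg)) or img.std() or 1.0
        dog = ndimage.gaussian_filter(img, psf_sigma_guess_px) \
            - ndimage.gaussian_filter(img, 2.5 * psf_sigma_guess_px)
        # local maxima of the band-passed image above k sigma of raw noise
        maxima = (dog == ndimage.maximum_filter(dog, size=2 * min_distance_px + 1))
        cand = np.argwhere(maxima & (img - bg > threshold_k * noise))
        for cy, cx in cand:
            y0, y1 = cy - win, cy + win + 1
            x0, x1 = cx - win, cx + win + 1
            if y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]:
                continue
            patch = img[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1]
            p0 = (float(img[cy, cx] - bg), float(cx), float(cy),
                  psf_sigma_guess_px, float(bg))
            try:
                popt, _ = optimize.curve_fit(
                    _gauss2d, (yy, xx), patch.ravel(), p0=p0,
                    bounds=([0, x0, y0, 0.3, -np.inf],
                            [np.inf, x1, y1, 4 * psf_sigma_guess_px, np.inf]),
                    maxfev=400,
                )
            except (RuntimeError, ValueError):
                continue
            amp, xf, yf, sig, off = popt
            photons = 2 * np.pi * sig ** 2 * amp
            if photons <= 0:
                continue
            sig_nm = sig * pixel_nm
            rows.append({
                "frame": f_idx,
                # pixel-index i maps to physical (i + 0.5) * a
                "x": (xf + 0.5) * pixel_nm,
                "y": (yf + 0.5) * pixel_nm,
                "uncertainty": thompson_uncertainty(sig_nm, photons, pixel_nm, noise),
                "sigma_psf": sig_nm,
                "photons": photons,
                "merged_id": np.nan,
                "is_fiducial": False,
            })
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


# --------------------------------------------------------------------------
# drift correction


def _fiducial_tracks(locs: pd.DataFrame) -> list[pd.DataFrame]:
    """Group fiducial records into per-bead tracks by incremental nearest
    neighbour from the earliest frame."""
    fid = locs[locs["is_fiducial"]].sort_values("frame", kind="stable")
    if fid.empty:
        raise DomainError("no fiducial records in the table")
    first_frame = fid["frame"].min()
    seeds = fid[fid["frame"] == first_frame]
    tracks = [[row] for row in seeds.itertuples()]
    last = [np.array([t[0].x, t[0].y]) for t in tracks]
    for row in fid[fid["frame"] > first_frame].itertuples():
        p = np.array([row.x, row.y])
        d = [np.hypot(*(p - q)) for q in last]
        i = int(np.argmin(d))
        tracks[i].append(row)
        last[i] = p
    return [pd.DataFrame(t) for t in tracks]


def correct_drift(
    locs: pd.DataFrame,
    smooth_window: int = 51,
) -> tuple[pd.DataFrame, DriftTrajectory]:
    """Estimate stage drift from fiducial beads and subtract it.

    Drift at frame ``f`` is the mean over beads of (position(f) −
    position(first frame)), linearly interpolated over frames where a bead
    is dark and smoothed by a centred moving average of ``smooth_window``
    frames. The trajectory is re-anchored so drift(0) = (0, 0). Fiducial
    records are corrected too and stay flagged; the record count is
    unchanged.
    """
    if locs.empty:
        raise DomainError("empty localization table")
    n_frames = int(locs["frame"].max()) + 1
    frames = np.arange(n_frames)
    tracks = _fiducial_tracks(locs)

    disp = np.zeros((len(tracks), n_frames, 2))
    for i, tr in enumerate(tracks):
        fx = tr["frame"].to_numpy()
        x = tr["x"].to_numpy()
        y = tr["y"].to_numpy()
        disp[i, :, 0] = np.interp(frames, fx, x - x[0])
        disp[i, :, 1] = np.interp(frames, fx, y - y[0])
    drift = disp.mean(axis=0)
    if smooth_window > 1 and n_frames > 2:
        # local-linear smoothing: unbiased for steady stage drift, including
        # at the sequence ends where a moving average would flatten the trend
        w = min(smooth_window, n_frames if n_frames % 2 else n_frames - 1)
        if w % 2 == 0:
            w -= 1
        if w >= 3:
            drift = np.column_stack([
                signal.savgol_filter(drift[:, 0], w, 1, mode="interp"),
                signal.savgol_filter(drift[:, 1], w, 1, mode="interp"),
            ])
    drift = drift - drift[0]  # anchor to frame 0

    traj = DriftTrajectory(frames=frames, dx=drift[:, 0], dy=drift[:, 1])
    out = locs.copy()
    corr = traj.at(out["frame"].to_numpy())
    out["x"] = out["x"].to_numpy() - corr[:, 0]
    out["y"] = out["y"].to_numpy() - corr[:, 1]
    return out, traj


# --------------------------------------------------------------------------
# merging


def merge_consecutive(
    locs: pd.DataFrame,
    radius_nm: float = 50.0,
    max_gap: int = 1,
) -> pd.DataFrame:
    """Collapse consecutive detections of the same molecule into one record.

    Detections in consecutive frames (allowing up to ``max_gap`` dark
    frames) within ``radius_nm`` are linked greedily by nearest neighbour.
    Each chain becomes one record: inverse-variance-weighted mean position,
    summed photons, combined uncertainty 1/√(Σ 1/σᵢ²), first frame, and a
    ``merged_id`` chain label. The output never has more rows than the
    input. Fiducial records are passed through unmerged.
    """
    if radius_nm < 0:
        raise DomainError("radius must be >= 0")
    if locs.empty:
        return locs.copy()
    fid = locs[locs["is_fiducial"]]
    mol = locs[~locs["is_fiducial"]].sort_values("frame", kind="stable")

    chains: list[dict] = []          # active + closed
    active: list[int] = []           # indices into chains
    for row in mol.itertuples():
        f = int(row.frame)
        active = [i for i in active
                  if f - chains[i]["last_frame"] <= max_gap + 1]
        best, best_d = None, np.inf
        for i in active:
            c = chains[i]
            if c["last_frame"] >= f:   # one detection per chain per frame
                continue
            d = np.hypot(row.x - c["x"][-1], row.y - c["y"][-1])
            if d <= radius_nm and d < best_d:
                best, best_d = i, d
        if best is None:
            chains.append({
                "first_frame": f, "last_frame": f, "x": [row.x], "y": [row.y],
                "sigma": [row.uncertainty], "photons": [row.photons],
                "sigma_psf": [row.sigma_psf],
            })
            active.append(len(chains) - 1)
        else:
            c = chains[best]
            c["last_frame"] = f
            c["x"].append(row.x)
            c["y"].append(row.y)
            c["sigma"].append(row.uncertainty)
            c["photons"].append(row.photons)
            c["sigma_psf"].append(row.sigma_psf)

    rows = []
    for cid, c in enumerate(chains):
        sig = np.asarray(c["sigma"], dtype=float)
        x = np.asarray(c["x"])
        y = np.asarray(c["y"])
        if np.all(sig > 0):
            w = 1.0 / sig ** 2
            sigma_merged = 1.0 / np.sqrt(w.sum())
        else:
            w = np.ones_like(sig)
            sigma_merged = 0.0
        rows.append({
            "frame": c["first_frame"],
            "x": float(np.average(x, weights=w)),
            "y": float(np.average(y, weights=w)),
            "uncertainty": float(sigma_merged),
            "sigma_psf": float(np.nanmean(np.asarray(c["sigma_psf"], dtype=float))),
            "photons": float(np.nansum(c["photons"])),
            "merged_id": cid,
            "is_fiducial": False,
        })
    merged = pd.DataFrame(rows, columns=LOC_COLUMNS)
    if not fid.empty:
        merged = pd.concat([merged, fid[LOC_COLUMNS]], ignore_index=True)
    return merged.sort_values(["frame"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# rendering and cluster area


def render(
    locs: pd.DataFrame,
    raw_pixel_nm: float = 144.0,
    upsample: int = 10,
    frame_shape: tuple[int, int] | None = None,
    truncate_sigma: float = 4.0,
) -> SuperResImage:
    """Render localizations as a sum of unit-amplitude 2D Gaussians.

    The canvas pixel is ``raw_pixel_nm / upsample`` (144 nm → 14.4 nm at
    the default tenfold upsampling). Each record contributes a Gaussian of
    peak amplitude 1 and σ equal to its localization uncertainty, evaluated
    out to ``truncate_sigma`` σ. Fiducial records are ignored. An empty
    table yields an all-zero canvas.
    """
    px = raw_pixel_nm / upsample
    work = locs[~locs["is_fiducial"]] if "is_fiducial" in locs else locs
    if frame_shape is not None:
        shape = (frame_shape[0] * upsample, frame_shape[1] * upsample)
    elif len(work):
        shape = (
            int(np.ceil((work["y"].max() + 4 * work["uncertainty"].max()) / px)) + 1,
            int(np.ceil((work["x"].max() + 4 * work["uncertainty"].max()) / px)) + 1,
        )
    else:
        shape = (upsample, upsample)
    canvas = np.zeros(shape)
    for row in work.itertuples():
        sig_px = max(float(row.uncertainty) / px, 1e-6)
        # canvas pixel (i, j) centre at ((j + 0.5) px, (i + 0.5) px)
        cx = row.x / px - 0.5
        cy = row.y / px - 0.5
        half = max(int(np.ceil(truncate_sigma * sig_px)), 1)
        x0 = max(int(np.floor(cx)) - half, 0)
        x1 = min(int(np.floor(cx)) + half + 1, shape[1])
        y0 = max(int(np.floor(cy)) - half, 0)
        y1 = min(int(np.floor(cy)) + half + 1, shape[0])
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        canvas[y0:y1, x0:x1] += np.exp(
            -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sig_px ** 2)
        )
    return SuperResImage(canvas, px)


def cluster_area(
    img: SuperResImage,
    roi_nm: tuple[float, float, float, float],
    threshold: float = 0.5,
) -> ClusterMeasurement:
    """Area of a max-normalized cluster ROI above an intensity threshold.

    The ROI ``(x0, x1, y0, y1)`` in nm (half-open) is cropped, divided by
    its maximum pixel value — removing density differences between clusters
    so only extent is compared — and the area is the count of pixels with
    normalized intensity ≥ ``threshold`` times the pixel area, in µm².
    """
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    x0, x1, y0, y1 = roi_nm
    px = img.pixel_nm
    j0, j1 = int(np.floor(x0 / px)), int(np.ceil(x1 / px))
    i0, i1 = int(np.floor(y0 / px)), int(np.ceil(y1 / px))
    j0, i0 = max(j0, 0), max(i0, 0)
    j1 = min(j1, img.data.shape[1])
    i1 = min(i1, img.data.shape[0])
    if j0 >= j1 or i0 >= i1:
        raise DomainError("ROI lies outside the canvas")
    patch = img.data[i0:i1, j0:j1]
    peak = patch.max()
    if peak <= 0:
        raise UndefinedValueError("ROI is all zero; area undefined")
    n_above = int(np.count_nonzero(patch / peak >= threshold))
    area_um2 = n_above * (px / 1000.0) ** 2
    return ClusterMeasurement(roi_nm=tuple(map(float, roi_nm)),
                              threshold=float(threshold),
                              area_um2=area_um2, n_pixels=n_above)
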