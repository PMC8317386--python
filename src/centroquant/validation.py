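"""End-to-end recovery experiments on synthetic data.

Each experiment generates data with a known effect, runs the full analysis
pipeline on it and reports how well the truth is recovered. They double as
integration checks and as the package's reproducible benchmark: the same
functions back the acceptance script and the heavy integration tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PlacementError
from .ploidy import instability_report
from .quant import densities_by_nucleus, marker_effect, rank_sum_test
from .segmentation import segment_foci, segment_nuclei
from .simulate import (
    PloidySimConfig, SmlmSimConfig, StackSimConfig,
    simulate_if_stack, simulate_ploidy_population, simulate_smlm,
)
from .smlm import cluster_area, correct_drift, merge_consecutive, render

__all__ = [
    "recover_marker_effect", "smlm_drift_and_area_experiment",
    "aneuploidy_recovery_experiment",
]


def recover_marker_effect(
    n_per_group: int = 200,
    delta: float = 0.20,
    seed: int = 0,
    shape: tuple[int, int, int] = (24, 96, 96),
) -> dict:
    """Recover a fractional marker loss δ through the full imaging pipeline.

    Simulates ``n_per_group`` single-nucleus stacks per condition (control
    marker enrichment vs the same enrichment reduced by ``delta`` in the
    treated group), segments nuclei and foci, computes per-nucleus
    normalized densities and estimates δ from the group means.
    """
    rng = np.random.default_rng(seed)

    def run_group(group: str) -> list[float]:
        dens: list[float] = []
        while len(dens) < n_per_group:
            s = int(rng.integers(0, 2 ** 31))
            cfg = StackSimConfig(shape=shape, n_nuclei=1, group=group,
                                 delta=delta, seed=s)
            try:
                grid, _ = simulate_if_stack(cfg)
            except PlacementError:   # unlucky geometry draw: resample
                continue
            labels, nuclei = segment_nuclei(grid)
            _, foci = segment_foci(grid, 1, labels)
            df = densities_by_nucleus(foci, nuclei, "marker1", group,
                                      skip_excluded=False)
            dens.extend(df["density"].tolist()[: n_per_group - len(dens)])
        return dens

    control = run_group("control")
    treated = run_group("treated")
    return {
        "delta_true": delta,
        "delta_hat": marker_effect(control, treated),
        "mean_density_control": float(np.mean(control)),
        "mean_density_treated": float(np.mean(treated)),
        "n_per_group": n_per_group,
    }


def smlm_drift_and_area_experiment(
    seed: int = 0,
    n_frames: int = 2000,
    drift_nm_per_frame: tuple[float, float] = (0.5, 0.0),
    n_clusters: int = 12,
    cluster_radius_nm: float = 60.0,
    roi_half_nm: float = 500.0,
    threshold: float = 0.5,
) -> dict:
    """Drift recovery plus cluster-area comparison of two equal conditions.

    Two acquisitions with identical true cluster radius are simulated,
    drift-corrected, merged and rendered at tenfold upsampling; per-cluster
    areas are measured in 1 µm × 1 µm ROIs around the true cluster centres
    and compared with a two-sided rank-sum test. With equal true radii the
    areas should be statistically indistinguishable.
    """
    rng = np.random.default_rng(seed)

    def run_condition() -> tuple[float, list[float]]:
        cfg = SmlmSimConfig(
            n_frames=n_frames, n_clusters=n_clusters,
            cluster_radius_nm=cluster_radius_nm,
            drift_nm_per_frame=drift_nm_per_frame,
            seed=int(rng.integers(0, 2 ** 31)),
        )
        locs, truth = simulate_smlm(cfg)
        corrected, traj = correct_drift(locs)
        rms = float(np.sqrt(np.mean(
            (traj.dx - truth.drift["dx"].to_numpy()) ** 2
            + (traj.dy - truth.drift["dy"].to_numpy()) ** 2)))
        merged = merge_consecutive(corrected)
        img = render(merged, raw_pixel_nm=cfg.pixel_nm,
                     frame_shape=cfg.frame_shape)
        areas = []
        centres = truth.emitters.groupby("cluster")[["x", "y"]].mean()
        for c in centres.itertuples():
            roi = (c.x - roi_half_nm, c.x + roi_half_nm,
                   c.y - roi_half_nm, c.y + roi_half_nm)
            areas.append(cluster_area(img, roi, threshold).area_um2)
        return rms, areas

    rms_a, areas_a = run_condition()
    rms_b, areas_b = run_condition()
    _, p = rank_sum_test(areas_a, areas_b)
    return {
        "drift_rms_nm": max(rms_a, rms_b),
        "median_area_um2_a": float(np.median(areas_a)),
        "median_area_um2_b": float(np.median(areas_b)),
        "equal_radius_area_p": float(p),
    }


def aneuploidy_recovery_experiment(
    n_replicates: int = 200,
    n_per_group: int = 1200,
    rate_uninduced: float = 0.039,
    rate_induced: float = 0.063,
    seed: int = 0,
    alpha: float = 0.01,
) -> dict:
    """Replicate the instability-scoring pipeline on simulated populations.

    Each replicate draws an uninduced and an induced population, applies the
    S/G2 and volume exclusions, scores per-group instability rates and the
    chi-squared contrast, and records the percent increase. Reports the mean
    recovered increase and the fraction of replicates rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    pct, reject = [], 0
    for _ in range(n_replicates):
        s1, s2 = (int(v) for v in rng.integers(0, 2 ** 31, 2))
        un = simulate_ploidy_population(PloidySimConfig(
            n_nuclei=n_per_group, instability=rate_uninduced,
            group="uninduced", seed=s1))
        ind = simulate_ploidy_population(PloidySimConfig(
            n_nuclei=n_per_group, instability=rate_induced,
            group="induced", seed=s2))
        rep = instability_report(pd.concat([un, ind], ignore_index=True))
        pct.append(rep["percent_change"])
        reject += rep["p_value"] < alpha
    expected = 100.0 * (rate_induced - rate_uninduced) / rate_uninduced
    return {
        "expected_percent_increase": expected,
        "mean_percent_increase": float(np.mean(pct)),
        "sd_percent_increase": float(np.std(pct)),
        "rejection_fraction": reject / n_replicates,
        "n_replicates": n_replicates,
    }
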