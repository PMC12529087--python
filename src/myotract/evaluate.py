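"""Evaluation statistics: sampling uniformity, Bland-Altman agreement,
ICC(3,1), and the Monte-Carlo noise experiment.

The agreement analysis compares the pennation angle of each smoothed-tract
segment with the ground-truth pennation angle at the segment's voxel
(ground truth = angle between the true fiber direction and the central-axis
tangent at that slice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .phantom import (
    DWIStack,
    EncodingScheme,
    LabelVolume,
    OrientationField,
    PhantomSpec,
    add_noise,
)
from .quantify import (
    CentralAxis,
    fss_sample,
    ground_truth_alpha_map,
    quantify_tracts,
    segment_alphas,
    tract_length,
)
from .seeding import SeedSet, apo_seeds, build_apo_mesh, edge_seeds, vxl_seeds
from .tensorfit import wls_fit
from .tracking import (
    FilterCriteria,
    SmoothedStreamline,
    TrackOptions,
    filter_tracts,
    smooth,
    track_all,
)
from ._utils import to_mm

__all__ = [
    "SamplingStats",
    "AgreementStats",
    "MonteCarloResult",
    "sampling_stats",
    "bland_altman",
    "icc31",
    "collect_alpha_pairs",
    "monte_carlo",
    "run_tractography",
]


@dataclass
class SamplingStats:
    """Uniformity of muscle-volume sampling by fiber-tract points.

    The headline mean/SD/CV aggregate the slice-wise mean points/voxel
    across slices (the across-slice uniformity that farthest streamline
    sampling targets); ``voxel_*`` fields are computed directly over all
    mask voxels with zero counts included.  ``percent_filled`` always uses
    the full mask as denominator.
    """

    per_slice: pd.DataFrame  # columns: slice, mean, sd
    mean: float  # mean over slices of the slice-wise mean points/voxel
    sd: float  # SD (n-1) of the slice-wise means
    cv_percent: float
    voxel_mean: float  # over all mask voxels, zeros included
    voxel_sd: float
    voxel_cv_percent: float
    percent_filled: float

    def summary_row(self) -> dict:
        """Summary-table row: "mean (SD)" points/voxel, CV, % filled."""
        return {
            "points_per_voxel": f"{self.mean:.1f} ({self.sd:.1f})",
            "cv_percent": round(self.cv_percent, 1),
            "percent_filled": round(self.percent_filled, 1),
        }


@dataclass
class AgreementStats:
    """Bland-Altman mean difference / limits of agreement, plus ICC(3,1)."""

    mean_difference: float
    loa_low: float
    loa_high: float
    icc31: Optional[float] = None


@dataclass
class MonteCarloResult:
    """Noise-trial statistics of whole-muscle architecture means."""

    snr: float
    n_trials: int
    trial_means: pd.DataFrame  # columns: trial, length_mm, alpha_deg, kappa_per_m
    population_mean: dict
    ci_low: dict
    ci_high: dict
    n_failed: int = 0

    def table_row(self) -> dict:
        """"mean [low high]" formatting per property."""
        out = {}
        for k in ("length_mm", "alpha_deg", "kappa_per_m"):
            out[k] = (
                f"{self.population_mean[k]:.1f} "
                f"[{self.ci_low[k]:.1f} {self.ci_high[k]:.1f}]"
            )
        return out


def sampling_stats(
    smoothed: Sequence[SmoothedStreamline], muscle_mask: np.ndarray
) -> SamplingStats:
    """Count smoothed tract points per muscle voxel and summarize.

    Points are binned by nearest voxel.  Slice-wise statistics are over
    that slice's mask voxels (zeros included); the whole-muscle headline
    statistics aggregate the slice-wise means across slices, and the
    ``voxel_*`` statistics pool all mask voxels.  SD uses the sample (n-1)
    convention.  % filled is the percentage of mask voxels containing at
    least one point.
    """
    if not muscle_mask.any():
        raise ValueError("empty muscle mask")
    counts = np.zeros(muscle_mask.shape, dtype=np.int64)
    shape = np.array(muscle_mask.shape)
    for sm in smoothed:
        vox = round_half_up(sm.fitted_points)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        np.add.at(counts, tuple(vox[ok].T), 1)
    in_mask = counts[muscle_mask]
    v_mean = float(in_mask.mean())
    v_sd = float(in_mask.std(ddof=1)) if len(in_mask) > 1 else 0.0
    v_cv = 100.0 * v_sd / v_mean if v_mean > 0 else np.nan
    filled = 100.0 * float((in_mask > 0).sum()) / len(in_mask)
    rows = []
    for s in range(muscle_mask.shape[2]):
        msk = muscle_mask[:, :, s]
        if not msk.any():
            continue
        v = counts[:, :, s][msk]
        rows.append(
            {
                "slice": s,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            }
        )
    per_slice = pd.DataFrame(rows)
    sm_means = per_slice["mean"].to_numpy()
    mean = float(sm_means.mean())
    sd = float(sm_means.std(ddof=1)) if len(sm_means) > 1 else 0.0
    cv = 100.0 * sd / mean if mean > 0 else np.nan
    return SamplingStats(
        per_slice=per_slice,
        mean=mean,
        sd=sd,
        cv_percent=cv,
        voxel_mean=v_mean,
        voxel_sd=v_sd,
        voxel_cv_percent=v_cv,
        percent_filled=filled,
    )


def bland_altman(estimates: np.ndarray, truths: np.ndarray) -> AgreementStats:
    """Mean difference and 1.96-SD limits of agreement of (estimate - truth)."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if len(est) < 2 or len(est) != len(tru):
        raise ValueError("need >= 2 paired observations")
    d = est - tru
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        mean_difference=md, loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd
    )


def icc31(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Type (3,1) intraclass correlation: two-way mixed, single measure,
    consistency.

    ICC = (MS_rows - MS_error) / (MS_rows + (k-1) MS_error) with k = 2
    raters, from the standard two-way ANOVA decomposition.  Raises when the
    between-row variance is zero (ICC undefined).
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if len(est) < 3 or len(est) != len(tru):
        raise ValueError("need >= 3 paired observations")
    data = np.column_stack([est, tru])  # n rows (targets) x k raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("zero between-row variance: ICC undefined")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def collect_alpha_pairs(
    smoothed: Sequence[SmoothedStreamline],
    gt_alpha: np.ndarray,
    axis: CentralAxis,
    voxel_dims_mm,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment (estimated, ground-truth) pennation angle pairs.

    Segments whose midpoint voxel has no ground truth (outside the muscle)
    are dropped.
    """
    est_all, tru_all = [], []
    shape = np.array(gt_alpha.shape)
    for sm in smoothed:
        if len(sm.fitted_points) < 2:
            continue
        angles, vox = segment_alphas(sm.fitted_points, axis, voxel_dims_mm)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        angles, vox = angles[ok], vox[ok]
        tru = gt_alpha[vox[:, 0], vox[:, 1], vox[:, 2]]
        keep = np.isfinite(tru)
        est_all.append(angles[keep])
        tru_all.append(tru[keep])
    if not est_all:
        return np.empty(0), np.empty(0)
    return np.concatenate(est_all), np.concatenate(tru_all)


# ---------------------------------------------------------------------------
# pipeline helpers and the Monte-Carlo experiment


def make_seeds(
    scheme: str,
    labels: LabelVolume,
    mesh_shape: tuple[int, int] = (40, 40),
    vxl_stride: int = 2,
) -> SeedSet:
    """Build the seed set for one scheme (APO mesh default 40 x 40)."""
    if scheme == "APO":
        mesh = build_apo_mesh(labels, *mesh_shape)
        return apo_seeds(mesh, labels)
    if scheme == "VXL":
        return vxl_seeds(labels.muscle_mask, stride=vxl_stride)
    if scheme == "EDGE":
        return edge_seeds(labels.muscle_mask, labels.aponeurosis_mask)
    raise ValueError(f"unknown seeding scheme: {scheme}")


def run_tractography(
    tensors,
    labels: LabelVolume,
    seeds: SeedSet,
    opts: Optional[TrackOptions] = None,
    criteria: Optional[FilterCriteria] = None,
    n_keep: Optional[int] = None,
) -> list[SmoothedStreamline]:
    """Track, trim (voxel schemes), length-filter, smooth, and FSS-sample."""
    from .tracking import trim_aponeurosis

    criteria = criteria if criteria is not None else FilterCriteria()
    tracts = track_all(seeds, tensors, labels, opts)
    if seeds.scheme in ("VXL", "EDGE"):
        tracts = [trim_aponeurosis(t, labels.aponeurosis_mask) for t in tracts]
    lengths = np.array([tract_length(t.points, labels.voxel_dims_mm) for t in tracts])
    tracts, _, _ = filter_tracts(tracts, lengths, criteria)
    smoothed = [smooth(t) for t in tracts if len(t) > 1]
    if n_keep is not None and len(smoothed) > n_keep:
        pts_mm = [to_mm(sm.fitted_points, labels.voxel_dims_mm) for sm in smoothed]
        idx = fss_sample(pts_mm, n_keep)
        smoothed = [smoothed[i] for i in idx]
    return smoothed


def monte_carlo(
    clean_stack: DWIStack,
    scheme: EncodingScheme,
    labels: LabelVolume,
    seeds: SeedSet,
    axis: CentralAxis,
    snr: float,
    n_trials: int,
    root_seed: int,
    n_keep: Optional[int] = 500,
    opts: Optional[TrackOptions] = None,
    criteria: Optional[FilterCriteria] = None,
    ci_method: str = "percentile",
) -> MonteCarloResult:
    """Repeated noise trials of the full tractography pipeline.

    Per trial: add Gaussian noise (independent substream per trial), WLS
    tensor fit, track the given seeds, length-filter, smooth, FSS-sample,
    and record whole-muscle mean fiber length, pennation angle, and
    curvature.  Across trials, the population mean and a 95% CI of the
    trial means are reported (``ci_method``: "percentile" 2.5/97.5, or
    "normal" for mean +- 1.96 SD).  Trials with zero surviving tracts are
    counted and excluded.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rows = []
    n_failed = 0
    for trial in range(n_trials):
        noisy = add_noise(clean_stack, snr, root_seed, trial_index=trial)
        tensors = wls_fit(noisy, scheme, labels.tissue_mask)
        smoothed = run_tractography(tensors, labels, seeds, opts, criteria, n_keep)
        df = quantify_tracts(smoothed, axis, labels.voxel_dims_mm)
        if df.empty:
            n_failed += 1
            continue
        rows.append(
            {
                "trial": trial,
                "length_mm": df["length_mm"].mean(),
                "alpha_deg": df["alpha_mean_deg"].mean(),
                "kappa_per_m": df["kappa_mean_per_m"].mean(),
            }
        )
    trial_means = pd.DataFrame(rows)
    props = ["length_mm", "alpha_deg", "kappa_per_m"]
    pop = {p: float(trial_means[p].mean()) for p in props}
    if ci_method == "percentile":
        lo = {p: float(np.percentile(trial_means[p], 2.5)) for p in props}
        hi = {p: float(np.percentile(trial_means[p], 97.5)) for p in props}
    elif ci_method == "normal":
        sd = {p: float(trial_means[p].std(ddof=1)) for p in props}
        lo = {p: pop[p] - 1.96 * sd[p] for p in props}
        hi = {p: pop[p] + 1.96 * sd[p] for p in props}
    else:
        raise ValueError("ci_method must be 'percentile' or 'normal'")
    return MonteCarloResult(
        snr=snr,
        n_trials=n_trials,
        trial_means=trial_means,
        population_mean=pop,
        ci_low=lo,
        ci_high=hi,
        n_failed=n_failed,
    )
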