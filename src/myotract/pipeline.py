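"""End-to-end pipeline driver and run configuration.

``run_pipeline`` executes simulate/fit -> seed -> track -> filter ->
smooth -> FSS -> quantify -> evaluate for each requested seeding scheme and
writes volumes (NIfTI), the encoding table (bval/bvec), seeds and
streamlines (CSV + TRK), per-tract and summary tables (CSV), and a run log
capturing the configuration and seeds, so every run is reproducible from
its output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .evaluate import (
    bland_altman,
    collect_alpha_pairs,
    icc31,
    make_seeds,
    monte_carlo,
    run_tractography,
    sampling_stats,
)
from .phantom import (
    LabelVolume,
    PhantomSpec,
    add_noise,
    build_geometry,
    build_orientation_field,
    build_tensor_field,
    make_encoding,
    synthesize_dwi,
    DWIStack,
)
from .quantify import central_axis, ground_truth_alpha_map, quantify_tracts
from .tensorfit import wls_fit
from .tracking import FilterCriteria, TrackOptions

__all__ = ["RunConfig", "run_pipeline", "simulate_phantom"]


@dataclass
class RunConfig:
    """Pipeline configuration; mirrors the CLI flags one-to-one."""

    mode: str = "simulate"  # or "real"
    out_dir: str = "myotract_run"
    schemes: tuple[str, ...] = ("APO",)
    # simulate mode
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    snr: float = np.inf
    # real mode inputs
    dwi_path: Optional[str] = None
    encoding_prefix: Optional[str] = None
    muscle_mask_path: Optional[str] = None
    aponeurosis_mask_path: Optional[str] = None
    # analysis options
    mesh_shape: tuple[int, int] = (40, 40)
    vxl_stride: int = 2
    track: TrackOptions = field(default_factory=TrackOptions)
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    fss_sizes: tuple[Optional[int], ...] = (None, 1000, 500)
    n_trials: int = 0  # >0 enables the Monte-Carlo experiment
    mc_snrs: tuple[float, ...] = (39.0, 54.0)
    root_seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ValueError("mode must be 'simulate' or 'real'")
        if not self.schemes:
            raise ValueError("at least one seeding scheme must be selected")
        if self.mode == "real":
            for p in (self.dwi_path, self.muscle_mask_path, self.aponeurosis_mask_path):
                if p is None or not Path(p).exists():
                    raise ValueError(f"real mode requires existing input path: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = {
            k: v for k, v in dataclasses.asdict(self.spec).items()
            if k != "ellipse_semi_axes_schedule"
        }
        d["snr"] = None if np.isinf(self.snr) else self.snr
        return d


def simulate_phantom(spec: PhantomSpec, snr: float = np.inf, root_seed: int = 0):
    """Generate geometry, ground truth, encoding, and (noisy) DWI."""
    labels = build_geometry(spec)
    orient = build_orientation_field(labels, spec)
    tensors_true = build_tensor_field(orient, spec)
    scheme = make_encoding(spec.n_directions, spec.b_value, spec.rng_seed)
    stack = synthesize_dwi(tensors_true, scheme, labels.tissue_mask)
    noisy = add_noise(stack, snr, root_seed) if np.isfinite(snr) else stack
    return labels, orient, scheme, stack, noisy


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            spec = config.spec
            labels, orient, enc, clean, stack = simulate_phantom(
                spec, config.snr, config.root_seed
            )
            vd = labels.voxel_dims_mm
            mio.save_volume(out / "muscle_mask.nii.gz", labels.muscle_mask, vd)
            mio.save_volume(out / "aponeurosis_mask.nii.gz", labels.aponeurosis_mask, vd)
            mio.save_volume(out / "dwi.nii.gz", stack.signals, vd)
            mio.save_volume(out / "gt_eps1.nii.gz", np.nan_to_num(orient.eps1), vd)
            mio.save_volume(out / "gt_theta.nii.gz", np.nan_to_num(orient.theta_deg), vd)
            mio.save_volume(out / "gt_phi.nii.gz", np.nan_to_num(orient.phi_deg), vd)
            mio.save_encoding(out / "encoding", enc)
        else:
            stage = "load"
            arr, vd, _ = mio.load_volume(config.dwi_path)
            enc = mio.load_encoding(config.encoding_prefix)
            if arr.shape[-1] != enc.n_images:
                raise ValueError(
                    f"DWI volume count {arr.shape[-1]} does not match encoding "
                    f"table length {enc.n_images}"
                )
            stack = DWIStack(signals=arr, snr=np.nan)
            muscle, _, _ = mio.load_volume(config.muscle_mask_path)
            apo, _, _ = mio.load_volume(config.aponeurosis_mask_path)
            labels = LabelVolume(muscle > 0.5, apo > 0.5, vd)
            orient = None

        stage = "fit"
        tensors = wls_fit(stack, enc, labels.tissue_mask)
        mio.save_volume(out / "fa.nii.gz", np.nan_to_num(tensors.fa), labels.voxel_dims_mm)
        mio.save_volume(
            out / "evals.nii.gz", np.nan_to_num(tensors.evals), labels.voxel_dims_mm
        )

        stage = "central_axis"
        axis = central_axis(labels.muscle_mask, labels.voxel_dims_mm)
        gt_alpha = ground_truth_alpha_map(orient, axis) if orient is not None else None

        summary_rows = []
        sampling_rows = []
        for scheme_name in config.schemes:
            stage = f"seed[{scheme_name}]"
            seeds = make_seeds(
                scheme_name, labels, mesh_shape=config.mesh_shape, vxl_stride=config.vxl_stride
            )
            mio.seeds_to_csv(out / f"seeds_{scheme_name}.csv", seeds)
            for n_keep in config.fss_sizes:
                cond = "all" if n_keep is None else f"fss{n_keep}"
                stage = f"track[{scheme_name}/{cond}]"
                smoothed = run_tractography(
                    tensors, labels, seeds, config.track, config.filter, n_keep
                )
                tag = f"{scheme_name}_{cond}"
                mio.tracts_to_csv(
                    out / f"tracts_{tag}.csv", [sm.fitted_points for sm in smoothed]
                )
                mio.save_trk(
                    out / f"tracts_{tag}.trk",
                    [sm.fitted_points for sm in smoothed],
                    labels.voxel_dims_mm,
                    labels.shape,
                )
                stage = f"quantify[{scheme_name}/{cond}]"
                df = quantify_tracts(
                    smoothed,
                    axis,
                    labels.voxel_dims_mm,
                    with_gamma=(scheme_name == "APO"),
                )
                df.to_csv(out / f"architecture_{tag}.csv", index=False)
                stats = sampling_stats(smoothed, labels.muscle_mask)
                row = {
                    "scheme": scheme_name,
                    "condition": cond,
                    "n_tracts": len(smoothed),
                    **stats.summary_row(),
                }
                sampling_rows.append(row)
                srow = {
                    "scheme": scheme_name,
                    "condition": cond,
                    "length_mm": df["length_mm"].mean(),
                    "alpha_deg": df["alpha_mean_deg"].mean(),
                    "kappa_per_m": df["kappa_mean_per_m"].mean(),
                }
                if "gamma_deg" in df:
                    srow["gamma_deg"] = df["gamma_deg"].mean()
                    srow["beta_deg"] = df["beta_deg"].mean()
                if gt_alpha is not None:
                    est, tru = collect_alpha_pairs(
                        smoothed, gt_alpha, axis, labels.voxel_dims_mm
                    )
                    if len(est) >= 3:
                        ba = bland_altman(est, tru)
                        srow["alpha_mean_diff_deg"] = ba.mean_difference
                        srow["alpha_loa_low"] = ba.loa_low
                        srow["alpha_loa_high"] = ba.loa_high
                        srow["alpha_icc31"] = icc31(est, tru)
                summary_rows.append(srow)

        pd.DataFrame(sampling_rows).to_csv(out / "sampling_summary.csv", index=False)
        pd.DataFrame(summary_rows).to_csv(out / "architecture_summary.csv", index=False)

        if config.n_trials > 0 and config.mode == "simulate":
            stage = "montecarlo"
            mc_rows = []
            for scheme_name in config.schemes:
                seeds = make_seeds(
                    scheme_name, labels, mesh_shape=config.mesh_shape, vxl_stride=config.vxl_stride
                )
                for snr in config.mc_snrs:
                    res = monte_carlo(
                        clean,
                        enc,
                        labels,
                        seeds,
                        axis,
                        snr=snr,
                        n_trials=config.n_trials,
                        root_seed=config.root_seed,
                        n_keep=500,
                        opts=config.track,
                        criteria=config.filter,
                    )
                    mc_rows.append(
                        {"scheme": scheme_name, "snr": snr, **res.table_row()}
                    )
            pd.DataFrame(mc_rows).to_csv(out / "montecarlo_summary.csv", index=False)

        stage = "log"
        import myotract

        log = {
            "config": config.to_dict(),
            "version": getattr(myotract, "__version__", "unknown"),
            "root_seed": config.root_seed,
        }
        (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    except Exception as err:  # partial outputs stay on disk for inspection
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    return out
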