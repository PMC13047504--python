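"""End-to-end orchestration: simulate (or load) volumes, fit maps, build the
cohort metrics table, run the statistics, write tables / figures / manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io
from .acquisition import AcquisitionGrid, SignalArray, default_grid
from .fitting import (CouplingMetrics, coupling_slopes, estimate_snr,
                      fit_mono_adc, fit_mono_r2, fit_parameter_maps,
                      roi_mean_series)
from .stats import CohortStatistics, cohort_statistics
from .synth import (CohortConfig, default_region_table, iter_subject_volumes,
                    noiseless_subject, simulate_cohort)

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "render_report",
           "signal_coupling_metrics", "analyze_labelled_volume",
           "build_cohort_table", "measure_worst_case_snr"]

logger = logging.getLogger("drcoupling")


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run.

    ``mode="simulate"`` generates the synthetic cohort (fast ROI-only mode
    unless ``write_volumes``); ``mode="analyze"`` reads previously written
    volumes + label maps + sidecar from ``input_dir``.
    """

    mode: str = "simulate"
    out_dir: Path = Path("drcoupling_run")
    input_dir: Path | None = None
    seed: int = 42
    n_subjects: int = 57
    #: default: the study sex ratio (24/57) applied to n_subjects
    n_male: int | None = None
    age_min: float = 10.0
    age_max: float = 73.0
    age_sampler: str = "uniform"
    target_snr: float = 63.8
    noise: bool = True
    jitter_scale: float = 1.0
    roi_only: bool = True
    write_volumes: bool = False
    alpha: float = 0.05
    make_figures: bool = True
    log_level: str = "INFO"

    @field_validator("mode")
    @classmethod
    def _mode_known(cls, v):
        if v not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v):
        if not 0 < v < 1:
            raise ValueError("alpha must be in (0, 1)")
        return v

    def cohort_config(self) -> CohortConfig:
        n_male = self.n_male
        if n_male is None:
            n_male = round(self.n_subjects * 24 / 57)
        return CohortConfig(
            n_subjects=self.n_subjects,
            n_male=n_male,
            age_range=(self.age_min, self.age_max),
            age_sampler=self.age_sampler,
            target_snr=self.target_snr,
            noise=self.noise,
            jitter_scale=self.jitter_scale,
            master_seed=self.seed,
        )


@dataclass
class RunSummary:
    """Everything a run produced, with the on-disk paths."""

    config: RunConfig
    cohort_table: pd.DataFrame
    statistics: CohortStatistics
    snr_worst_case: float | None
    out_dir: Path


# ---------------------------------------------------------------------------
# metric extraction

def signal_coupling_metrics(signal: SignalArray) -> CouplingMetrics:
    """Coupling metrics of one ROI-mean signal array: mono-exponential ADC
    per TE and R2 per b, then the slope regressions."""
    grid = signal.grid
    adcs = [fit_mono_adc(signal.decay_over_b(i), grid.b_array).rate
            for i in range(len(grid.tes))]
    r2s = [fit_mono_r2(signal.decay_over_te(j), grid.te_array).rate
           for j in range(len(grid.bvals))]
    return coupling_slopes(adcs, grid.te_array, r2s, grid.b_array)


def analyze_labelled_volume(volume5d: np.ndarray, labels: np.ndarray,
                            grid: AcquisitionGrid, region_names) -> dict:
    """Per-region coupling metrics from a labelled 5D volume.

    Label value ``i + 1`` corresponds to ``region_names[i]``.  A region name
    with no labelled voxels aborts with an error naming it.
    """
    metrics = {}
    mask = labels > 0
    maps = fit_parameter_maps(volume5d, grid, mask)
    for li, name in enumerate(region_names, start=1):
        roi = labels == li
        if not roi.any():
            raise ValueError(f"ROI label for region '{name}' is missing from the label map")
        mean_adc, mean_r2, n = roi_mean_series(maps, roi)
        metrics[name] = coupling_slopes(mean_adc, grid.te_array, mean_r2, grid.b_array)
    return metrics


def build_cohort_table(dataset) -> pd.DataFrame:
    """Cohort metrics table from a fast-mode CohortDataset."""
    rows = []
    for row in dataset.subjects.itertuples(index=False):
        for region in dataset.config.regions:
            m = signal_coupling_metrics(dataset.signals[(row.subject_id, region.name)])
            rows.append({"subject_id": row.subject_id, "age": row.age,
                         "sex": row.sex, "region": region.name,
                         "k_adc_te": m.k_adc_te, "k_r2_b": m.k_r2_b,
                         "r2_b0": m.r2_b0})
    return pd.DataFrame(rows)


def measure_worst_case_snr(config: CohortConfig, seed: int | None = None) -> float:
    """Measured SNR of the most attenuated image of one mid-cohort subject.

    Builds a noisy phantom volume for a jitter-free subject at the cohort
    mean age and applies the background-Rayleigh SNR estimator with the
    reference region (putamen if present) as signal mask and the phantom
    background as noise mask.
    """
    from .synth import add_rician_noise, build_phantom, sigma_for_target_snr

    subject = noiseless_subject(config, config.mean_age)
    vol, labels = build_phantom(subject, config.grid, config.regions)
    rng = np.random.default_rng(config.master_seed if seed is None else seed)
    noisy = add_rician_noise(vol, sigma_for_target_snr(config), config.grid.nex_array, rng)
    names = [r.name for r in config.regions]
    ref = names.index("putamen") + 1 if "putamen" in names else 1
    worst = noisy[..., -1, -1]  # max TE, max b
    return estimate_snr(worst, labels == ref, labels == 0)


# ---------------------------------------------------------------------------
# orchestration

def _write_manifest(out_dir: Path, config: RunConfig) -> None:
    cfg = json.loads(config.model_dump_json())
    payload = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
    }
    io.save_json(out_dir / "manifest.json", payload)


def _versions() -> dict:
    import nibabel
    import scipy
    import statsmodels

    from . import __version__
    return {"drcoupling": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "nibabel": nibabel.__version__}


def _simulate_table(config: RunConfig, out_dir: Path) -> tuple:
    cohort = config.cohort_config()
    if config.roi_only and not config.write_volumes:
        t0 = time.perf_counter()
        dataset = simulate_cohort(cohort)
        logger.info("simulated %d subjects (fast ROI mode) in %.1f s",
                    config.n_subjects, time.perf_counter() - t0)
        io.save_table(out_dir / "subjects.csv", dataset.subjects)
        return build_cohort_table(dataset), cohort

    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(exist_ok=True)
    names = [r.name for r in cohort.regions]
    io.save_grid_sidecar(vol_dir / "grid.json", cohort.grid,
                         extra={"region_names": names})
    rows, subj_rows = [], []
    for subject, noisy, labels in iter_subject_volumes(cohort):
        sid = subject.subject_id
        t0 = time.perf_counter()
        io.save_volume(vol_dir / f"sub-{sid:03d}_dwi.nii.gz", noisy, cohort.grid)
        io.save_labels(vol_dir / f"sub-{sid:03d}_labels.nii.gz", labels, cohort.grid)
        metrics = analyze_labelled_volume(noisy, labels, cohort.grid, names)
        for name, m in metrics.items():
            rows.append({"subject_id": sid, "age": subject.age, "sex": subject.sex,
                         "region": name, "k_adc_te": m.k_adc_te,
                         "k_r2_b": m.k_r2_b, "r2_b0": m.r2_b0})
        subj_rows.append({"subject_id": sid, "age": subject.age, "sex": subject.sex})
        logger.info("subject %03d: simulated, written and fitted in %.1f s",
                    sid, time.perf_counter() - t0)
    io.save_table(out_dir / "subjects.csv", pd.DataFrame(subj_rows))
    return pd.DataFrame(rows), cohort


def _analyze_table(config: RunConfig) -> tuple:
    in_dir = Path(config.input_dir)
    vol_dir = in_dir / "volumes" if (in_dir / "volumes").exists() else in_dir
    grid = io.load_grid_sidecar(vol_dir / "grid.json")
    sidecar = io.load_json(vol_dir / "grid.json")
    names = sidecar.get("region_names", list(np.arange(1, 100).astype(str)))
    subjects = io.load_table(in_dir / "subjects.csv")
    rows = []
    for row in subjects.itertuples(index=False):
        sid = int(row.subject_id)
        vol = io.load_volume(vol_dir / f"sub-{sid:03d}_dwi.nii.gz", grid)
        labels = io.load_labels(vol_dir / f"sub-{sid:03d}_labels.nii.gz")
        t0 = time.perf_counter()
        metrics = analyze_labelled_volume(vol, labels, grid, names)
        for name, m in metrics.items():
            rows.append({"subject_id": sid, "age": row.age, "sex": row.sex,
                         "region": name, "k_adc_te": m.k_adc_te,
                         "k_r2_b": m.k_r2_b, "r2_b0": m.r2_b0})
        logger.info("subject %03d: fitted in %.1f s", sid, time.perf_counter() - t0)
    return pd.DataFrame(rows), None


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute a full run and write all artifacts under ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        table, cohort = _simulate_table(config, out_dir)
    else:
        if config.input_dir is None:
            raise ValueError("mode='analyze' requires input_dir")
        table, cohort = _analyze_table(config)

    io.save_table(out_dir / "cohort_metrics.csv", table)
    stats = cohort_statistics(table, alpha=config.alpha)
    io.save_table(out_dir / "correlations.csv", stats.correlations)
    io.save_table(out_dir / "linear_models.csv", stats.linear_models)
    io.save_table(out_dir / "quadratic.csv", stats.quadratic)

    snr = None
    if config.mode == "simulate" and config.noise:
        snr = measure_worst_case_snr(config.cohort_config())
        logger.info("worst-case SNR (max TE, max b): %.1f", snr)

    summary = RunSummary(config, table, stats, snr, out_dir)
    _write_report_text(summary)
    _write_manifest(out_dir, config)
    if config.make_figures:
        render_report(summary)
    return summary


def _write_report_text(summary: RunSummary) -> None:
    lines = ["drcoupling run report", "=" * 40, ""]
    if summary.snr_worst_case is not None:
        lines.append(f"worst-case SNR (max TE, max b): {summary.snr_worst_case:.1f}")
        lines.append("")
    lines.append("Per-region mean R2_b=0 (1/ms):")
    means = summary.cohort_table.groupby("region")["r2_b0"].agg(["mean", "std", "count"])
    for region, row in means.iterrows():
        lines.append(f"  {region:20s} {row['mean']:.4f} +- {row['std']:.4f} (n={int(row['count'])})")
    lines.append("")
    lines.append("Correlations (Pearson r, BH-FDR q):")
    for _, row in summary.statistics.correlations.iterrows():
        lines.append(f"  {row['region']:20s} {row['x']:9s} vs {row['y']:6s} "
                     f"r={row['r']:+.2f} q={row['q']:.2g}")
    lines.append("")
    lines.append("Sex covariate (linear model p):")
    for _, row in summary.statistics.linear_models.iterrows():
        lines.append(f"  {row['region']:20s} {row['metric']:9s} p_sex={row['p_sex']:.3f}")
    lines.append("")
    lines.append("Quadratic age check (q after FDR; keep if q < alpha):")
    for _, row in summary.statistics.quadratic.iterrows():
        lines.append(f"  {row['region']:20s} {row['metric']:9s} "
                     f"q_age2={row['q_age2']:.3f} keep={bool(row['keep_quadratic'])}")
    (summary.out_dir / "report.txt").write_text("\n".join(lines) + "\n")


def regression_line(lm_row, xs: np.ndarray) -> np.ndarray:
    """The group-level fit line drawn in the report figures, computed from
    the linear-models table row (never refitted in the renderer)."""
    return lm_row["beta_const"] + lm_row["beta_age"] * np.asarray(xs, float)


def render_report(summary: RunSummary) -> list:
    """Scatter figures: each metric against age and against R2_b=0, one
    panel per region, with the group-level regression line (slope and
    intercept straight from the linear-models table; no refitting)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = summary.cohort_table
    if table.empty:
        raise ValueError("cannot render a report for an empty cohort")
    regions = list(dict.fromkeys(table["region"]))
    lm = summary.statistics.linear_models
    corr = summary.statistics.correlations
    paths = []
    for metric, label in (("k_adc_te", "k_ADC/TE (mm$^2$/s$^2$)"),
                          ("k_r2_b", "k_R2/b (mm$^2$/s$^2$)"),
                          ("r2_b0", "R2$_{b=0}$ (1/ms)")):
        fig, axes = plt.subplots(1, len(regions), figsize=(4 * len(regions), 3.4),
                                 sharey=True, squeeze=False)
        for ax, region in zip(axes[0], regions):
            d = table[table["region"] == region]
            ax.scatter(d["age"], d[metric], s=14,
                       c=np.where(d["sex"] == 1, "tab:blue", "tab:red"))
            if metric in ("k_adc_te", "k_r2_b"):
                row = lm[(lm["region"] == region) & (lm["metric"] == metric)].iloc[0]
                xs = np.array([d["age"].min(), d["age"].max()])
                ax.plot(xs, regression_line(row, xs), "k-", lw=1)
                crow = corr[(corr["region"] == region) & (corr["x"] == metric)
                            & (corr["y"] == "age")].iloc[0]
                ax.set_title(f"{region}\nr={crow['r']:+.2f}, q={crow['q']:.2g}", fontsize=9)
            else:
                crow = corr[(corr["region"] == region) & (corr["x"] == "r2_b0")].iloc[0]
                ax.set_title(f"{region}\nr={crow['r']:+.2f}, q={crow['q']:.2g}", fontsize=9)
            ax.set_xlabel("age (years)")
        axes[0][0].set_ylabel(label)
        fig.tight_layout()
        path = summary.out_dir / f"fig_{metric}_vs_age.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
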