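"""Box-plot summary statistics, figures and the pipeline orchestrator.

Box statistics follow the R conventions: quartiles by the R-default type-7
quantile rule (linear interpolation, numpy's default percentile), whiskers at
the most extreme observations within 1.5 x IQR of the quartiles, and notch
half-width 1.58 x IQR / sqrt(n) approximating a 95% confidence interval for
the median — so non-overlapping notches give roughly 95% confidence that two
medians differ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import compaction_model, colocalization, ring_geometry, synthetic_data
from .config import merged_config
from .image_io import write_manifest, write_roiset, write_stack


@dataclass(frozen=True)
class BoxStats:
    """Notched-box-plot summary of one sample."""

    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    notch_half_width: float
    n: int


def boxplot_stats(values) -> BoxStats:
    """R-style box statistics (type-7 quartiles, 1.5 IQR whiskers, notches)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])  # linear = R type 7
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    whisker_low = float(inside.min()) if inside.size else float(q1)
    whisker_high = float(inside.max()) if inside.size else float(q3)
    outliers = tuple(float(v) for v in np.sort(values[(values < lo_fence) | (values > hi_fence)]))
    notch = 1.58 * iqr / math.sqrt(values.size)
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
        notch_half_width=float(notch),
        n=int(values.size),
    )


def notch_overlap(a: BoxStats, b: BoxStats) -> str:
    """'distinct' iff the median +/- notch intervals are disjoint."""
    a_lo, a_hi = a.median - a.notch_half_width, a.median + a.notch_half_width
    b_lo, b_hi = b.median - b.notch_half_width, b.median + b.notch_half_width
    return "distinct" if (a_hi < b_lo or b_hi < a_lo) else "not-distinct"


def _bxp_dict(stats: BoxStats, label: str) -> dict:
    return {
        "label": label,
        "med": stats.median,
        "q1": stats.q1,
        "q3": stats.q3,
        "whislo": stats.whisker_low,
        "whishi": stats.whisker_high,
        "fliers": list(stats.outliers),
        "cilo": stats.median - stats.notch_half_width,
        "cihi": stats.median + stats.notch_half_width,
    }


def notched_boxplot_figure(groups: dict[str, np.ndarray], ylabel: str, path: Path) -> None:
    """Save a notched box plot of named samples (our own statistics, not mpl's)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 4.0))
    ax.bxp(
        [_bxp_dict(boxplot_stats(v), k) for k, v in groups.items()],
        shownotches=True,
    )
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline orchestration


def run_pipeline(config: dict | None, seed: int, outdir: str | Path) -> Path:
    """Execute the configured stages simulate -> coloc -> rings -> compaction
    -> report, writing CSVs, figures, JSON and a reproducibility manifest.

    Any stage failure halts the run with the stage named.  Identical config
    and seed give identical tabular outputs.
    """
    cfg = merged_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    state: dict = {}

    def _stage(name, fn):
        if not stages.get(name, False):
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - halt with the stage named
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    def do_simulate():
        sc = cfg["scene"]
        noise = synthetic_data.NoiseModel(
            photon_scale=cfg["noise"]["photon_scale"],
            read_sigma=cfg["noise"]["read_sigma"],
            background=cfg["noise"]["background"],
        )
        ds = synthetic_data.simulate_two_channel_dataset(
            n_rings=sc["n_rings"],
            diameter_mean=sc["diameter_mean_nm"],
            diameter_sd=sc["diameter_sd_nm"],
            coloc_mixing=sc["coloc_mixing"],
            canvas_shape=tuple(sc["canvas_shape"]),
            voxel_size=tuple(sc["voxel_size_nm"]),
            sigma_xy=cfg["blur"]["sigma_xy_nm"],
            sigma_z=cfg["blur"]["sigma_z_nm"],
            noise=noise,
            jitter_sd=sc["jitter_sd_nm"],
            amplitude=sc["amplitude"],
            tube_sigma=sc["tube_sigma_nm"],
            seed=seed,
        )
        state["dataset"] = ds
        sim_dir = outdir / "simulated"
        sim_dir.mkdir(exist_ok=True)
        write_stack(ds.ch1, sim_dir / "ch1.ome.tif")
        write_stack(ds.ch2, sim_dir / "ch2.ome.tif")
        write_roiset(ds.rois, sim_dir / "rois.tif")
        synthetic_data.rings_to_json(ds.scene.rings["ch1"], sim_dir / "truth_ch1.json")
        synthetic_data.rings_to_json(ds.scene.rings["ch2"], sim_dir / "truth_ch2.json")

    def do_coloc():
        ds = state["dataset"]
        table = colocalization.roi_colocalization(
            ds.ch1,
            ds.ch2,
            ds.rois,
            n_perm=cfg["coloc"]["n_perm"],
            seed=seed,
            block_nm=cfg["coloc"]["block_nm"],
        )
        table.to_csv(outdir / "coloc.csv", index=False)
        state["coloc"] = table

    def do_rings():
        ds = state["dataset"]
        psf = None
        if cfg["rings"]["psf_correction"]:
            psf = (cfg["blur"]["sigma_xy_nm"], cfg["blur"]["sigma_z_nm"])
        measurements = ring_geometry.measure_ring_diameters(
            ds.ch1,
            ds.rois.nucleolus,
            min_voxels=cfg["rings"]["min_voxels"],
            profile_length_nm=cfg["rings"]["profile_length_nm"],
            psf_sigma=psf,
        )
        frame = ring_geometry.measurements_to_frame(measurements)
        frame.to_csv(outdir / "rings.csv", index=False)
        state["measurements"] = measurements
        accepted = [m for m in measurements if m.accepted]
        if accepted:
            state["summary"] = ring_geometry.summarize_diameters(measurements)

    def do_compaction():
        cc = cfg["compaction"]
        diameter = cfg["scene"]["diameter_mean_nm"]
        source = "configured population mean"
        if "summary" in state:
            diameter = state["summary"].mean
            source = "measured population mean"
        result = compaction_model.compaction_summary(
            compaction_model.CompactionInput(
                ring_diameter=diameter,
                region_bp=cc["region_bp"],
                nm_per_nt=cc["nm_per_nt"],
            ),
            compaction_range=tuple(cc["compaction_range"]),
        )
        payload = {"ring_diameter_nm": diameter, "diameter_source": source}
        payload.update(asdict(result))
        (outdir / "compaction.json").write_text(json.dumps(payload, indent=2) + "\n")
        state["compaction"] = result

    def do_report():
        if "measurements" in state:
            accepted = [m for m in state["measurements"] if m.accepted]
            if accepted:
                per_profile = np.concatenate([np.asarray(m.distances) for m in accepted])
                notched_boxplot_figure(
                    {"ring diameter": per_profile},
                    "peak-to-peak distance (nm)",
                    outdir / "ring_diameters_boxplot.png",
                )
        if "coloc" in state:
            table = state["coloc"].dropna(subset=["pcc"])
            if len(table):
                notched_boxplot_figure(
                    {row.roi: np.array([row.pcc, row.m1, row.m2, row.moc]) for row in table.itertuples()},
                    "colocalization coefficients",
                    outdir / "coloc_overview.png",
                )
        write_manifest(outdir, seed, cfg)

    _stage("simulate", do_simulate)
    _stage("coloc", do_coloc)
    _stage("rings", do_rings)
    _stage("compaction", do_compaction)
    _stage("report", do_report)
    return outdir
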