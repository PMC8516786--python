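"""File formats, experiment runners and run metadata.

Trace CSV layout: columns ``t_s, dev_h_deg, dev_v_deg, pupil, valid`` with a
mandatory header; missing values are empty fields.  Numeric table output is
serialized with 9 significant digits so reruns are byte-identical.
Existing output files are never silently overwritten unless ``force``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import optics
from .signal import (FilterConfig, PSAModel, SignalTrace)

log = logging.getLogger("psakit")

FLOAT_FMT = "%.9g"

__all__ = [
    "read_trace",
    "write_trace",
    "write_table",
    "load_config",
    "run_simulation_experiment",
    "run_psa_workflow",
]


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True/--force to "
                              "overwrite")


def read_trace(path, rate: float | None = None,
               pupil_unit: str = "mm") -> SignalTrace:
    """Read a trace CSV (``t_s, dev_h_deg, dev_v_deg, pupil, valid``)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trace file")
    return SignalTrace.from_dataframe(df, rate=rate, pupil_unit=pupil_unit)


def write_trace(trace: SignalTrace, path, force: bool = False) -> Path:
    path = Path(path)
    _check_overwrite(path, force)
    trace.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT,
                                na_rep="")
    return path


def write_table(df: pd.DataFrame, path, force: bool = False) -> Path:
    path = Path(path)
    _check_overwrite(path, force)
    df.to_csv(path, index=False, float_format=FLOAT_FMT, na_rep="")
    return path


def load_config(path) -> dict:
    """Read a flat key/value config file (YAML subset)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping of key: value pairs")
    return cfg


def _write_metadata(outdir: Path, name: str, payload: dict,
                    force: bool) -> None:
    path = outdir / name
    _check_overwrite(path, force)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------


def run_simulation_experiment(outdir,
                              geometry: optics.EyeGeometry | None = None,
                              camera: optics.CameraModel | None = None,
                              viewing_angles=optics.DEFAULT_VIEWING_ANGLES,
                              pupil_grid=optics.DEFAULT_PUPIL_GRID,
                              d_cal: float = 4.0, lut_step: float = 0.001,
                              variants: Sequence[str] = ("spherical",
                                                         "ellipsoidal"),
                              plots: bool = False, force: bool = False,
                              ) -> dict[str, optics.PsaSimResult]:
    """Run the optical-PSA sweep for both eye-model variants and write
    deviation and slope tables (plus optional figures) to ``outdir``.

    Per variant: ``deviation_<variant>.csv`` has one row per
    (viewing angle, pupil diameter) cell; ``slopes_<variant>.csv`` one row
    per angle.  Deterministic: reruns produce identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = geometry or optics.EyeGeometry()
    camera = camera or optics.CameraModel()
    results: dict[str, optics.PsaSimResult] = {}
    for variant in variants:
        if variant == "spherical":
            geo = geometry
        elif variant == "ellipsoidal":
            geo = optics.ellipsoidal_variant(base=geometry)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        log.info("simulating %s variant (lut step %g deg)", variant, lut_step)
        res = optics.simulate_psa(geo, camera, viewing_angles=viewing_angles,
                                  pupil_grid=pupil_grid, d_cal=d_cal,
                                  lut_step=lut_step)
        results[variant] = res
        write_table(res.to_frame(), outdir / f"deviation_{variant}.csv",
                    force=force)
        slopes = pd.DataFrame({
            "viewing_angle_deg": res.viewing_angles,
            "psa_slope_deg_per_mm": res.slopes,
            "intercept_deg": res.intercepts,
        })
        write_table(slopes, outdir / f"slopes_{variant}.csv", force=force)
        if plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            axes = res.plot()
            fig = axes[0].figure
            fig.tight_layout()
            path = outdir / f"psa_{variant}.png"
            _check_overwrite(path, force)
            fig.savefig(path, dpi=120)
            plt.close(fig)
    _write_metadata(outdir, "simulation_meta.json", {
        "d_cal_mm": d_cal,
        "lut_step_deg": lut_step,
        "viewing_angles_deg": list(map(float, viewing_angles)),
        "pupil_grid_mm": list(map(float, pupil_grid)),
        "camera_distance_mm": camera.pinhole_distance,
        "variants": list(variants),
    }, force)
    return results


def run_psa_workflow(trace_files: Sequence, outdir,
                     component: str = "horizontal",
                     filter_config: FilterConfig | None = None,
                     mm_per_unit: float | None = None,
                     force: bool = False) -> pd.DataFrame:
    """Fit the PSA on each trace file and write curve + summary tables.

    The per-trace pipeline runs filter -> median centering -> decile curve ->
    slope.  Writes ``<stem>_curve.csv`` (seven rows) per trace and one
    ``psa_summary.csv``; returns the summary frame.  Filtering statistics
    (velocity threshold, samples removed) are logged per trace so the 2-SD
    step is auditable.
    """
    if not trace_files:
        raise ValueError("no trace files given")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in trace_files:
        path = Path(path)
        trace = read_trace(path,
                           pupil_unit="mm" if mm_per_unit is None else "au")
        if mm_per_unit is not None:
            from .signal import convert_pupil_units

            trace = convert_pupil_units(trace, mm_per_unit)
        model = PSAModel(trace, component=component,
                         filter_config=filter_config)
        res = model.fit()
        fs = res.filter_stats
        log.info("%s: velocity threshold %.6g (mean %.6g, sd %.6g); "
                 "masked %d by velocity + %d by padding; data loss %.4f",
                 path.name, fs.threshold, fs.velocity_mean, fs.velocity_sd,
                 fs.n_masked_velocity, fs.n_masked_pad, res.data_loss)
        write_table(res.curve_frame(), outdir / f"{path.stem}_curve.csv",
                    force=force)
        rows.append({
            "trace": path.name,
            "component": component,
            "slope_deg_per_mm": res.slope,
            "intercept_deg": res.intercept,
            "slope_se_deg_per_mm": res.slope_se,
            "data_loss": res.data_loss,
            "velocity_threshold": fs.threshold,
            "n_masked_velocity": fs.n_masked_velocity,
            "n_masked_pad": fs.n_masked_pad,
        })
    summary = pd.DataFrame(rows)
    write_table(summary, outdir / "psa_summary.csv", force=force)
    return summary
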