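"""Staged pipeline: simulate → reconstruct → evaluate, from one config.

Each stage reads its inputs from the output directory (or from the
in-memory results of an earlier stage in the same call), derives its own
random stream from the global seed, writes its artifacts, and contributes
to one machine-readable run report.  Re-running with the same config and
seed reproduces every output.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import io as fio
from .config import RunConfig
from .evaluate import (
    background_ripple,
    element_contrast,
    line_profile,
    profile_for_element,
    resolvable,
    rmse_complex,
    smallest_resolved_period,
)
from .experiments import _blank_slices, stacked_bar_chart
from .recon import ReconConfig, auto_upsampling_factor, reconstruct
from .samples import phase_object
from .simulate import draw_factors, normalize_stack, simulate_stack
from .system import illumination_na, make_plan, overlap_ratio

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

STAGES = ("simulate", "reconstruct", "evaluate")


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % 2**31)


def _build_sample(config: RunConfig, shape: tuple[int, int], pitch_um: float, seed: int):
    s = config.sample
    if s.kind == "bar_chart":
        return stacked_bar_chart(
            s.periods_um, shape=shape, pitch_um=pitch_um, n_bars=s.n_bars
        )
    return phase_object(
        s.feature_scale_um, s.max_phase_rad, shape=shape, pitch_um=pitch_um, seed=seed
    )


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = STAGES,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Execute the requested stages in order and return the run report."""
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; choose from {STAGES}")
    stages = [st for st in STAGES if st in stages]
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sys = config.optics.build()
    geom = config.geometry.build()
    cam = config.camera.build()
    logger.info(
        "illumination NA axial=%.3f radial=%.3f, adjacent overlap=%.3f",
        illumination_na(geom, "axial"),
        illumination_na(geom, "radial"),
        overlap_ratio(sys, geom),
    )

    report: dict[str, Any] = {
        "config": config.model_dump(mode="json"),
        "stages": {},
        "outputs": {},
    }
    stack_path = out / "stack.tiff"

    for stage in stages:
        t0 = time.perf_counter()
        seed = _stage_seed(config.seed, stage)

        if stage == "simulate":
            plan = make_plan(
                geom,
                max_ring=config.plan.max_ring,
                exposure_map=config.plan.exposure_map,
                duty_cycle=config.plan.duty_cycle,
                order=config.plan.order,
            )
            max_ring = config.plan.max_ring or geom.half_extent
            factor = auto_upsampling_factor(sys, geom, max_ring=max_ring)
            n_lr = sys.sensor_shape[0]
            truth = _build_sample(
                config, (n_lr * factor, n_lr * factor), sys.object_pixel_um / factor, seed
            )
            rng = np.random.default_rng(seed)
            factors = draw_factors(plan, config.sim.factors_sigma, seed=rng.integers(2**31))
            stack = simulate_stack(
                truth, sys, geom, plan, factors, cam, seed=rng.integers(2**31)
            )
            fio.write_stack(stack, stack_path)
            fio.write_field(truth, out, prefix="truth")
            fio.write_factors_csv(stack.metadata, factors, out / "true_factors.csv")
            report["stages"]["simulate"] = {
                "n_images": len(stack),
                "upsampling_factor": factor,
                "seed": seed,
            }
            report["outputs"]["stack"] = str(stack_path)

        elif stage == "reconstruct":
            if not stack_path.exists():
                raise FileNotFoundError(
                    f"reconstruct stage requires the simulated stack at {stack_path}"
                )
            stack = fio.read_stack(stack_path)
            norm = normalize_stack(stack, cam)
            cfg = ReconConfig(
                upsampling_factor=config.recon.upsampling_factor,
                max_sweeps=config.recon.max_sweeps,
                rel_tol=config.recon.rel_tol,
                update_order=config.recon.update_order,
                seed=seed,
            )
            sa_cfg = config.sa.build(seed=seed) if config.recon.sa_enabled else None
            result = reconstruct(norm, sys, geom, cfg, sa=sa_cfg)
            fio.write_field(result.hr_field, out, prefix="recon")
            mag = np.log1p(np.abs(result.hr_spectrum.data)).astype(np.float32)
            import tifffile

            tifffile.imwrite(out / "spectrum_magnitude.tiff", mag)
            fio.write_trace_csv(result.trace, out / "trace.csv")
            fio.write_factors_csv(norm.metadata, result.factors, out / "recovered_factors.csv")
            report["stages"]["reconstruct"] = {
                "sweeps_run": result.sweeps_run,
                "final_cost": result.trace[-1] if result.trace else None,
                "sa_enabled": config.recon.sa_enabled,
                "seed": seed,
            }
            report["outputs"]["recon"] = str(out / "recon_amplitude.tiff")

        elif stage == "evaluate":
            recon_sidecar = out / "recon.json"
            if not recon_sidecar.exists():
                raise FileNotFoundError(
                    f"evaluate stage requires a reconstruction at {recon_sidecar}"
                )
            recon = fio.read_field(out, prefix="recon")
            truth_sidecar = out / "truth.json"
            truth = fio.read_field(out, prefix="truth") if truth_sidecar.exists() else None
            min_contrast = config.evaluation.min_contrast
            summary: dict[str, Any] = {}
            rows = ["period_um,contrast,resolved"]
            chart_meta = truth.meta if truth is not None else {}
            if chart_meta.get("elements"):
                for el in chart_meta["elements"]:
                    contrast = element_contrast(recon.intensity, recon.pixel_pitch_um, el)
                    prof = line_profile(
                        recon.intensity, profile_for_element(el), recon.pixel_pitch_um
                    )
                    ok = resolvable(prof, el["n_bars"], min_contrast)
                    rows.append(f"{el['period_um']},{contrast:.6g},{ok}")
                summary["smallest_resolved_um"] = smallest_resolved_period(
                    recon, chart_meta, min_contrast
                )
            if chart_meta.get("blank_region_um"):
                summary["background_ripple"] = background_ripple(
                    recon.intensity, _blank_slices(chart_meta, recon.pixel_pitch_um)
                )
            if truth is not None and truth.shape == recon.shape:
                summary["rmse_complex"] = rmse_complex(recon, truth)
            (out / "metrics.csv").write_text("\n".join(rows) + "\n")
            fio.write_json(summary, out / "summary.json")
            report["stages"]["evaluate"] = {**summary, "seed": seed}
            report["outputs"]["summary"] = str(out / "summary.json")

        report["stages"][stage]["elapsed_s"] = round(time.perf_counter() - t0, 3)

    fio.write_json(report, out / "report.json")
    return report
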