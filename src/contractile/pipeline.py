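"""End-to-end pipeline: simulate -> demux -> focus -> metrics -> beats -> overlay.

Driven by a flat YAML run config; every stage writes its outputs under the
run's output directory and the whole run is summarised in a JSON manifest
listing each artefact with its producing stage.  Fixed config + seed gives
byte-identical trace and beat CSVs across runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beats as beats_mod
from . import fringes as fringes_mod
from .focus import focus_report
from .io import read_stack, write_stack, write_trace
from .metrics import MetricParams, mm_speed, pv_speed
from .phantom import PhantomConfig, generate_acquisition, load_phantom_config
from .schedule import AcquisitionLayout, demux, load_layout

log = logging.getLogger("contractile")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    layout: AcquisitionLayout
    phantom: PhantomConfig | None = None
    input_stack: Path | None = None
    duration_s: float = 15.0
    metric: str = "pv"
    frame_delay_N: int = 2
    normalize: bool = True
    smooth_window: int = 1
    min_prominence_mads: float = 5.0
    pair_window_s: float | None = None
    jolt_z_thresh: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.phantom is None and self.input_stack is None:
            raise ValueError("run config needs either a phantom section or an input stack")
        if self.metric not in ("pv", "mm"):
            raise ValueError("metric must be 'pv' or 'mm'")


def load_run_config(path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    base = path.parent

    layout_val = data["layout"]
    if isinstance(layout_val, str):
        layout_path = base / layout_val
        if not layout_path.exists():
            raise FileNotFoundError(f"layout file not found: {layout_path}")
        layout = load_layout(layout_path)
    else:
        layout = AcquisitionLayout(
            wells=tuple(str(w) for w in layout_val["wells"]),
            colours=tuple(layout_val.get("colours", ("R", "G", "B"))),
            camera_fps=float(layout_val.get("camera_fps", 100.0)),
            frames_per_slot=int(layout_val.get("frames_per_slot", 1)),
        )

    phantom = None
    if "phantom" in data:
        ph_val = data["phantom"]
        if isinstance(ph_val, str):
            ph_path = base / ph_val
            if not ph_path.exists():
                raise FileNotFoundError(f"phantom file not found: {ph_path}")
            phantom = load_phantom_config(ph_path)
        else:
            phantom = PhantomConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in (ph_val or {}).items()
            })
    input_stack = base / data["input_stack"] if data.get("input_stack") else None
    if input_stack is not None and not input_stack.exists():
        raise FileNotFoundError(f"input stack not found: {input_stack}")

    kwargs = {
        k: data[k]
        for k in (
            "duration_s",
            "metric",
            "frame_delay_N",
            "normalize",
            "smooth_window",
            "min_prominence_mads",
            "pair_window_s",
            "jolt_z_thresh",
            "seed",
        )
        if k in data
    }
    return RunConfig(
        outdir=base / data.get("outdir", "run_out"),
        layout=layout,
        phantom=phantom,
        input_stack=input_stack,
        **kwargs,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "artefacts": []}

    def record(stage: str, path: Path) -> None:
        manifest["artefacts"].append({"stage": stage, "path": str(path)})

    def stage(name: str):
        t0 = time.perf_counter()
        log.info("stage %s started", name)
        manifest["stages"].append({"name": name, "started_s": t0})

        def done():
            manifest["stages"][-1]["elapsed_s"] = time.perf_counter() - t0
            log.info("stage %s finished in %.2fs", name, manifest["stages"][-1]["elapsed_s"])

        return done

    try:
        # --- acquire ------------------------------------------------------
        done = stage("simulate" if config.phantom else "load")
        if config.phantom is not None:
            from dataclasses import replace

            phantom = replace(config.phantom, seed=config.seed)
            seq, truth = generate_acquisition(phantom, config.layout, config.duration_s)
            sim_path = outdir / "sim.tif"
            write_stack(seq, sim_path)
            record("simulate", sim_path)
            truth_path = outdir / "truth.json"
            truth.save(truth_path)
            record("simulate", truth_path)
        else:
            seq = read_stack(config.input_stack, camera_fps=config.layout.camera_fps)
        done()

        # --- demux --------------------------------------------------------
        done = stage("demux")
        stacks = demux(seq, config.layout)
        wells_dir = outdir / "wells"
        wells_dir.mkdir(parents=True, exist_ok=True)
        import tifffile

        for (well, colour), stk in stacks.items():
            p = wells_dir / f"{well}_{colour}.tif"
            tifffile.imwrite(p, stk.frames, photometric="minisblack")
            record("demux", p)
        done()

        # --- focus --------------------------------------------------------
        done = stage("focus")
        report = focus_report(stacks)
        focus_path = outdir / "focus.csv"
        report.to_csv(focus_path, index=False)
        record("focus", focus_path)
        selected = {
            row["well"]: row["colour"]
            for _, row in report[report["selected"]].iterrows()
        }
        done()

        # --- metrics ------------------------------------------------------
        done = stage("analyze")
        params = MetricParams(frame_delay_N=config.frame_delay_N)
        metric_fn = pv_speed if config.metric == "pv" else mm_speed
        traces = {}
        traces_dir = outdir / "traces"
        for well, colour in selected.items():
            trace = metric_fn(stacks[(well, colour)], params)
            if config.smooth_window > 1:
                from .metrics import moving_average

                trace = moving_average(trace, config.smooth_window)
            if config.normalize:
                from .metrics import normalize_trace

                trace = normalize_trace(trace)
            traces[well] = trace
            p = traces_dir / f"{well}.csv"
            write_trace(trace, p)
            record("analyze", p)
        done()

        # --- jolts --------------------------------------------------------
        if len(traces) >= 2:
            done = stage("jolts")
            jolt_report = beats_mod.detect_jolts(traces, z_thresh=config.jolt_z_thresh)
            jolts_path = outdir / "jolts.csv"
            pd.DataFrame(
                {
                    "frame": jolt_report.flagged_frames,
                    "wells": [";".join(jolt_report.wells_affected[f]) for f in jolt_report.flagged_frames],
                }
            ).to_csv(jolts_path, index=False)
            record("jolts", jolts_path)
            done()

        # --- beats --------------------------------------------------------
        done = stage("beats")
        all_beats = []
        for well, trace in traces.items():
            table = beats_mod.detect_beats(
                trace,
                min_prominence_mads=config.min_prominence_mads,
                pair_window_s=config.pair_window_s,
            )
            table.insert(0, "well", well)
            all_beats.append(table)
        beats_df = pd.concat(all_beats, ignore_index=True) if all_beats else pd.DataFrame()
        beats_path = outdir / "beats.csv"
        beats_df.to_csv(beats_path, index=False)
        record("beats", beats_path)
        done()

        # --- fringe overlay ------------------------------------------------
        # prefer a beat with distinct contraction/relaxation velocity peaks;
        # at low effective sampling rates the two peaks merge into one, in
        # which case the overlay falls back to the beat peak and the sample
        # one frame-delay later (still two phases of the same contraction)
        done = stage("fringes")
        N = config.frame_delay_N
        for well, trace in traces.items():
            table = beats_df[beats_df["well"] == well] if len(beats_df) else beats_df
            if len(table) == 0:
                continue
            two_peak = table[np.isfinite(table["relaxation_peak_time_s"])]
            if len(two_peak):
                t1, t2 = fringes_mod.pick_fringe_timepoints(
                    trace, two_peak.reset_index(drop=True), 0
                )
            else:
                times = trace.frame_times_s
                t1 = int(np.argmin(np.abs(times - table.iloc[0]["contraction_peak_time_s"])))
                t2 = min(t1 + max(N, 1), len(times) - 1)
            if t1 < N or t2 < N or t1 == t2:
                continue
            overlay = fringes_mod.fringe_overlay(stacks[(well, selected[well])], t1, t2, N)
            p = outdir / f"overlay_{well}.png"
            fringes_mod.save_overlay_png(overlay, p)
            record("fringes", p)
            break
        done()
    except Exception as exc:
        failed = manifest["stages"][-1]["name"] if manifest["stages"] else "config"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
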