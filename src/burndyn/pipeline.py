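"""End-to-end pipeline: simulate -> invert -> params -> segment -> label ->
dynamics -> classify -> report.

Each stage reads its inputs from and writes its outputs to a run directory,
so stages can be re-run individually from the CLI. All randomness derives
from the master seed through named substreams (one per stage), making two
runs with the same seed byte-identical; the final manifest records the
configuration and a SHA-256 hash of every data artifact (figures are
written but not hashed — plot rasterisation is not part of the data
contract).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .chromophores import LayerModelConfig, load_chromophores
from .classify import classify_cohort, evaluate_day
from .config import RunConfig
from .dynamics import class_regions, discrimination_table, trajectories
from .inverse import InverseConfig, fit_cube
from .io import (
    HyperspectralCube,
    read_cube,
    read_label_png,
    read_mask_png,
    write_cube,
    write_label_png,
    write_mask_png,
)
from .reference import classify_healing, read_healing_csv
from .secondary import PARAM_CHANNELS, PS1, PS2, secondary_maps
from .segmentation import segment_wound
from .synthetic import DAYS, CohortConfig, generate_cohort

__all__ = ["run_pipeline", "StageError", "STAGES"]

log = logging.getLogger("burndyn")

STAGES = (
    "simulate",
    "invert",
    "params",
    "segment",
    "label",
    "dynamics",
    "classify",
    "report",
)

CLASS_COLORS = {"2a": "tab:blue", "2b1": "tab:green", "2b2": "gold", "3": "tab:red"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(master: int, stage: str) -> int:
    """Named substream scheme: one derived seed (< 2^31) per stage."""
    ss = np.random.SeedSequence([master, STAGES.index(stage)])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _wound_ids(run_dir: Path) -> list[str]:
    return sorted(p.name for p in (run_dir / "cohort").iterdir() if p.is_dir())


def _cube_path(wdir: Path, day: int, dialect: str) -> Path:
    ext = "npz" if dialect == "npz" else "raw"
    return wdir / f"cube_day{day}.{ext}"


def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    sim = cfg.simulate
    lib = load_chromophores()
    model_cfg = LayerModelConfig(xa=cfg.model.xa)
    ccfg = CohortConfig(
        n_wounds=sim.n_wounds,
        segments_per_wound_mean=sim.segments_per_wound_mean,
        pixel_pitch_mm=sim.pixel_pitch_mm,
        spectral_noise_sd=sim.spectral_noise_sd,
        spread_scale=sim.spread_scale,
        balanced_classes=sim.balanced_classes,
        render_cubes=True,
        wound_box_px=sim.wound_box_px,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    cohort = generate_cohort(ccfg, lib=lib, model_cfg=model_cfg)
    root = run_dir / "cohort"
    root.mkdir(parents=True, exist_ok=True)
    for wid in cohort.masks:
        wdir = root / wid
        wdir.mkdir(exist_ok=True)
        write_mask_png(cohort.masks[wid], wdir / "mask.png")
        write_label_png(cohort.label_maps[wid], wdir / "labels_truth.png")
        for day in DAYS:
            cube = HyperspectralCube(
                cohort.cubes[(wid, day)], lib.wavelengths,
                metadata={"wound_id": wid, "day": day},
            )
            write_cube(cube, _cube_path(wdir, day, cfg.io.cube_dialect),
                       dialect=cfg.io.cube_dialect)
    _float_csv(cohort.truth, root / "truth.csv")
    _float_csv(cohort.segments, root / "segments_truth.csv")
    healing = pd.DataFrame(
        [
            {
                "segment_id": r.segment_id,
                "closure_day": r.closure_day,
                "surgical": r.surgical,
                "clinical_grade3": r.clinical_grade3,
            }
            for r in cohort.healing
        ]
    )
    _float_csv(healing, root / "healing.csv")


def stage_invert(cfg: RunConfig, run_dir: Path) -> None:
    lib = load_chromophores()
    model_cfg = LayerModelConfig(xa=cfg.model.xa)
    icfg = InverseConfig(
        n_starts=cfg.inverse.n_starts,
        smoothness=cfg.inverse.smoothness,
        polish_smoothness=cfg.inverse.polish_smoothness,
        max_nfev=cfg.inverse.max_nfev,
    )
    seed = stage_seed(cfg.seed, "invert")
    out = run_dir / "inverted"
    out.mkdir(parents=True, exist_ok=True)
    for wid in _wound_ids(run_dir):
        wdir = run_dir / "cohort" / wid
        mask = read_mask_png(wdir / "mask.png")
        for day in DAYS:
            cube = read_cube(_cube_path(wdir, day, cfg.io.cube_dialect))
            maps = fit_cube(cube.data, cube.wavelengths, mask, lib, model_cfg,
                            seed=seed, inverse_cfg=icfg)
            stack = np.concatenate(
                [maps["vhb"], maps["xhbo2"], maps["residual"][..., None]], axis=-1
            )
            np.save(out / f"{wid}_day{day}_profiles.npy", stack)


def stage_params(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "params"
    out.mkdir(parents=True, exist_ok=True)
    for wid in _wound_ids(run_dir):
        for day in DAYS:
            stack = np.load(run_dir / "inverted" / f"{wid}_day{day}_profiles.npy")
            pm = secondary_maps(stack[..., :6], stack[..., 6:12], xa=cfg.model.xa)
            np.save(out / f"{wid}_day{day}_params.npy", pm)


def stage_segment(cfg: RunConfig, run_dir: Path) -> None:
    """Segment each wound on the stacked day-0..3 parameter maps.

    Stacking all days makes a segment homogeneous over the whole observation
    window, matching the premise that a segment carries a single class with
    a coherent time course.
    """
    out = run_dir / "segments"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for wid in _wound_ids(run_dir):
        mask = read_mask_png(run_dir / "cohort" / wid / "mask.png")
        day_maps = [
            np.load(run_dir / "params" / f"{wid}_day{day}_params.npy")
            for day in DAYS
        ]
        idx = [PARAM_CHANNELS.index(c) for c in cfg.segmentation.channels]
        stacked = np.nan_to_num(
            np.concatenate([m[..., idx] for m in day_maps], axis=-1)
        )
        labels, segments = segment_wound(
            stacked, mask,
            tau=cfg.segmentation.tau,
            min_area=cfg.segmentation.min_area,
            pixel_pitch_mm=cfg.simulate.pixel_pitch_mm,
        )
        write_label_png(labels, out / f"{wid}_labels.png")
        for seg in segments:
            for di, day in enumerate(DAYS):
                vals = day_maps[di][seg.pixels[:, 0], seg.pixels[:, 1], :]
                mean = np.nanmean(vals, axis=0)
                rows.append(
                    {
                        "segment_id": f"{wid}seg{seg.id}",
                        "wound_id": wid,
                        "day": day,
                        "n_pixels": len(seg.pixels),
                        "area_cm2": seg.area_cm2,
                        **dict(zip(PARAM_CHANNELS, mean.tolist())),
                    }
                )
    _float_csv(pd.DataFrame(rows), out / "segment_params.csv")


def stage_label(cfg: RunConfig, run_dir: Path) -> None:
    """Match discovered segments to truth segments and attach the healing-
    time reference class, propagated to every observed day."""
    records = {r.segment_id: r for r in
               read_healing_csv(run_dir / "cohort" / "healing.csv")}
    truth_seg = pd.read_csv(run_dir / "cohort" / "segments_truth.csv")
    table = pd.read_csv(run_dir / "segments" / "segment_params.csv")

    match = {}
    purity = {}
    for wid in _wound_ids(run_dir):
        found = read_label_png(run_dir / "segments" / f"{wid}_labels.png")
        truth = read_label_png(run_dir / "cohort" / wid / "labels_truth.png")
        ids = truth_seg[truth_seg["wound_id"] == wid].reset_index()
        for lab in np.unique(found):
            if lab == 0:
                continue
            overlap_ids, counts = np.unique(truth[found == lab], return_counts=True)
            best = overlap_ids[np.argmax(counts)]
            sid_truth = ids.loc[best - 1, "segment_id"] if best > 0 else None
            match[f"{wid}seg{lab}"] = sid_truth
            purity[f"{wid}seg{lab}"] = float(counts.max() / counts.sum())

    table["truth_segment_id"] = table["segment_id"].map(match)
    table["match_purity"] = table["segment_id"].map(purity)
    table["ref_class"] = [
        classify_healing(records[t]).value if t in records else None
        for t in table["truth_segment_id"]
    ]
    out = run_dir / "labeled"
    out.mkdir(parents=True, exist_ok=True)
    _float_csv(table, out / "segment_table.csv")


def stage_dynamics(cfg: RunConfig, run_dir: Path) -> None:
    table = pd.read_csv(run_dir / "labeled" / "segment_table.csv").dropna(
        subset=["ref_class"]
    )
    out = run_dir / "dynamics"
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    region_records = []
    for space in (PS1, PS2):
        for day in DAYS:
            regs = class_regions(
                table, day, space,
                mass=cfg.kde.mass, grid_n=cfg.kde.grid_n,
                bandwidth=cfg.kde.bandwidth, label_col="ref_class",
            )
            if regs:
                mat, summary = discrimination_table(regs)
                mat.to_csv(out / f"overlap_{space}_day{day}.csv")
                summaries[f"{space}_day{day}"] = summary
                for cls, reg in regs.items():
                    region_records.append(
                        {
                            "class": cls.value,
                            "day": day,
                            "space": space,
                            "mass_captured": reg.mass_captured,
                            "vertices": [[round(float(a), 6) for a in v]
                                         for v in reg.hull],
                        }
                    )
            _plot_regions(table, regs, day, space,
                          figdir / f"regions_{space}_day{day}.png")
    (out / "regions.json").write_text(
        json.dumps(region_records, indent=2, sort_keys=True)
    )
    (out / "discrimination.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True)
    )
    trs = trajectories(table, PS2, label_col="ref_class")
    rows = [
        {
            "segment_id": t.segment_id,
            "class": t.burn_class.value,
            "days": "|".join(map(str, t.days)),
            "points": "|".join(f"{x:.6f},{y:.6f}" for x, y in t.points),
        }
        for t in trs
    ]
    _float_csv(pd.DataFrame(rows), out / "trajectories.csv")


def _plot_regions(table, regs, day, space, path):
    xcol, ycol = ("v1", "xrate") if space == PS1 else ("v2", "flow2")
    fig, ax = plt.subplots(figsize=(4, 4))
    sub = table[table["day"] == day]
    for cls, color in CLASS_COLORS.items():
        pts = sub[sub["ref_class"] == cls]
        ax.scatter(pts[xcol], pts[ycol], s=8, color=color, label=cls, alpha=0.6)
    for cls, reg in (regs or {}).items():
        hull = np.vstack([reg.hull, reg.hull[:1]])
        ax.plot(hull[:, 0], hull[:, 1], color=CLASS_COLORS[cls.value], lw=1.5)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.set_title(f"{space} day {day}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def stage_classify(cfg: RunConfig, run_dir: Path) -> None:
    table = pd.read_csv(run_dir / "labeled" / "segment_table.csv").dropna(
        subset=["ref_class"]
    )
    out = run_dir / "classify"
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    estimates = classify_cohort(
        table,
        leave_one_wound_out=cfg.classification.leave_one_wound_out,
        mass=cfg.kde.mass,
        grid_n=cfg.kde.grid_n,
        label_col="ref_class",
    )
    _float_csv(estimates, out / "estimates.csv")
    ref = table[["segment_id", "ref_class"]].drop_duplicates("segment_id")
    evaluation = {}
    days_estimated = sorted(set(estimates["day"])) if len(estimates) else []
    for day in days_estimated:
        ev = evaluate_day(estimates, ref, day)
        evaluation[f"day{day}"] = {
            "accuracy": ev["accuracy"],
            "recall": ev["recall"],
            "n": ev["n"],
            "confusion": ev["confusion"].to_dict(),
        }
    (out / "evaluation.json").write_text(
        json.dumps(evaluation, indent=2, sort_keys=True)
    )
    if len(estimates):
        _plot_classmaps(run_dir, estimates, figdir)


def _plot_classmaps(run_dir, estimates, figdir):
    import matplotlib.colors as mcolors

    palette = {0: (1, 1, 1), 1: mcolors.to_rgb("tab:blue"),
               2: mcolors.to_rgb("tab:green"), 3: mcolors.to_rgb("gold"),
               4: mcolors.to_rgb("tab:red")}
    code = {"2a": 1, "2b1": 2, "2b2": 3, "3": 4}
    est = estimates.set_index(["segment_id", "day"])["estimated_class"]
    for wid in _wound_ids(run_dir):
        labels = read_label_png(run_dir / "segments" / f"{wid}_labels.png")
        fig, axes = plt.subplots(1, len(DAYS), figsize=(3 * len(DAYS), 3))
        for ax, day in zip(axes, DAYS):
            img = np.zeros(labels.shape + (3,))
            for lab in np.unique(labels):
                if lab == 0:
                    continue
                cls = est.get((f"{wid}seg{lab}", day))
                img[labels == lab] = palette[code.get(cls, 0)]
            ax.imshow(img, interpolation="nearest")
            ax.set_title(f"{wid} day {day}", fontsize=8)
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(figdir / f"classmap_{wid}.png", dpi=100)
        plt.close(fig)


def stage_report(cfg: RunConfig, run_dir: Path) -> None:
    files = {}
    for p in sorted(run_dir.rglob("*")):
        if not p.is_file() or p.name == "manifest.json":
            continue
        rel = p.relative_to(run_dir).as_posix()
        if "/figures/" in f"/{rel}":
            continue
        files[rel] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package": "burndyn",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in STAGES},
        "files": files,
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "invert": stage_invert,
    "params": stage_params,
    "segment": stage_segment,
    "label": stage_label,
    "dynamics": stage_dynamics,
    "classify": stage_classify,
    "report": stage_report,
}


def run_stage(name: str, cfg: RunConfig, run_dir: Path) -> None:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}")
    t0 = time.perf_counter()
    try:
        _STAGE_FUNCS[name](cfg, Path(run_dir))
    except (FileNotFoundError, OSError) as exc:
        raise StageError(f"stage '{name}' failed: missing input ({exc})") from exc
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %-9s %6.2f s", name, time.perf_counter() - t0)


def run_pipeline(cfg: RunConfig, run_dir) -> Path:
    """Execute all stages into ``run_dir`` and return it."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if not cfg.simulate.enabled and cfg.simulate.input_dir is None:
        raise StageError("stage 'simulate' failed: missing input "
                         "(simulation disabled and no input_dir given)")
    for name in STAGES:
        if name == "simulate" and not cfg.simulate.enabled:
            continue
        run_stage(name, cfg, run_dir)
    return run_dir
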