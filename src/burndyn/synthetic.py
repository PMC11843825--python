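"""Synthetic burn-wound cohorts with class-specific perfusion dynamics.

No patient data are deposited with the study this package models, so every
stage is exercised on generated cohorts. The generator encodes the
qualitative day-0..3 dynamics of the four burn classes in the deep-perfusion
space PS_2 = (vHb_2, flow_2):

* 2a  — medium start, strong hyperemic drift up-right, widening on day 1,
        compact again by day 3;
* 2b1 — slightly lower start than 2a, strong drift up-right with a strong
        day-1 widening, staying below the 2a area;
* 2b2 — lower start, limited drift, smallest distribution area, and a
        characteristic vHb peak at layer 2 (blood congestion under the
        damaged capillary bed);
* 3   — low perfusion, nearly stationary, drifting further down-left with a
        widening over days.

All generative means, spreads and drifts in ``CLASS_DAY_MEANS`` /
``CLASS_DAY_SPREAD`` are *synthetic calibration constants*: they were chosen
once so the qualitative signatures above hold, and they are not measured
values. Healing records are drawn consistently with each class so the
healing-time reference rule round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromophores import (
    ChromophoreLibrary,
    LayerModelConfig,
    PerfusionProfile,
    render_spectrum,
)
from .reference import BurnClass, HealingRecord
from .secondary import (
    PS1,
    PS2,
    PARAM_CHANNELS,
    ParamPoint,
    secondary_from_profile,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "CLASS_DAY_MEANS",
    "CLASS_DAY_SPREAD",
    "PARAM_CHANNELS",
    "sample_profile",
    "mean_profile",
    "generate_cohort",
    "reference_scenarios",
]

DAYS = (0, 1, 2, 3)

# Composed-parameter targets (v1, x1, v2, x2, v3) per class and day.
# Synthetic calibration constants, version 1 — not measured data.
CLASS_DAY_MEANS: dict[BurnClass, tuple] = {
    BurnClass.C2A: (
        (0.30, 0.45, 0.28, 0.55, 0.25),
        (0.45, 0.50, 0.45, 0.65, 0.32),
        (0.55, 0.53, 0.62, 0.71, 0.38),
        (0.62, 0.55, 0.75, 0.74, 0.42),
    ),
    BurnClass.C2B1: (
        (0.26, 0.44, 0.24, 0.52, 0.22),
        (0.38, 0.48, 0.38, 0.60, 0.28),
        (0.46, 0.50, 0.50, 0.65, 0.32),
        (0.52, 0.52, 0.60, 0.68, 0.35),
    ),
    BurnClass.C2B2: (
        (0.24, 0.42, 0.20, 0.50, 0.20),
        (0.28, 0.43, 0.24, 0.53, 0.22),
        (0.31, 0.44, 0.28, 0.56, 0.23),
        (0.33, 0.45, 0.32, 0.58, 0.24),
    ),
    BurnClass.C3: (
        (0.18, 0.35, 0.15, 0.45, 0.15),
        (0.16, 0.33, 0.13, 0.42, 0.13),
        (0.14, 0.31, 0.11, 0.39, 0.12),
        (0.12, 0.30, 0.10, 0.37, 0.11),
    ),
}

# Between-segment spread per class and day (volume-axis SD; the saturation
# SD is X_SPREAD_FACTOR times this). 2a/2b1 widen on day 1 and tighten by
# day 3; 2b2 stays smallest; class 3 widens while drifting down-left.
CLASS_DAY_SPREAD: dict[BurnClass, tuple] = {
    BurnClass.C2A: (0.055, 0.075, 0.050, 0.035),
    BurnClass.C2B1: (0.055, 0.075, 0.055, 0.040),
    BurnClass.C2B2: (0.045, 0.048, 0.042, 0.032),
    BurnClass.C3: (0.045, 0.050, 0.055, 0.058),
}

X_SPREAD_FACTOR = 0.4
# share of the spread carried by the per-segment latent (constant across
# days, makes trajectories coherent) vs. fresh per-day jitter
LATENT_SHARE = 0.8
DAY_SHARE = 0.6
# 2b2 blood congestion: upper-layer split putting the peak at layer 2
CONGESTION_SPLIT = (0.7, 1.3)


def mean_profile(burn_class: BurnClass, day: int) -> PerfusionProfile:
    """Noise-free class/day mean profile (the SD -> 0 limit of the sampler)."""
    v1, x1, v2, x2, v3 = CLASS_DAY_MEANS[burn_class][day]
    split = CONGESTION_SPLIT if burn_class is BurnClass.C2B2 else (1.0, 1.0)
    vhb = np.array([split[0] * v1, split[1] * v1, v3, v3, v2, v2])
    xm = 0.5 * (x1 + x2)
    xhbo2 = np.array([x1, x1, xm, xm, x2, x2])
    return PerfusionProfile(np.clip(vhb, 0, 1), np.clip(xhbo2, 0, 1))


def _perturbed(burn_class, day, z_latent, z_day, spread_scale=1.0):
    v1, x1, v2, x2, v3 = CLASS_DAY_MEANS[burn_class][day]
    s = CLASS_DAY_SPREAD[burn_class][day] * spread_scale
    dv = s * (LATENT_SHARE * z_latent[:3] + DAY_SHARE * z_day[:3])
    dx = X_SPREAD_FACTOR * s * (LATENT_SHARE * z_latent[3:] + DAY_SHARE * z_day[3:])
    v1, v3, v2 = v1 + dv[0], v3 + dv[1], v2 + dv[2]
    x1, x2 = x1 + dx[0], x2 + dx[2]
    xm = 0.5 * (x1 + x2) + 0.5 * dx[1]
    split = CONGESTION_SPLIT if burn_class is BurnClass.C2B2 else (1.0, 1.0)
    vhb = np.clip([split[0] * v1, split[1] * v1, v3, v3, v2, v2], 0, 1)
    xhbo2 = np.clip([x1, x1, xm, xm, x2, x2], 0, 1)
    return PerfusionProfile(vhb, xhbo2)


def sample_profile(
    burn_class: BurnClass,
    day: int,
    rng: np.random.Generator,
    spread_scale: float = 1.0,
) -> PerfusionProfile:
    """Draw one six-layer profile from the class/day distribution.

    The draw is a truncated Gaussian around the class/day mean profile;
    ``spread_scale -> 0`` recovers :func:`mean_profile` exactly.
    """
    if day not in DAYS:
        raise ValueError(f"day must be one of {DAYS}")
    z = rng.standard_normal(6)
    zd = rng.standard_normal(6)
    return _perturbed(burn_class, day, z, zd, spread_scale)


def segment_series(
    burn_class: BurnClass,
    rng: np.random.Generator,
    spread_scale: float = 1.0,
) -> dict[int, PerfusionProfile]:
    """Coherent day-0..3 profile series for one segment (shared latent)."""
    z = rng.standard_normal(6)
    return {
        day: _perturbed(burn_class, day, z, rng.standard_normal(6), spread_scale)
        for day in DAYS
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings.

    Defaults mirror the modelled cohort: 59 wounds, a mean of 4.6 segments
    per wound, measurements on days 0-3, 0.5 mm pixel pitch. Cube rendering
    is off by default (the distribution analysis runs on composed
    parameters); switch ``render_cubes`` on for small end-to-end runs.
    """

    n_wounds: int = 59
    segments_per_wound_mean: float = 4.6
    pixel_pitch_mm: float = 0.5
    class_mixture: tuple = (0.25, 0.25, 0.25, 0.25)
    balanced_classes: bool = False  # cycle classes instead of sampling (small cohorts)
    spread_scale: float = 1.0
    spectral_noise_sd: float = 0.005
    render_cubes: bool = False
    wound_box_px: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9 or any(
            p < 0 for p in self.class_mixture
        ):
            raise ValueError("class mixture must be a probability vector")
        if self.spectral_noise_sd < 0 or self.spread_scale < 0:
            raise ValueError("noise and spread must be >= 0")
        if self.n_wounds < 1:
            raise ValueError("need at least one wound")


@dataclass
class SyntheticCohort:
    """A generated cohort with full provenance.

    ``segments`` holds one row per segment (id, wound, true class, geometry);
    ``truth`` one row per segment and day with the true composed parameters;
    ``profiles`` maps (segment_id, day) to the true six-layer profile;
    ``label_maps`` maps wound_id to an integer segment-index image (0 =
    background) with ``masks`` the wound masks; ``cubes`` (optional) maps
    (wound_id, day) to rendered H x W x B remission arrays.
    """

    config: CohortConfig
    segments: pd.DataFrame
    truth: pd.DataFrame
    profiles: dict
    healing: list[HealingRecord]
    masks: dict
    label_maps: dict
    segment_index: dict
    cubes: dict = field(default_factory=dict)
    wavelengths: np.ndarray | None = None


def _split_layout(n_seg: int, side: int, rng: np.random.Generator) -> np.ndarray:
    """Partition a side x side box into n_seg rectangles by recursive splits."""
    rects = [(0, 0, side, side)]  # (r0, c0, r1, c1)
    while len(rects) < n_seg:
        areas = [(r[2] - r[0]) * (r[3] - r[1]) for r in rects]
        i = int(np.argmax(areas))
        r0, c0, r1, c1 = rects.pop(i)
        f = rng.uniform(0.35, 0.65)
        if (r1 - r0) >= (c1 - c0):
            cut = r0 + max(1, int(round(f * (r1 - r0))))
            cut = min(cut, r1 - 1)
            rects[i:i] = [(r0, c0, cut, c1), (cut, c0, r1, c1)]
        else:
            cut = c0 + max(1, int(round(f * (c1 - c0))))
            cut = min(cut, c1 - 1)
            rects[i:i] = [(r0, c0, r1, cut), (r0, cut, r1, c1)]
    label = np.zeros((side, side), dtype=np.int32)
    for k, (r0, c0, r1, c1) in enumerate(rects, start=1):
        label[r0:r1, c0:c1] = k
    return label


def _healing_record(sid: str, burn_class: BurnClass, rng) -> HealingRecord:
    if burn_class is BurnClass.C3:
        return HealingRecord(sid, closure_day=None, surgical=True, clinical_grade3=True)
    if burn_class is BurnClass.C2A:
        return HealingRecord(sid, closure_day=int(rng.integers(8, 15)))
    if burn_class is BurnClass.C2B1:
        return HealingRecord(sid, closure_day=int(rng.integers(15, 22)))
    if rng.random() < 0.5:
        return HealingRecord(sid, closure_day=None, surgical=True)
    return HealingRecord(sid, closure_day=int(rng.integers(22, 36)))


def generate_cohort(
    cfg: CohortConfig,
    lib: ChromophoreLibrary | None = None,
    model_cfg: LayerModelConfig | None = None,
) -> SyntheticCohort:
    """Generate a cohort: wounds, segment layouts, classes, per-day profiles,
    healing records and (optionally) rendered remission cubes.

    Reproducible bit-for-bit from ``cfg.seed``.
    """
    if cfg.render_cubes and lib is None:
        raise ValueError("cube rendering requires a chromophore library")
    model_cfg = model_cfg or LayerModelConfig()
    rng = np.random.default_rng(cfg.seed)
    classes = list(BurnClass)

    seg_rows, truth_rows, healing = [], [], []
    profiles: dict = {}
    masks: dict = {}
    label_maps: dict = {}
    segment_index: dict = {}
    cubes: dict = {}

    for w in range(cfg.n_wounds):
        wid = f"w{w:03d}"
        n_seg = 1 + int(rng.poisson(max(cfg.segments_per_wound_mean - 1.0, 0.0)))
        label = _split_layout(n_seg, cfg.wound_box_px, rng)
        if label.max() != n_seg:
            raise ValueError("infeasible geometry: segments exceed wound area")
        masks[wid] = label > 0
        label_maps[wid] = label
        seg_ids = []
        for k in range(1, n_seg + 1):
            sid = f"{wid}s{k}"
            seg_ids.append(sid)
            if cfg.balanced_classes:
                cls = classes[len(seg_rows) % 4]
            else:
                cls = classes[int(rng.choice(4, p=cfg.class_mixture))]
            n_px = int(np.sum(label == k))
            seg_rows.append(
                {
                    "segment_id": sid,
                    "wound_id": wid,
                    "true_class": cls.value,
                    "n_pixels": n_px,
                    "area_cm2": n_px * (cfg.pixel_pitch_mm / 10.0) ** 2,
                }
            )
            series = segment_series(cls, rng, cfg.spread_scale)
            for day, prof in series.items():
                profiles[(sid, day)] = prof
                sp = secondary_from_profile(prof, model_cfg)
                truth_rows.append(
                    {
                        "segment_id": sid,
                        "wound_id": wid,
                        "day": day,
                        "true_class": cls.value,
                        **{ch: getattr(sp, ch) for ch in PARAM_CHANNELS},
                    }
                )
            healing.append(_healing_record(sid, cls, rng))
        segment_index[wid] = seg_ids

        if cfg.render_cubes:
            for day in DAYS:
                cube = np.zeros((cfg.wound_box_px, cfg.wound_box_px, lib.n_bands))
                for k, sid in enumerate(seg_ids, start=1):
                    spec = render_spectrum(profiles[(sid, day)], lib, model_cfg)
                    cube[label == k] = spec.remission
                if cfg.spectral_noise_sd > 0:
                    cube = cube + rng.normal(0.0, cfg.spectral_noise_sd, cube.shape)
                cubes[(wid, day)] = np.clip(cube, 0.0, 1.0)

    return SyntheticCohort(
        config=cfg,
        segments=pd.DataFrame(seg_rows),
        truth=pd.DataFrame(truth_rows),
        profiles=profiles,
        healing=healing,
        masks=masks,
        label_maps=label_maps,
        segment_index=segment_index,
        cubes=cubes,
        wavelengths=None if lib is None else lib.wavelengths,
    )


def _constant_maps(params, shape):
    maps = np.empty(shape + (len(PARAM_CHANNELS),))
    for i, ch in enumerate(PARAM_CHANNELS):
        maps[..., i] = getattr(params, ch)
    return maps


def reference_scenarios(seed: int = 12345) -> dict:
    """Small deterministic fixtures used across the test suite.

    * ``uniform_wound`` — constant parameter maps over one mask;
    * ``two_class_wound`` — two rectangles with parameter means far apart,
      with the ground-truth partition;
    * ``trajectory_demo`` — one noise-free segment per class over days 0-3;
    * ``day0_overlap`` — per-class PS_2 point clouds drawn from the
      day-0 distributions (strongly overlapping by construction).
    """
    rng = np.random.default_rng(seed)
    model_cfg = LayerModelConfig()
    scenarios: dict = {}

    # uniform_wound: 24 x 20 mask, constant channels from the 2a day-0 mean
    p0 = secondary_from_profile(mean_profile(BurnClass.C2A, 0), model_cfg)
    mask = np.zeros((24, 20), bool)
    mask[2:22, 2:18] = True
    scenarios["uniform_wound"] = {
        "param_maps": _constant_maps(p0, mask.shape),
        "mask": mask,
    }

    # two_class_wound: left rect from 2a day-3, right rect from 3 day-3
    pa = secondary_from_profile(mean_profile(BurnClass.C2A, 3), model_cfg)
    pb = secondary_from_profile(mean_profile(BurnClass.C3, 3), model_cfg)
    maps = _constant_maps(pa, (24, 32))
    maps[:, 16:, :] = _constant_maps(pb, (24, 16))
    truth = np.ones((24, 32), np.int32)
    truth[:, 16:] = 2
    scenarios["two_class_wound"] = {
        "param_maps": maps,
        "mask": np.ones((24, 32), bool),
        "truth_labels": truth,
    }

    # trajectory_demo: per-class mean trajectories (SD -> 0)
    rows = []
    for cls in BurnClass:
        for day in DAYS:
            sp = secondary_from_profile(mean_profile(cls, day), model_cfg)
            rows.append(
                {
                    "segment_id": f"demo_{cls.value}",
                    "day": day,
                    "true_class": cls.value,
                    **{ch: getattr(sp, ch) for ch in PARAM_CHANNELS},
                }
            )
    scenarios["trajectory_demo"] = pd.DataFrame(rows)

    # day0_overlap: 60 segments per class drawn at day 0 with widened spread
    # (scale 1.5) so the clouds overlap strongly, as day-0 distributions do
    pts = {}
    for cls in BurnClass:
        arr = []
        for _ in range(60):
            sp = secondary_from_profile(sample_profile(cls, 0, rng, 1.5), model_cfg)
            arr.append((sp.v2, sp.flow2))
        pts[cls.value] = [ParamPoint(PS2, x, y) for x, y in arr]
    scenarios["day0_overlap"] = pts

    return scenarios
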