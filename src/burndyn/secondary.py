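"""Secondary perfusion parameters and the two 2-D parameter spaces.

From a six-layer perfusion profile, composed values are formed over three
layer groups — upper (layers 1-2), middle (3-4) and deeper (5-6):

* ``v1``, ``v2``: width-weighted hemoglobin volume of the upper / deeper group
* ``v3``: width-weighted volume of the middle group
* ``x1``, ``x2``: vHb-weighted oxygen saturation of the upper / deeper group

and from those the derived indices

* ``flow1 = v1 * x1 / (xa - x1)`` — upper-layer blood flow
* ``flow2 = v2 * (x2 - x1) / (xa - x2)`` — deeper-layer blood flow
* ``xrate = v3 * (xa - x1)`` — upper-layer oxygen consumption rate

with ``xa`` the arterial oxygen saturation. All values are clamped to
[0, 1]. The two parameter spaces used for class analysis are
PS_1 = (v1, xrate) ("superficial perfusion") and PS_2 = (v2, flow2)
("deep perfusion").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromophores import LayerModelConfig, PerfusionProfile

__all__ = [
    "SecondaryParams",
    "ParamPoint",
    "PS1",
    "PS2",
    "PARAM_CHANNELS",
    "DEFAULT_GROUP_WEIGHTS",
    "compose",
    "flow1",
    "flow2",
    "xrate",
    "secondary_from_profile",
    "secondary_maps",
    "project",
]

PS1 = "PS_1"
PS2 = "PS_2"

PARAM_CHANNELS = ("v1", "x1", "v2", "x2", "v3", "flow1", "flow2", "xrate")

# upper = layers 1-2, middle = 3-4, deeper = 5-6; equal weight inside a group
DEFAULT_GROUP_WEIGHTS = (0.5, 0.5)

_GROUPS = {"upper": (0, 1), "middle": (2, 3), "deeper": (4, 5)}


def _clamp01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


@dataclass(frozen=True)
class SecondaryParams:
    """Composed and derived perfusion indices, all in [0, 1]."""

    v1: float
    x1: float
    v2: float
    x2: float
    v3: float
    flow1: float
    flow2: float
    xrate: float

    def __post_init__(self) -> None:
        for name in ("v1", "x1", "v2", "x2", "v3", "flow1", "flow2", "xrate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")


@dataclass(frozen=True)
class ParamPoint:
    """A point in one of the 2-D parameter spaces (unit square)."""

    space: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.space not in (PS1, PS2):
            raise ValueError(f"unknown space {self.space!r}")
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError("point outside the unit square")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


def _group_values(vhb, xhbo2, idx, weights):
    w = np.asarray(weights, dtype=float)
    vw = w * vhb[list(idx)]
    v = float(np.sum(vw))
    x = float(np.sum(vw * xhbo2[list(idx)]) / v) if v > 0 else 0.0
    return _clamp01(v), _clamp01(x)


def compose(
    profile: PerfusionProfile, weights=DEFAULT_GROUP_WEIGHTS
) -> tuple[float, float, float, float, float]:
    """Composed (v1, x1, v2, x2, v3) over the upper/deeper/middle layer groups.

    Volumes are width-weighted sums (clamped to [0, 1]); saturations are
    vHb-weighted means, defined as 0 for a bloodless group.
    """
    v1, x1 = _group_values(profile.vhb, profile.xhbo2, _GROUPS["upper"], weights)
    v2, x2 = _group_values(profile.vhb, profile.xhbo2, _GROUPS["deeper"], weights)
    v3, _ = _group_values(profile.vhb, profile.xhbo2, _GROUPS["middle"], weights)
    return v1, x1, v2, x2, v3


def flow1(v1: float, x1: float, xa: float) -> float:
    """Upper-layer flow index v1*x1/(xa - x1), clamped to [0, 1].

    The pole at x1 >= xa saturates to 1 when the numerator is positive.
    """
    num = v1 * x1
    if num <= 0.0:
        return 0.0
    if x1 >= xa:
        return 1.0
    return _clamp01(num / (xa - x1))


def flow2(v2: float, x2: float, x1: float, xa: float) -> float:
    """Deeper-layer flow index v2*(x2 - x1)/(xa - x2), clamped to [0, 1].

    Negative raw values (x2 < x1, deeper blood less saturated than upper)
    clamp to 0; the pole at x2 >= xa saturates to 1 for a positive numerator.
    """
    num = v2 * (x2 - x1)
    if num <= 0.0:
        return 0.0
    if x2 >= xa:
        return 1.0
    return _clamp01(num / (xa - x2))


def xrate(v3: float, x1: float, xa: float) -> float:
    """Oxygen consumption index v3*(xa - x1), clamped to [0, 1]."""
    if x1 >= xa:
        return 0.0
    return _clamp01(v3 * (xa - x1))


def secondary_from_profile(
    profile: PerfusionProfile,
    cfg: LayerModelConfig | None = None,
    weights=DEFAULT_GROUP_WEIGHTS,
) -> SecondaryParams:
    """Full secondary-parameter set of a profile (xa from the model config)."""
    xa = cfg.xa if cfg is not None else 0.98
    v1, x1, v2, x2, v3 = compose(profile, weights)
    return SecondaryParams(
        v1=v1, x1=x1, v2=v2, x2=x2, v3=v3,
        flow1=flow1(v1, x1, xa),
        flow2=flow2(v2, x2, x1, xa),
        xrate=xrate(v3, x1, xa),
    )


def secondary_maps(
    vhb: np.ndarray,
    xhbo2: np.ndarray,
    xa: float = 0.98,
    weights=DEFAULT_GROUP_WEIGHTS,
) -> np.ndarray:
    """Vectorised secondary parameters for per-pixel maps.

    ``vhb`` and ``xhbo2`` have shape (..., 6); the result has shape
    (..., 8) with channels in :data:`PARAM_CHANNELS` order. NaN layers
    propagate to NaN outputs (unmasked pixels).
    """
    vhb = np.asarray(vhb, float)
    xhbo2 = np.asarray(xhbo2, float)
    w = np.asarray(weights, float)

    def group(idx):
        vw = vhb[..., idx] * w
        v = np.clip(vw.sum(axis=-1), 0, 1)
        num = (vw * xhbo2[..., idx]).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(v > 0, num / np.where(v > 0, v, 1.0), 0.0)
        x = np.where(np.isnan(num), np.nan, np.clip(x, 0, 1))
        return v, x

    v1, x1 = group([0, 1])
    v3, _ = group([2, 3])
    v2, x2 = group([4, 5])

    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(
            v1 * x1 <= 0, 0.0,
            np.where(x1 >= xa, 1.0, np.clip(v1 * x1 / (xa - x1), 0, 1)),
        )
        f2num = v2 * (x2 - x1)
        f2 = np.where(
            f2num <= 0, 0.0,
            np.where(x2 >= xa, 1.0, np.clip(f2num / (xa - x2), 0, 1)),
        )
        xr = np.where(x1 >= xa, 0.0, np.clip(v3 * (xa - x1), 0, 1))
    nanmask = np.isnan(v1) | np.isnan(x1) | np.isnan(v2) | np.isnan(x2)
    out = np.stack([v1, x1, v2, x2, v3, f1, f2, xr], axis=-1)
    out[nanmask] = np.nan
    return out


def project(params: SecondaryParams) -> tuple[ParamPoint, ParamPoint]:
    """Project onto PS_1 = (v1, xrate) and PS_2 = (v2, flow2)."""
    return (
        ParamPoint(PS1, params.v1, params.xrate),
        ParamPoint(PS2, params.v2, params.flow2),
    )
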