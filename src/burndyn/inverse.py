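"""Approximate inverse solver: remission spectrum -> six-layer perfusion profile.

The inverse problem is depth-ambiguous — overlying absorption masks deep
layers, and the rendered spectrum constrains composed rather than per-layer
quantities. The fit therefore minimises a penalised bounded least-squares
objective over the 12 parameters (6 vHb, 6 xHbO2):

    || R_model(p) - R_obs ||^2  +  lambda_s^2 * ( ||D2 vHb||^2 + ||D2 x||^2 )

where D2 takes second differences across layers. The smoothness penalty ties
adjacent layers together, which stabilises the composed upper/deeper values
that feed the downstream analysis. The penalty weight follows a
two-stage continuation: a strong-smoothness solve finds the basin, a
weak-smoothness polish then releases the bias so per-layer structure can
sharpen. Multi-start (deterministic, seed-derived initial points) guards
against local minima; the analytic Jacobian of the two-pass layered model
keeps per-pixel fits fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .chromophores import (
    N_LAYERS,
    ChromophoreLibrary,
    LayerModelConfig,
    PerfusionProfile,
    RemissionSpectrum,
    layer_absorption,
    path_factors,
)

__all__ = [
    "FitResult",
    "InverseConfig",
    "DegenerateSpectrumError",
    "fit_profile",
    "fit_cube",
]


class DegenerateSpectrumError(ValueError):
    """Spectrum is all-zero, negative or otherwise unusable for inversion."""


@dataclass(frozen=True)
class InverseConfig:
    """Solver settings: restart count, smoothness continuation, iteration budget."""

    n_starts: int = 5
    smoothness: float = 0.05
    polish_smoothness: float = 0.007
    max_nfev: int = 150


@dataclass(frozen=True)
class FitResult:
    """Best-of-multistart inversion result."""

    profile: PerfusionProfile
    residual: float  # RMS spectral misfit, dimensionless
    converged: bool
    n_restarts_used: int

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def _second_diff_matrix(n: int) -> np.ndarray:
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d2


_D2 = _second_diff_matrix(N_LAYERS)


class _ForwardOperator:
    """Precomputed pieces of the model and its Jacobian on a fixed grid."""

    def __init__(self, lib: ChromophoreLibrary, cfg: LayerModelConfig):
        self.lib = lib
        self.cfg = cfg
        self.d = path_factors(lib, cfg)
        self.widths = np.asarray(cfg.widths)
        self.scale = np.asarray(cfg.vhb_scale)
        self.b = np.asarray(cfg.backscatter)
        self.eps_o = lib.eps_hbo2
        self.eps_d = lib.eps_hb
        # 2 * w_i * d(lambda) per layer, shape (6, B)
        self.two_wd = 2.0 * self.widths[:, None] * self.d[None, :]
        self.base = np.stack(
            [
                layer_absorption(
                    PerfusionProfile(np.zeros(N_LAYERS), np.zeros(N_LAYERS)),
                    k + 1, lib, cfg,
                )
                for k in range(N_LAYERS)
            ]
        )

    def remission_and_ek(self, p: np.ndarray):
        v, x = p[:N_LAYERS], p[N_LAYERS:]
        hb = (v / self.scale)[:, None] * (
            x[:, None] * self.eps_o[None, :] + (1.0 - x)[:, None] * self.eps_d[None, :]
        )
        mu = hb + self.base
        tau = np.cumsum(mu * self.two_wd, axis=0)
        ek = np.exp(-tau)
        r = self.b @ ek
        return r, ek

    def remission(self, p: np.ndarray) -> np.ndarray:
        return self.remission_and_ek(p)[0]

    def jacobian(self, p: np.ndarray) -> np.ndarray:
        """d R / d p, shape (B, 12); the [0,1] clamp is ignored (rarely active)."""
        v, x = p[:N_LAYERS], p[N_LAYERS:]
        _, ek = self.remission_and_ek(p)
        # S_i = sum_{k>=i} b_k E_k, shape (6, B)
        s = np.cumsum((self.b[:, None] * ek)[::-1], axis=0)[::-1]
        jac = np.empty((self.lib.n_bands, 2 * N_LAYERS))
        for i in range(N_LAYERS):
            dmu_dv = (x[i] * self.eps_o + (1.0 - x[i]) * self.eps_d) / self.scale[i]
            dmu_dx = (v[i] / self.scale[i]) * (self.eps_o - self.eps_d)
            common = -s[i] * self.two_wd[i]
            jac[:, i] = common * dmu_dv
            jac[:, N_LAYERS + i] = common * dmu_dx
        return jac


def _residual_and_jac(op: _ForwardOperator, r_obs: np.ndarray, lam: float):
    pen_rows = np.zeros((2 * (N_LAYERS - 2), 2 * N_LAYERS))
    pen_rows[: N_LAYERS - 2, :N_LAYERS] = lam * _D2
    pen_rows[N_LAYERS - 2 :, N_LAYERS:] = lam * _D2

    def fun(p):
        v, x = p[:N_LAYERS], p[N_LAYERS:]
        spec = op.remission(p) - r_obs
        pen = np.concatenate([lam * (_D2 @ v), lam * (_D2 @ x)])
        return np.concatenate([spec, pen])

    def jac(p):
        return np.vstack([op.jacobian(p), pen_rows])

    return fun, jac


def _start_points(n_starts: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    starts = np.empty((n_starts, 2 * N_LAYERS))
    starts[0] = np.concatenate([np.full(N_LAYERS, 0.3), np.full(N_LAYERS, 0.6)])
    if n_starts > 1:
        starts[1:] = rng.uniform(0.05, 0.95, size=(n_starts - 1, 2 * N_LAYERS))
    return starts


def fit_profile(
    spectrum: RemissionSpectrum,
    lib: ChromophoreLibrary,
    cfg: LayerModelConfig,
    seed: int = 0,
    inverse_cfg: InverseConfig | None = None,
) -> FitResult:
    """Fit a six-layer perfusion profile to one remission spectrum.

    The spectrum must live on the library's wavelength grid. Returns the
    restart with the lowest RMS spectral misfit (ties: lowest restart index);
    non-convergence of every restart yields ``converged=False`` with the
    best-effort profile rather than an exception.
    """
    icfg = inverse_cfg or InverseConfig()
    wl = np.asarray(spectrum.wavelengths, float)
    if wl.shape != lib.wavelengths.shape or not np.allclose(wl, lib.wavelengths):
        raise ValueError("spectrum is not on the model wavelength grid; resample first")
    r_obs = np.asarray(spectrum.remission, float)
    if np.all(r_obs <= 0):
        raise DegenerateSpectrumError("all-zero (or negative) spectrum")

    op = _ForwardOperator(lib, cfg)
    fun1, jac1 = _residual_and_jac(op, r_obs, icfg.smoothness)
    fun2, jac2 = _residual_and_jac(op, r_obs, icfg.polish_smoothness)
    nb = lib.n_bands
    opts = dict(
        bounds=(0.0, 1.0), method="trf",
        max_nfev=icfg.max_nfev, xtol=1e-10, ftol=1e-10, gtol=1e-10,
    )

    best = None
    best_rms = np.inf
    any_converged = False
    for p0 in _start_points(icfg.n_starts, seed):
        stage1 = least_squares(fun1, p0, jac=jac1, **opts)
        sol = least_squares(fun2, stage1.x, jac=jac2, **opts)
        rms = float(np.sqrt(np.mean(sol.fun[:nb] ** 2)))
        if rms < best_rms:
            best_rms = rms
            best = sol
        any_converged = any_converged or sol.status > 0
    assert best is not None
    p = np.clip(best.x, 0.0, 1.0)
    return FitResult(
        profile=PerfusionProfile.from_vector(p),
        residual=best_rms,
        converged=any_converged,
        n_restarts_used=icfg.n_starts,
    )


def fit_cube(
    cube: np.ndarray,
    wavelengths: np.ndarray,
    mask: np.ndarray,
    lib: ChromophoreLibrary,
    cfg: LayerModelConfig,
    seed: int = 0,
    inverse_cfg: InverseConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel inversion of a masked H x W x B remission cube.

    Returns maps ``vhb`` (H, W, 6), ``xhbo2`` (H, W, 6) and ``residual``
    (H, W); unmasked pixels carry NaN. Deterministic given the seed (every
    pixel uses the same seed-derived restart set).
    """
    cube = np.asarray(cube, float)
    mask = np.asarray(mask, bool)
    if cube.ndim != 3:
        raise ValueError("cube must be H x W x B")
    if cube.shape[2] != lib.n_bands:
        raise ValueError(
            f"cube has {cube.shape[2]} bands, model grid has {lib.n_bands}"
        )
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if not mask.any():
        raise ValueError("empty mask")

    h, w, _ = cube.shape
    vhb = np.full((h, w, N_LAYERS), np.nan)
    xhbo2 = np.full((h, w, N_LAYERS), np.nan)
    residual = np.full((h, w), np.nan)
    for y, x in np.argwhere(mask):
        spec = RemissionSpectrum(lib.wavelengths, np.clip(cube[y, x], 0.0, 1.0))
        fit = fit_profile(spec, lib, cfg, seed=seed, inverse_cfg=inverse_cfg)
        vhb[y, x] = fit.profile.vhb
        xhbo2[y, x] = fit.profile.xhbo2
        residual[y, x] = fit.residual
    return {"vhb": vhb, "xhbo2": xhbo2, "residual": residual}
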