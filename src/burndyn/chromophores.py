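"""Chromophore spectra and the layered optical forward model.

The skin/wound is modelled as six plane layers, each carrying a hemoglobin
volume index ``vHb`` and an oxygen saturation ``xHbO2``. A remission
(diffuse-reflectance) spectrum over 450-1000 nm is rendered with a two-pass
modified Beer-Lambert scheme: light reaching layer *k* and scattered back
traverses layers 1..k twice, so layer *k* contributes a fixed backscatter
fraction ``b_k`` attenuated by ``exp(-2 * sum_{j<=k} mu_a,j * w_j * d_j)``
where ``w_j`` are layer widths and ``d_j`` path-length factors derived from
the reduced scattering curve. The model is deliberately simple: monotone in
every absorber, analytically differentiable, and invertible at desk scale.

The packaged chromophore table is a *synthetic* analytic approximation of
the literature extinction curves (it is not measured data): HbO2 alpha/beta
bands at 542/577 nm, Hb band at 556 nm with the 758 nm shoulder, isosbestic
crossings inside 500-600 nm, power-law melanin and reduced scattering, NIR
water and fat bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreLibrary",
    "LayerModelConfig",
    "PerfusionProfile",
    "RemissionSpectrum",
    "ChromophoreLoadError",
    "load_chromophores",
    "layer_absorption",
    "render_spectrum",
    "isosbestic_wavelength",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

N_LAYERS = 6

_ASSET_COLUMNS = [
    "wavelength_nm",
    "eps_hbo2",
    "eps_hb",
    "mu_melanin",
    "mu_water",
    "mu_fat",
    "mus_reduced",
]


class ChromophoreLoadError(ValueError):
    """Raised when the chromophore table is missing, truncated or non-finite."""


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Tabulated absorber spectra on a common wavelength grid.

    All absorption values are 1/mm at unit volume fraction; ``mus_reduced``
    is the reduced scattering coefficient in 1/mm.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    mu_melanin: np.ndarray
    mu_water: np.ndarray
    mu_fat: np.ndarray
    mus_reduced: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ChromophoreLoadError("wavelength grid must be a 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ChromophoreLoadError("wavelength grid must be strictly ascending")
        for name in _ASSET_COLUMNS[1:]:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ChromophoreLoadError(f"{name} length does not match grid")
            if not np.all(np.isfinite(arr)):
                bad = wl[~np.isfinite(arr)][0]
                raise ChromophoreLoadError(f"{name} non-finite at {bad:g} nm")
            if np.any(arr < 0):
                bad = wl[arr < 0][0]
                raise ChromophoreLoadError(f"{name} negative at {bad:g} nm")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class LayerModelConfig:
    """Geometry and global scaling of the six-layer model.

    ``widths`` are path-length weights per layer (mm-equivalent), ``vhb_scale``
    maps the vHb index to an effective blood volume fraction per layer, and
    ``xa`` is the arterial oxygen saturation. Melanin sits in layer 1 only;
    water and fat fractions apply to every layer. ``backscatter`` are the
    per-layer returned-light fractions b_k of the two-pass model.
    """

    widths: tuple = (0.10, 0.20, 0.30, 0.45, 0.70, 1.00)
    vhb_scale: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    xa: float = 0.98
    f_melanin: float = 0.02
    f_water: float = 0.65
    f_fat: float = 0.10
    backscatter: tuple = (0.10, 0.12, 0.15, 0.18, 0.20, 0.17)

    def __post_init__(self) -> None:
        if len(self.widths) != N_LAYERS or len(self.vhb_scale) != N_LAYERS:
            raise ValueError("exactly 6 widths and 6 scale factors required")
        if len(self.backscatter) != N_LAYERS:
            raise ValueError("exactly 6 backscatter fractions required")
        if any(w <= 0 for w in self.widths) or any(s <= 0 for s in self.vhb_scale):
            raise ValueError("widths and scale factors must be positive")
        if not 0.0 < self.xa <= 1.0:
            raise ValueError("xa must be in (0, 1]")


@dataclass(frozen=True)
class PerfusionProfile:
    """Six-layer perfusion profile: vHb index and xHbO2 fraction per layer.

    By convention a layer with no blood (vHb == 0) reports saturation 0,
    since the saturation of absent blood is undefined.
    """

    vhb: np.ndarray
    xhbo2: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vhb, dtype=float).copy()
        x = np.asarray(self.xhbo2, dtype=float).copy()
        if v.shape != (N_LAYERS,) or x.shape != (N_LAYERS,):
            raise ValueError("profile arrays must have length 6")
        if np.any(v < 0) or np.any(v > 1) or np.any(x < 0) or np.any(x > 1):
            raise ValueError("profile values must lie in [0, 1]")
        x[v == 0] = 0.0
        v.setflags(write=False)
        x.setflags(write=False)
        object.__setattr__(self, "vhb", v)
        object.__setattr__(self, "xhbo2", x)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.vhb, self.xhbo2])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "PerfusionProfile":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[:N_LAYERS], vec[N_LAYERS:])


@dataclass(frozen=True)
class RemissionSpectrum:
    """A remission (reflectance) spectrum on a wavelength grid, values in [0, 1]."""

    wavelengths: np.ndarray
    remission: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.remission, dtype=float)
        if wl.shape != r.shape or wl.ndim != 1:
            raise ValueError("wavelengths and remission must be equal-length 1-D arrays")
        if not np.all(np.isfinite(r)) or np.any(r < 0) or np.any(r > 1):
            raise ValueError("remission must be finite and in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "remission", r)


def _default_grid() -> np.ndarray:
    return np.arange(450.0, 1000.0 + 1e-9, 5.0)


def load_chromophores(source=None, grid: np.ndarray | None = None) -> ChromophoreLibrary:
    """Load the chromophore table and resample it onto ``grid``.

    ``source`` may be a path to a CSV with the packaged column layout; by
    default the packaged synthetic table is used. Resampling is linear; the
    default grid is 450-1000 nm in 5 nm steps (111 bands).
    """
    if source is None:
        source = resources.files("burndyn").joinpath("data/chromophores_synthetic.csv")
    try:
        with resources.as_file(source) as p:  # type: ignore[arg-type]
            df = pd.read_csv(p)
    except (TypeError, AttributeError):
        df = pd.read_csv(source)
    except FileNotFoundError as exc:
        raise ChromophoreLoadError(f"chromophore table not found: {source}") from exc

    missing = [c for c in _ASSET_COLUMNS if c not in df.columns]
    if missing:
        raise ChromophoreLoadError(f"chromophore table missing columns {missing}")
    if df[_ASSET_COLUMNS].isna().any().any():
        row = df[df[_ASSET_COLUMNS].isna().any(axis=1)].iloc[0]
        raise ChromophoreLoadError(
            f"missing value near wavelength {row['wavelength_nm']!r} nm"
        )

    wl_src = df["wavelength_nm"].to_numpy(dtype=float)
    if grid is None:
        grid = _default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] < wl_src[0] - 1e-9 or grid[-1] > wl_src[-1] + 1e-9:
        raise ChromophoreLoadError(
            f"requested grid {grid[0]:g}-{grid[-1]:g} nm outside the "
            f"tabulated range {wl_src[0]:g}-{wl_src[-1]:g} nm"
        )
    cols = {
        name: np.interp(grid, wl_src, df[name].to_numpy(dtype=float))
        for name in _ASSET_COLUMNS[1:]
    }
    return ChromophoreLibrary(wavelengths=grid, **cols)


def isosbestic_wavelength(lib: ChromophoreLibrary, lo: float = 500.0, hi: float = 600.0) -> float:
    """First oxy/deoxy crossing wavelength in [lo, hi], by linear interpolation."""
    wl = lib.wavelengths
    d = lib.eps_hbo2 - lib.eps_hb
    m = (wl >= lo) & (wl <= hi)
    idx = np.where(m)[0]
    for i in idx[:-1]:
        if d[i] == 0.0:
            return float(wl[i])
        if d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            return float(wl[i] + t * (wl[i + 1] - wl[i]))
    raise ValueError(f"no isosbestic crossing in [{lo:g}, {hi:g}] nm")


def _baseline_absorption(layer: int, lib: ChromophoreLibrary, cfg: LayerModelConfig) -> np.ndarray:
    mu = cfg.f_water * lib.mu_water + cfg.f_fat * lib.mu_fat
    if layer == 1:
        mu = mu + cfg.f_melanin * lib.mu_melanin
    return mu


def layer_absorption(
    profile: PerfusionProfile,
    layer: int,
    lib: ChromophoreLibrary,
    cfg: LayerModelConfig,
) -> np.ndarray:
    """Absorption spectrum mu_a (1/mm) of one layer (1-indexed).

    mu_a = (vHb/scale) * [x*eps_HbO2 + (1-x)*eps_Hb] + baseline absorbers.
    """
    if not 1 <= layer <= N_LAYERS:
        raise ValueError(f"layer must be in 1..{N_LAYERS}, got {layer}")
    i = layer - 1
    v = profile.vhb[i] / cfg.vhb_scale[i]
    x = profile.xhbo2[i]
    hb = v * (x * lib.eps_hbo2 + (1.0 - x) * lib.eps_hb)
    return hb + _baseline_absorption(layer, lib, cfg)


def path_factors(lib: ChromophoreLibrary, cfg: LayerModelConfig) -> np.ndarray:
    """Per-wavelength path-length factors d(lambda) from reduced scattering.

    Normalised to 1 at the grid's scattering mean so widths stay mm-scaled.
    """
    mus = lib.mus_reduced
    return mus / float(np.mean(mus))


def _attenuations(profile, lib, cfg):
    """Cumulative two-pass transmissions E_k = exp(-2 sum_{j<=k} mu_j w_j d)."""
    d = path_factors(lib, cfg)
    tau = np.zeros_like(lib.wavelengths)
    out = np.empty((N_LAYERS, lib.n_bands))
    for k in range(N_LAYERS):
        mu = layer_absorption(profile, k + 1, lib, cfg)
        tau = tau + 2.0 * mu * cfg.widths[k] * d
        out[k] = np.exp(-tau)
    return out


def render_spectrum(
    profile: PerfusionProfile,
    lib: ChromophoreLibrary,
    cfg: LayerModelConfig,
) -> RemissionSpectrum:
    """Render the remission spectrum of a perfusion profile.

    R(lambda) = sum_k b_k * E_k(lambda), clamped to [0, 1]; deterministic.
    """
    ek = _attenuations(profile, lib, cfg)
    r = np.asarray(cfg.backscatter) @ ek
    return RemissionSpectrum(lib.wavelengths, np.clip(r, 0.0, 1.0))


def read_spectrum_csv(path) -> RemissionSpectrum:
    df = pd.read_csv(path)
    return RemissionSpectrum(
        df["wavelength_nm"].to_numpy(float), df["remission"].to_numpy(float)
    )


def write_spectrum_csv(spectrum: RemissionSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "remission": spectrum.remission}
    ).to_csv(path, index=False)
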