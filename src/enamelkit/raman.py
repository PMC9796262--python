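"""Raman band metrics for apatite mineral-quality mapping.

Per-pixel metrics from 450-1800 cm-1 spectra of mineralized tissue:

* I960  - integrated area of the nu1 phosphate band at 960 cm-1
* I1070 - integrated area of the carbonate band at 1070 cm-1
* I1070/I960 - carbonate-to-phosphate ratio, a carbonate-substitution proxy
* FWHM960 - width of the 960 band (inverse crystallinity proxy), fitted
  with a pseudo-Voigt profile whose center may be imposed

Baselines default to a straight line through flanking anchor windows per
band; a rubberband (convex hull) baseline is available for sloping
fluorescence backgrounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit.models import LinearModel, PseudoVoigtModel
from scipy.spatial import ConvexHull

__all__ = [
    "RamanSpectrum",
    "BandFit",
    "RamanMap",
    "subtract_baseline",
    "band_metrics",
    "metric_maps",
    "FWHM_DISPLAY_RANGE",
]

# display clip for FWHM960 rendering (data itself is never clipped)
FWHM_DISPLAY_RANGE = (10.0, 16.0)

PHOSPHATE_WINDOW = (930.0, 990.0)
CARBONATE_WINDOW = (1050.0, 1090.0)


@dataclass(frozen=True)
class RamanSpectrum:
    wavenumbers: np.ndarray  # cm-1, strictly increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.shape != y.shape or w.ndim != 1:
            raise ValueError("wavenumbers/intensities must be 1-D, equal length")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def window(self, lo: float, hi: float) -> "RamanSpectrum":
        sel = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return RamanSpectrum(self.wavenumbers[sel], self.intensities[sel])


@dataclass(frozen=True)
class BandFit:
    center: float
    area: float       # trapezoid over the window after baseline subtraction
    area_fit: float   # analytic area of the fitted profile
    fwhm: float
    fraction: float   # pseudo-Voigt Lorentzian fraction
    success: bool
    residual_rms: float


@dataclass
class RamanMap:
    """Rectangular grid of spectra sharing one wavenumber axis.

    cube has shape (ny, nx, n_wavenumbers); step_um is the stage step.
    """

    wavenumbers: np.ndarray
    cube: np.ndarray
    step_um: float = 18.0
    phase_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3 or self.cube.shape[2] != self.wavenumbers.size:
            raise ValueError("cube must be (ny, nx, n_wavenumbers)")

    def spectrum(self, iy: int, ix: int) -> RamanSpectrum:
        return RamanSpectrum(self.wavenumbers, self.cube[iy, ix])


def _linear_baseline(spec: RamanSpectrum,
                     anchor_windows: tuple[tuple[float, float], ...]
                     ) -> np.ndarray:
    xs, ys = [], []
    for lo, hi in anchor_windows:
        if lo < spec.wavenumbers[0] or hi > spec.wavenumbers[-1]:
            raise ValueError(
                f"anchor window ({lo}, {hi}) outside spectral range "
                f"[{spec.wavenumbers[0]}, {spec.wavenumbers[-1]}]")
        sel = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
        xs.append(spec.wavenumbers[sel])
        ys.append(spec.intensities[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    coef = np.polyfit(x, y, 1)
    return np.polyval(coef, spec.wavenumbers)


def _rubberband_baseline(spec: RamanSpectrum) -> np.ndarray:
    pts = np.column_stack([spec.wavenumbers, spec.intensities])
    hull = ConvexHull(pts)
    v = np.sort(hull.vertices)
    # keep lower hull: vertices from first to last index walking the minimum
    lower = [0]
    for idx in v:
        if idx > lower[-1] and spec.intensities[idx] <= np.interp(
                spec.wavenumbers[idx],
                [spec.wavenumbers[lower[-1]], spec.wavenumbers[-1]],
                [spec.intensities[lower[-1]], spec.intensities[-1]]) + 1e-12:
            lower.append(int(idx))
    if lower[-1] != len(spec.wavenumbers) - 1:
        lower.append(len(spec.wavenumbers) - 1)
    return np.interp(spec.wavenumbers, spec.wavenumbers[lower],
                     spec.intensities[lower])


def subtract_baseline(spec: RamanSpectrum, method: str = "linear",
                      anchor_windows: tuple[tuple[float, float], ...] = (
                          (900.0, 930.0), (990.0, 1040.0), (1090.0, 1130.0)),
                      ) -> RamanSpectrum:
    """Subtract a baseline; default is linear through anchor windows."""
    if method == "linear":
        base = _linear_baseline(spec, anchor_windows)
    elif method == "rubberband":
        base = _rubberband_baseline(spec)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return RamanSpectrum(spec.wavenumbers, spec.intensities - base)


def band_metrics(spec: RamanSpectrum, band_center: float,
                 window: tuple[float, float],
                 fix_center: bool = True,
                 baseline: str | None = "linear") -> BandFit:
    """Area (trapezoid) and FWHM (pseudo-Voigt fit) of one band.

    With ``fix_center`` the profile center is imposed at ``band_center``,
    mirroring imposed-position fitting.  A non-convergent fit returns a
    flagged BandFit with NaN metrics rather than raising.
    """
    if window[0] < spec.wavenumbers[0] or window[1] > spec.wavenumbers[-1]:
        raise ValueError(f"window {window} outside spectrum coverage")
    if baseline is not None:
        lo, hi = window
        width = hi - lo
        spec = subtract_baseline(
            spec, method="linear",
            anchor_windows=((max(spec.wavenumbers[0], lo - 0.5 * width), lo),
                            (hi, min(spec.wavenumbers[-1], hi + 0.5 * width))))
    sub = spec.window(*window)
    area = float(np.trapezoid(sub.intensities, sub.wavenumbers))

    # composite profile + linear term: absorbs residual background slope
    # (including what anchor subtraction leaves of wide Lorentzian tails)
    model = PseudoVoigtModel() + LinearModel(prefix="bg_")
    params = PseudoVoigtModel().guess(sub.intensities, x=sub.wavenumbers)
    params["center"].set(value=band_center, vary=not fix_center)
    params.add("bg_slope", value=0.0)
    params.add("bg_intercept", value=0.0)
    try:
        res = model.fit(sub.intensities, params, x=sub.wavenumbers)
        ok = res.success and np.isfinite(res.params["fwhm"].value)
    except Exception:
        res, ok = None, False
    if not ok:
        return BandFit(center=band_center, area=area, area_fit=float("nan"),
                       fwhm=float("nan"), fraction=float("nan"),
                       success=False, residual_rms=float("nan"))
    rms = float(np.sqrt(np.mean(res.residual ** 2)))
    return BandFit(center=float(res.params["center"].value), area=max(area, 0.0),
                   area_fit=float(res.params["amplitude"].value),
                   fwhm=float(res.params["fwhm"].value),
                   fraction=float(res.params["fraction"].value),
                   success=True, residual_rms=rms)


def metric_maps(rmap: RamanMap,
                phosphate_center: float = 960.0,
                carbonate_center: float = 1070.0,
                phosphate_window: tuple[float, float] = PHOSPHATE_WINDOW,
                carbonate_window: tuple[float, float] = CARBONATE_WINDOW,
                ) -> dict[str, np.ndarray]:
    """Per-pixel I960, I1070, I1070/I960 and FWHM960 rasters.

    Failed pixels become NaN; more than 20% failures raises a run-level
    warning.
    """
    ny, nx, _ = rmap.cube.shape
    i960 = np.full((ny, nx), np.nan)
    i1070 = np.full((ny, nx), np.nan)
    fwhm = np.full((ny, nx), np.nan)
    failed = 0
    for iy in range(ny):
        for ix in range(nx):
            spec = rmap.spectrum(iy, ix)
            f960 = band_metrics(spec, phosphate_center, phosphate_window)
            f1070 = band_metrics(spec, carbonate_center, carbonate_window)
            if not (f960.success and f1070.success):
                failed += 1
                continue
            i960[iy, ix] = f960.area
            i1070[iy, ix] = f1070.area
            fwhm[iy, ix] = f960.fwhm
    if failed > 0.2 * ny * nx:
        warnings.warn(f"{failed}/{ny * nx} pixels failed to fit", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i960 > 0, i1070 / i960, np.nan)
    return {"I960": i960, "I1070": i1070,
            "I1070_over_I960": ratio, "FWHM960": fwhm}


def render_metric_map(raster: np.ndarray, path: str, metric: str = "FWHM960",
                      step_um: float = 18.0) -> None:
    """Save a PNG rendering; FWHM960 display is clipped to 10-16 cm-1."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmin, vmax = (FWHM_DISPLAY_RANGE if metric == "FWHM960"
                  else (np.nanmin(raster), np.nanmax(raster)))
    fig, ax = plt.subplots()
    ny, nx = raster.shape
    im = ax.imshow(raster, vmin=vmin, vmax=vmax, cmap="viridis",
                   extent=(0, nx * step_um, ny * step_um, 0))
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.colorbar(im, ax=ax, label=metric)
    fig.savefig(path, dpi=120)
    plt.close(fig)
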