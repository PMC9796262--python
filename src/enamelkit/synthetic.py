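"""Synthetic tooth-section fixtures with known ground truth.

Generates everything the downstream stages consume - growth-line
measurement tables, per-element concentration rasters, Raman spectral
cubes, and foil calibration pseudo-measurements - for a simplified 2D
enamel wedge:

* straight prism paths from the EDJ to the OES;
* daily increment spacing (DSR) linear in path length, anchored so that
  the innermost and outermost 100-µm zone averages equal ``dsr_inner`` and
  ``dsr_outer``;
* every ``periodicity_days``-th increment accentuated (a stria);
* Sr bands parallel to the striae spanning [onset, onset+duration] in
  developmental days, imprinted simultaneously in the dentin;
* uniform Ca, surface-peaking Zn.

The day <-> distance maps are closed-form: with r(s) = a + m s,
t(s) = ln(1 + m s / a) / m and s(t) = a (exp(m t) - 1) / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean

import numpy as np
import pandas as pd

from .chronology import CrownChronology
from .raman import RamanMap
from .sxrf import (PHASE_BACKGROUND, PHASE_DENTIN, PHASE_ENAMEL, ElementMap,
                   FoilStandard, MatrixModel, attenuation_factor)
from .xraydata import KALPHA_KEV

__all__ = [
    "SrEventSpec",
    "SectionConfig",
    "GroundTruth",
    "SectionResult",
    "DEFAULT_SR_EVENTS",
    "generate_section",
    "generate_foil_standards",
    "forward_xrf_counts",
    "day_to_distance",
    "distance_to_day",
]


@dataclass(frozen=True)
class SrEventSpec:
    onset_day: float
    duration_days: float
    amplitude_ppm: float
    sign: str  # "enrich" | "deplete"

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("event duration must be > 0")
        if self.amplitude_ppm < 0:
            raise ValueError("event amplitude must be >= 0")
        if self.sign not in ("enrich", "deplete"):
            raise ValueError(f"sign must be enrich/deplete, got {self.sign!r}")


# Default banding schedule: eight alternating enrichment/depletion events
# with aperiodic onsets (inter-onset CV ~ 0.35) and durations inside the
# 33-121 day range observed for such events, all completed within the
# ~437-day cuspal window implied by the default DSR gradient.
DEFAULT_SR_EVENTS: tuple[SrEventSpec, ...] = tuple(
    SrEventSpec(onset, dur, amp, sign)
    for onset, dur, amp, sign in [
        (12.0, 33.0, 400.0, "enrich"),
        (48.0, 35.0, 120.0, "deplete"),
        (140.0, 33.0, 400.0, "enrich"),
        (178.0, 36.0, 120.0, "deplete"),
        (240.0, 33.0, 400.0, "enrich"),
        (278.0, 34.0, 120.0, "deplete"),
        (340.0, 33.0, 400.0, "enrich"),
        (385.0, 33.0, 120.0, "deplete"),
    ]
)


@dataclass(frozen=True)
class SectionConfig:
    """Parameters of the synthetic section; defaults follow the study tooth.

    ``dsr_inner``/``dsr_outer`` are the innermost and outermost zone-average
    daily secretion rates (µm/day); the gradient between them is linear in
    prism-path length.  Deciles 1-2 of the lateral enamel carry no stria
    counts - they are timed from a prism-path length and the local DSR.
    """

    cuspal_thickness_um: float = 1330.0
    dsr_inner: float = 1.96
    dsr_outer: float = 4.62
    periodicity_days: int = 8
    decile_stria_counts: tuple[int, ...] = (0, 0, 3, 5, 7, 9, 12, 14, 19, 20)
    deciles12_prism_length_um: float = 102.0
    sr_event_spec: tuple[SrEventSpec, ...] = DEFAULT_SR_EVENTS
    zn_surface_peak_ppm: float = 1800.0
    zn_interior_ppm: float = 100.0
    zn_decay_um: float = 100.0
    ca_level_ppm: float = 4.0e5
    ca_dentin_ppm: float = 3.4e5
    sr_baseline_ppm: float = 430.0
    zn_dentin_ppm: float = 220.0
    dentin_band_scale: float = 0.6
    pixel_size_um: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0
    zone_width_um: float = 100.0
    dentin_width_um: float = 400.0
    dentin_rate_um_per_day: float = 2.5
    section_height_um: float = 200.0
    margin_um: float = 20.0
    deciles12_path: str = "straight"  # or "curved"
    deciles12_curvature_factor: float = 1.05

    def __post_init__(self) -> None:
        if self.dsr_inner <= 0 or self.dsr_inner > self.dsr_outer:
            raise ValueError("require 0 < dsr_inner <= dsr_outer")
        if self.periodicity_days < 1:
            raise ValueError("periodicity must be >= 1 day")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if len(self.decile_stria_counts) != 10 or \
                any(c < 0 for c in self.decile_stria_counts):
            raise ValueError("decile_stria_counts must be 10 non-negative ints")
        if self.decile_stria_counts[0] or self.decile_stria_counts[1]:
            raise ValueError(
                "deciles 1-2 are timed from prism-path length / local DSR; "
                "their stria counts must be 0")
        if self.deciles12_path not in ("straight", "curved"):
            raise ValueError("deciles12_path must be 'straight' or 'curved'")
        total = self.total_cuspal_days
        last_end = 0.0
        for ev in self.sr_event_spec:
            if ev.onset_day < last_end:
                raise ValueError("Sr events must be ordered and non-overlapping")
            last_end = ev.onset_day + ev.duration_days
            if last_end > total:
                raise ValueError(
                    f"Sr event ending at day {last_end:.0f} falls beyond the "
                    f"cuspal window ({total:.0f} days)")

    # -- analytic DSR model ------------------------------------------------
    @property
    def _gradient(self) -> tuple[float, float]:
        """(a, m) of r(s) = a + m s anchored at zone-midpoint averages."""
        L, w = self.cuspal_thickness_um, self.zone_width_um
        n_zones = int(math.ceil(L / w))
        mid_first = w / 2
        mid_last = (min(L, (n_zones - 1) * w) + L) / 2
        if mid_last <= mid_first:  # single-zone section
            return self.dsr_inner, 0.0
        m = (self.dsr_outer - self.dsr_inner) / (mid_last - mid_first)
        return self.dsr_inner - m * mid_first, m

    @property
    def total_cuspal_days(self) -> float:
        return distance_to_day(self, self.cuspal_thickness_um)

    @property
    def deciles12_length_um(self) -> float:
        if self.deciles12_path == "curved":
            return self.deciles12_prism_length_um * self.deciles12_curvature_factor
        return self.deciles12_prism_length_um


def day_to_distance(config: SectionConfig, t: float | np.ndarray) -> np.ndarray:
    """Prism-path distance (µm from EDJ) reached after t days."""
    a, m = config._gradient
    t = np.asarray(t, dtype=float)
    if m == 0:
        return a * t
    return a * np.expm1(m * t) / m


def distance_to_day(config: SectionConfig, s: float | np.ndarray) -> np.ndarray:
    """Developmental day at prism-path distance s (µm from EDJ)."""
    a, m = config._gradient
    s = np.asarray(s, dtype=float)
    if m == 0:
        return s / a
    return np.log1p(m * s / a) / m


@dataclass(frozen=True)
class GroundTruth:
    chronology: CrownChronology
    event_days: tuple[tuple[str, float, float], ...]  # (label, onset, duration)
    element_fields: dict[str, np.ndarray]
    zone_mean_rates: tuple[float, ...]
    total_cuspal_days_analytic: float

    def __post_init__(self) -> None:
        onsets = [o for _, o, _ in self.event_days]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")


@dataclass
class SectionResult:
    config: SectionConfig
    tables: dict[str, pd.DataFrame]
    element_maps: dict[str, ElementMap]
    raman_map: RamanMap
    ground_truth: GroundTruth

    def midline_transect(self, element: str = "Sr"):
        """EDJ->OES transect along the section midline, sampled at pixel
        centers so raster values pass through unblended."""
        from .io import extract_transect

        cfg = self.config
        px = cfg.pixel_size_um
        y = (round((cfg.margin_um + cfg.section_height_um / 2) / px) + 0.5) * px
        x0 = cfg.margin_um + cfg.dentin_width_um + px / 2
        return extract_transect(
            self.element_maps[element],
            [(x0, y), (x0 + cfg.cuspal_thickness_um - px, y)])


def _increment_positions(config: SectionConfig) -> np.ndarray:
    """Positions (µm from EDJ) of daily increment boundaries, day 0 first."""
    total = config.total_cuspal_days
    days = np.arange(0.0, math.floor(total) + 1.0)
    return day_to_distance(config, days)


def _spacing_table(config: SectionConfig, rng: np.random.Generator,
                   noiseless: bool) -> pd.DataFrame:
    """Per-zone spacing measurements, each bridging 3 cross-striations."""
    s = _increment_positions(config)
    w = config.zone_width_um
    rows = []
    mids = (s[:-3] + s[3:]) / 2
    zones = np.minimum((mids // w).astype(int),
                       int(math.ceil(config.cuspal_thickness_um / w)) - 1)
    for k in range(0, len(s) - 3, 3):
        span = s[k + 3] - s[k]
        if not noiseless and config.noise_sd > 0:
            span *= 1.0 + config.noise_sd * rng.standard_normal()
        rows.append({"zone_index": int(zones[k]),
                     "span_um": float(span), "n_crossings": 3})
    return pd.DataFrame(rows)


def _truth_chronology(config: SectionConfig,
                      spacing: pd.DataFrame) -> tuple[CrownChronology, tuple]:
    """Chronology arithmetic applied inline to the noiseless tables."""
    by_zone: dict[int, list[float]] = {}
    for r in spacing.itertuples():
        by_zone.setdefault(int(r.zone_index), []).append(r.span_um / r.n_crossings)
    zone_rates = tuple(fmean(by_zone[z]) for z in sorted(by_zone))
    cuspal = config.cuspal_thickness_um / fmean(zone_rates)
    d12 = round(config.deciles12_length_um / config.dsr_inner)
    per_decile = (d12, 0) + tuple(
        c * config.periodicity_days for c in config.decile_stria_counts[2:])
    chron = CrownChronology(cuspal_days=round(cuspal), deciles12_days=d12,
                            per_decile_days=per_decile)
    return chron, zone_rates


def _element_fields(config: SectionConfig, shape: tuple[int, int],
                    x_edj_px: int, phase_mask: np.ndarray
                    ) -> dict[str, np.ndarray]:
    ny, nx = shape
    px = config.pixel_size_um
    col_um = (np.arange(nx) + 0.5) * px  # pixel-center x coordinate
    enamel_s = col_um - (x_edj_px * px)  # path distance from EDJ (enamel > 0)
    L = config.cuspal_thickness_um

    ca_row = np.zeros(nx)
    zn_row = np.zeros(nx)
    sr_row = np.full(nx, 0.0)

    en = (enamel_s >= 0) & (enamel_s <= L)
    de = enamel_s < 0
    ca_row[en] = config.ca_level_ppm
    ca_row[de] = config.ca_dentin_ppm
    zn_row[en] = config.zn_interior_ppm + \
        (config.zn_surface_peak_ppm - config.zn_interior_ppm) * \
        np.exp(-(L - enamel_s[en]) / config.zn_decay_um)
    zn_row[de] = config.zn_dentin_ppm
    sr_row[en | de] = config.sr_baseline_ppm

    # Sr bands: enamel pixels by the enamel clock, dentin pixels by a
    # constant dentin apposition rate - the same developmental days.
    t_en = np.full(nx, np.nan)
    t_en[en] = distance_to_day(config, enamel_s[en])
    t_de = np.full(nx, np.nan)
    t_de[de] = -enamel_s[de] / config.dentin_rate_um_per_day
    for ev in config.sr_event_spec:
        amp = ev.amplitude_ppm if ev.sign == "enrich" else -ev.amplitude_ppm
        in_band_en = en & (t_en >= ev.onset_day) & \
            (t_en <= ev.onset_day + ev.duration_days)
        in_band_de = de & (t_de >= ev.onset_day) & \
            (t_de <= ev.onset_day + ev.duration_days)
        sr_row[in_band_en] += amp
        sr_row[in_band_de] += amp * config.dentin_band_scale
    sr_row = np.clip(sr_row, 0.0, None)

    fields = {}
    for name, row in (("Ca", ca_row), ("Zn", zn_row), ("Sr", sr_row)):
        grid = np.tile(row, (ny, 1))
        grid[phase_mask == PHASE_BACKGROUND] = 0.0
        fields[name] = grid
    return fields


def _raman_cube(config: SectionConfig, rng: np.random.Generator
                ) -> tuple[RamanMap, np.ndarray]:
    """Small spectral map: dentin columns (left) broader 960 band and more
    carbonate than enamel columns (right)."""
    wn = np.arange(450.0, 1800.0 + 1e-9, 3.0)
    ny, nx = 4, 10
    n_dentin = 4
    cube = np.zeros((ny, nx, wn.size))
    mask = np.full((ny, nx), PHASE_ENAMEL)
    mask[:, :n_dentin] = PHASE_DENTIN
    for ix in range(nx):
        dentin = ix < n_dentin
        fwhm960 = 15.0 if dentin else 11.5
        ratio = 0.25 if dentin else 0.10
        a960 = 100.0
        sig = fwhm960 / 2.3548
        g960 = a960 / (sig * math.sqrt(2 * math.pi)) * \
            np.exp(-0.5 * ((wn - 960.0) / sig) ** 2)
        sig2 = 14.0 / 2.3548
        g1070 = ratio * a960 / (sig2 * math.sqrt(2 * math.pi)) * \
            np.exp(-0.5 * ((wn - 1070.0) / sig2) ** 2)
        base = 0.5 + 0.001 * (wn - 450.0)
        for iy in range(ny):
            y = g960 + g1070 + base
            if config.noise_sd > 0:
                y = y + config.noise_sd * 0.1 * y.max() * \
                    rng.standard_normal(wn.size)
            cube[iy, ix] = y
    return RamanMap(wavenumbers=wn, cube=cube, step_um=18.0,
                    phase_mask=mask), mask


def generate_section(config: SectionConfig) -> SectionResult:
    """Generate measurement tables, element maps, a Raman map and truth.

    Deterministic under ``config.seed``; ``noise_sd`` applies
    multiplicatively to rasters and spacing spans (Gaussian).
    """
    rng = np.random.default_rng(config.seed)

    spacing_clean = _spacing_table(config, rng, noiseless=True)
    spacing = _spacing_table(config, np.random.default_rng(config.seed + 1),
                             noiseless=False) \
        if config.noise_sd > 0 else spacing_clean
    deciles = pd.DataFrame({
        "decile": np.arange(1, 11),
        "stria_count": list(config.decile_stria_counts)})
    period_tbl = pd.DataFrame({
        "location": [1, 2, 3],
        "crossings_between_striae": [config.periodicity_days] * 3})

    chron, zone_rates = _truth_chronology(config, spacing_clean)

    # raster geometry: [margin | dentin | enamel | margin] columns
    px = config.pixel_size_um
    m_px = int(round(config.margin_um / px))
    d_px = int(round(config.dentin_width_um / px))
    e_px = int(round(config.cuspal_thickness_um / px))
    ny = int(round(config.section_height_um / px)) + 2 * m_px
    nx = m_px + d_px + e_px + m_px
    x_edj = m_px + d_px
    phase_mask = np.full((ny, nx), PHASE_BACKGROUND)
    phase_mask[m_px:ny - m_px, m_px:m_px + d_px] = PHASE_DENTIN
    phase_mask[m_px:ny - m_px, x_edj:x_edj + e_px] = PHASE_ENAMEL

    fields = _element_fields(config, (ny, nx), x_edj, phase_mask)
    maps = {}
    for el, grid in fields.items():
        noisy = grid
        if config.noise_sd > 0:
            noisy = grid * (1.0 + config.noise_sd *
                            rng.standard_normal(grid.shape))
            noisy = np.clip(noisy, 0.0, None)
        maps[el] = ElementMap(element=el, grid=noisy, pixel_size_um=px,
                              units_state="ppm", phase_mask=phase_mask)

    raman_map, _ = _raman_cube(config, rng)

    truth = GroundTruth(
        chronology=chron,
        event_days=tuple(
            (lbl, ev.onset_day, ev.duration_days)
            for lbl, ev in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ",
                               config.sr_event_spec)),
        element_fields=fields,
        zone_mean_rates=zone_rates,
        total_cuspal_days_analytic=float(config.total_cuspal_days),
    )
    tables = {"spacing": spacing, "deciles": deciles,
              "periodicity": period_tbl}
    return SectionResult(config=config, tables=tables, element_maps=maps,
                         raman_map=raman_map, ground_truth=truth)


def generate_foil_standards(elements: tuple[str, ...] = ("Ti", "Fe", "Cu"),
                            areal_densities: tuple[float, ...] = (59.0, 55.0, 47.9),
                            sensitivity_truth: dict[str, float] | None = None,
                            flux: float = 1.0,
                            poisson_noise: bool = False,
                            seed: int = 0) -> list[FoilStandard]:
    """Foil pseudo-measurements: counts = sensitivity x areal density x flux."""
    if flux <= 0:
        raise ValueError("flux must be > 0")
    if any(ad <= 0 for ad in areal_densities):
        raise ValueError("areal densities must be > 0")
    if sensitivity_truth is None:
        sensitivity_truth = {el: 2.0 for el in elements}
    rng = np.random.default_rng(seed)
    foils = []
    for el, ad in zip(elements, areal_densities):
        counts = sensitivity_truth[el] * ad * flux
        if poisson_noise:
            counts = float(rng.poisson(counts))
        foils.append(FoilStandard(element=el, areal_density_ug_cm2=ad,
                                  counts=counts, flux=flux))
    return foils


def forward_xrf_counts(ppm_map: ElementMap, sensitivity: float,
                       matrix: MatrixModel,
                       flux: np.ndarray | float = 1.0,
                       background: np.ndarray | float = 0.0) -> ElementMap:
    """Forward model: ppm field -> detector counts (inverse of quantify_map)."""
    if ppm_map.units_state != "ppm":
        raise ValueError("forward model expects a ppm map")
    if ppm_map.phase_mask is None:
        raise ValueError("forward model requires a phase mask")
    line_e = KALPHA_KEV[ppm_map.element]
    counts = np.zeros_like(ppm_map.grid)
    for code, phase in ((PHASE_ENAMEL, "enamel"), (PHASE_DENTIN, "dentin")):
        sel = ppm_map.phase_mask == code
        if not np.any(sel):
            continue
        rho_t = matrix.density(phase) * matrix.thickness_um * 1e-4
        a = attenuation_factor(line_e, matrix, phase)
        counts[sel] = ppm_map.grid[sel] * rho_t * a * sensitivity
    counts = (counts + background) * np.broadcast_to(
        np.asarray(flux, dtype=float), counts.shape)
    return ElementMap(element=ppm_map.element, grid=counts,
                      pixel_size_um=ppm_map.pixel_size_um,
                      units_state="counts", phase_mask=ppm_map.phase_mask)
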