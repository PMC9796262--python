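# Methods

`enamelkit` analyzes thin sections of tooth crowns: it reconstructs the
developmental chronology of the enamel from incremental growth markings,
registers trace-element banding onto that chronology, and quantifies
elemental and mineral-quality maps. This note records the models, the
defaults and why they were chosen, and what the synthetic fixtures do and
do not establish.

## Growth chronology

Enamel is deposited by ameloblasts in daily increments (cross-striations)
along prisms running from the enamel–dentin junction (EDJ) to the outer
enamel surface (OES). The spacing of successive increments is the daily
secretion rate (DSR, µm/day). Accentuated longer-period lines (striae of
Retzius) recur every *P* daily increments; *P* (the periodicity, in days)
is taken as constant for a tooth and is estimated as the modal
cross-striation count between adjacent striae over several sampling
locations (a tie resolves to the smallest mode, with a warning — the
conservative choice, flagged for review).

The crown formation time decomposes as

```
T_total   = T_cuspal + T_lateral
T_cuspal  = cuspal enamel thickness / mean cuspal DSR
T_lateral = T_deciles1-2 + Σ_{d=3..10} (stria count in decile d) × P
```

where the cuspal transect is divided into 100-µm zones, each zone's DSR is
the arithmetic mean of spacing measurements (each bridging at least three
cross-striations), and the mean cuspal DSR is the unweighted mean of zone
means — with equal-width zones this coincides with a length-weighted mean
except in a partial last zone. Crown height is divided into ten deciles
from cusp tip to cervix; in deciles 1–2 striae are usually unresolvable, so
their time is the prism-path length through them divided by the local DSR,
rounded to whole days. All computation is floating point; day counts are
rounded only at report time, and years are days/365 to two decimals.

The per-decile report keeps deciles 1–2 as a single, jointly estimated
entry (index 0; index 1 is zero) because the length/DSR estimate cannot be
split between them observationally.

## Synthetic sections

The generator builds a simplified 2D wedge: straight prism paths, DSR
linear in path length, striae (and Sr bands) as iso-distance fronts
parallel to the EDJ. Straight prisms lose nothing for the chronology
arithmetic, which depends only on path-length parameterization; curved
prisms are an image-reading concern. For the jointly timed deciles 1–2 the
prism-path length can optionally be inflated by a curvature factor
(`deciles12_path="curved"`) for sensitivity testing.

`dsr_inner` and `dsr_outer` (defaults 1.96 and 4.62 µm/day) are anchored as
the innermost and outermost *zone averages*, matching how zone tables are
reported; the linear gradient runs between the first and last zone
midpoints. With r(s) = a + m·s the day↔distance maps are closed form:
t(s) = ln(1 + m·s/a)/m and s(t) = a·(e^{mt} − 1)/m, mutually inverse. Under
these defaults the 1330 µm cuspal transect forms in ≈437 days (the exact
integral of 1/r); the thickness-over-mean-DSR estimator applied to the same
geometry gives ≈404 days. The two differ because the estimator replaces a
harmonic-style integral by an arithmetic mean — an inherent property of the
method, visible here because the synthetic gradient is exactly linear.

Default study conditions: cuspal thickness 1330 µm, periodicity 8 days,
decile stria counts (–, –, 3, 5, 7, 9, 12, 14, 19, 20) summing to 89 for
deciles 3–10, deciles 1–2 timed from 102 µm at 1.96 µm/day (52 days).
Element fields: uniform Ca at 4.0×10⁵ ppm (enamel) and 3.4×10⁵ ppm
(dentin); Zn rising exponentially (length scale 100 µm) from 100 ppm
interior to an 1800 ppm OES peak; Sr at a 430 ppm baseline carrying eight
alternating enrichment (+400 ppm) / depletion (−120 ppm) bands with
aperiodic onsets (12, 48, 140, 178, 240, 278, 340, 385 days; inter-onset
CV ≈ 0.35) and durations of 33–36 days, inside the 33–121-day range
reported for such events; eight non-overlapping events must fit the
≈437-day cuspal window, which keeps the durations at the low end of that
range. The same banding is imprinted in the dentin (at a constant
2.5 µm/day apposition rate and 0.6× amplitude), as such events appear
simultaneously in both tissues. Noise is multiplicative Gaussian on rasters
and spacing spans (default 2%, the high-SNR regime of synchrotron maps) and
Poisson on foil counts — standard detector statistics. Everything is
deterministic under a fixed seed.

What the synthetic fixtures do **not** emulate: curved prisms and striae,
spatially correlated instrument noise, beam-hardening or thickness
variation across the section, diagenetic overprinting, or partial-volume
mixing at the EDJ. Passing recovery tests therefore demonstrates the
correctness of the arithmetic and the detection logic under the stated
noise model, not performance on raw micrographs.

## Sr event registration

A concentration transect sampled along a prism path is segmented into
events by exceedance of a running-median baseline. Two implementation
choices matter at realistic band coverage (more than half the transect can
lie inside bands):

* The **noise scale** is a robust sigma from lag-1 differences,
  σ = 1.4826·median|Δv|/√2, rather than a running MAD of residuals: the
  bands themselves inflate a MAD until genuine depletions fall below a
  3·MAD threshold. The lag-1 estimator sees only point-to-point noise.
* The **baseline window** (default 400 µm) must straddle the widest band;
  a window narrower than twice the band width absorbs the band into the
  baseline and truncates or splits it.

Runs exceeding k·σ (default k = 3) are tagged enrich/deplete by sign,
same-sign runs closer than one sample spacing are merged, isolated
single-sample exceedances are discarded as noise, and events are lettered
A, B, … in order of formation (increasing distance from the EDJ). Event
edges are placed half a sample beyond the exceeding run, so a band's
detected extent matches its true extent to about one pixel.

Distances convert to developmental days by exact piecewise-constant
integration of the zone DSR profile (each traversed zone contributes
length/rate), matching the methodology used for the cuspal time rather
than a single global mean rate. Regularity of the event train is judged
from the coefficient of variation of inter-onset intervals: fewer than
three events is indeterminate; otherwise the verdict is periodic only if
CV ≤ 0.25 *and* a seeded Monte-Carlo comparison against uniformly random
onsets over the same span puts the observed CV below the 5th percentile.
Both guards are needed because the underlying claim — "no regular
pattern" — is qualitative.

The Sr/(Sr+Ca) molar ratio is computed from mass fractions with
M(Sr) = 87.62 and M(Ca) = 40.08 g/mol. Note that an 860 ppm Sr peak
against 4.0×10⁵ ppm Ca gives ≈0.00098 by direct arithmetic; the function
reports what the inputs imply and nothing is hard-coded.

## SXRF quantification

Net K-α intensity maps are calibrated through

```
counts → /flux → −background → /sensitivity   (areal density, µg/cm²)
       → /A(E)  → /(ρ·t)                       (mass fraction, ppm)
```

Sensitivity (counts per µg/cm² at unit flux) is anchored on thin
single-element foils (Ti/Fe/Cu at 59.0/55.0/47.9 µg/cm²) and interpolated
log-linearly in fluorescence-line energy between anchors; queries outside
the anchor range are answered but flagged as extrapolated. The
self-attenuation factor uses the intermediate-thickness form
A = (1 − e^{−χρt})/(χρt) with
χ = µ/ρ(E₀)/sin ψ_in + µ/ρ(E_line)/sin ψ_out, which reduces to the thin
(A→1) and thick (A→1/χρt) limits. Matrix µ/ρ is the mass-weighted
hydroxyapatite (Ca₁₀(PO₄)₆(OH)₂) mixture over Ca, P, O, H, with enamel at
2.85 and dentin at 1.6 g/cm³ and per-specimen thickness (160 µm for the
case-study section, 61 µm for the control). Geometry defaults to normal
incidence with a 45° take-off — a representative choice for a backscatter
dual-detector layout at 135° scattering, with both angles configurable;
the two detectors are treated as one summed channel.

µ/ρ values ship as a small embedded 3–20 keV table (log-log interpolated,
Ca K-edge split at 4.038 keV) derived from Cromer–Liberman photoabsorption
cross sections, so runs are bit-reproducible without an atomic-data
service. Photoabsorption dominates total attenuation at these energies for
Z ≥ 8; the neglected scattering contribution (and hydrogen's ≈0.2% mass
share) biases matrix µ/ρ by a few percent at most, which cancels in the
calibrated round trip. Degenerate inputs are handled without NaN
propagation: zero-flux pixels are masked to zero and counted, negative
post-background values are clipped to zero and counted, background-phase
pixels report 0 ppm.

Map denoising is a normalized Gaussian kernel (default 0.8 px), which is
mass-preserving away from edges.

## Raman band metrics

Per-pixel metrics from 450–1800 cm⁻¹ spectra: the integrated areas of the
ν₁ phosphate band at 960 cm⁻¹ (I₉₆₀) and the carbonate band at 1070 cm⁻¹
(I₁₀₇₀), their ratio (carbonate-substitution proxy), and FWHM₉₆₀ (inverse
crystallinity proxy). Integration windows default to 930–990 and
1050–1090 cm⁻¹ — standard apatite practice — and are configurable.

The baseline is a straight line fitted through flanking anchor windows
(a rubberband/convex-hull option exists for curved fluorescence
backgrounds). The band profile for width estimation is a pseudo-Voigt —
it subsumes the Gaussian and Lorentzian limits — fitted jointly with a
linear background term, with the center imposed at the nominal band
position by default (imposed-position fitting); the joint linear term
absorbs whatever a straight baseline cannot represent, including the
wings of wide Lorentzian bands, so closed-form widths (2.3548σ, Γ) are
recovered to well under 0.5%. Each fit reports both the trapezoid area
over the window (the mapping metric) and the analytic area of the fitted
profile; non-convergent pixels are flagged and set to NaN, and a run-level
warning fires if more than 20% of pixels fail. FWHM₉₆₀ renderings clip the
*display* to 10–16 cm⁻¹; the data are never clipped.

## EDX ratios

Per specimen and enamel layer (outer/inner, at least three spots each) the
module reports max/min/mean/SD of P, Ca and Mg atomic percent, plus Ca/P
and (Ca+Mg)/P computed as ratios of the *unrounded* means (rounding to two
decimals only at report time). Ratio-of-means is the default because it
reproduces published inner-layer values exactly; averaging per-spot ratios
is a different estimator and is intentionally not silently substituted.

## Pipeline and reproducibility

Stages (`simulate`, `chronology`, `events`, `sxrf`, `raman`, `edx`,
`worked-example`) run in dependency order from a `RunConfig`; every report
embeds the package version, the seed and a config hash, and a fixed
config + seed yields a byte-identical `report.json`. Rasters use pixel-
center, 0-based, row-major coordinates with the pixel size in µm in a JSON
sidecar. On failure the completed-stage manifest is retained and the exit
is non-zero.

Problem sizes used by the test suite and the acceptance script — a
1330 µm × ~200 µm section at 2 µm pixels (~10⁵ pixels per element), a
4×10-pixel Raman cube, 100 foil replicates — were chosen so the full suite
exercises every stage end to end in seconds while leaving the recovery
statistics comfortably resolved.

## Known limitations

* The chronology operates on measurement tables; automatic detection of
  cross-striations in raw micrographs is out of scope (detection exists
  only for synthetic transects).
* The event detector assumes bands narrower than the baseline window and
  approximately piecewise-constant baselines; overlapping events of the
  same sign merge.
* The XRF chain starts from net intensities: spectral deconvolution,
  secondary fluorescence, pile-up and per-detector effects are upstream or
  out of scope.
* Raman metrics assume a single dominant band per window; shoulder bands
  bias both area and width.
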