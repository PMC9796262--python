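# enamelkit

Quantitative analysis of tooth thin sections for dental histology and
biomineralization studies: enamel growth chronology from incremental
markings, registration of trace-element (Sr) banding onto developmental
time, synchrotron-XRF elemental-map quantification with foil calibration
and matrix attenuation correction, Raman apatite band metrics, and EDX
atomic-ratio summaries. A synthetic tooth-section generator with known
ground truth makes every stage testable end to end without instrument
data.

It is aimed at researchers who have growth-line measurement tables,
net-intensity element maps, Raman spectral maps or EDX tables from a
sectioned tooth and want a reproducible, scripted route from those inputs
to formation times, timed elemental events and calibrated concentration
maps.

## The models in brief

**Chronology.** Cross-striations are daily increments; their spacing is the
daily secretion rate (DSR). Striae of Retzius recur every *P* days (*P* =
modal cross-striation count between striae). Formation time decomposes as

    T_total  = T_cuspal + T_lateral
    T_cuspal = cuspal thickness / mean cuspal DSR      (100-µm zone means)
    T_lateral = T_deciles1-2 + Σ_{d=3..10} count_d × P

with deciles 1–2 timed as prism-path length / local DSR.

**Event registration.** Sr enrichments/depletions along an EDJ→OES transect
are maximal runs where |value − running median| exceeds k·σ (σ robustly
estimated from lag-1 differences), lettered A, B, … in formation order.
Distances become days by piecewise integration over zone DSRs:
days = Σ (length in zone / zone DSR). Regularity is judged by the CV of
inter-onset intervals plus a Monte-Carlo guard.

**SXRF quantification.** counts → flux-normalized → background-subtracted →
÷ foil sensitivity (areal density, µg/cm²) → ÷ attenuation factor
A = (1 − e^{−χρt})/(χρt) → ÷ ρt → ppm, with χ = µ/ρ(E₀)/sin ψ_in +
µ/ρ(E_line)/sin ψ_out and hydroxyapatite-mixture µ/ρ.

**Raman.** I₉₆₀ and I₁₀₇₀ band areas after linear-anchor baseline
subtraction, I₁₀₇₀/I₉₆₀ (carbonate substitution) and FWHM₉₆₀
(inverse crystallinity) from a center-imposed pseudo-Voigt fit.

**EDX.** Per-layer element statistics and Ca/P, (Ca+Mg)/P as ratios of
unrounded means.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The built-in replication preset recomputes the published case-study
numbers (a retained third molar from a patient with HELIX syndrome) from
the printed inputs:

```
$ enamelkit worked-example --out out
report written to out/report.json
```

`out/report.json` contains (abridged):

```json
"chronology": {
  "cuspal_days": 564,
  "deciles12_days": 52,
  "lateral_decile_days_3_10": 712,
  "lateral_days": 764,
  "total_days": 1328,
  "total_years": 3.64,
  "periodicity_days": 8
},
"edx_ratios": [
  {"specimen": "HELIX",   "layer": "outer", "Ca_P": 1.54, "CaMg_P": 1.56},
  {"specimen": "control", "layer": "outer", "Ca_P": 1.58, "CaMg_P": 1.6},
  {"specimen": "HELIX",   "layer": "inner", "Ca_P": 1.59, "CaMg_P": 1.62},
  {"specimen": "control", "layer": "inner", "Ca_P": 1.6,  "CaMg_P": 1.63}
]
```

Reading: the cuspal enamel took 564 days; deciles 1–2 of the lateral
enamel took 52 days (102 µm at 1.96 µm/day); the 89 striae in deciles 3–10
at an 8-day periodicity add 712 days; the crown formed in 1328 days
(3.64 years). The EDX block gives per-layer Ca/P and (Ca+Mg)/P atomic
ratios for the case and control enamel.

A fully synthetic run — generate a section, recover its chronology and
time its Sr bands — looks like:

```
$ enamelkit -v simulate --out out --noise-sd 0.02
$ python - <<'PY'
from enamelkit.synthetic import SectionConfig, generate_section
from enamelkit.chronology import dsr_profile, spacing_table_to_measurements
from enamelkit.events import detect_events, time_events

sec = generate_section(SectionConfig())
prof = dsr_profile(spacing_table_to_measurements(sec.tables["spacing"]))
timeline = time_events(detect_events(sec.midline_transect("Sr")), prof)
for e in timeline.events:
    print(f"{e.label} {e.kind:7s} day {e.onset_day:5.1f} "
          f"for {e.duration_days:4.1f} d")
print("verdict:", timeline.verdict)
PY
A enrich  day  10.7 for 33.6 d
B deplete day  47.4 for 34.6 d
C enrich  day 140.0 for 33.3 d
D deplete day 177.9 for 36.6 d
E enrich  day 240.4 for 32.7 d
F deplete day 278.1 for 34.3 d
G enrich  day 340.2 for 33.2 d
H deplete day 385.7 for 33.0 d
verdict: aperiodic
```

Eight injected bands are recovered with onsets/durations within a couple
of days of ground truth, and the event train is correctly judged
aperiodic.

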