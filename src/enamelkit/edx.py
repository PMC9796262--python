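"""EDX atomic-percent summaries and Ca/P, (Ca+Mg)/P ratios per enamel layer.

Measurements are atomic % of P, Ca and Mg taken in the outer and inner
enamel layers (at least three spots per layer).  Ratios are computed as
ratio-of-means on unrounded means; rounding (one decimal for elements, two
for ratios) happens only at report time.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["layer_summary", "ratios_from_means", "ELEMENTS"]

ELEMENTS = ("P", "Ca", "Mg")


def ratios_from_means(p: float, ca: float, mg: float) -> dict[str, float]:
    """Ca/P and (Ca+Mg)/P from layer-mean atomic percents (unrounded)."""
    if p <= 0:
        raise ValueError("P atomic percent must be > 0")
    return {"Ca_P": ca / p, "CaMg_P": (ca + mg) / p}


def layer_summary(measurements: pd.DataFrame, min_per_layer: int = 3
                  ) -> pd.DataFrame:
    """Per specimen x layer max/min/mean/sd per element plus ratios.

    Expects columns specimen, layer (outer|inner), P, Ca, Mg.  Statistics
    are reported to one decimal (elements) and two decimals (ratios); the
    ratios are taken on the unrounded means.
    """
    missing = {"specimen", "layer", *ELEMENTS} - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (measurements[list(ELEMENTS)] < 0).any().any():
        raise ValueError("atomic percents must be non-negative")

    rows = []
    for (spec, layer), grp in measurements.groupby(["specimen", "layer"],
                                                   sort=False):
        if len(grp) < min_per_layer:
            raise ValueError(
                f"{spec}/{layer}: {len(grp)} measurements, "
                f"need >= {min_per_layer}")
        row: dict[str, object] = {"specimen": spec, "layer": layer,
                                  "n": len(grp)}
        means = {}
        for el in ELEMENTS:
            vals = grp[el]
            means[el] = vals.mean()
            row[f"{el}_max"] = round(vals.max(), 1)
            row[f"{el}_min"] = round(vals.min(), 1)
            row[f"{el}_mean"] = round(means[el], 1)
            row[f"{el}_sd"] = round(vals.std(ddof=1), 1)
        ratios = ratios_from_means(means["P"], means["Ca"], means["Mg"])
        row["Ca_P"] = round(ratios["Ca_P"], 2)
        row["CaMg_P"] = round(ratios["CaMg_P"], 2)
        rows.append(row)
    return pd.DataFrame(rows)
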