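#!/usr/bin/env python
"""Apply the image-analysis pipeline to synthetic dewetting time series.

Generates control and transformed (dewetting-like) island series, measures
footprint morphometrics per frame, decomposes the traction into edge-relative
components, builds the ring-averaged radial-traction kymograph, and compares
whole/outer/inner subdomain statistics. Writes results/morphometrics_<mode>.csv,
results/kymograph_transformed.csv, and results/subdomain_stats_transformed.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dewetsim import (
    decompose_traction,
    morphometrics,
    ring_kymograph,
    ring_labels,
    subdomain_timeseries,
)
from dewetsim.synth import SynthParams, synth_dewetting_series

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = SynthParams(
    radius=200.0,
    pixel_size=4.0,
    boundary_noise_amp=6.0,
    field_noise_sd=0.02,
    n_frames=12,
    seed=7,
)

for mode in ("control", "transformed"):
    series = synth_dewetting_series(params, mode=mode)
    rows = []
    for i, mask in enumerate(series.masks):
        rec = morphometrics(mask)
        rows.append(
            {
                "frame": i,
                "area_um2": rec.area,
                "aspect_ratio": rec.aspect_ratio,
                "circularity": rec.circularity,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / f"morphometrics_{mode}.csv", index=False)
    print(
        f"{mode}: area {df.area_um2.iloc[0]:.3g} -> {df.area_um2.iloc[-1]:.3g} um^2, "
        f"aspect ratio {df.aspect_ratio.iloc[0]:.2f} -> {df.aspect_ratio.iloc[-1]:.2f}, "
        f"circularity {df.circularity.iloc[0]:.2f} -> {df.circularity.iloc[-1]:.2f}"
    )

series = synth_dewetting_series(params, mode="transformed")
tps, rings = [], []
for mask, field in zip(series.masks, series.fields):
    tp, _ = decompose_traction(field, mask)
    tps.append(tp)
    rings.append(ring_labels(mask))
ky = ring_kymograph(tps, rings)
pd.DataFrame(
    ky.data,
    index=pd.RangeIndex(1, ky.n_rings + 1, name="ring"),
    columns=[f"frame_{i}" for i in range(len(tps))],
).to_csv(OUT / "kymograph_transformed.csv")
peak_rings = np.nanargmax(ky.data, axis=0) + 1
print(
    f"kymograph: radial traction peaks at ring {peak_rings.min()}–{peak_rings.max()} "
    "(tissue edge) in every frame — traction stays rim-concentrated as the island dewets."
)

stats = subdomain_timeseries(series.fields, series.masks)
stats.to_csv(OUT / "subdomain_stats_transformed.csv", index=False)
outer = stats[stats.domain == "outer"].median_mag.values
inner = stats[stats.domain == "inner"].median_mag.values
print(
    f"subdomains: outer median |T| exceeds inner in {np.sum(outer > inner)}/{len(outer)} "
    "frames (equal-pixel split)."
)
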