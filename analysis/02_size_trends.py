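#!/usr/bin/env python
"""Species- and community-level size trends with seasonal cross-check.

Reads the simulated monitoring tables from 01_simulate.py, fits linear
trends of species biovolume (top species per group, region scale),
community mean size and Small% (per station) against lagged months, both
directly and after period-12 seasonal adjustment, applies
Benjamini-Hochberg within each family, and reports how many species/
stations decline.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402

from phytosize import data, size_metrics as sm, trends as tr  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main():
    obs = data.read_observations(DATA / "observations.csv").records
    origin = obs["date"].min()

    top = sm.select_top_species(obs, {"diatom": 10, "dinoflagellate": 10, "other": 5})
    series = [sm.species_size_series(obs, sp, scope="region", origin=origin) for sp in top["species_id"]]
    sp_trends = tr.trend_table(series, top["species_id"])
    sp_trends.insert(0, "scope", "region")
    sp_trends.to_csv(OUT / "species_trends.csv", index=False)

    comm = sm.community_size_table(obs, origin)
    small = sm.classify_small_species(obs)
    sf = sm.small_fraction_table(obs, small, origin=origin)

    def station_trends(table, col, fname):
        ser, ids = [], []
        for st, g in table.groupby("station_id"):
            ser.append((g["lagged_month"].to_numpy(float), g[col].to_numpy(float)))
            ids.append(st)
        out = tr.trend_table(ser, ids)
        out.insert(0, "scope", "station")
        out.to_csv(OUT / fname, index=False)
        return out

    comm_trends = station_trends(comm, "community_mean_size", "community_trends.csv")
    small_trends = station_trends(sf, "small_fraction", "small_fraction_trends.csv")

    lm = sp_trends.query("method == 'lm'")
    n_decline = (lm["class"] == "decline").sum()
    n_q = ((lm["class"] == "decline") & (lm["q"] < 0.05)).sum()
    print(f"top {len(lm)} species, region scale: {n_decline} significant biovolume declines "
          f"(BH-confirmed: {n_q}); {int((lm['class'] == 'increase').sum())} increases")
    ds = sp_trends.query("method == 'deseason'")
    print(f"  de-seasoned cross-check: {(ds['class'] == 'decline').sum()} declines")
    print(f"small-species threshold: {small.threshold:.1f} um^3 "
          f"(ESD {sm.esd_from_biovolume(small.threshold):.1f} um), {len(small.members)} species")
    for name, t in (("community mean size", comm_trends), ("Small%", small_trends)):
        lmt = t.query("method == 'lm'")
        print(f"{name}: {(lmt['class'] == 'decline').sum()} station declines, "
              f"{(lmt['class'] == 'increase').sum()} increases, "
              f"{(lmt['class'] == 'none').sum()} non-significant of {len(lmt)}")
    med_arc = np.median([tr.annual_relative_change(tr.linear_trend(s)) for s in series])
    print(f"median annual relative change in species biovolume: {med_arc:.2f}% per year")


if __name__ == "__main__":
    main()
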