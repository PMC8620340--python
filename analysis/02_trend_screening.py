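"""Trend screening of the panel: Mann-Kendall + Sen slopes per station and
per year, Kruskal-Wallis homogeneity across sites and across years, and
loess smooths of the spatio-temporal variation at three spans.

Reads results/panel.csv; writes the Sen-slope grids ('-' where the null
stands), the Kruskal-Wallis table, and the loess fitted values.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from riverwqi import loess_fit, read_panel
from riverwqi.pipeline import (
    kruskal_by_parameter,
    slope_grid,
    station_trend_table,
    year_trend_table,
)
from riverwqi.trend import flatten_panel

OUT = Path(__file__).resolve().parents[1] / "results"
ALPHA = 0.05
SPANS = (0.10, 0.25, 0.50)


def main() -> None:
    panel = read_panel(OUT / "panel.csv")

    st = station_trend_table(panel, alpha=ALPHA)
    yt = year_trend_table(panel, alpha=ALPHA)
    slope_grid(st).to_csv(OUT / "trends_stations.csv")
    slope_grid(yt).to_csv(OUT / "trends_years.csv")
    n_station_trends = st.notna().sum().sum()
    n_year_trends = yt.notna().sum().sum()
    print(f"station series with a trend at alpha={ALPHA}: {n_station_trends} "
          f"of {st.size}; yearly series: {n_year_trends} of {yt.size}")
    print("\nSen slopes per station ('-' = null not rejected):")
    print(slope_grid(st).to_string())

    kw_sites = kruskal_by_parameter(panel, group_by="station")
    kw_years = kruskal_by_parameter(panel, group_by="year")
    kw = kw_sites.merge(kw_years, on="parameter", suffixes=("_sites", "_years"))
    kw.to_csv(OUT / "kruskal_wallis.csv", index=False)
    print("\nKruskal-Wallis (same distribution across sites / across years):")
    print(kw.round(4).to_string(index=False))

    rows = []
    for param in panel.parameters:
        series = flatten_panel(panel, param)
        x = np.arange(len(series), dtype=float)
        ok = ~np.isnan(series)
        for span in SPANS:
            fit = loess_fit(x[ok], series[ok], span_alpha=span, degree=2)
            rows.append(pd.DataFrame({
                "parameter": param, "position": x[ok], "span": span,
                "value": series[ok], "fitted": fit.fitted,
            }))
    pd.concat(rows).to_csv(OUT / "loess_fits.csv", index=False)
    print(f"\nloess smooths at spans {SPANS} written to loess_fits.csv")


if __name__ == "__main__":
    main()
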