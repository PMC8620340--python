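"""Compute the three water-quality indices per station (study period) and per
year (all stations), classify them under the three printed scales, and write
the Value/Class tables.

Reads results/panel.csv; writes wqi_stations.csv and wqi_years.csv.
"""

from pathlib import Path

from riverwqi import read_objectives, read_panel, write_results_table
from riverwqi.pipeline import value_class_table, wqi_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = read_panel(OUT / "panel.csv")
    specs = read_objectives()

    stations = wqi_table(panel, specs, by="station")
    years = wqi_table(panel, specs, by="year")
    write_results_table(value_class_table(stations), OUT / "wqi_stations.csv")
    write_results_table(value_class_table(years), OUT / "wqi_years.csv")

    print("per-station indices (study period):")
    print(value_class_table(stations).to_string(index=False))
    print("\nper-year indices (all stations):")
    print(value_class_table(years).to_string(index=False))
    print("\nclass tallies:")
    for col in ("ccme_class", "bc_class", "weighted_class"):
        print(f"  {col}: {stations[col].value_counts().to_dict()} (stations), "
              f"{years[col].value_counts().to_dict()} (years)")


if __name__ == "__main__":
    main()
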