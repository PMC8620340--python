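"""Cluster the stations and the years by their scaled WQI triplets.

The cluster count is chosen by majority vote over five internal validity
indices; the agglomerative coefficient summarises how strong the hierarchical
structure is.  Reads results/panel.csv; writes the cluster memberships.
"""

from pathlib import Path

import pandas as pd

from riverwqi import read_objectives, read_panel
from riverwqi.pipeline import cluster_entities, wqi_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1729


def main() -> None:
    panel = read_panel(OUT / "panel.csv")
    specs = read_objectives()

    for by, name in (("station", "stations"), ("year", "years")):
        table = wqi_table(panel, specs, by=by)
        result = cluster_entities(table, linkage_method="average", k=None,
                                  seed=SEED)
        pd.DataFrame({
            "entity": result.entities,
            "cluster": [result.labels[e] for e in result.entities],
        }).to_csv(OUT / f"clusters_{name}.csv", index=False)
        sizes = pd.Series(result.labels).value_counts().sort_index()
        print(f"{name}: k={result.k} chosen by vote {result.votes}; "
              f"agglomerative coefficient "
              f"{result.agglomerative_coefficient:.3f}")
        print(f"  cluster sizes: {sizes.to_dict()}")
        for c in sizes.index:
            members = [e for e in result.entities if result.labels[e] == c]
            print(f"  cluster {c}: {members}")


if __name__ == "__main__":
    main()
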