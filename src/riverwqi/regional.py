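"""Regional and temporal representative WQI series (cluster-then-average).

Given a periods x stations matrix of yearly index values and a clustering of
the stations, the regional series is the row-wise mean over the stations in
the largest cluster; its fit against *every* station's own series is measured
by MAE, RMSE and MAPE.  Transposing the matrix (entities become years, index
runs over stations) yields the temporal 'global' series by the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist


class RegionalError(ValueError):
    pass


@dataclass
class RegionalSeries:
    axis: str  # "regional" | "temporal"
    member_entities: list[str]
    representative: pd.Series  # indexed by period (regional) or station
    fit_metrics: pd.DataFrame  # index: entity; columns: MAE, RMSE, MAPE


def _largest_cluster(matrix: pd.DataFrame, labels: dict) -> list:
    """Members of the largest cluster; ties broken by smallest internal
    mean pairwise distance between the entities' series."""
    groups: dict[int, list] = {}
    for entity, c in labels.items():
        groups.setdefault(c, []).append(entity)
    top = max(len(v) for v in groups.values())
    candidates = [v for v in groups.values() if len(v) == top]
    if len(candidates) == 1:
        return candidates[0]

    def mean_pairwise(members: list) -> float:
        pts = matrix[members].T.to_numpy()
        return float(pdist(pts).mean()) if len(members) > 1 else 0.0

    return min(candidates, key=lambda m: (mean_pairwise(m), tuple(map(str, m))))


def build_regional(
    wqi_matrix: pd.DataFrame, cluster_labels: dict, axis: str = "regional"
) -> RegionalSeries:
    """Representative series from the largest cluster, with fit metrics.

    ``wqi_matrix`` has periods as rows and stations as columns (for the
    regional axis).  Member columns must be complete.  Metrics compare the
    representative against every column: MAE = mean |r - y|, RMSE =
    sqrt(mean (r - y)^2), MAPE = (100/n) sum |r - y|/|y| (NaN where y = 0).
    """
    if not cluster_labels:
        raise RegionalError("empty cluster labelling")
    unknown = set(cluster_labels) - set(wqi_matrix.columns)
    if unknown:
        raise RegionalError(f"labels for unknown entities: {sorted(unknown)}")
    members = _largest_cluster(wqi_matrix, cluster_labels)
    sub = wqi_matrix[members]
    if sub.isna().any().any():
        raise RegionalError("member entity has a missing period (complete-case)")
    representative = sub.mean(axis=1)
    rows = {}
    for entity in wqi_matrix.columns:
        y = wqi_matrix[entity]
        err = representative - y
        mae = err.abs().mean()
        rmse = float(np.sqrt((err**2).mean()))
        with np.errstate(divide="ignore", invalid="ignore"):
            ape = (err.abs() / y.abs()).to_numpy()
        mape = float("nan") if np.isinf(ape).any() else 100.0 * np.nanmean(ape)
        rows[entity] = {"MAE": mae, "RMSE": rmse, "MAPE": mape}
    return RegionalSeries(
        axis=axis,
        member_entities=list(members),
        representative=representative,
        fit_metrics=pd.DataFrame.from_dict(rows, orient="index"),
    )


def build_temporal(
    wqi_matrix: pd.DataFrame, cluster_labels: dict
) -> RegionalSeries:
    """Temporal 'global' series: the regional rule on the transposed matrix.

    ``wqi_matrix`` is still periods x stations; ``cluster_labels`` map
    periods to clusters, and the representative runs over stations.
    """
    return build_regional(wqi_matrix.T, cluster_labels, axis="temporal")


#: Accepted metric-name aliases ("MSE" is sometimes used for the root form).
METRIC_ALIASES = {"MSE": "RMSE", "RMSE": "RMSE", "MAE": "MAE", "MAPE": "MAPE"}


def get_metric(series: RegionalSeries, entity, name: str) -> float:
    """Fit metric by (possibly aliased) name for one entity."""
    key = METRIC_ALIASES.get(name.upper())
    if key is None:
        raise RegionalError(f"unknown metric {name!r}")
    return float(series.fit_metrics.loc[entity, key])


def fit_report(series: RegionalSeries, decimals: int = 2) -> pd.DataFrame:
    """Tables-style metrics grid: one column per entity, 3 metric rows."""
    table = series.fit_metrics.T
    return table.map(lambda v: "NA" if pd.isna(v) else f"{v:.{decimals}f}")
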