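"""Full-pipeline orchestration: trends -> WQIs -> classes -> clusters ->
regional/temporal representative series, with publication-shaped tables.

Each stage writes one CSV into the output directory; a run log records the
package version, seed, configuration echo, and one line per stage with
input/output shapes.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import DEFAULT_SCHEMES, classify_all
from .cluster import hierarchical_cluster, select_k, standardize_features
from .panel import (
    MonitoringPanel,
    ObjectiveSpec,
    read_objectives,
    read_panel,
    write_panel,
    write_results_table,
)
from .regional import build_regional, build_temporal, fit_report
from .synth import brahmaputra_like, generate_panel, load_scenario
from .trend import TrendError, kruskal_wallis, mann_kendall
from .wqi import compute_all, weighted_wqi

log = logging.getLogger("riverwqi")


@dataclass
class PipelineConfig:
    panel_path: str | None = None
    objectives_path: str | None = None
    scenario_path: str | None = None  # None + no panel -> built-in scenario
    alpha: float = 0.05
    spans: tuple[float, ...] = (0.10, 0.25, 0.50)
    linkage: str = "average"
    k_stations: int | None = None  # None -> select_k vote
    k_years: int | None = None
    method2_scheme: str = "WEIGHTED"
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")


# -- stage computations (library surface; the CLI and analysis scripts are
#    thin wrappers over these) ----------------------------------------------


def station_trend_table(
    panel: MonitoringPanel, alpha: float = 0.05
) -> pd.DataFrame:
    """Sen slopes per (parameter, station); NaN where the MK null stands."""
    rows = {}
    for param in panel.parameters:
        row = {}
        for station in panel.stations:
            y = panel.series(station, param).reindex(panel.periods)
            try:
                res = mann_kendall(y.to_numpy(), alpha=alpha)
            except TrendError:
                row[station] = np.nan
                continue
            row[station] = res.sen_slope if res.decision != "no_trend" else np.nan
        rows[param] = row
    return pd.DataFrame.from_dict(rows, orient="index")[panel.stations]


def year_trend_table(panel: MonitoringPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Sen slopes per (parameter, year) over the downstream station order."""
    order = {s: i for i, s in enumerate(panel.stations)}
    rows = {}
    for param in panel.parameters:
        row = {}
        for year in panel.periods:
            sub = panel.year_slice(year)
            sub = sub[sub["parameter"] == param]
            y = (
                sub.assign(pos=sub["station"].map(order))
                .sort_values("pos")["value"]
                .to_numpy()
            )
            try:
                res = mann_kendall(y, alpha=alpha)
            except TrendError:
                row[year] = np.nan
                continue
            row[year] = res.sen_slope if res.decision != "no_trend" else np.nan
        rows[param] = row
    return pd.DataFrame.from_dict(rows, orient="index")[panel.periods]


def kruskal_by_parameter(
    panel: MonitoringPanel, group_by: str = "station"
) -> pd.DataFrame:
    """Kruskal-Wallis per parameter, grouping series by station or by year."""
    rows = []
    for param in panel.parameters:
        df = panel.data[panel.data["parameter"] == param]
        key = "station" if group_by == "station" else "year"
        groups = [g["value"].to_numpy() for _, g in df.groupby(key)]
        try:
            h, p = kruskal_wallis(groups)
        except TrendError:
            h, p = np.nan, np.nan
        rows.append({"parameter": param, "H": h, "p_value": p})
    return pd.DataFrame(rows)


def wqi_table(
    panel: MonitoringPanel,
    specs: list[ObjectiveSpec],
    by: str = "station",
    schemes=None,
) -> pd.DataFrame:
    """Index triplet + class per entity (Tables 3/4 shape)."""
    entities = panel.stations if by == "station" else panel.periods
    rows = []
    for entity in entities:
        sl = (
            panel.station_slice(entity)
            if by == "station"
            else panel.year_slice(entity)
        )
        results = list(compute_all(sl, specs, entity=str(entity)).values())
        classify_all(results, schemes or DEFAULT_SCHEMES)
        row = {"entity": str(entity)}
        for res in results:
            row[f"{res.scheme.lower()}_value"] = res.value
            row[f"{res.scheme.lower()}_class"] = res.class_label
        rows.append(row)
    cols = ["entity"]
    for scheme in ("ccme", "bc", "weighted"):
        cols += [f"{scheme}_value", f"{scheme}_class"]
    return pd.DataFrame(rows)[cols]


def yearly_index_matrix(
    panel: MonitoringPanel, specs: list[ObjectiveSpec], scheme: str = "WEIGHTED"
) -> pd.DataFrame:
    """Periods x stations matrix of per-(station, year) index values.

    The regional/temporal representative-series algorithm runs on the yearly
    weighted index by convention; other schemes are accepted too.
    """
    func = {
        "WEIGHTED": lambda sl, e: weighted_wqi(sl, specs, e).value,
        "CCME": lambda sl, e: compute_all(sl, specs, e)["CCME"].value,
        "BC": lambda sl, e: compute_all(sl, specs, e)["BC"].value,
    }[scheme.upper()]
    mat = pd.DataFrame(index=panel.periods, columns=panel.stations, dtype=float)
    for station in panel.stations:
        sl = panel.station_slice(station)
        for year in panel.periods:
            sub = sl[sl["year"] == year]
            if sub["value"].notna().any():
                mat.loc[year, station] = func(sub, f"{station}:{year}")
    return mat


def cluster_entities(
    table: pd.DataFrame,
    linkage_method: str = "average",
    k: int | None = None,
    seed: int = 0,
):
    """Standardize the 3-index features and cluster; auto-select k if None."""
    features = standardize_features(
        table[["ccme_value", "bc_value", "weighted_value"]].to_numpy()
    )
    entities = table["entity"].tolist()
    votes = {}
    if k is None:
        k, votes = select_k(
            features, range(2, min(6, len(entities) - 1) + 1),
            linkage_method=linkage_method, seed=seed,
        )
    result = hierarchical_cluster(
        features, k=k, entities=entities, linkage_method=linkage_method
    )
    result.votes = votes
    return result


# -- publication-shaped tables ----------------------------------------------


def slope_grid(table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Sen-slope grid with '-' where the trend null was not rejected."""
    return table.map(lambda v: "-" if pd.isna(v) else f"{v:.{decimals}f}")


def value_class_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Paired Value/Class columns per scheme (Tables 3/4 style)."""
    out = pd.DataFrame({"Entity": table["entity"]})
    for scheme, title in (("ccme", "CCME WQI"), ("bc", "BC WQI"),
                          ("weighted", "Weighted WQI")):
        out[f"{title} Value"] = table[f"{scheme}_value"].map(
            lambda v: f"{v:.{decimals}f}"
        )
        out[f"{title} Class"] = table[f"{scheme}_class"]
    return out


def make_paper_tables(stage_outputs: dict) -> dict[str, pd.DataFrame]:
    """Format raw stage outputs into the publication table shapes."""
    tables = {}
    if "station_trends" in stage_outputs:
        tables["sen_slopes_stations"] = slope_grid(stage_outputs["station_trends"])
    if "year_trends" in stage_outputs:
        tables["sen_slopes_years"] = slope_grid(stage_outputs["year_trends"])
    for key in ("wqi_stations", "wqi_years"):
        if key in stage_outputs:
            tables[key] = value_class_table(stage_outputs[key])
    for key in ("regional", "temporal"):
        if key in stage_outputs:
            tables[f"{key}_metrics"] = fit_report(stage_outputs[key])
    return tables


# -- full pipeline -----------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing one CSV per stage plus a run log.

    Returns the in-memory stage outputs.  Raises on the first stage error
    (partial outputs are retained on disk).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict = {}
    try:
        log.info("riverwqi %s | python %s | numpy %s | pandas %s",
                 __version__, sys.version.split()[0],
                 np.__version__, pd.__version__)
        log.info("config: %s", config)

        specs = read_objectives(config.objectives_path)
        if config.panel_path:
            panel = read_panel(config.panel_path)
            log.info("stage load: read panel %s", config.panel_path)
        else:
            scen = (
                load_scenario(config.scenario_path)
                if config.scenario_path
                else brahmaputra_like(seed=config.seed)
            )
            if scen.seed != config.seed:
                from dataclasses import replace
                scen = replace(scen, seed=config.seed)
            panel = generate_panel(scen)
            write_panel(panel, outdir / "panel.csv")
            log.info("stage simulate: %d stations x %d years x %d parameters",
                     len(panel.stations), len(panel.periods),
                     len(panel.parameters))
        outputs["panel"] = panel

        st = station_trend_table(panel, alpha=config.alpha)
        yt = year_trend_table(panel, alpha=config.alpha)
        outputs["station_trends"], outputs["year_trends"] = st, yt
        slope_grid(st).to_csv(outdir / "trends_stations.csv")
        slope_grid(yt).to_csv(outdir / "trends_years.csv")
        log.info("stage trend: station grid %s, year grid %s",
                 st.shape, yt.shape)

        ws = wqi_table(panel, specs, by="station")
        wy = wqi_table(panel, specs, by="year")
        outputs["wqi_stations"], outputs["wqi_years"] = ws, wy
        write_results_table(value_class_table(ws), outdir / "wqi_stations.csv")
        write_results_table(value_class_table(wy), outdir / "wqi_years.csv")
        log.info("stage wqi+classify: %d stations, %d years", len(ws), len(wy))

        cs = cluster_entities(ws, config.linkage, config.k_stations, config.seed)
        cy = cluster_entities(wy, config.linkage, config.k_years, config.seed)
        outputs["clusters_stations"], outputs["clusters_years"] = cs, cy
        pd.DataFrame({
            "entity": cs.entities,
            "cluster": [cs.labels[e] for e in cs.entities],
        }).to_csv(outdir / "clusters_stations.csv", index=False)
        pd.DataFrame({
            "entity": cy.entities,
            "cluster": [cy.labels[e] for e in cy.entities],
        }).to_csv(outdir / "clusters_years.csv", index=False)
        log.info("stage cluster: stations k=%d AC=%.3f | years k=%d AC=%.3f",
                 cs.k, cs.agglomerative_coefficient,
                 cy.k, cy.agglomerative_coefficient)

        mat = yearly_index_matrix(panel, specs, scheme=config.method2_scheme)
        regional = build_regional(mat, cs.labels)
        temporal = build_temporal(
            mat, {int(e): c for e, c in cy.labels.items()}
        )
        outputs["regional"], outputs["temporal"] = regional, temporal
        regional.representative.rename("wqi").to_csv(
            outdir / "regional_series.csv", index_label="year"
        )
        temporal.representative.rename("wqi").to_csv(
            outdir / "temporal_series.csv", index_label="station"
        )
        fit_report(regional).to_csv(outdir / "regional_metrics.csv")
        fit_report(temporal).to_csv(outdir / "temporal_metrics.csv")
        log.info("stage regional: members %s | temporal members %s",
                 regional.member_entities, temporal.member_entities)
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outputs
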