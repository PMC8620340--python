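"""The three water-quality indices: CCME WQI, BC WQI, weighted arithmetic WQI.

All three operate on a *slice* of a monitoring panel — either one station
across years or one year across stations — evaluated against per-parameter
objectives.  A "test" is one non-missing measurement; a "failed parameter" is
a parameter with at least one failed test in the slice.

CCME WQI = 100 - sqrt(F1^2 + F2^2 + F3^2) / 1.732, where F1 is the percentage
of failed parameters (scope), F2 the percentage of failed tests (frequency),
and F3 = nse / (0.01 nse + 0.01) rescales the mean excursion nse (amplitude)
into [0, 100).

BC WQI = sqrt(F1^2 + F2^2 + (F3/3)^2) / 1.453 with F3 the maximum single
excursion in percent (0 = best water; the 1.453 divisor maps the worst case
F1 = F2 = F3 = 100 to roughly 100).

Weighted WQI = sum(wi * Qi) with sub-indices Qi = 100|Vi - V0| / |Si - V0|
and inverse-standard weights wi = (1/Si) / sum(1/Si); 0 is ideal water, 100
means every parameter sits exactly at its standard, and values above 100 are
possible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .panel import ObjectiveSpec, PanelError, specs_by_parameter

#: sqrt(3) as conventionally rounded in the CCME index definition.
CCME_DIVISOR = 1.732
BC_DIVISOR = 1.453

#: Excursions against a zero bound (or a zero measurement under a lower
#: limit) are undefined; they are capped here instead (configurable).
DEFAULT_EXCURSION_CAP = 100.0


@dataclass(frozen=True)
class CcmeFactors:
    """Scope (F1), frequency (F2) and amplitude (F3) of objective failures."""

    F1: float
    F2: float
    F3: float
    nse: float
    n_parameters: int
    n_tests: int
    n_failed_parameters: int
    n_failed_tests: int
    excursions: tuple[float, ...] = ()


@dataclass
class WqiResult:
    """One index value for one entity (a station or a year)."""

    entity: str
    scheme: str  # CCME | BC | WEIGHTED
    value: float
    class_label: str | None = None
    factors: CcmeFactors | None = None
    subindices: list[tuple[str, float, float]] = field(default_factory=list)


def excursion(
    value: float,
    spec: ObjectiveSpec,
    cap: float = DEFAULT_EXCURSION_CAP,
) -> float:
    """Normalized departure of a measurement from its objective.

    Returns 0 when the objective is met.  An exceeded upper limit yields
    ``value/objective - 1``; an undershot lower limit yields
    ``objective/value - 1``.  For a range objective the violated bound's rule
    applies.  Division by a zero bound or zero value is capped at ``cap``.
    """
    if spec.meets(value):
        return 0.0
    if spec.direction == "upper_limit":
        bound, kind = spec.objective_high, "upper"
    elif spec.direction == "lower_limit":
        bound, kind = spec.objective_low, "lower"
    else:  # range: pick the violated bound
        if value > spec.objective_high:
            bound, kind = spec.objective_high, "upper"
        else:
            bound, kind = spec.objective_low, "lower"
    if kind == "upper":
        if bound == 0:
            warnings.warn(
                f"{spec.parameter}: zero objective bound, excursion capped",
                stacklevel=2,
            )
            return cap
        return value / bound - 1.0
    if value == 0:
        warnings.warn(
            f"{spec.parameter}: zero measurement under lower limit, "
            "excursion capped",
            stacklevel=2,
        )
        return cap
    return bound / value - 1.0


def _tests(slice_df: pd.DataFrame, specs: list[ObjectiveSpec], flag: str):
    """Yield (parameter, value, spec) for each non-missing included test."""
    by_param = specs_by_parameter(specs)
    for _, row in slice_df.iterrows():
        spec = by_param.get(row["parameter"])
        if spec is None or not getattr(spec, flag):
            continue
        if pd.isna(row["value"]):
            continue
        yield row["parameter"], float(row["value"]), spec


def ccme_factors(
    slice_df: pd.DataFrame,
    specs: list[ObjectiveSpec],
    cap: float = DEFAULT_EXCURSION_CAP,
) -> CcmeFactors:
    """Compute F1/F2/F3 for a panel slice under the CCME definitions."""
    included = [s for s in specs if s.include_in_ccme]
    if not included:
        raise PanelError("no parameters included in the CCME index")
    tests = list(_tests(slice_df, specs, "include_in_ccme"))
    if not tests:
        raise PanelError("CCME index undefined: zero tests in slice")
    excursions = []
    failed_params: set[str] = set()
    n_failed_tests = 0
    for param, value, spec in tests:
        if not spec.meets(value):
            failed_params.add(param)
            n_failed_tests += 1
            excursions.append(excursion(value, spec, cap=cap))
    tested_params = {p for p, _, _ in tests}
    n_tests = len(tests)
    nse = sum(excursions) / n_tests
    return CcmeFactors(
        F1=100.0 * len(failed_params) / len(tested_params),
        F2=100.0 * n_failed_tests / n_tests,
        F3=nse / (0.01 * nse + 0.01),
        nse=nse,
        n_parameters=len(tested_params),
        n_tests=n_tests,
        n_failed_parameters=len(failed_params),
        n_failed_tests=n_failed_tests,
        excursions=tuple(excursions),
    )


def ccme_wqi(factors: CcmeFactors) -> float:
    """CCME index value from its factors, clamped into [0, 100]."""
    raw = 100.0 - math.sqrt(
        factors.F1**2 + factors.F2**2 + factors.F3**2
    ) / CCME_DIVISOR
    return min(100.0, max(0.0, raw))


def ccme(
    slice_df: pd.DataFrame,
    specs: list[ObjectiveSpec],
    entity: str = "",
    cap: float = DEFAULT_EXCURSION_CAP,
) -> WqiResult:
    """CCME WQI for a slice (convenience wrapper over the two stages)."""
    factors = ccme_factors(slice_df, specs, cap=cap)
    return WqiResult(entity=entity, scheme="CCME", value=ccme_wqi(factors),
                     factors=factors)


def bc_wqi(
    slice_df: pd.DataFrame,
    specs: list[ObjectiveSpec],
    entity: str = "",
    cap: float = DEFAULT_EXCURSION_CAP,
) -> WqiResult:
    """British Columbia WQI for a slice.

    F3 is 100 x the maximum excursion over all failed tests, capped at 100
    ("maximum deviation from any objective").
    """
    included = [s for s in specs if s.include_in_bc]
    if not included:
        raise PanelError("no parameters included in the BC index")
    tests = list(_tests(slice_df, specs, "include_in_bc"))
    if not tests:
        raise PanelError("BC index undefined: zero tests in slice")
    failed_params: set[str] = set()
    n_failed = 0
    max_exc = 0.0
    for param, value, spec in tests:
        if not spec.meets(value):
            failed_params.add(param)
            n_failed += 1
            max_exc = max(max_exc, excursion(value, spec, cap=cap))
    tested_params = {p for p, _, _ in tests}
    f1 = 100.0 * len(failed_params) / len(tested_params)
    f2 = 100.0 * n_failed / len(tests)
    f3 = min(100.0, 100.0 * max_exc)
    value = math.sqrt(f1**2 + f2**2 + (f3 / 3.0) ** 2) / BC_DIVISOR
    factors = CcmeFactors(
        F1=f1, F2=f2, F3=f3, nse=max_exc,
        n_parameters=len(tested_params), n_tests=len(tests),
        n_failed_parameters=len(failed_params), n_failed_tests=n_failed,
    )
    return WqiResult(entity=entity, scheme="BC", value=value, factors=factors)


def weighted_wqi(
    slice_df: pd.DataFrame,
    specs: list[ObjectiveSpec],
    entity: str = "",
) -> WqiResult:
    """Weighted arithmetic WQI for a slice.

    The representative concentration Vi is the slice mean over non-missing
    entries; weights are renormalized over the parameters actually available.
    """
    by_param = {s.parameter: s for s in specs if s.include_in_weighted}
    if not by_param:
        raise PanelError("no parameters included in the weighted index")
    means = (
        slice_df[slice_df["parameter"].isin(by_param)]
        .dropna(subset=["value"])
        .groupby("parameter")["value"]
        .mean()
    )
    if means.empty:
        raise PanelError("weighted index undefined: all parameters missing")
    inv_s = {p: 1.0 / abs(by_param[p].standard_S) for p in means.index}
    total = sum(inv_s.values())
    subindices = []
    value = 0.0
    for p, vi in means.items():
        spec = by_param[p]
        qi = 100.0 * abs(vi - spec.ideal_V0) / abs(spec.standard_S - spec.ideal_V0)
        wi = inv_s[p] / total
        subindices.append((p, qi, wi))
        value += wi * qi
    return WqiResult(
        entity=entity, scheme="WEIGHTED", value=value, subindices=subindices
    )


def compute_all(
    slice_df: pd.DataFrame, specs: list[ObjectiveSpec], entity: str = ""
) -> dict[str, WqiResult]:
    """All three indices for one slice, keyed by scheme name."""
    return {
        "CCME": ccme(slice_df, specs, entity),
        "BC": bc_wqi(slice_df, specs, entity),
        "WEIGHTED": weighted_wqi(slice_df, specs, entity),
    }
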