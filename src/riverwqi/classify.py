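"""Quality-class assignment for the three index scales.

The published scales are closed integer-bounded bins that leave open gaps
between consecutive classes (e.g. the BC scale jumps from Fair [18, 43] to
Borderline [44, 59], leaving (43, 44) unassigned).  Real-valued indices do
land in those gaps; the combined-label policy assigns them the two adjacent
class names joined by "/", ordered better quality first (e.g. a BC value of
43.57 is "Fair/Borderline").  ``nearest`` and ``truncate`` policies are
provided for users of the conventional scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .panel import PanelError
from .wqi import WqiResult


@dataclass(frozen=True)
class Bin:
    label: str
    low: float
    high: float


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered closed bins plus gap and open-top handling for one scale."""

    scheme: str
    bins: tuple[Bin, ...]  # ordered by value, ascending
    higher_is_better: bool
    open_top_label: str | None = None
    gap_policy: str = "combined_label"  # combined_label | nearest | truncate

    def __post_init__(self) -> None:
        lows = [b.low for b in self.bins]
        if lows != sorted(lows):
            raise PanelError(f"{self.scheme}: bins must be ordered ascending")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.low <= a.high:
                raise PanelError(f"{self.scheme}: overlapping bins {a} / {b}")


# CCME scale: higher index = better water.
CCME_SCHEME = ClassificationScheme(
    scheme="CCME",
    bins=(
        Bin("Poor", 0, 44),
        Bin("Marginal", 45, 64),
        Bin("Fair", 65, 79),
        Bin("Good", 80, 94),
        Bin("Excellent", 95, 100),
    ),
    higher_is_better=True,
)

# BC scale: lower index = better water.
BC_SCHEME = ClassificationScheme(
    scheme="BC",
    bins=(
        Bin("Excellent", 0, 3),
        Bin("Good", 4, 17),
        Bin("Fair", 18, 43),
        Bin("Borderline", 44, 59),
        Bin("Poor", 60, 100),
    ),
    higher_is_better=False,
)

# Weighted arithmetic scale: lower = better, open-ended above 100.
WEIGHTED_SCHEME = ClassificationScheme(
    scheme="WEIGHTED",
    bins=(
        Bin("Excellent", 0, 25),
        Bin("Good", 26, 50),
        Bin("Poor", 51, 75),
        Bin("Very Poor", 76, 100),
    ),
    higher_is_better=False,
    open_top_label="Unsuitable",
)

DEFAULT_SCHEMES: dict[str, ClassificationScheme] = {
    "CCME": CCME_SCHEME,
    "BC": BC_SCHEME,
    "WEIGHTED": WEIGHTED_SCHEME,
}


def with_gap_policy(scheme: ClassificationScheme, policy: str) -> ClassificationScheme:
    if policy not in {"combined_label", "nearest", "truncate"}:
        raise PanelError(f"unknown gap policy {policy!r}")
    return replace(scheme, gap_policy=policy)


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Class label for an index value; full precision, endpoints inclusive.

    Values in an open gap between two printed bins get the combined label of
    exactly those bins (better class first) under the default policy;
    ``nearest`` snaps to the closer bin edge, ``truncate`` to the lower bin.
    """
    if value < 0:
        raise PanelError(f"negative index value {value}")
    for b in scheme.bins:
        if b.low <= value <= b.high:
            return b.label
    if value > scheme.bins[-1].high:
        if scheme.open_top_label is not None:
            return scheme.open_top_label
        # beyond the printed top (e.g. BC > 100): worst class
        return scheme.bins[-1].label
    if value < scheme.bins[0].low:
        return scheme.bins[0].label
    # in an open gap between two consecutive bins
    for lower, upper in zip(scheme.bins, scheme.bins[1:]):
        if lower.high < value < upper.low:
            if scheme.gap_policy == "truncate":
                return lower.label
            if scheme.gap_policy == "nearest":
                return (
                    lower.label
                    if value - lower.high <= upper.low - value
                    else upper.label
                )
            better, worse = (
                (upper, lower) if scheme.higher_is_better else (lower, upper)
            )
            return f"{better.label}/{worse.label}"
    raise PanelError(f"value {value} not covered by scheme {scheme.scheme}")


def classify_all(
    results: list[WqiResult],
    schemes: dict[str, ClassificationScheme] | None = None,
) -> list[WqiResult]:
    """Attach class labels to a list of index results (in place, returned)."""
    schemes = schemes or DEFAULT_SCHEMES
    for res in results:
        if res.scheme not in schemes:
            raise PanelError(f"no classification scheme for {res.scheme!r}")
        res.class_label = classify(res.value, schemes[res.scheme])
    return results
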