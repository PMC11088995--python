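"""Polysome-profile quantification: fraction areas and polysomal ratio.

A polysome profile is the A254 absorbance recorded along a sucrose
gradient after ultracentrifugation of a cytoplasmic lysate: free
ribosomal subunits (40S, 60S), the 80S monosome, and then mRNAs loaded
with increasing numbers of ribosomes (polysomes). The fraction of
above-baseline area in the polysomal region indexes the overall
translational engagement of the sample; comparing it between treatment
groups asks whether global translation changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid


class TraceRangeError(ValueError):
    """Raised when a fraction interval falls outside the trace."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when the total above-baseline area is zero."""


@dataclass(frozen=True)
class PolysomeTrace:
    """Digitised absorbance-vs-position curve.

    ``positions`` strictly increasing (chart distance or eluted volume,
    arbitrary units); ``absorbance`` the A254 signal.
    """

    positions: np.ndarray = field(repr=False)
    absorbance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if pos.ndim != 1 or pos.size < 2 or pos.shape != ab.shape:
            raise ValueError("trace needs >= 2 (position, absorbance) points")
        if not (np.diff(pos) > 0).all():
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class FractionScheme:
    """Named, ordered, non-overlapping intervals over trace positions.

    ``intervals`` partitions the quantified region (typically a
    sub-polysomal interval covering 40S/60S/80S and a polysomal interval
    from the first to the last polysome peak); ``polysomal`` names the
    intervals counted as polysomal. ``pools`` optionally records how
    collected fractions were pooled for downstream RNA work (monosome M,
    light polysomes LP, heavy polysomes HP1/HP2); pools may subdivide or
    overlap the quantification intervals and are not used for the ratio.
    """

    intervals: dict[str, tuple[float, float]]
    polysomal: tuple[str, ...]
    pools: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        items = list(self.intervals.items())
        if not items:
            raise ValueError("scheme needs at least one interval")
        for label, (a, b) in items:
            if b <= a:
                raise ValueError(f"interval {label!r} is empty or reversed")
        for (_, (_, b1)), (label, (a2, _)) in zip(items, items[1:]):
            if a2 < b1:
                raise ValueError(f"interval {label!r} overlaps its predecessor")
        unknown = set(self.polysomal) - set(self.intervals)
        if unknown:
            raise ValueError(f"polysomal labels not in intervals: {sorted(unknown)}")


def fraction_areas(
    trace: PolysomeTrace,
    scheme: FractionScheme,
    baseline: float | None = None,
) -> dict[str, float]:
    """Above-baseline area under the trace within each scheme interval.

    The baseline defaults to the trace minimum (the lowest point on the
    chart); the signal is clipped at the baseline and integrated by the
    trapezoidal rule on a cumulative grid, so areas of adjacent
    intervals add exactly.
    """
    pos, ab = trace.positions, trace.absorbance
    if baseline is None:
        baseline = float(ab.min())
    signal = np.maximum(ab - baseline, 0.0)
    cum = np.concatenate(([0.0], cumulative_trapezoid(signal, pos)))

    areas: dict[str, float] = {}
    for label, (a, b) in scheme.intervals.items():
        if a < pos[0] - 1e-12 or b > pos[-1] + 1e-12:
            raise TraceRangeError(
                f"interval {label!r} = ({a}, {b}) outside trace range "
                f"({pos[0]}, {pos[-1]})"
            )
        areas[label] = float(np.interp(b, pos, cum) - np.interp(a, pos, cum))
    return areas


def polysome_ratio(
    trace: PolysomeTrace,
    scheme: FractionScheme,
    baseline: float | None = None,
) -> float:
    """Polysomal area over total (sub-polysomal + polysomal) area, in [0, 1]."""
    areas = fraction_areas(trace, scheme, baseline=baseline)
    total = sum(areas.values())
    if total <= 0:
        raise UndefinedRatioError("total above-baseline area is zero")
    return sum(areas[label] for label in scheme.polysomal) / total


def mann_whitney_compare(ratios_a, ratios_b) -> float:
    """Two-sided Mann-Whitney U p-value between two groups of ratios.

    The rank-based two-sample test, the standard non-parametric
    analogue of the two-sample t-test: exact enumeration of the U null
    for small untied samples (<= 10 observations in total), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tied = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 1.0  # identical constant groups carry no evidence
    method = "exact" if (a.size + b.size <= 10 and not tied) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def welch_compare(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Degenerate inputs follow the convention: zero variance in both
    groups with equal means gives p = 1; zero variance with unequal
    means gives p = 0 (flagged with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 1.0
        warn("zero within-group variance with unequal means: p -> 0",
             stacklevel=2)
        return 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
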