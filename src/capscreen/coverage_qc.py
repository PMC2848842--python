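"""Capture-coverage homogeneity QC, CGH-style.

The target regions are tiled with 15-base windows; for each window the index

    Is = log2( ((m_s + pc) / M_s) / ((m_c + pc) / M_c) )

compares the sample's window median depth m_s, normalised by its global
median M_s, with the control pool's (m_c, M_c). Is near 0 means the capture
behaved identically in sample and control; windows beyond mean +/- (SD + 0.5)
are flagged as putatively altered. A pseudocount (default 0.5) keeps windows
with zero coverage finite. Flagged windows bordering a region edge are
annotated as such, since target flanks are naturally low-coverage and produce
large index excursions by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import round_half_up
from .io_formats import TargetRegion
from .pileup_depth import DepthProfile

DEFAULT_WINDOW = 15
THRESHOLD_MARGIN = 0.5  # added to the SD when setting flagging thresholds


@dataclass(frozen=True)
class CoverageWindow:
    chrom: str
    start: int  # 1-based first base of the window
    width: int
    mean_depth: float
    median_depth: float
    partial: bool = False  # trailing window shorter than the nominal width
    region_edge: bool = False  # first or last window of its region

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("window width must be >= 1")


@dataclass(frozen=True)
class IsValue:
    window: CoverageWindow
    is_value: float


@dataclass(frozen=True)
class IsThresholds:
    mean_is: float
    sd_is: float
    upper: float
    lower: float

    def __post_init__(self) -> None:
        if not self.lower <= self.mean_is <= self.upper:
            raise ValueError("thresholds must bracket the mean")


@dataclass(frozen=True)
class FlaggedWindow:
    value: IsValue
    direction: str  # "high" | "low"

    @property
    def at_region_edge(self) -> bool:
        return self.value.window.region_edge


def make_windows(
    profile: DepthProfile,
    regions: Sequence[TargetRegion],
    width: int = DEFAULT_WINDOW,
) -> list[CoverageWindow]:
    """Tile each region with consecutive non-overlapping windows.

    The trailing window of a region may be shorter than ``width`` and is
    flagged as partial rather than dropped.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    windows = []
    for r in sorted(regions):
        v = profile.vectors[(r.chrom, r.start, r.end)]
        n_windows = (r.length + width - 1) // width
        for w in range(n_windows):
            lo = w * width
            hi = min(lo + width, r.length)
            chunk = v[lo:hi]
            windows.append(
                CoverageWindow(
                    chrom=r.chrom,
                    start=r.start + lo,
                    width=hi - lo,
                    mean_depth=float(chunk.mean()),
                    median_depth=float(np.median(chunk)),
                    partial=hi - lo < width,
                    region_edge=w == 0 or w == n_windows - 1,
                )
            )
    return windows


def is_index(
    sample_windows: Sequence[CoverageWindow],
    control_windows: Sequence[CoverageWindow],
    m_sample_global: float,
    m_control_global: float,
    pseudocount: float = 0.5,
    log_base: float = 2.0,
) -> list[IsValue]:
    """Per-window normalised log-ratio of sample vs control median depth."""
    if m_sample_global <= 0 or m_control_global <= 0:
        raise ValueError("global medians must be positive")
    if len(sample_windows) != len(control_windows):
        raise ValueError("sample and control window grids differ in length")
    values = []
    for ws, wc in zip(sample_windows, control_windows):
        if (ws.chrom, ws.start, ws.width) != (wc.chrom, wc.start, wc.width):
            raise ValueError(
                f"window grids misaligned at {ws.chrom}:{ws.start} vs {wc.chrom}:{wc.start}"
            )
        ratio = ((ws.median_depth + pseudocount) / m_sample_global) / (
            (wc.median_depth + pseudocount) / m_control_global
        )
        values.append(IsValue(ws, float(np.log(ratio) / np.log(log_base))))
    return values


def thresholds_from_moments(mean_is: float, sd_is: float) -> IsThresholds:
    """Flagging bounds mean +/- (SD + 0.5) from precomputed moments."""
    return IsThresholds(
        mean_is=mean_is,
        sd_is=sd_is,
        upper=mean_is + sd_is + THRESHOLD_MARGIN,
        lower=mean_is - sd_is - THRESHOLD_MARGIN,
    )


def is_thresholds(values: Sequence[IsValue | float]) -> IsThresholds:
    """Moments of the Is distribution and the flagging bounds.

    The SD is population-flavoured (ddof=0); with only 2-decimal printed
    summaries the sample/population distinction is unresolvable, and the
    population form is the CGH convention.
    """
    xs = np.array([v.is_value if isinstance(v, IsValue) else float(v) for v in values])
    if xs.size < 2:
        raise ValueError("need at least 2 index values")
    return thresholds_from_moments(float(xs.mean()), float(xs.std(ddof=0)))


def flag_windows(
    values: Sequence[IsValue], thresholds: IsThresholds
) -> list[FlaggedWindow]:
    """Windows strictly beyond the thresholds, annotated with edge status."""
    flagged = []
    for v in values:
        if v.is_value > thresholds.upper:
            flagged.append(FlaggedWindow(v, "high"))
        elif v.is_value < thresholds.lower:
            flagged.append(FlaggedWindow(v, "low"))
    return flagged


def correlation_diagnostics(
    x: Sequence[float], y: Sequence[float], log_transform: bool = False
) -> float:
    """Squared Pearson correlation, optionally on log-transformed x.

    Used to check e.g. that global depth tracks the number of on-target reads,
    and that window means track window medians (no within-window coverage
    gaps).
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.size != ys.size or xs.size < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    if log_transform:
        if np.any(xs <= 0):
            raise ValueError("log transform requires positive x")
        xs = np.log(xs)
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(xs, ys).statistic
    return float(r * r)
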