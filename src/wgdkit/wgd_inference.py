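"""From per-pair divergence estimates to whole-genome-duplication evidence.

The corrected 4DTv values of syntenic gene pairs are summarised as a
histogram plus a Gaussian kernel-density estimate (Silverman bandwidth,
recorded in the output); WGD and speciation events appear as density peaks.
Peaks are local KDE maxima with prominence above a configurable fraction of
the maximum density, reported at the KDE argmax to three decimals. Relative
event order (did the duplication precede the speciation?) is read off by
comparing self-comparison and cross-comparison peak locations with an
equality tolerance, and homeolog retention is quantified from directional
best hits against a pre-duplication outgroup.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal, stats

from .homology import best_hits
from .io_formats import FormatError, HitTable
from .molevol import DivergenceEstimate

__all__ = [
    "DistributionSummary",
    "PeakCall",
    "RetentionReport",
    "summarize_distribution",
    "detect_peaks",
    "order_events",
    "retention_analysis",
]


@dataclass
class DistributionSummary:
    """Histogram + KDE of corrected 4DTv values for one comparison."""

    comparison: str
    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    n_excluded: int
    values: np.ndarray

    def to_table(self) -> list[tuple[float, int, float]]:
        """(bin start, count, density at bin start) rows for TSV output."""
        dens = np.interp(self.bin_edges[:-1], self.grid, self.density)
        return [
            (float(e), int(c), float(d))
            for e, c, d in zip(self.bin_edges[:-1], self.counts, dens)
        ]


@dataclass(frozen=True)
class PeakCall:
    """One KDE peak: location (4DTv units), height, prominence, width."""

    location: float
    height: float
    prominence: float
    width: float


def _defined_values(estimates: Iterable[DivergenceEstimate]) -> tuple[np.ndarray, int]:
    values, excluded = [], 0
    for est in estimates:
        if est.fourdtv_defined:
            values.append(est.fourdtv_corrected)
        else:
            excluded += 1
    return np.asarray(values, dtype=float), excluded


def summarize_distribution(
    estimates: Sequence[DivergenceEstimate] | np.ndarray,
    comparison: str,
    bin_width: float = 0.01,
    value_range: tuple[float, float] = (0.0, 1.0),
    min_pairs: int = 50,
    grid_points: int = 1001,
) -> DistributionSummary:
    """Histogram and Silverman-bandwidth KDE over defined corrected 4DTv.

    Saturated/undefined pairs are excluded and counted. Fewer than
    ``min_pairs`` values triggers a warning (callers should not call peaks
    on such a summary); zero values is an error. The KDE is renormalised to
    integrate to 1 on the evaluation grid.
    """
    if isinstance(estimates, np.ndarray) or (
        len(estimates) and not isinstance(estimates[0], DivergenceEstimate)
    ):
        values = np.asarray(estimates, dtype=float)
        excluded = int(np.isnan(values).sum())
        values = values[~np.isnan(values)]
    else:
        values, excluded = _defined_values(estimates)
    if values.size == 0:
        raise FormatError(f"{comparison}: no defined 4DTv values")
    if values.size < min_pairs:
        warnings.warn(
            f"{comparison}: only {values.size} pairs (< {min_pairs}); "
            "peak calls would be unreliable"
        )
    lo, hi = value_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    grid = np.linspace(lo, hi, grid_points)
    if values.size > 1 and np.ptp(values) > 0:
        kde = stats.gaussian_kde(values, bw_method="silverman")
        bandwidth = float(kde.factor * values.std(ddof=1))
        # boundary reflection at both support edges removes the KDE edge
        # falloff that would otherwise fake an interior mode on flat data
        density = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
    else:
        # degenerate sample: a narrow Gaussian bump at the single value
        bandwidth = bin_width
        density = stats.norm.pdf(grid, loc=float(values[0]), scale=bandwidth)
    area = np.trapezoid(density, grid)
    if area > 0:
        density = density / area
    return DistributionSummary(
        comparison=comparison,
        bin_edges=edges,
        counts=counts,
        grid=grid,
        density=density,
        bandwidth=bandwidth,
        n=int(values.size),
        n_excluded=excluded,
        values=values,
    )


def detect_peaks(
    summary: DistributionSummary, prominence_fraction: float = 0.1
) -> list[PeakCall]:
    """Local KDE maxima with prominence >= the fraction of max density.

    Returned sorted by location; an empty list when nothing qualifies.
    """
    threshold = prominence_fraction * float(summary.density.max())
    idx, props = signal.find_peaks(summary.density, prominence=threshold)
    widths, _, left, right = signal.peak_widths(summary.density, idx, rel_height=0.5)
    step = float(summary.grid[1] - summary.grid[0])
    peaks = [
        PeakCall(
            location=round(float(summary.grid[i]), 3),
            height=float(summary.density[i]),
            prominence=float(p),
            width=float(w) * step,
        )
        for i, p, w in zip(idx, props["prominences"], widths)
    ]
    peaks.sort(key=lambda p: p.location)
    return peaks


def order_events(
    peaksets: Mapping[str, Sequence[PeakCall]],
    self_comparisons: Sequence[str],
    cross_comparisons: Sequence[str],
    tolerance: float = 0.01,
) -> list[dict]:
    """Pair each self-comparison's youngest peak with each cross peak.

    The youngest (smallest-location) self peak is the candidate WGD; each
    cross-comparison peak is a speciation marker. The report gives the
    qualitative order at the stated tolerance: a WGD peak smaller than the
    speciation peak by more than the tolerance is "younger" (lineage-
    specific duplication), larger is "older" (shared duplication), otherwise
    "indistinguishable".
    """
    for name in list(self_comparisons) + list(cross_comparisons):
        if name not in peaksets:
            raise FormatError(f"missing required comparison {name!r}")
    report: list[dict] = []
    for self_name in self_comparisons:
        self_peaks = peaksets[self_name]
        if not self_peaks:
            continue
        wgd = min(p.location for p in self_peaks)
        for cross_name in cross_comparisons:
            for peak in peaksets[cross_name]:
                delta = wgd - peak.location
                if abs(delta) <= tolerance:
                    order = "indistinguishable"
                    note = (
                        f"indistinguishable at tolerance {tolerance}; "
                        "shared-WGD consistent"
                    )
                elif delta < 0:
                    order = "younger"
                    note = "WGD younger than speciation (lineage-specific)"
                else:
                    order = "older"
                    note = "WGD older than speciation (shared)"
                report.append(
                    {
                        "self_comparison": self_name,
                        "cross_comparison": cross_name,
                        "wgd_location": wgd,
                        "speciation_location": peak.location,
                        "order": order,
                        "interpretation": note,
                    }
                )
    return report


@dataclass
class RetentionReport:
    """Homeolog retention against a pre-duplication outgroup."""

    #: homolog count -> number of outgroup genes with that many focal homologs
    counts: dict[int, int] = field(default_factory=dict)
    two_copy_percent: float = math.nan
    n_considered: int = 0
    k: int = 2

    @property
    def two_copy_fraction(self) -> float:
        return self.two_copy_percent / 100.0


def retention_analysis(
    hits: HitTable,
    focal_ids: Iterable[str],
    outgroup_ids: Iterable[str],
    k: int = 2,
) -> RetentionReport:
    """Count focal homeologs per outgroup gene via directional best hits.

    For every focal-genome query its top-``k`` outgroup subjects are taken
    (bit score ranking); each outgroup gene then has a homolog count equal to
    the number of focal queries listing it. Outgroup genes with between 1 and
    ``k`` homologs are considered, and the share with exactly ``k`` (both
    copies retained after the duplication) is reported to one decimal.
    """
    focal_ids = set(focal_ids)
    outgroup_ids = set(outgroup_ids)
    cross = HitTable(
        [
            r
            for r in hits
            if r.query_id in focal_ids and r.subject_id in outgroup_ids
        ]
    )
    if len(cross) == 0:
        raise FormatError("no focal-to-outgroup hits in the table")
    top = best_hits(cross, k)
    per_outgroup: dict[str, int] = {}
    for rec in top:
        per_outgroup[rec.subject_id] = per_outgroup.get(rec.subject_id, 0) + 1
    report = RetentionReport(k=k)
    for count in per_outgroup.values():
        report.counts[count] = report.counts.get(count, 0) + 1
    considered = sum(n for c, n in report.counts.items() if 1 <= c <= k)
    report.n_considered = considered
    if considered:
        n_two = report.counts.get(k, 0)
        report.two_copy_percent = round(100.0 * n_two / considered, 1)
    return report
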