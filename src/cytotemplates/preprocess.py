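"""Per-sample preprocessing: spectral unmixing, boundary-event filtering,
and asinh variance stabilization with cofactors chosen by Bartlett's test.

The variance-stabilizing transform is ``asinh(z / c)`` with one cofactor c
per channel, shared by every sample in the cohort. c is selected by
minimizing Bartlett's homogeneity-of-variances statistic over the
one-dimensional density-peak clusters found in the transformed channel,
pooled across all samples: when the within-population variances of dim and
bright populations are equal, the channel is variance-stabilized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .model import EventMatrix, SpilloverMatrix

log = logging.getLogger(__name__)

__all__ = [
    "compensate",
    "filter_boundary",
    "asinh_transform",
    "find_density_peaks_1d",
    "bartlett_statistic",
    "select_cofactor",
    "PeakClustering1D",
    "CofactorProfile",
    "default_cofactor_grid",
]


def compensate(events: EventMatrix, spill: SpilloverMatrix) -> EventMatrix:
    """Unmix observed signals o into source signals s by solving o = M s.

    The noise term of the full measurement model is ignored; the system of
    linear equations is solved exactly for the channels covered by the
    spillover matrix. Channels absent from the spillover matrix pass
    through untouched.
    """
    missing = [c for c in spill.channel_names if c not in events.channel_names]
    if missing:
        raise ValueError(f"spillover channels {missing} not present in sample")
    idx = [events.channel_index(c) for c in spill.channel_names]
    observed = events.values[:, idx]
    unmixed = np.linalg.solve(spill.M, observed.T).T
    values = events.values.copy()
    values[:, idx] = unmixed
    return EventMatrix(values, list(events.channel_names), events.sample_id)


def filter_boundary(
    events: EventMatrix,
    low: float,
    high: float,
    channels: list[str] | None = None,
) -> EventMatrix:
    """Drop cells whose total fluorescence falls outside [low, high].

    Cells with very low totals are likely debris expressing no marker;
    very high totals are likely doublets or instrument noise. The total is
    the per-cell sum over ``channels`` (default: all channels).
    """
    if not low < high:
        raise ValueError("low threshold must be below high threshold")
    if channels is None:
        totals = events.values.sum(axis=1)
    else:
        idx = [events.channel_index(c) for c in channels]
        totals = events.values[:, idx].sum(axis=1)
    keep = (totals >= low) & (totals <= high)
    n_low = int(np.sum(totals < low))
    n_high = int(np.sum(totals > high))
    if not keep.any():
        raise ValueError(
            f"boundary filter removed all {events.n_cells} cells "
            f"({n_low} below {low}, {n_high} above {high})"
        )
    if n_low or n_high:
        log.info(
            "%s: removed %d dim and %d bright boundary events of %d",
            events.sample_id,
            n_low,
            n_high,
            events.n_cells,
        )
    return EventMatrix(
        events.values[keep], list(events.channel_names), events.sample_id
    )


def asinh_transform(events: EventMatrix, cofactors) -> EventMatrix:
    """Apply asinh(value / c) per channel; c may be a scalar or per-channel."""
    c = np.broadcast_to(np.asarray(cofactors, dtype=float), (events.n_channels,))
    if np.any(c <= 0):
        raise ValueError("cofactors must be positive")
    return EventMatrix(
        np.arcsinh(events.values / c), list(events.channel_names), events.sample_id
    )


@dataclass
class PeakClustering1D:
    """1-D density-peak clustering of one transformed channel."""

    peak_locations: np.ndarray
    assignments: np.ndarray
    variances: np.ndarray
    sizes: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.peak_locations)


MIN_CELLS_FOR_PEAKS = 50
PEAK_HEIGHT_FRACTION = 0.05
PEAK_PROMINENCE_FRACTION = 0.05


def find_density_peaks_1d(
    values,
    grid_size: int = 512,
    height_fraction: float = PEAK_HEIGHT_FRACTION,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> PeakClustering1D:
    """Find 1-D clusters as modes of a kernel density estimate.

    Local maxima of a Silverman-bandwidth KDE exceeding ``height_fraction``
    of the global density maximum, with at least ``prominence_fraction`` of
    it in prominence, become peaks; density minima between adjacent peaks
    are the assignment boundaries. Fewer than 50 values (or constant input)
    yield a single all-spanning peak.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    spread = np.ptp(x)
    if n < MIN_CELLS_FOR_PEAKS or spread == 0 or np.std(x) == 0:
        var = float(np.var(x, ddof=1)) if n > 1 else 0.0
        return PeakClustering1D(
            peak_locations=np.array([float(np.mean(x))]),
            assignments=np.zeros(n, dtype=int),
            variances=np.array([var]),
            sizes=np.array([n]),
        )

    kde = gaussian_kde(x, bw_method="silverman")
    pad = 0.05 * spread
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    density = kde(grid)
    dmax = density.max()
    peaks, _ = find_peaks(
        density,
        height=height_fraction * dmax,
        prominence=prominence_fraction * dmax,
    )
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(density))])

    locations = grid[peaks]
    # Valley between adjacent peaks = density minimum between them
    boundaries = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        boundaries.append(grid[a + int(np.argmin(density[a : b + 1]))])
    boundaries = np.asarray(boundaries)
    assignments = np.searchsorted(boundaries, x)

    variances = np.zeros(len(peaks))
    sizes = np.zeros(len(peaks), dtype=int)
    for i in range(len(peaks)):
        members = x[assignments == i]
        sizes[i] = members.size
        variances[i] = float(np.var(members, ddof=1)) if members.size > 1 else 0.0
    return PeakClustering1D(locations, assignments, variances, sizes)


def bartlett_statistic(variances, sizes) -> float:
    """Bartlett's likelihood-ratio statistic for homogeneity of variances.

    chi2 = [(N - m) ln s2_p - sum (n_i - 1) ln s2_i] / C with pooled
    variance s2_p and the usual correction factor C. Returns 0 for fewer
    than two usable clusters. Zero-variance clusters are excluded (their
    log-variance is undefined) with a warning.
    """
    var = np.asarray(variances, dtype=float)
    n = np.asarray(sizes, dtype=float)
    usable = (var > 0) & (n >= 2)
    if np.any(~usable):
        log.warning(
            "dropping %d zero-variance or undersized clusters from Bartlett pool",
            int(np.sum(~usable)),
        )
    var, n = var[usable], n[usable]
    m = var.size
    if m < 2:
        log.warning("fewer than 2 clusters: Bartlett statistic trivially 0")
        return 0.0
    N = n.sum()
    dof = n - 1.0
    pooled = float(np.sum(dof * var) / (N - m))
    numerator = (N - m) * np.log(pooled) - float(np.sum(dof * np.log(var)))
    correction = 1.0 + (np.sum(1.0 / dof) - 1.0 / (N - m)) / (3.0 * (m - 1))
    return max(float(numerator / correction), 0.0)


@dataclass
class CofactorProfile:
    """Bartlett statistic across a cofactor grid and the minimizing cofactor."""

    grid: np.ndarray
    bartlett_values: np.ndarray
    best_cofactor: float
    flagged: list[float] = field(default_factory=list)


def default_cofactor_grid(
    low: float = 1.0, high: float = 1e5, n: int = 30
) -> np.ndarray:
    return np.geomspace(low, high, n)


def select_cofactor(
    samples: list[EventMatrix], channel: str, grid=None
) -> CofactorProfile:
    """Pick the asinh cofactor that best stabilizes a channel's variances.

    For each candidate cofactor the channel is transformed in every sample,
    per-sample 1-D density peaks are found, and all peak variances are
    pooled into one Bartlett statistic. The argmin cofactor is returned
    (ties break toward the smaller cofactor); the same cofactor is then
    applied to this channel in every sample.
    """
    if grid is None:
        grid = default_cofactor_grid()
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("cofactor grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("cofactors must be positive")

    columns = [s.channel(channel) for s in samples]
    stats = np.empty(grid.size)
    flagged: list[float] = []
    for gi, c in enumerate(grid):
        pooled_var: list[float] = []
        pooled_n: list[int] = []
        for col in columns:
            pc = find_density_peaks_1d(np.arcsinh(col / c))
            pooled_var.extend(pc.variances.tolist())
            pooled_n.extend(pc.sizes.tolist())
        usable = sum(1 for v, k in zip(pooled_var, pooled_n) if v > 0 and k >= 2)
        if usable < 2:
            flagged.append(float(c))
        stats[gi] = bartlett_statistic(pooled_var, pooled_n)

    best_idx = int(np.argmin(stats))  # first minimum = smallest cofactor
    return CofactorProfile(
        grid=grid,
        bartlett_values=stats,
        best_cofactor=float(grid[best_idx]),
        flagged=flagged,
    )
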