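"""Map statistics, marker-density tracks, funnel accounting and
cross-population transferability summaries.

All percentages are recomputed from counts at presentation time, never
stored; a helper flags printed percentages that disagree with the
recomputed value by more than half a point, which is useful when checking
published tables against their own counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import GeneticMap


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent(numerator: float, denominator: float) -> float:
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    return 100.0 * numerator / denominator


class PercentageMismatchWarning(UserWarning):
    pass


def check_printed_percentage(numerator: int, denominator: int, printed: float,
                             label: str = "") -> float:
    """Recompute a percentage and warn if a printed value disagrees.

    Returns the recomputed percentage; warns (never raises) when the
    printed figure is off by more than 0.5 points.
    """
    value = percent(numerator, denominator)
    if abs(value - printed) > 0.5:
        warnings.warn(
            f"printed {printed}% for {label or f'{numerator}/{denominator}'} "
            f"disagrees with recomputed {value:.1f}%",
            PercentageMismatchWarning,
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# map statistics


@dataclass
class MapStats:
    total_length_cM: float
    group_lengths: dict[str, float]
    group_counts: dict[str, int]
    n_markers: int
    mean_group_length: float
    mean_markers_per_group: float
    mean_interval_cM: float

    def rounded(self) -> dict[str, float]:
        """Presentation view with half-up integer rounding of the means."""
        return {
            "total_length_cM": round_half_up(self.total_length_cM),
            "mean_group_length_cM": round_half_up(self.mean_group_length),
            "mean_markers_per_group": round_half_up(self.mean_markers_per_group),
            "mean_interval_cM": round(self.mean_interval_cM, 3),
        }


def map_stats(gmap: GeneticMap, interval_denominator: str = "markers") -> MapStats:
    """Summary statistics of a genetic map.

    The mean marker interval is total length / marker count by default;
    ``interval_denominator='intervals'`` uses (markers - groups) instead.
    """
    if not gmap.groups:
        raise ValueError("empty map")
    lengths, counts = {}, {}
    for gid, markers, positions in gmap.groups:
        if not markers:
            raise ValueError(f"group {gid} is empty")
        lengths[gid] = float(max(positions))
        counts[gid] = len(markers)
    total = sum(lengths.values())
    n_markers = sum(counts.values())
    n_groups = len(lengths)
    if interval_denominator == "markers":
        denom = n_markers
    elif interval_denominator == "intervals":
        denom = n_markers - n_groups
    else:
        raise ValueError("interval_denominator must be 'markers' or 'intervals'")
    return MapStats(
        total_length_cM=total,
        group_lengths=lengths,
        group_counts=counts,
        n_markers=n_markers,
        mean_group_length=total / n_groups,
        mean_markers_per_group=n_markers / n_groups,
        mean_interval_cM=total / denom,
    )


# ---------------------------------------------------------------------------
# density track


@dataclass
class DensityTrack:
    group_id: str
    window_size_cM: float
    step_cM: float
    starts: np.ndarray
    counts: np.ndarray

    @property
    def min_count(self) -> int:
        return int(self.counts.min())

    @property
    def max_count(self) -> int:
        return int(self.counts.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group_id, "window_start_cM": self.starts, "count": self.counts}
        )


def density_track(
    positions,
    group_id: str = "",
    group_length: float | None = None,
    window_size: float = 3.0,
    step: float = 0.3,
) -> DensityTrack:
    """Sliding-window marker counts along one linkage group.

    Windows are half-open ``[x, x + window)`` with starts 0, step, 2*step,
    ... up to the group length (so the windows cover the whole group). The
    per-group min/max counts feed colour scaling adjusted per group.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if window_size <= 0:
        raise ValueError("window size must be positive")
    positions = np.asarray(list(positions), dtype=float)
    length = group_length if group_length is not None else (
        float(positions.max()) if positions.size else 0.0
    )
    if positions.size and (positions.min() < 0 or positions.max() > length + 1e-9):
        raise ValueError("marker positions outside [0, group length]")
    n_windows = int(math.floor(length / step + 1e-9)) + 1
    starts = np.round(np.arange(n_windows) * step, 10)
    if positions.size:
        counts = np.array(
            [np.sum((positions >= s) & (positions < s + window_size)) for s in starts],
            dtype=int,
        )
    else:
        counts = np.zeros(n_windows, dtype=int)
    return DensityTrack(group_id, window_size, step, starts, counts)


def density_tracks(gmap: GeneticMap, window_size: float = 3.0, step: float = 0.3):
    return [
        density_track(pos, gid, window_size=window_size, step=step)
        for gid, _, pos in gmap.groups
    ]


# ---------------------------------------------------------------------------
# transferability


@dataclass
class TransferabilitySummary:
    panel_size: int
    populations: pd.DataFrame  # per-population counts and recomputed %
    polymorphic_in_all: int
    polymorphic_in_any: int


def transferability(
    status: pd.DataFrame,
    panel_size: int,
    call_rates: dict[str, float] | None = None,
) -> TransferabilitySummary:
    """Cross-population assay-performance table.

    ``status`` is populations x markers with values in {'no_signal',
    'monomorphic', 'polymorphic'}. Per population the summary gives the
    number (and recomputed percentage) of markers generating signals, and
    polymorphic markers referred both to signal-generating markers and to
    the full panel.
    """
    if status.empty:
        raise ValueError("no populations")
    rows = []
    for pop, row in status.iterrows():
        assayed = int((row != "absent").sum())
        if assayed == 0:
            raise ValueError(f"population {pop} has no assayed markers")
        signals = int((row != "no_signal").sum())
        poly = int((row == "polymorphic").sum())
        rows.append(
            {
                "population": pop,
                "call_rate": (call_rates or {}).get(pop, float("nan")),
                "signals": signals,
                "signals_pct_of_panel": percent(signals, panel_size),
                "polymorphic": poly,
                "polymorphic_pct_of_signals": percent(poly, signals) if signals else 0.0,
                "polymorphic_pct_of_panel": percent(poly, panel_size),
            }
        )
    poly_mask = status == "polymorphic"
    return TransferabilitySummary(
        panel_size=panel_size,
        populations=pd.DataFrame(rows).set_index("population"),
        polymorphic_in_all=int(poly_mask.all(axis=0).sum()),
        polymorphic_in_any=int(poly_mask.any(axis=0).sum()),
    )


# ---------------------------------------------------------------------------
# funnel accounting


@dataclass
class FunnelStage:
    label: str
    removed: int
    remaining: int
    pct_of_input: float


def accounting_summary(initial: int, removals: list[tuple[str, int]]) -> list[FunnelStage]:
    """The pipeline funnel: successive removals from an initial count.

    Each stage records what was removed, what remains, and the remaining
    fraction of the initial count (recomputed). Removing more than remains
    is a conservation error.
    """
    if initial <= 0:
        raise ValueError("initial count must be positive")
    remaining = initial
    stages = [FunnelStage("input", 0, initial, 100.0)]
    for label, removed in removals:
        if removed < 0:
            raise ValueError(f"negative removal at {label}")
        remaining -= removed
        if remaining < 0:
            raise ValueError(f"funnel does not conserve counts at {label}")
        stages.append(FunnelStage(label, removed, remaining, percent(remaining, initial)))
    return stages


def funnel_frame(stages: list[FunnelStage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stage": s.label,
                "removed": s.removed,
                "remaining": s.remaining,
                "pct_of_input": round(s.pct_of_input, 1),
            }
            for s in stages
        ]
    )


def density_heatmap(tracks, path) -> bool:
    """Optional PNG heat map of marker density; returns False without a
    plotting backend installed."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return False
    fig, axes = plt.subplots(len(tracks), 1, figsize=(8, 0.6 * len(tracks) + 1),
                             squeeze=False)
    for ax, tr in zip(axes.ravel(), tracks):
        counts = tr.counts[None, :].astype(float)
        span = max(tr.max_count - tr.min_count, 1)
        ax.imshow((counts - tr.min_count) / span, aspect="auto", cmap="jet",
                  extent=(0, tr.starts[-1] + tr.step_cM, 0, 1))
        ax.set_yticks([])
        ax.set_ylabel(tr.group_id, rotation=0, ha="right", va="center")
    axes.ravel()[-1].set_xlabel("position (cM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True
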