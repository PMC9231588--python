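"""Social preference and shoaling cohesion metrics.

The social preference index (SPI) contrasts dwell in the sector adjacent
to conspecifics against the opposite empty sector::

    SPI = (conspecific - empty) / (conspecific + empty)

computed on time or on swum distance; dwell outside both sectors does not
enter the denominator. SPI spans -1 (always by the empty side) through 0
(no preference) to +1 (always by the conspecifics). The juvenile paradigm
compares a pre-exposure *baseline* period against the *test* period
(delta-SPI); the adult paradigm reports test-period SPI directly.

Shoaling cohesion is the mean inter-individual distance (IID): at each
frame the mean over all unordered pairs of fish, then averaged over
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArenaPartition, GroupRecording, Trajectory, zone_occupancy

__all__ = ["SPIResult", "ShoalResult", "spi", "delta_spi", "shoaling_iid"]


@dataclass
class SPIResult:
    fish_id: str
    genotype: str
    paradigm: str  # juvenile | adult
    mode: str  # time | distance
    period: str  # baseline | test
    spi: float  # in [-1, 1]; NaN when undefined
    conspecific_dwell: float  # s (time mode) or mm (distance mode)
    empty_dwell: float
    defined: bool


@dataclass
class ShoalResult:
    group_id: str
    genotype: str
    iid_series: np.ndarray  # per-frame mean pairwise distance, mm
    mean_iid: float  # grand mean over frames with >= 2 valid fish
    n_fish: int


def spi(
    traj: Trajectory,
    partition: ArenaPartition,
    window: tuple[float, float] | None = None,
    mode: str = "time",
    *,
    paradigm: str = "juvenile",
    period: str = "test",
) -> SPIResult:
    """Social preference index over a window.

    The partition must name ``conspecific`` and ``empty`` sectors. With
    zero combined dwell the index is undefined (NaN, ``defined=False``).
    """
    if mode not in ("time", "distance"):
        raise ValueError(f"mode must be time or distance, got {mode!r}")
    for need in ("conspecific", "empty"):
        if need not in partition.zone_names:
            raise ValueError(f"partition lacks required sector {need!r}")
    occ = zone_occupancy(traj, partition, window)
    pick = 0 if mode == "time" else 1
    c = occ["conspecific"][pick]
    e = occ["empty"][pick]
    denom = c + e
    value = (c - e) / denom if denom > 0 else float("nan")
    return SPIResult(traj.fish_id, traj.genotype, paradigm, mode, period,
                     value, c, e, denom > 0)


def delta_spi(baseline: SPIResult, test: SPIResult) -> float:
    """Test-period SPI minus baseline-period SPI (range [-2, 2]).

    NaN when either period's SPI is undefined. Both results must belong to
    the same fish and mode, with periods baseline and test.
    """
    if baseline.fish_id != test.fish_id or baseline.mode != test.mode:
        raise ValueError("delta_spi requires the same fish and mode")
    if baseline.period != "baseline" or test.period != "test":
        raise ValueError("arguments must be (baseline, test) period results")
    if not (baseline.defined and test.defined):
        return float("nan")
    return test.spi - baseline.spi


def shoaling_iid(group: GroupRecording, window: tuple[float, float] | None = None) -> ShoalResult:
    """Mean inter-individual distance of a shoal.

    Per frame: the mean of all n(n-1)/2 unordered pairwise Euclidean
    distances among fish with a valid position in that frame; frames with
    fewer than two valid fish are skipped. ``mean_iid`` is the mean over
    contributing frames.
    """
    trajs = group.trajectories
    if window is not None:
        trajs = [tr.slice(*window) for tr in trajs]
    n = len(trajs)
    if n < 2:
        raise ValueError("shoaling_iid needs at least 2 fish")
    n_frames = min(len(tr) for tr in trajs)
    xs = np.stack([tr.x[:n_frames] for tr in trajs])
    ys = np.stack([tr.y[:n_frames] for tr in trajs])
    ok = np.stack([tr.valid[:n_frames] for tr in trajs])
    pair_sum = np.zeros(n_frames)
    pair_cnt = np.zeros(n_frames)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            d = np.hypot(xs[i] - xs[j], ys[i] - ys[j])
            pair_sum[both] += d[both]
            pair_cnt[both] += 1
    usable = pair_cnt > 0
    if not np.any(usable):
        raise ValueError("no frame with at least 2 valid fish")
    series = np.full(n_frames, np.nan)
    series[usable] = pair_sum[usable] / pair_cnt[usable]
    return ShoalResult(group.group_id, trajs[0].genotype, series,
                       float(np.nanmean(series)), n)
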