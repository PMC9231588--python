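"""Thigmotaxis ("wall hugging"): anxiety index for open-field recordings.

The tank is split into two equal-area zones — a concentric central zone
and the surrounding peripheral zone — and thigmotaxis is the fraction of
time (or of swum distance) spent in the periphery. Under the equal-area
split an unbiased swimmer's expected time ratio is 0.5, so excess above
0.5 reads directly as wall preference.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Arena, ArenaPartition, Trajectory, equal_area_split, zone_occupancy

__all__ = ["ThigmotaxisResult", "thigmotaxis"]


@dataclass
class ThigmotaxisResult:
    fish_id: str
    genotype: str
    time_ratio: float  # peripheral time / total zone time, in [0, 1]
    distance_ratio: float  # peripheral distance / total distance
    partition: ArenaPartition
    defined: bool  # False when there is no usable time (ratios NaN)


def thigmotaxis(
    traj: Trajectory,
    arena: Arena,
    mode: str = "both",
    partition: ArenaPartition | None = None,
    window: tuple[float, float] | None = None,
) -> ThigmotaxisResult:
    """Peripheral-zone time and distance fractions of a recording.

    ``mode`` selects which ratios are populated ("time", "distance" or
    "both"); the unrequested one is NaN. A custom ``partition`` may replace
    the default equal-area split (it must define zones named ``periphery``
    and ``center``). A recording with zero usable time (or, for the
    distance ratio, zero swum distance) yields an undefined, flagged
    result.
    """
    if mode not in ("time", "distance", "both"):
        raise ValueError(f"mode must be time/distance/both, got {mode!r}")
    if partition is None:
        partition = equal_area_split(arena)
    for need in ("periphery", "center"):
        if need not in partition.zone_names:
            raise ValueError(f"partition lacks required zone {need!r}")
    occ = zone_occupancy(traj, partition, window)
    t_per, d_per = occ["periphery"]
    t_cen, d_cen = occ["center"]
    t_tot = t_per + t_cen
    d_tot = d_per + d_cen
    time_ratio = t_per / t_tot if (mode != "distance" and t_tot > 0) else float("nan")
    dist_ratio = d_per / d_tot if (mode != "time" and d_tot > 0) else float("nan")
    # a frozen but tracked fish still has a defined time ratio
    defined = d_tot > 0 if mode == "distance" else t_tot > 0
    return ThigmotaxisResult(traj.fish_id, traj.genotype, time_ratio, dist_ratio,
                             partition, defined)
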