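"""Locomotor activity and visual-motor-response metrics.

Activity is the tracker's native readout: distance moved per 30-s bin,
averaged over a stated window (the first 15 min of light for the larval
assay). The visual motor response to an illumination transition is the
ratio of mean swimming speed in the 30 s after the switch to the 30 s
before it; per fish, the three same-direction transitions of the light/dark
assay are averaged. The exact functional form of the published "rate of
velocity change" is not recoverable from its description, so the
dimensionless after/before ratio is the documented convention here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LightSchedule, Trajectory, binned_distance, step_lengths

__all__ = [
    "ActivityProfile",
    "TransitionResponse",
    "activity_profile",
    "epoch_mean_activity",
    "transition_response",
]


@dataclass
class ActivityProfile:
    """Per-bin distance series (mm per bin) for one fish over a window."""

    fish_id: str
    genotype: str
    bins: pd.DataFrame  # bin_start_s, distance_mm, epoch, flagged
    bin_s: float
    mean_activity: float  # mm per bin over unflagged complete bins

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class TransitionResponse:
    """Speed change across same-direction illumination transitions.

    ``ratios[i]`` is (mean speed 30 s after) / (mean speed 30 s before) the
    i-th transition; undefined ratios (zero speed before) are NaN and
    excluded from ``mean_ratio``.
    """

    fish_id: str
    genotype: str
    direction: str  # light_to_dark | dark_to_light
    v_before: list[float]  # mm/s
    v_after: list[float]
    ratios: list[float]
    mean_ratio: float
    n_defined: int


def _epoch_label_per_bin(bin_starts: np.ndarray, bin_s: float, schedule: LightSchedule) -> list[str]:
    labels = []
    for b in bin_starts:
        mid = b + bin_s / 2.0
        lab = ""
        for e in schedule.epochs:
            if e.start_s <= mid < e.end_s:
                lab = e.label
                break
        labels.append(lab)
    return labels


def activity_profile(
    traj: Trajectory,
    schedule: LightSchedule | None = None,
    window: tuple[float, float] | None = None,
    bin_s: float = 30.0,
) -> ActivityProfile:
    """Binned distance with epoch labels and the windowed mean activity.

    ``window`` defaults to the whole recording; the mean is over complete,
    unflagged bins whose start lies in the window.
    """
    if window is None:
        window = (float(traj.t[0]), float(traj.t[-1]) + traj.dt)
    if window[1] - window[0] < bin_s:
        raise ValueError(f"window shorter than one bin ({bin_s}s)")
    table = binned_distance(traj, bin_s)
    table = table[
        (table["bin_start_s"] >= window[0] - 1e-9)
        & (table["bin_start_s"] + bin_s <= window[1] + 1e-9)
    ].reset_index(drop=True)
    if schedule is not None:
        table["epoch"] = _epoch_label_per_bin(
            table["bin_start_s"].to_numpy(), bin_s, schedule
        )
    else:
        table["epoch"] = ""
    used = table[~table["flagged"]]
    mean_act = float(used["distance_mm"].mean()) if len(used) else float("nan")
    return ActivityProfile(traj.fish_id, traj.genotype, table, bin_s, mean_act)


def epoch_mean_activity(
    traj: Trajectory,
    schedule: LightSchedule,
    bin_s: float = 30.0,
    epochs: list[str] | None = None,
) -> dict[str, float]:
    """Mean distance per bin for each labelled epoch.

    Only bins lying wholly inside an epoch count; an epoch without a single
    complete unflagged bin maps to NaN. Requesting an epoch label missing
    from the schedule is an error.
    """
    if epochs is None:
        epochs = schedule.labels
    missing = set(epochs) - set(schedule.labels)
    if missing:
        raise ValueError(f"schedule has no epoch(s) {sorted(missing)}")
    table = binned_distance(traj, bin_s)
    out: dict[str, float] = {}
    for lab in epochs:
        e = next(ep for ep in schedule.epochs if ep.label == lab)
        sel = table[
            (table["bin_start_s"] >= e.start_s - 1e-9)
            & (table["bin_start_s"] + bin_s <= e.end_s + 1e-9)
            & (~table["flagged"])
        ]
        out[lab] = float(sel["distance_mm"].mean()) if len(sel) else float("nan")
    return out


def _mean_speed(traj: Trajectory, start: float, end: float) -> float:
    """Mean speed (mm/s) over frames in [start, end): accrued distance over
    accrued step time (so a constant-speed segment recovers its speed
    exactly, with no end-frame bias)."""
    sub = traj.slice(start, end)
    if len(sub) < 2:
        return float("nan")
    d = float(np.sum(step_lengths(sub)))
    _, _, ok = sub.cleaned_xy()
    t_used = float(np.sum(ok[:-1] & ok[1:])) * sub.dt
    return d / t_used if t_used > 0 else float("nan")


def transition_response(
    traj: Trajectory,
    schedule: LightSchedule,
    direction: str,
    window_s: float = 30.0,
) -> TransitionResponse:
    """After/before speed ratio at each same-direction transition.

    Per transition at time T: ratio = mean speed over [T, T+window) /
    mean speed over [T-window, T). A transition with zero (or undefined)
    pre-switch speed yields a NaN ratio, flagged by exclusion from
    ``mean_ratio``; the mean is over the remaining transitions.
    """
    if direction not in ("light_to_dark", "dark_to_light"):
        raise ValueError(f"unknown direction {direction!r}")
    times = [t for t, d in schedule.transitions if d == direction]
    if not times:
        raise ValueError(f"schedule has no {direction} transitions")
    t0, t1 = float(traj.t[0]), float(traj.t[-1]) + traj.dt
    v_before, v_after, ratios = [], [], []
    for T in times:
        if T - window_s < t0 - 1e-9 or T + window_s > t1 + 1e-9:
            raise ValueError(
                f"transition at {T}s lacks {window_s}s of recording on both sides"
            )
        vb = _mean_speed(traj, T - window_s, T)
        va = _mean_speed(traj, T, T + window_s)
        v_before.append(vb)
        v_after.append(va)
        ratios.append(va / vb if vb > 0 else float("nan"))
    defined = [r for r in ratios if np.isfinite(r)]
    mean_ratio = float(np.mean(defined)) if defined else float("nan")
    return TransitionResponse(
        traj.fish_id, traj.genotype, direction,
        v_before, v_after, ratios, mean_ratio, len(defined),
    )
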