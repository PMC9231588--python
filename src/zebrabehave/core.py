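"""Domain types and geometric/kinematic primitives for fish-trajectory analysis.

Everything downstream (activity, thigmotaxis, social preference, shoaling)
is built from four ingredients defined here:

* :class:`Trajectory` — a time-ordered 2-D track of one fish in arena-local
  millimetre coordinates (origin at the lower-left corner for rectangular
  tanks, at the centre for circular wells, y increasing upward).
* :class:`Arena` / :class:`ArenaPartition` — the physical tank and a named
  set of zones inside it (periphery/centre, conspecific/empty sectors).
* :class:`LightSchedule` — labelled illumination epochs with transitions.
* The primitive operations: :func:`path_length`, :func:`binned_distance`,
  :func:`zone_occupancy`, :func:`segment_epochs`, :func:`point_in_zone`.

Tracking dropouts (``valid == False``) are bridged by linear interpolation
when the gap is at most ``max_gap_s`` (default 1 s); frames inside longer
gaps are excluded from both time and distance accrual, and any distance bin
with more than 20 % excluded frames is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

__all__ = [
    "TrackSample",
    "Trajectory",
    "Arena",
    "ArenaPartition",
    "Epoch",
    "LightSchedule",
    "GroupRecording",
    "OutOfArenaError",
    "point_in_zone",
    "path_length",
    "step_lengths",
    "binned_distance",
    "zone_occupancy",
    "segment_epochs",
    "equal_area_split",
    "juvenile_sectors",
    "adult_sectors",
    "larval_light_dark_schedule",
    "constant_light_schedule",
]

GENOTYPES = ("WT", "HET", "HOM")

#: fraction of missing frames above which a 30-s bin is flagged
BIN_MISSING_FLAG_FRACTION = 0.20

#: longest tracking dropout (seconds) bridged by linear interpolation
DEFAULT_MAX_GAP_S = 1.0


class OutOfArenaError(ValueError):
    """A queried point lies outside the arena bounds."""


@dataclass(frozen=True)
class TrackSample:
    """One tracked video frame: time (s), position (mm), tracking-success flag."""

    t: float
    x: float
    y: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if self.valid and not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("valid samples must have finite coordinates")


class Trajectory:
    """Time-ordered 2-D track of a single fish.

    Parameters
    ----------
    fish_id : str
        Identifier of the fish (unique within a trial).
    genotype : {"WT", "HET", "HOM"}
        Genotype label (wild-type, heterozygous, homozygous mutant).
    t, x, y : array-like
        Per-frame time (s, strictly increasing), position (mm).
    valid : array-like of bool, optional
        Tracking-success flag per frame; defaults to all valid.
    fps : float
        Nominal frame rate (frames per second); 25 for the standard setup.
    arena_id : str
        Identifier of the arena the coordinates refer to.
    """

    def __init__(
        self,
        fish_id: str,
        genotype: str,
        t: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        valid: Sequence[bool] | None = None,
        fps: float = 25.0,
        arena_id: str = "arena",
    ) -> None:
        if genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) == 0:
            raise ValueError("trajectory must contain at least one sample")
        if np.any(t < 0):
            raise ValueError("sample times must be >= 0")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"sample times must be strictly increasing (fish {fish_id})")
        if fps <= 0:
            raise ValueError("fps must be positive")
        valid_arr = (
            np.ones(len(t), dtype=bool)
            if valid is None
            else np.asarray(valid, dtype=bool)
        )
        if len(valid_arr) != len(t):
            raise ValueError("valid must match t in length")
        finite = np.isfinite(x) & np.isfinite(y)
        if np.any(valid_arr & ~finite):
            raise ValueError("valid samples must have finite coordinates")
        if len(t) > 1:
            mean_dt = float(np.mean(np.diff(t)))
            if abs(mean_dt - 1.0 / fps) > 0.1 / fps:
                raise ValueError(
                    f"mean sampling interval {mean_dt:.4f}s deviates >10% "
                    f"from nominal 1/fps = {1.0 / fps:.4f}s"
                )
        self.fish_id = str(fish_id)
        self.genotype = genotype
        self.t = t
        self.x = x
        self.y = y
        self.valid = valid_arr
        self.fps = float(fps)
        self.arena_id = str(arena_id)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[TrackSample]:
        for i in range(len(self.t)):
            yield TrackSample(self.t[i], self.x[i], self.y[i], bool(self.valid[i]))

    @property
    def samples(self) -> list[TrackSample]:
        return list(self)

    @property
    def dt(self) -> float:
        """Nominal frame interval in seconds."""
        return 1.0 / self.fps

    @property
    def duration(self) -> float:
        """Recording span in seconds (first to last frame)."""
        return float(self.t[-1] - self.t[0])

    def slice(self, start_s: float, end_s: float, *, include_end: bool = False) -> "Trajectory":
        """Sub-trajectory with ``start_s <= t < end_s`` (or ``<= end_s``)."""
        mask = (self.t >= start_s) & ((self.t <= end_s) if include_end else (self.t < end_s))
        if not np.any(mask):
            raise ValueError(f"no samples in window [{start_s}, {end_s})")
        return Trajectory(
            self.fish_id, self.genotype,
            self.t[mask], self.x[mask], self.y[mask], self.valid[mask],
            fps=self.fps, arena_id=self.arena_id,
        )

    def cleaned_xy(self, max_gap_s: float = DEFAULT_MAX_GAP_S) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated coordinates and a per-frame usability mask.

        Invalid frames inside dropouts no longer than ``max_gap_s`` are
        filled by linear interpolation (and count as usable); frames inside
        longer dropouts, or before the first / after the last valid frame,
        are unusable and excluded from time and distance accrual.

        Returns ``(x, y, ok)``.
        """
        if not np.any(self.valid):
            raise ValueError(f"trajectory {self.fish_id} has no valid samples")
        ok = self.valid.copy()
        x = self.x.copy()
        y = self.y.copy()
        idx = np.flatnonzero(self.valid)
        # walk each internal run of invalid frames
        for a, b in zip(idx[:-1], idx[1:]):
            if b - a <= 1:
                continue
            gap = self.t[b] - self.t[a]
            if gap <= max_gap_s:
                inner = np.arange(a + 1, b)
                w = (self.t[inner] - self.t[a]) / gap
                x[inner] = self.x[a] + w * (self.x[b] - self.x[a])
                y[inner] = self.y[a] + w * (self.y[b] - self.y[a])
                ok[inner] = True
        return x, y, ok


@dataclass(frozen=True)
class Arena:
    """Physical tank/well geometry in millimetres.

    ``rectangle`` arenas use a lower-left origin; ``circle`` arenas
    (multi-well plates) are centred on the origin.
    """

    shape: Literal["rectangle", "circle"]
    dims: tuple[float, ...]  # (width, height) or (diameter,)
    arena_id: str = "arena"

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        n_expected = 2 if self.shape == "rectangle" else 1
        if len(self.dims) != n_expected:
            raise ValueError(f"{self.shape} arena needs {n_expected} dims, got {self.dims}")
        if any(d <= 0 for d in self.dims):
            raise ValueError("arena dimensions must be positive")

    @property
    def geometry(self) -> Polygon:
        if self.shape == "rectangle":
            w, h = self.dims
            return box(0.0, 0.0, w, h)
        (d,) = self.dims
        return Point(0.0, 0.0).buffer(d / 2.0, quad_segs=256)

    @property
    def area(self) -> float:
        if self.shape == "rectangle":
            w, h = self.dims
            return w * h
        (d,) = self.dims
        return np.pi * (d / 2.0) ** 2

    def bounds(self) -> tuple[float, float, float, float]:
        if self.shape == "rectangle":
            w, h = self.dims
            return (0.0, 0.0, w, h)
        (d,) = self.dims
        r = d / 2.0
        return (-r, -r, r, r)

    def contains(self, x, y, *, tol: float = 1e-9):
        """Vectorised membership test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "rectangle":
            w, h = self.dims
            return (x >= -tol) & (x <= w + tol) & (y >= -tol) & (y <= h + tol)
        (d,) = self.dims
        return x * x + y * y <= (d / 2.0 + tol) ** 2


@dataclass
class ArenaPartition:
    """Named, pairwise-disjoint zones inside an arena.

    Zone order matters: a point lying exactly on a shared boundary belongs
    to the first zone that contains it. If ``covering`` is true the zones
    tile the whole arena (asserted to 1e-6 relative area tolerance).
    """

    arena: Arena
    zones: list[tuple[str, Polygon]]
    covering: bool = False

    def __post_init__(self) -> None:
        names = [n for n, _ in self.zones]
        if len(set(names)) != len(names):
            raise ValueError("zone names must be unique")
        for i, (na, ga) in enumerate(self.zones):
            for nb, gb in self.zones[i + 1 :]:
                inter = ga.intersection(gb).area
                if inter > 1e-6 * min(ga.area, gb.area):
                    raise ValueError(f"zones {na!r} and {nb!r} overlap (area {inter:.3g})")
        if self.covering:
            total = sum(g.area for _, g in self.zones)
            if abs(total - self.arena.geometry.area) > 1e-6 * self.arena.geometry.area:
                raise ValueError("covering partition does not tile the arena")

    @property
    def zone_names(self) -> list[str]:
        return [n for n, _ in self.zones]

    def geometry(self, zone_name: str) -> Polygon:
        for n, g in self.zones:
            if n == zone_name:
                return g
        raise KeyError(f"unknown zone {zone_name!r}; have {self.zone_names}")

    def classify(self, x, y) -> np.ndarray:
        """Zone index per point (first containing zone wins); -1 if in the
        arena but in no zone. Raises :class:`OutOfArenaError` for points
        outside the arena."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.arena.contains(x, y)
        if not np.all(inside):
            i = int(np.flatnonzero(~inside)[0])
            raise OutOfArenaError(
                f"point ({x[i]:.3f}, {y[i]:.3f}) lies outside the arena"
            )
        out = np.full(x.shape, -1, dtype=np.int64)
        unassigned = np.ones(x.shape, dtype=bool)
        for k, (_, geom) in enumerate(self.zones):
            if not np.any(unassigned):
                break
            hit = unassigned & shapely.intersects_xy(geom, x, y)
            out[hit] = k
            unassigned &= ~hit
        return out


def point_in_zone(p: tuple[float, float], partition: ArenaPartition, zone_name: str) -> bool:
    """True iff point ``p`` (mm) lies in the named zone.

    Boundary points belong to the first zone listed in the partition, so a
    point on a shared boundary reports True only for that zone.
    """
    if zone_name not in partition.zone_names:
        raise KeyError(f"unknown zone {zone_name!r}; have {partition.zone_names}")
    k = partition.classify([p[0]], [p[1]])[0]
    return k >= 0 and partition.zone_names[k] == zone_name


# ---------------------------------------------------------------------------
# light schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float
    illumination: Literal["light", "dark"]
    lux: float = 100.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch {self.label!r} has non-positive duration")
        if self.illumination not in ("light", "dark"):
            raise ValueError(f"illumination must be light/dark, got {self.illumination!r}")


@dataclass
class LightSchedule:
    """Contiguous labelled illumination epochs.

    Transitions are derived: one per epoch boundary where illumination
    flips, tagged ``light_to_dark`` or ``dark_to_light``.
    """

    epochs: list[Epoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule must contain at least one epoch")
        labels = [e.label for e in self.epochs]
        if len(set(labels)) != len(labels):
            raise ValueError("epoch labels must be unique")
        for a, b in zip(self.epochs[:-1], self.epochs[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ValueError(f"epochs {a.label!r} and {b.label!r} are not contiguous")

    @property
    def start_s(self) -> float:
        return self.epochs[0].start_s

    @property
    def end_s(self) -> float:
        return self.epochs[-1].end_s

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]

    @property
    def transitions(self) -> list[tuple[float, str]]:
        out = []
        for a, b in zip(self.epochs[:-1], self.epochs[1:]):
            if a.illumination != b.illumination:
                direction = (
                    "light_to_dark" if a.illumination == "light" else "dark_to_light"
                )
                out.append((b.start_s, direction))
        return out

    def illumination_at(self, t) -> np.ndarray:
        """Per-time illumination as a boolean 'is dark' array.

        Times outside the schedule take the nearest epoch's illumination.
        Epoch membership is ``start <= t < end`` (final epoch closed).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        is_dark = np.zeros(t.shape, dtype=bool)
        for e in self.epochs:
            mask = (t >= e.start_s) & (t < e.end_s)
            is_dark[mask] = e.illumination == "dark"
        is_dark[t < self.start_s] = self.epochs[0].illumination == "dark"
        is_dark[t >= self.end_s] = self.epochs[-1].illumination == "dark"
        return is_dark


def larval_light_dark_schedule(
    baseline_s: float = 600.0,
    l0_s: float = 300.0,
    cycle_epoch_s: float = 300.0,
    n_cycles: int = 3,
    lux_light: float = 100.0,
) -> LightSchedule:
    """The standard larval light/dark schedule.

    A 15-min initial light period — split as *baseline* (first 10 min) plus
    *L0* (last 5 min) — followed by ``n_cycles`` dark/light cycles labelled
    D1, L1, ... Defaults give the 45-min assay (100 lx light, 0 lx dark).
    """
    epochs = [
        Epoch("baseline", 0.0, baseline_s, "light", lux_light),
        Epoch("L0", baseline_s, baseline_s + l0_s, "light", lux_light),
    ]
    t = baseline_s + l0_s
    for k in range(1, n_cycles + 1):
        epochs.append(Epoch(f"D{k}", t, t + cycle_epoch_s, "dark", 0.0))
        t += cycle_epoch_s
        epochs.append(Epoch(f"L{k}", t, t + cycle_epoch_s, "light", lux_light))
        t += cycle_epoch_s
    return LightSchedule(epochs)


def constant_light_schedule(duration_s: float, lux: float = 100.0) -> LightSchedule:
    """Single uninterrupted light epoch (open-field and social assays)."""
    return LightSchedule([Epoch("light", 0.0, duration_s, "light", lux)])


@dataclass
class GroupRecording:
    """Simultaneously recorded trajectories sharing one arena and time base."""

    trajectories: list[Trajectory]
    paradigm: Literal["open_field", "light_dark", "social_juvenile", "social_adult", "shoal"]
    group_id: str = "group"

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("group recording needs at least one trajectory")
        if self.paradigm == "shoal" and len(self.trajectories) < 2:
            raise ValueError("shoal paradigm requires at least 2 fish")
        ref = self.trajectories[0]
        for tr in self.trajectories[1:]:
            if abs(tr.duration - ref.duration) > 1.0 / ref.fps + 1e-9:
                raise ValueError("member trajectories must share duration within one frame")
            if tr.arena_id != ref.arena_id:
                raise ValueError("member trajectories must share one arena")

    @property
    def n_fish(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# partition factories
# ---------------------------------------------------------------------------

def equal_area_split(arena: Arena) -> ArenaPartition:
    """Split an arena into equal-area *center* and *periphery* zones.

    For a rectangle the central zone is the concentric rectangle scaled by
    1/sqrt(2) per side; for a circle, the concentric disc of radius
    r/sqrt(2). Both halves then have exactly half the arena area, so an
    unbiased walker's expected peripheral dwell fraction is 0.5.
    """
    if arena.shape == "rectangle":
        w, h = arena.dims
        cw, ch = w / np.sqrt(2.0), h / np.sqrt(2.0)
        center = box((w - cw) / 2.0, (h - ch) / 2.0, (w + cw) / 2.0, (h + ch) / 2.0)
    else:
        (d,) = arena.dims
        center = Point(0.0, 0.0).buffer(d / 2.0 / np.sqrt(2.0), quad_segs=256)
    periphery = arena.geometry.difference(center)
    return ArenaPartition(arena, [("periphery", periphery), ("center", center)], covering=True)


def juvenile_sectors(arena: Arena, conspecific_side: Literal["+y", "-y"] = "+y") -> ArenaPartition:
    """Conspecific/empty quarter-zone sectors of a circular well.

    The well is cut by two chords perpendicular to the social axis (the
    y axis: stimulus wells sit above/below the test well in the plate) at
    +/- d/4 from the centre. The band nearest the conspecific well is the
    *conspecific* sector, the opposite band the *empty* sector; the middle
    half of the well belongs to neither.
    """
    if arena.shape != "circle":
        raise ValueError("juvenile sectors are defined for circular wells")
    (d,) = arena.dims
    r = d / 2.0
    big = 2.0 * d
    upper = arena.geometry.intersection(box(-big, r / 2.0, big, big))
    lower = arena.geometry.intersection(box(-big, -big, big, -r / 2.0))
    if conspecific_side == "+y":
        zones = [("conspecific", upper), ("empty", lower)]
    else:
        zones = [("conspecific", lower), ("empty", upper)]
    return ArenaPartition(arena, zones, covering=False)


def adult_sectors(arena: Arena, conspecific_side: Literal["+x", "-x"] = "+x") -> ArenaPartition:
    """Two equal sectors of the rectangular test compartment.

    The compartment is split by a line parallel to the transparent divider
    (the divider runs along y at one x edge); the half nearest the
    conspecific group is the *conspecific* sector.
    """
    if arena.shape != "rectangle":
        raise ValueError("adult sectors are defined for rectangular compartments")
    w, h = arena.dims
    left = box(0.0, 0.0, w / 2.0, h)
    right = box(w / 2.0, 0.0, w, h)
    if conspecific_side == "+x":
        zones = [("conspecific", right), ("empty", left)]
    else:
        zones = [("conspecific", left), ("empty", right)]
    return ArenaPartition(arena, zones, covering=True)


# ---------------------------------------------------------------------------
# kinematic primitives
# ---------------------------------------------------------------------------

def step_lengths(traj: Trajectory, max_gap_s: float = DEFAULT_MAX_GAP_S) -> np.ndarray:
    """Per-step Euclidean distances (mm), one per frame-to-frame step.

    Steps with an unusable endpoint (long tracking dropout) contribute 0.
    Length is ``len(traj) - 1``.
    """
    x, y, ok = traj.cleaned_xy(max_gap_s)
    d = np.hypot(np.diff(x), np.diff(y))
    d[~(ok[:-1] & ok[1:])] = 0.0
    return d


def path_length(traj: Trajectory, max_gap_s: float = DEFAULT_MAX_GAP_S) -> float:
    """Total swum distance (mm): sum of step lengths between usable frames."""
    if len(traj) < 2:
        if not np.any(traj.valid):
            raise ValueError("no valid samples")
        return 0.0
    return float(np.sum(step_lengths(traj, max_gap_s)))


def binned_distance(
    traj: Trajectory,
    bin_s: float = 30.0,
    *,
    t0: float | None = None,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """Distance moved per fixed time bin (the tracker's native readout).

    Bins start at ``t0`` (default: the first sample time) and only complete
    bins are returned. Each step is assigned to the bin containing its
    start frame, so bin sums equal :func:`path_length` when the recording
    is an exact multiple of ``bin_s``. Returns a DataFrame with columns
    ``bin_start_s``, ``distance_mm``, ``missing_fraction``, ``flagged``.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    if t0 is None:
        t0 = float(traj.t[0])
    span = float(traj.t[-1]) - t0 + traj.dt  # last frame closes its interval
    n_bins = int(np.floor(span / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError(f"recording ({span:.1f}s) shorter than one bin ({bin_s}s)")
    steps = step_lengths(traj, max_gap_s)
    _, _, ok = traj.cleaned_xy(max_gap_s)
    idx_step = np.floor((traj.t[:-1] - t0) / bin_s + 1e-9).astype(np.int64)
    idx_frame = np.floor((traj.t - t0) / bin_s + 1e-9).astype(np.int64)
    dist = np.zeros(n_bins)
    in_range = (idx_step >= 0) & (idx_step < n_bins)
    np.add.at(dist, idx_step[in_range], steps[in_range])
    n_frames = np.zeros(n_bins)
    n_ok = np.zeros(n_bins)
    fr_range = (idx_frame >= 0) & (idx_frame < n_bins)
    np.add.at(n_frames, idx_frame[fr_range], 1.0)
    np.add.at(n_ok, idx_frame[fr_range], ok[fr_range].astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        missing = np.where(n_frames > 0, 1.0 - n_ok / n_frames, 1.0)
    return pd.DataFrame(
        {
            "bin_start_s": t0 + bin_s * np.arange(n_bins),
            "distance_mm": dist,
            "missing_fraction": missing,
            "flagged": missing > BIN_MISSING_FLAG_FRACTION,
        }
    )


def zone_occupancy(
    traj: Trajectory,
    partition: ArenaPartition,
    window: tuple[float, float] | None = None,
    *,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> dict[str, tuple[float, float]]:
    """Per-zone dwell time (s) and in-zone path length (mm).

    Dwell time is frame count x frame interval over usable frames; each
    step's distance goes to the zone of its start frame. For a covering
    partition the zone times sum to the windowed usable duration.
    """
    if window is not None:
        start, end = window
        if end <= start:
            raise ValueError("empty window")
        traj = traj.slice(start, end)
    x, y, ok = traj.cleaned_xy(max_gap_s)
    zone_idx = np.full(len(traj), -1, dtype=np.int64)
    if np.any(ok):
        zone_idx[ok] = partition.classify(x[ok], y[ok])
    steps = step_lengths(traj, max_gap_s)
    out: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(partition.zone_names):
        frames = zone_idx == k
        t_zone = float(np.sum(frames)) * traj.dt
        d_zone = float(np.sum(steps[frames[:-1]])) if len(traj) > 1 else 0.0
        out[name] = (t_zone, d_zone)
    return out


def segment_epochs(traj: Trajectory, schedule: LightSchedule) -> dict[str, Trajectory]:
    """Slice a trajectory into the schedule's labelled epochs.

    Membership is ``start <= t < end`` (final epoch closed at its end), so
    the slices are disjoint and jointly cover the scheduled span.
    """
    if schedule.duration > traj.duration + traj.dt + 1e-9:
        raise ValueError(
            f"schedule ({schedule.duration:.0f}s) longer than recording "
            f"({traj.duration:.0f}s)"
        )
    out: dict[str, Trajectory] = {}
    for i, e in enumerate(schedule.epochs):
        last = i == len(schedule.epochs) - 1
        out[e.label] = traj.slice(e.start_s, e.end_s, include_end=last)
    return out
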