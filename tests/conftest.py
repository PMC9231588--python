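"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own geometry/accumulation
code paths: zone membership is recomputed analytically per partition
shape, and distances/dwell times by explicit per-frame Python loops.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from zebrabehave.core import Arena, Trajectory


@pytest.fixture
def square_arena() -> Arena:
    return Arena("rectangle", (300.0, 300.0), "tank")


@pytest.fixture
def circle_arena() -> Arena:
    return Arena("circle", (22.1,), "well")


def make_random_trajectory(
    arena: Arena,
    duration_s: float = 60.0,
    fps: float = 25.0,
    seed: int = 0,
    step_mm: float = 2.0,
    genotype: str = "WT",
    fish_id: str = "f0",
) -> Trajectory:
    """Clipped random walk inside the arena (not the package simulator)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps)) + 1
    xmin, ymin, xmax, ymax = arena.bounds()
    x = np.empty(n)
    y = np.empty(n)
    if arena.shape == "rectangle":
        x[0] = rng.uniform(xmin, xmax)
        y[0] = rng.uniform(ymin, ymax)
    else:
        (d,) = arena.dims
        rr = 0.9 * d / 2.0 * math.sqrt(rng.uniform())
        aa = rng.uniform(0, 2 * math.pi)
        x[0], y[0] = rr * math.cos(aa), rr * math.sin(aa)
    steps = rng.normal(0.0, step_mm, size=(n - 1, 2))
    for i in range(1, n):
        px, py = x[i - 1] + steps[i - 1, 0], y[i - 1] + steps[i - 1, 1]
        if arena.shape == "rectangle":
            px = min(max(px, xmin), xmax)
            py = min(max(py, ymin), ymax)
        else:
            (d,) = arena.dims
            r = math.hypot(px, py)
            if r > d / 2.0:
                px *= (d / 2.0) / r
                py *= (d / 2.0) / r
        x[i], y[i] = px, py
    t = np.arange(n) / fps
    return Trajectory(fish_id, genotype, t, x, y, fps=fps, arena_id=arena.arena_id)


# ---------------------------------------------------------------------------
# analytic zone-membership oracles (independent of shapely)
# ---------------------------------------------------------------------------

def oracle_center_membership(arena: Arena, x: float, y: float) -> bool:
    """Equal-area concentric central zone, computed analytically."""
    if arena.shape == "rectangle":
        w, h = arena.dims
        cw, ch = w / math.sqrt(2.0), h / math.sqrt(2.0)
        return (
            (w - cw) / 2.0 <= x <= (w + cw) / 2.0
            and (h - ch) / 2.0 <= y <= (h + ch) / 2.0
        )
    (d,) = arena.dims
    return math.hypot(x, y) <= d / 2.0 / math.sqrt(2.0)


def oracle_juvenile_sector(arena: Arena, x: float, y: float) -> str:
    """'conspecific' / 'empty' / '' for the +y juvenile quarter-zone bands."""
    (d,) = arena.dims
    r = d / 2.0
    if math.hypot(x, y) > r:
        raise ValueError("outside well")
    if y >= r / 2.0:
        return "conspecific"
    if y <= -r / 2.0:
        return "empty"
    return ""


def oracle_adult_sector(arena: Arena, x: float, y: float) -> str:
    """'conspecific' (+x half) or 'empty' for the adult sector split."""
    w, _ = arena.dims
    return "conspecific" if x >= w / 2.0 else "empty"


def loop_path_length(traj: Trajectory) -> float:
    total = 0.0
    for i in range(1, len(traj)):
        total += math.hypot(traj.x[i] - traj.x[i - 1], traj.y[i] - traj.y[i - 1])
    return total


def loop_binned_distance(traj: Trajectory, bin_s: float) -> np.ndarray:
    """Frame-by-frame accumulation into bins (fully valid trajectories)."""
    t0 = traj.t[0]
    span = traj.t[-1] - t0 + 1.0 / traj.fps
    n_bins = int(math.floor(span / bin_s + 1e-9))
    out = np.zeros(n_bins)
    for i in range(1, len(traj)):
        b = int(math.floor((traj.t[i - 1] - t0) / bin_s + 1e-9))
        if 0 <= b < n_bins:
            out[b] += math.hypot(traj.x[i] - traj.x[i - 1], traj.y[i] - traj.y[i - 1])
    return out


def loop_mean_iid(xs: np.ndarray, ys: np.ndarray) -> float:
    """Brute-force double loop over pairs and frames; xs/ys (n_fish, n_frames)."""
    n, m = xs.shape
    per_frame = []
    for f in range(m):
        acc = 0.0
        cnt = 0
        for i in range(n):
            for j in range(i + 1, n):
                acc += math.hypot(xs[i, f] - xs[j, f], ys[i, f] - ys[j, f])
                cnt += 1
        per_frame.append(acc / cnt)
    return float(np.mean(per_frame))
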