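"""Seeded generators of behavioral and physiological raw data.

These emulate the inputs the phenotype metrics consume: a wall-attracted
correlated random walk for the open field, Bernoulli corner-visit streams
with saturating learning for the IntelliCage, Markov arm sequences for the
Y-maze, and exponentially decaying calcium transients on a shared background
drift.  They are agent/noise models for exercising the metrics, not fitted
models of real animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "VisitLog",
    "CalciumRecording",
    "simulate_open_field",
    "simulate_intellicage",
    "simulate_ymaze",
    "simulate_calcium",
]


@dataclass
class Trajectory:
    """Body-center positions at a constant sampling interval (s, cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(dtype=float)
        return cls(t=t, x=df["x_cm"].to_numpy(dtype=float), y=df["y_cm"].to_numpy(dtype=float),
                   dt=float(np.median(np.diff(t))))


@dataclass
class VisitLog:
    """Timestamped corner visits with correctness and poke/lick counts."""

    data: pd.DataFrame  # timestamp, corner_id, correct, n_nosepokes, n_licks

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VisitLog":
        return cls(pd.read_csv(path))


def simulate_open_field(
    duration_s: float = 600.0,
    dt: float = 0.1,
    speed: float = 10.0,
    wall_attraction: float = 0.0,
    arena: tuple[float, float] = (50.0, 50.0),
    *,
    turn_sd: float = 0.6,
    seed: int = 0,
) -> Trajectory:
    """Reflected correlated random walk in a rectangular arena.

    Each step the heading is the direction of a blend
    ``(1 - w) * persistence + w * toward-nearest-wall`` plus Gaussian turn
    noise (sd ``turn_sd`` rad); ``w = wall_attraction`` in [0, 1].  Steps of
    ``speed * dt`` cm are reflected off the walls and clipped to the arena.
    ``speed = 0`` leaves the agent at its start point.  Deterministic for a
    fixed seed.
    """
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration_s and dt must be positive")
    if not (0.0 <= wall_attraction <= 1.0):
        raise ValueError("wall_attraction must lie in [0, 1]")
    width, height = arena
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([rng.uniform(0, width), rng.uniform(0, height)])
    theta = rng.uniform(0, 2 * np.pi)
    x[0], y[0] = pos
    step = speed * dt
    for i in range(1, n):
        # unit vector toward the nearest wall point
        dists = np.array([pos[0], width - pos[0], pos[1], height - pos[1]])
        nearest = int(np.argmin(dists))
        u_wall = {
            0: np.array([-1.0, 0.0]),
            1: np.array([1.0, 0.0]),
            2: np.array([0.0, -1.0]),
            3: np.array([0.0, 1.0]),
        }[nearest]
        u_persist = np.array([np.cos(theta), np.sin(theta)])
        blend = (1 - wall_attraction) * u_persist + wall_attraction * u_wall
        if np.allclose(blend, 0):
            blend = u_persist
        theta = np.arctan2(blend[1], blend[0]) + rng.normal(0, turn_sd)
        pos = pos + step * np.array([np.cos(theta), np.sin(theta)])
        # reflect off walls
        for k, hi in ((0, width), (1, height)):
            if pos[k] < 0:
                pos[k] = -pos[k]
            if pos[k] > hi:
                pos[k] = 2 * hi - pos[k]
        pos[0] = np.clip(pos[0], 0, width)
        pos[1] = np.clip(pos[1], 0, height)
        x[i], y[i] = pos
    return Trajectory(t=t, x=x, y=y, dt=dt)


def simulate_intellicage(
    n_visits: int,
    p0: float = 0.25,
    learning_rate: float = 0.0,
    *,
    ceiling: float = 0.9,
    mean_interval_s: float = 120.0,
    seed: int = 0,
) -> VisitLog:
    """Corner-visit stream with success probability saturating toward a ceiling.

    Visit k (0-based) is correct with probability
    ``ceiling - (ceiling - p0) * exp(-learning_rate * k)`` — a saturating
    learning curve that starts at chance ``p0`` and approaches ``ceiling``;
    ``learning_rate = 0`` gives a stationary Bernoulli(p0) stream.  Incorrect
    visits go to one of the three other corners uniformly.  Inter-visit
    times are exponential with the given mean.
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    rng = np.random.default_rng(seed)
    assigned = int(rng.integers(1, 5))
    k = np.arange(n_visits)
    p = ceiling - (ceiling - p0) * np.exp(-learning_rate * k)
    correct = rng.random(n_visits) < p
    others = [c for c in (1, 2, 3, 4) if c != assigned]
    corners = np.where(correct, assigned, rng.choice(others, size=n_visits))
    timestamps = np.cumsum(rng.exponential(mean_interval_s, size=n_visits))
    data = pd.DataFrame(
        {
            "timestamp": timestamps,
            "corner_id": corners,
            "correct": correct,
            "n_nosepokes": 1 + rng.poisson(2.0, size=n_visits),
            "n_licks": rng.poisson(5.0, size=n_visits),
        }
    )
    return VisitLog(data)


def simulate_ymaze(
    n_visits: int,
    alternation_prob: float = 0.7,
    *,
    mean_interval_s: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Markov arm-visit sequence over arms A/B/C with timestamps.

    After the first two (distinct, random) visits, each step chooses the arm
    not among the last two with probability ``alternation_prob``, otherwise
    returns to the next-to-last arm.  Probability 1 gives perfect
    alternation (100 %), probability 0 gives none (0 %).
    """
    if not (0.0 <= alternation_prob <= 1.0):
        raise ValueError("alternation_prob must lie in [0, 1]")
    if n_visits < 2:
        raise ValueError("need at least two visits")
    rng = np.random.default_rng(seed)
    arms = ["A", "B", "C"]
    first, second = rng.choice(3, size=2, replace=False)
    seq = [arms[first], arms[second]]
    for _ in range(n_visits - 2):
        novel = next(a for a in arms if a not in seq[-2:])
        back = seq[-2]
        seq.append(novel if rng.random() < alternation_prob else back)
    timestamps = np.cumsum(rng.exponential(mean_interval_s, size=n_visits))
    return pd.DataFrame({"timestamp": timestamps, "arm": seq})


@dataclass
class CalciumRecording:
    """Cell traces plus the five shared-background ROI traces."""

    t: np.ndarray
    cells: np.ndarray  # (n_cells, n_frames)
    background: np.ndarray  # (5, n_frames)
    stim_frame: int

    def to_csv(self, path) -> None:
        cols = {"t_s": self.t}
        for i in range(self.cells.shape[0]):
            cols[f"cell{i + 1}"] = self.cells[i]
        for i in range(self.background.shape[0]):
            cols[f"bg{i + 1}"] = self.background[i]
        pd.DataFrame(cols).to_csv(path, index=False)


def simulate_calcium(
    n_cells: int = 15,
    *,
    n_frames: int = 120,
    dt: float = 1.0,
    baseline: float = 100.0,
    amplitude: float = 50.0,
    decay_tau: float = 10.0,
    noise_sd: float = 1.0,
    drift_amplitude: float = 5.0,
    stim_frame: int = 30,
    seed: int = 0,
) -> CalciumRecording:
    """Calcium traces: shared slow drift + exponential post-stimulus transient.

    Every cell trace is ``baseline_c + drift(t) + amplitude * exp(-(t -
    t_stim)/tau)`` after the stimulus plus Gaussian noise; the five
    background ROI traces carry the same drift term (so background
    subtraction removes it exactly in the noise-free case).
    """
    if not (0 <= stim_frame < n_frames):
        raise ValueError("stim_frame must lie within the trace")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    drift = drift_amplitude * np.sin(2 * np.pi * t / (n_frames * dt))
    transient = np.where(
        t >= t[stim_frame], amplitude * np.exp(-(t - t[stim_frame]) / decay_tau), 0.0
    )
    cell_baselines = baseline * (1 + 0.1 * rng.standard_normal(n_cells))
    cells = (
        cell_baselines[:, None]
        + drift[None, :]
        + transient[None, :]
        + noise_sd * rng.standard_normal((n_cells, n_frames))
    )
    bg_levels = 0.2 * baseline * (1 + 0.05 * rng.standard_normal(5))
    background = bg_levels[:, None] + drift[None, :]
    return CalciumRecording(t=t, cells=cells, background=background, stim_frame=stim_frame)
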