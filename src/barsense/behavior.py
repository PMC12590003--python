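"""Behavioral and physiological phenotype metrics.

Implements the explicitly defined readouts of the phenotyping battery:

* **Open field zone occupancy** — time, distance and entries in three 5-cm
  concentric wall strips (strip 1 = periphery, the thigmotaxis zone), the
  20 x 20 cm center, and the four 10 x 10 cm corners of a 50 x 50 cm arena,
  scored from the body-center trajectory.
* **Weighted preference score** — (choicesA*pA - choicesB*pB) /
  (choicesA*pA + choicesB*pB), in [-1, 1]; used for place preference,
  sucrose preference and nocturnality alike.
* **Spontaneous alternation** — percent of Y-maze triads whose three arms
  are all distinct, out of visits - 2, after entry/exit hysteresis
  (enter at 85 % body area, exit below 75 %).
* **SPRT learning time** — cumulative Bernoulli sequential probability
  ratio test declaring "learned" when performance exceeds chance (p0) by a
  margin (10 percentage points) at 5 % significance.
* **Calcium ΔF** — background-corrected fluorescence change,
  ΔF = F_corr - F_baseline with F_corr = F_cell - mean of the five
  background ROIs and F_baseline the pre-stimulus mean of F_corr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArenaSpec",
    "ZoneMetrics",
    "SPRTConfig",
    "SPRTResult",
    "CalciumTrace",
    "BehaviorError",
    "classify_zones",
    "zone_metrics",
    "preference_score",
    "spontaneous_alternation",
    "entry_exit_hysteresis",
    "sprt_learning_time",
    "delta_f",
    "ZONES",
]

ZONES = ("strip1", "strip2", "strip3", "interior", "center", "corners")
#: The strips plus interior partition the arena; center and corners overlap
#: the strips and are reported independently.
PARTITION_ZONES = ("strip1", "strip2", "strip3", "interior")


class BehaviorError(ValueError):
    pass


@dataclass
class ArenaSpec:
    """Open-field arena geometry (cm).

    Three concentric wall strips of ``strip_width``, a centered
    ``center_size`` square, and four ``corner_size`` corner squares.
    Boundary ties resolve to the more peripheral zone (closed outer
    boundaries), matching the thigmotaxis emphasis of the readout.
    """

    width: float = 50.0
    height: float = 50.0
    strip_width: float = 5.0
    center_size: float = 20.0
    corner_size: float = 10.0

    def __post_init__(self) -> None:
        if 3 * self.strip_width >= min(self.width, self.height) / 2:
            raise BehaviorError("three strips must fit inside half the arena")
        if self.center_size > min(self.width, self.height) - 6 * self.strip_width:
            raise BehaviorError("center square must fit inside the innermost region")


@dataclass
class ZoneMetrics:
    """Per-zone time, time fraction, distance and entry counts."""

    time_s: dict[str, float]
    time_fraction: dict[str, float]
    distance_cm: dict[str, float]
    entries: dict[str, int]
    total_time_s: float
    total_distance_cm: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "time_fraction": self.time_fraction,
                "distance_cm": self.distance_cm,
                "entries": self.entries,
            }
        ).rename_axis("zone")


def classify_zones(x: np.ndarray, y: np.ndarray, arena: ArenaSpec) -> dict[str, np.ndarray]:
    """Boolean membership of each frame in each zone.

    Strips are classified by distance to the nearest wall ``d``:
    strip1: d <= w, strip2: w < d <= 2w, strip3: 2w < d <= 3w, interior:
    d > 3w (ties go outward).  The center square is open (strictly inside)
    and the corner squares are closed, again resolving boundaries
    peripherally.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (x > arena.width).any() or (y < 0).any() or (y > arena.height).any():
        raise BehaviorError("trajectory frame outside arena bounds; pre-clip real data explicitly")
    d = np.minimum.reduce([x, arena.width - x, y, arena.height - y])
    w = arena.strip_width
    half = arena.center_size / 2.0
    cx, cy = arena.width / 2.0, arena.height / 2.0
    cs = arena.corner_size
    return {
        "strip1": d <= w,
        "strip2": (d > w) & (d <= 2 * w),
        "strip3": (d > 2 * w) & (d <= 3 * w),
        "interior": d > 3 * w,
        "center": (np.abs(x - cx) < half) & (np.abs(y - cy) < half),
        "corners": ((x <= cs) | (x >= arena.width - cs)) & ((y <= cs) | (y >= arena.height - cs)),
    }


def zone_metrics(traj, arena: ArenaSpec | None = None) -> ZoneMetrics:
    """Score a body-center trajectory against the arena zones.

    ``traj`` is anything with ``t``, ``x``, ``y`` attributes or columns
    (seconds and cm).  Time in zone is the sum of frame intervals whose
    frame lies in the zone; each path segment's distance goes to the zone of
    its starting frame; an entry is an outside-to-inside transition (initial
    presence counts as the first entry).
    """
    if arena is None:
        arena = ArenaSpec()
    t, x, y = (_column(traj, c) for c in ("t", "x", "y"))
    if len(t) < 2:
        raise BehaviorError("trajectory needs >= 2 frames")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise BehaviorError("timestamps must be strictly increasing")
    # each frame owns the interval that follows it; the last frame owns the
    # median interval so total time matches duration for uniform sampling
    frame_dt = np.append(dt, np.median(dt))
    seg_len = np.hypot(np.diff(x), np.diff(y))
    member = classify_zones(x, y, arena)

    total_time = float(frame_dt.sum())
    time_s, frac, dist, entries = {}, {}, {}, {}
    for zone in ZONES:
        m = member[zone]
        time_s[zone] = float(frame_dt[m].sum())
        frac[zone] = time_s[zone] / total_time
        dist[zone] = float(seg_len[m[:-1]].sum())
        inside = m.astype(int)
        entries[zone] = int(inside[0] + (np.diff(inside) == 1).sum())
    return ZoneMetrics(
        time_s=time_s,
        time_fraction=frac,
        distance_cm=dist,
        entries=entries,
        total_time_s=total_time,
        total_distance_cm=float(seg_len.sum()),
    )


def _column(obj, name: str) -> np.ndarray:
    if hasattr(obj, name):
        return np.asarray(getattr(obj, name), dtype=float)
    if isinstance(obj, pd.DataFrame):
        for cand in (name, f"{name}_s", f"{name}_cm"):
            if cand in obj.columns:
                return obj[cand].to_numpy(dtype=float)
    raise BehaviorError(f"trajectory lacks a {name!r} field")


def preference_score(
    choices_a: float,
    choices_b: float,
    probability_a: float = 0.5,
    probability_b: float = 0.5,
) -> float:
    """Weighted preference score in [-1, 1].

    (choicesA*pA - choicesB*pB) / (choicesA*pA + choicesB*pB), where the
    probabilities are the chance weights of the two options (e.g. 0.5/0.5
    for two bottles, day/night duration fractions for nocturnality).
    """
    if choices_a < 0 or choices_b < 0:
        raise BehaviorError("choice counts must be non-negative")
    if choices_a + choices_b == 0:
        raise BehaviorError("undefined preference score: both choice counts are zero")
    for p in (probability_a, probability_b):
        if not (0 < p <= 1):
            raise BehaviorError(f"chance weight {p} outside (0, 1]")
    num = choices_a * probability_a - choices_b * probability_b
    den = choices_a * probability_a + choices_b * probability_b
    return num / den


def spontaneous_alternation(arms) -> float:
    """Percent of visit triads with three distinct arms, of visits - 2.

    Expects the arm-visit sequence after entry/exit hysteresis (so no
    consecutive duplicates in well-formed input); triads are the sliding
    windows (i, i+1, i+2).
    """
    arms = list(arms)
    if len(arms) < 3:
        raise BehaviorError("spontaneous alternation needs >= 3 visits")
    triads = len(arms) - 2
    alternations = sum(
        len({arms[i], arms[i + 1], arms[i + 2]}) == 3 for i in range(triads)
    )
    return 100.0 * alternations / triads


def entry_exit_hysteresis(
    fractions: pd.DataFrame,
    enter: float = 0.85,
    exit: float = 0.75,
) -> list[str]:
    """Segment per-arm body-area fractions into a visit sequence.

    ``fractions`` has one column per arm and one row per video sample, each
    value the fraction of the body area inside that arm.  The animal enters
    an arm when its fraction reaches ``enter`` while in no arm, and leaves
    when the current arm's fraction drops below ``exit`` — oscillation
    between the two thresholds neither ends the visit nor starts a new one.
    """
    if enter <= exit:
        raise BehaviorError(f"enter threshold ({enter}) must exceed exit threshold ({exit})")
    vals = fractions.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise BehaviorError("area fractions must lie in [0, 1]")
    arms = list(fractions.columns)
    visits: list[str] = []
    current: str | None = None
    for row in vals:
        if current is not None:
            if row[arms.index(current)] < exit:
                current = None
        if current is None:
            above = [a for a, v in zip(arms, row) if v >= enter]
            if above:
                current = max(above, key=lambda a: row[arms.index(a)])
                visits.append(current)
    return visits


@dataclass
class SPRTConfig:
    """Bernoulli SPRT configuration.

    H0: success probability = ``p0`` (chance, e.g. 0.25 for one of four
    corners); H1: p = p0 + ``delta``.  ``alpha`` is the significance level
    of the learning criterion; ``beta`` the symmetric type-II level.
    """

    p0: float = 0.25
    delta: float = 0.10
    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p0 < self.p0 + self.delta < 1):
            raise BehaviorError(f"need 0 < p0 < p0+delta < 1, got p0={self.p0}, delta={self.delta}")
        if not (0 < self.alpha < 0.5 and 0 < self.beta < 0.5):
            raise BehaviorError("alpha and beta must lie in (0, 0.5)")

    @property
    def upper_boundary(self) -> float:
        return math.log((1 - self.beta) / self.alpha)

    @property
    def lower_boundary(self) -> float:
        return math.log(self.beta / (1 - self.alpha))


@dataclass
class SPRTResult:
    learned: bool
    visit_index: int | None  # 1-based index of the crossing visit
    timestamp: float | None
    llr_trace: np.ndarray = field(repr=False)
    reason: str = ""  # 'crossed' | 'rejected' | 'exhausted'


def sprt_learning_time(log, cfg: SPRTConfig | None = None) -> SPRTResult:
    """Time to reach the learning criterion by cumulative SPRT.

    ``log`` is a DataFrame with ``correct`` (bool) and ``timestamp``
    columns (a visit log), or any boolean sequence (then timestamps are the
    1-based visit indices).  Each success adds ln(p1/p0) to the cumulative
    log-likelihood ratio and each failure ln((1-p1)/(1-p0)); the animal has
    learned at the first visit where the LLR reaches
    ln((1-beta)/alpha).  Crossing the lower boundary ln(beta/(1-alpha))
    stops the test as 'rejected'; running out of visits is 'exhausted' —
    both are censored outcomes.
    """
    if cfg is None:
        cfg = SPRTConfig()
    if isinstance(log, pd.DataFrame):
        correct = log["correct"].to_numpy(dtype=bool)
        ts = log["timestamp"].to_numpy(dtype=float)
    else:
        correct = np.asarray(list(log), dtype=bool)
        ts = np.arange(1, len(correct) + 1, dtype=float)
    if len(correct) == 0:
        raise BehaviorError("empty visit log")

    p1 = cfg.p0 + cfg.delta
    step_win = math.log(p1 / cfg.p0)
    step_loss = math.log((1 - p1) / (1 - cfg.p0))
    llr = np.cumsum(np.where(correct, step_win, step_loss))

    upper, lower = cfg.upper_boundary, cfg.lower_boundary
    for i, value in enumerate(llr):
        if value >= upper:
            return SPRTResult(True, i + 1, float(ts[i]), llr[: i + 1], "crossed")
        if value <= lower:
            return SPRTResult(False, i + 1, float(ts[i]), llr[: i + 1], "rejected")
    return SPRTResult(False, None, None, llr, "exhausted")


@dataclass
class CalciumTrace:
    """Background-corrected calcium response of one cell."""

    t: np.ndarray
    delta_f: np.ndarray
    f_corr: np.ndarray
    f_baseline: float
    peak_delta_f: float
    time_to_peak_s: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "delta_f": self.delta_f, "f_corr": self.f_corr})


def delta_f(
    f_cell: np.ndarray,
    f_background: np.ndarray,
    t: np.ndarray,
    baseline_window: tuple[int, int],
    stim_frame: int,
) -> CalciumTrace:
    """ΔF trace of one cell: background-subtract, then baseline-subtract.

    ``f_background`` is (n_rois, n_frames) — conventionally the five ROIs
    from the four corners and the middle of the field of view; their
    per-frame mean is subtracted from ``f_cell`` to give F_corr.
    ``baseline_window`` is a half-open frame range [start, stop) that must
    end at or before ``stim_frame``; F_baseline is the mean of F_corr over
    it and ΔF = F_corr - F_baseline.  Peak ΔF and time-to-peak (from the
    stimulus frame) are taken over the post-stimulus frames.
    """
    f_cell = np.asarray(f_cell, dtype=float)
    bg = np.atleast_2d(np.asarray(f_background, dtype=float))
    t = np.asarray(t, dtype=float)
    if bg.shape[1] != f_cell.shape[0]:
        raise BehaviorError(
            f"background traces have {bg.shape[1]} frames, cell trace has {f_cell.shape[0]}"
        )
    start, stop = baseline_window
    if not (0 <= start < stop):
        raise BehaviorError(f"empty or invalid baseline window {baseline_window}")
    if stop > stim_frame:
        raise BehaviorError("baseline window must end at or before the stimulus frame")
    if not (0 <= stim_frame < len(f_cell)):
        raise BehaviorError("stimulus frame outside the trace")

    f_corr = f_cell - bg.mean(axis=0)
    f_baseline = float(f_corr[start:stop].mean())
    df_trace = f_corr - f_baseline
    post = df_trace[stim_frame:]
    peak_idx = int(np.argmax(post))
    return CalciumTrace(
        t=t,
        delta_f=df_trace,
        f_corr=f_corr,
        f_baseline=f_baseline,
        peak_delta_f=float(post[peak_idx]),
        time_to_peak_s=float(t[stim_frame + peak_idx] - t[stim_frame]),
    )
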