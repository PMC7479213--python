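"""Morris swim-task proximity scoring: CIPL and the learning index.

CIPL (corrected integrated path length, also called cumulative search error)
is the time integral of the animal's distance to the escape platform over a
trial, minus the same integral for an ideal straight-line approach from the
release point at the animal's own mean swim speed. The correction makes
trials comparable across release locations and swim speeds; a direct
constant-speed swim scores 0, and any search detour adds positive area.
Units are metre-seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SwimTrial", "cipl", "learning_index", "day_means",
           "behavior_table", "load_trials", "save_trials"]


@dataclass
class SwimTrial:
    """One tracked swim trial.

    ``t`` (s), ``x``/``y`` (m) are the tracked samples; distances are
    measured to the platform edge (center distance minus platform radius,
    floored at 0) since escape occurs at the edge.
    """

    subject_id: str
    day: int
    trial: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    platform_center: tuple[float, float]
    platform_radius: float
    release_point: tuple[float, float]
    pool_radius: float
    escaped: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a trial needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        r = np.hypot(self.x, self.y)
        if np.any(r > self.pool_radius * (1 + 1e-9)):
            raise ValueError("path exits the pool boundary")

    def platform_distance(self) -> np.ndarray:
        """Distance to the platform *edge* at each sample (>= 0)."""
        d = np.hypot(self.x - self.platform_center[0],
                     self.y - self.platform_center[1])
        return np.maximum(d - self.platform_radius, 0.0)

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _ideal_integral(d0: float, speed: float, duration: float) -> float:
    """Integral of platform-edge distance for a straight approach at ``speed``.

    The distance falls linearly from ``d0`` to 0; if the animal did not move
    (speed 0) the integrand stays at ``d0`` for the whole trial, so the
    correction degenerates to ``d0 * duration``.
    """
    if d0 <= 0:
        return 0.0
    if speed <= 0:
        return d0 * duration
    t_star = min(d0 / speed, duration)
    # integral of (d0 - speed*t) from 0 to t_star, clamped at 0 afterwards
    return d0 * t_star - 0.5 * speed * t_star**2


def cipl(trial: SwimTrial) -> float:
    """Corrected integrated path length of one trial, in m*s.

    Trapezoidal integral of the distance to the platform edge over the
    recorded samples, minus the ideal straight-approach integral from the
    release point at the animal's mean speed; floored at 0.
    """
    d = trial.platform_distance()
    ipl = float(np.trapezoid(d, trial.t))
    duration = trial.duration()
    mean_speed = trial.path_length() / duration if duration > 0 else 0.0
    d0 = max(
        np.hypot(trial.release_point[0] - trial.platform_center[0],
                 trial.release_point[1] - trial.platform_center[1])
        - trial.platform_radius,
        0.0,
    )
    ideal = _ideal_integral(d0, mean_speed, duration)
    return max(ipl - ideal, 0.0)


def learning_index(day_mean_cipl: np.ndarray) -> float:
    """(Day1 - Day4) / (Day1 + Day4) from the per-day mean CIPLs.

    Normalized improvement over training: 0 means no learning, 1 maximal
    (day-4 performance perfect), negative values mean worsening. Defined for
    day1 + day4 > 0.
    """
    vals = np.asarray(day_mean_cipl, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least first-day and last-day means")
    d1, d4 = vals[0], vals[-1]
    if d1 + d4 <= 0:
        raise ValueError("learning index undefined: day1 + day4 must be > 0")
    return float((d1 - d4) / (d1 + d4))


def day_means(trials: list[SwimTrial], subject_id: str,
              n_days: int = 4) -> np.ndarray:
    """Arithmetic mean trial CIPL per day for one subject (NaN if no trials)."""
    means = np.full(n_days, np.nan)
    for day in range(1, n_days + 1):
        vals = [cipl(tr) for tr in trials
                if tr.subject_id == subject_id and tr.day == day]
        if vals:
            means[day - 1] = float(np.mean(vals))
        else:
            warnings.warn(
                f"subject {subject_id!r} has no trials on day {day}; "
                "mean left missing", stacklevel=2,
            )
    return means


def behavior_table(trials: list[SwimTrial], n_days: int = 4) -> pd.DataFrame:
    """Per-subject table of day-mean CIPLs and the learning index."""
    subjects = sorted({tr.subject_id for tr in trials})
    rows = []
    for sid in subjects:
        means = day_means(trials, sid, n_days=n_days)
        row = {"subject_id": sid}
        row.update({f"day{d}_cipl": means[d - 1] for d in range(1, n_days + 1)})
        row["learning_index"] = learning_index(means)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text persistence: tracking CSV + pool-geometry JSON sidecar

def save_trials(trials: list[SwimTrial], csv_path: str | Path,
                geometry_path: str | Path) -> None:
    frames = []
    geom: dict[str, dict] = {}
    for tr in trials:
        frames.append(pd.DataFrame({
            "subject_id": tr.subject_id, "day": tr.day, "trial": tr.trial,
            "t": tr.t, "x": tr.x, "y": tr.y,
        }))
        geom[f"{tr.subject_id}/{tr.day}/{tr.trial}"] = {
            "platform_center": list(tr.platform_center),
            "platform_radius": tr.platform_radius,
            "release_point": list(tr.release_point),
            "pool_radius": tr.pool_radius,
            "escaped": tr.escaped,
        }
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    Path(geometry_path).write_text(json.dumps(geom, indent=1))


def load_trials(csv_path: str | Path, geometry_path: str | Path) -> list[SwimTrial]:
    table = pd.read_csv(csv_path, dtype={"subject_id": str})
    geom = json.loads(Path(geometry_path).read_text())
    trials = []
    for (sid, day, trial), grp in table.groupby(
            ["subject_id", "day", "trial"], sort=True):
        g = geom[f"{sid}/{day}/{trial}"]
        grp = grp.sort_values("t")
        trials.append(SwimTrial(
            subject_id=str(sid), day=int(day), trial=int(trial),
            t=grp["t"].to_numpy(), x=grp["x"].to_numpy(), y=grp["y"].to_numpy(),
            platform_center=tuple(g["platform_center"]),
            platform_radius=g["platform_radius"],
            release_point=tuple(g["release_point"]),
            pool_radius=g["pool_radius"], escaped=g["escaped"],
        ))
    return trials
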