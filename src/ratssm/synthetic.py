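"""Synthetic imaging + behavior cohorts with the covariance structure the
analysis pipeline assumes.

The imaging generator writes a signed spatial pattern into log gray matter:

    gm_sv = baseline * scale_s * exp(score_s * pattern_v + noise_sv)

so the log transform and double centering of the SSM recover exactly a
rank-one signal (score outer pattern) plus noise, and per-subject global
scaling is removed by construction. The pattern consists of axis-aligned
cubic blocks, two negative (age-reduced) and two positive (age-increased),
each comfortably above the 50-voxel cluster extent used downstream. Subject
scores are Gaussian with group means separated by ``pattern_effect`` (the
per-voxel log difference between groups inside pattern blocks, since block
amplitude is +-1).

The behavior generator emits Morris swim-task tracking paths: each trial is
a circling search phase around the pool followed by a straight approach to
the platform, with the circling time calibrated per (subject, day) so that
trial CIPL matches a target schedule. Targets decay geometrically over days
to a per-subject learning index that is linear in a latent ability, and the
ability is constructed (by in-sample orthogonalization) to correlate with
the subject's true pattern expression at exactly ``behavior_coupling``.
Aged subjects' CIPL targets are inflated by ``1 + behavior_age_deficit``;
this multiplicative deficit shifts performance levels without biasing the
learning index, so the ability-expression coupling stays interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import SwimTrial, behavior_table, save_trials
from .data import GrayMatterStack, save_volume

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort",
           "generate_swim_paths", "make_true_pattern", "write_cohort"]

# pool geometry (m) and trial protocol constants
POOL_RADIUS = 0.9
PLATFORM_RADIUS = 0.06
PLATFORM_POLAR = (0.45, 1.25 * np.pi)     # radius (m), angle of the platform
RELEASE_RADIUS_FRAC = 0.8
RELEASE_ANGLES = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi)
SWIM_SPEED = 0.25                          # m/s
TRIAL_TIMEOUT = 60.0                       # s
SAMPLE_DT = 0.25                           # s

# behavior target schedule (m*s) and learning-index distribution
DAY1_CIPL = 18.0
LI_MEAN, LI_SD = 0.45, 0.15
VISUAL_DAY_MEANS = (2.0, 1.2)              # visual-task CIPL means, days 1-2
ETIV_MEAN_MM3 = 2000.0


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the design the pipeline targets: 10 young + 10 aged
    subjects, a 32x32x24 grid of 150-um voxels, four days of six swim trials,
    a bidirectional gray-matter pattern whose per-voxel group log-difference
    (``pattern_effect``) is five times the voxel noise, and a -0.5 coupling
    between pattern expression and the learning index.
    """

    seed: int = 0
    n_young: int = 10
    n_aged: int = 10
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_um: tuple[float, float, float] = (150.0, 150.0, 150.0)
    baseline_gm: float = 0.5
    subject_scale_sd: float = 0.1
    pattern_effect: float = 0.1
    score_sd: float = 0.02       # within-group spread of pattern expression
    noise_sd: float = 0.02
    n_days: int = 4
    trials_per_day: int = 6
    behavior_age_deficit: float = 0.5
    behavior_coupling: float = -0.5

    def __post_init__(self) -> None:
        if isinstance(self.voxel_size_um, (int, float)):
            self.voxel_size_um = (float(self.voxel_size_um),) * 3
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.n_young < 1 or self.n_aged < 1:
            raise ValueError("need at least one subject per group")
        if any(g < 1 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if int(np.prod(self.grid_shape)) < 500:
            raise ValueError("grid volume must be >= 10x the 50-voxel extent "
                             "threshold used downstream")
        if self.baseline_gm <= 0 or self.subject_scale_sd <= 0:
            raise ValueError("baseline_gm and subject_scale_sd must be positive")
        if self.noise_sd < 0 or self.score_sd < 0:
            raise ValueError("noise_sd and score_sd must be non-negative")
        if self.n_days < 1 or self.trials_per_day < 1:
            raise ValueError("n_days and trials_per_day must be >= 1")
        if self.behavior_age_deficit < 0:
            raise ValueError("behavior_age_deficit must be >= 0")
        if not -1.0 <= self.behavior_coupling <= 1.0:
            raise ValueError("behavior_coupling must be in [-1, 1]")


@dataclass
class GroundTruth:
    """What the generator actually embedded, for recovery checks."""

    true_pattern: np.ndarray          # signed 3D volume (+- block amplitude 1)
    true_scores: np.ndarray           # per-subject pattern expression
    true_learning_index: np.ndarray   # per-subject target learning index
    mask: np.ndarray = field(repr=False, default=None)  # type: ignore

    def masked_pattern(self) -> np.ndarray:
        return self.true_pattern[self.mask]


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0 - 2.0, 1.0) for s in shape]
    idx = np.indices(shape)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def make_true_pattern(shape: tuple[int, int, int],
                      mask: np.ndarray) -> np.ndarray:
    """Signed block pattern: two -1 cubes and two +1 cubes inside the mask.

    Each block is 7 voxels on edge (343 voxels); at least 60 voxels of every
    block must fall inside the mask so that the blocks remain above the
    downstream cluster extent threshold.
    """
    edge = 7
    cx, cy, cz = [(s - 1) / 2.0 for s in shape]
    dx = max(int(round(shape[0] * 0.19)), edge)
    dy = max(int(round(shape[1] * 0.19)), edge)
    pattern = np.zeros(shape)

    def block(center: tuple[float, float, float], value: float) -> None:
        sl = tuple(
            slice(max(int(np.floor(c - edge / 2)), 0),
                  min(int(np.floor(c - edge / 2)) + edge, s))
            for c, s in zip(center, shape)
        )
        pattern[sl] = value

    block((cx - dx, cy, cz), -1.0)
    block((cx, cy - dy, cz), -1.0)
    block((cx + dx, cy, cz), +1.0)
    block((cx, cy + dy, cz), +1.0)
    pattern[~mask] = 0.0
    for sign in (-1.0, 1.0):
        n_in = int((pattern == sign).sum())
        if n_in < 2 * 60:
            raise ValueError(
                f"grid too small: only {n_in} in-mask voxels of sign {sign:+.0f} "
                "(each block needs >= 60)"
            )
    return pattern


def _true_scores(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    mu = np.concatenate([
        np.full(config.n_young, -config.pattern_effect / 2.0),
        np.full(config.n_aged, +config.pattern_effect / 2.0),
    ])
    return mu + rng.normal(0.0, config.score_sd, size=len(mu))


def _ability(config: CohortConfig, true_scores: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Latent learning ability with exact in-sample corr to true scores."""
    n = len(true_scores)
    eta = rng.normal(size=n)
    z = true_scores - true_scores.mean()
    rho = config.behavior_coupling
    if np.linalg.norm(z) < 1e-12 or n < 3:
        out = eta - eta.mean()
        return out / max(np.linalg.norm(out), 1e-12) * np.sqrt(n)
    z = z / np.linalg.norm(z)
    eta = eta - eta.mean()
    eta = eta - (eta @ z) * z
    eta = eta / max(np.linalg.norm(eta), 1e-12)
    out = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * eta
    return out * np.sqrt(n)   # unit-variance scaling


def generate_cohort(
    config: CohortConfig,
    include_behavior: bool = True,
) -> tuple[GrayMatterStack, pd.DataFrame | None, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns ``(stack, behavior, subjects, truth)`` where ``behavior`` is the
    per-subject day-mean CIPL / learning-index table (None when
    ``include_behavior`` is False, which skips the comparatively slow swim
    path synthesis for imaging-only simulations).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    mask = _ellipsoid_mask(shape)
    pattern = make_true_pattern(shape, mask)
    p_masked = pattern[mask]

    n = config.n_young + config.n_aged
    groups = ["young"] * config.n_young + ["aged"] * config.n_aged
    subject_ids = [f"{g[0].upper()}{i + 1:02d}" for i, g in enumerate(groups)]
    scores = _true_scores(config, rng)
    scales = np.exp(rng.normal(0.0, config.subject_scale_sd, size=n))
    noise = rng.normal(0.0, config.noise_sd, size=(n, int(mask.sum())))

    log_gm = (np.log(config.baseline_gm) + np.log(scales)[:, None]
              + np.outer(scores, p_masked) + noise)
    data = np.exp(log_gm)
    if np.any(data <= 0) or not np.all(np.isfinite(data)):
        raise ValueError("generated gray matter is not strictly positive and "
                         "finite; config parameters are out of range")

    ability = _ability(config, scores, rng)
    li = np.clip(LI_MEAN + LI_SD * ability, 0.02, 0.90)

    ages = np.concatenate([
        rng.uniform(9.6, 11.7, size=config.n_young),
        rng.uniform(24.1, 26.2, size=config.n_aged),
    ])
    etiv = ETIV_MEAN_MM3 * np.exp(rng.normal(0.0, 0.05, size=n))
    aged = np.array([g == "aged" for g in groups], dtype=float)
    visual = np.empty((n, 2))
    for d, base in enumerate(VISUAL_DAY_MEANS):
        visual[:, d] = (base * (1.0 + 0.4 * config.behavior_age_deficit * aged)
                        * np.exp(rng.normal(0.0, 0.2, size=n)))

    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "age_months": np.round(ages, 2),
        "etiv": np.round(etiv, 2),
        "visual_day1": np.round(visual[:, 0], 4),
        "visual_day2": np.round(visual[:, 1], 4),
    })

    stack = GrayMatterStack(
        data=data, mask=mask, voxel_size_um=config.voxel_size_um,
        subject_ids=subject_ids, group_labels=groups,
    )
    truth = GroundTruth(true_pattern=pattern, true_scores=scores,
                        true_learning_index=li, mask=mask)

    behavior = None
    if include_behavior:
        trials = generate_swim_paths(
            config, subject_effects={
                "subject_ids": subject_ids, "groups": groups,
                "learning_index": li,
            },
            rng=rng,
        )
        behavior = behavior_table(trials, n_days=config.n_days)
        # behavior_table sorts by subject_id; restore cohort row order
        behavior = (behavior.set_index("subject_id")
                    .loc[subject_ids].reset_index())
        behavior.attrs["trials"] = trials
    return stack, behavior, subjects, truth


# ---------------------------------------------------------------------------
# swim-path synthesis

def _build_path(t_circle: float, release_angle: float, speed: float,
                wobble: tuple[float, float, float]) -> SwimTrial | dict:
    """Construct one trial path: circling phase then straight approach."""
    r0 = RELEASE_RADIUS_FRAC * POOL_RADIUS
    release = (r0 * np.cos(release_angle), r0 * np.sin(release_angle))
    pr, pa = PLATFORM_POLAR
    platform = (pr * np.cos(pa), pr * np.sin(pa))

    amp, freq, phase = wobble
    omega = speed / r0

    # circling phase samples
    tc = np.arange(0.0, t_circle, SAMPLE_DT)
    if len(tc) == 0 or tc[-1] < t_circle - 1e-9:
        tc = np.append(tc, t_circle)
    radius = r0 + amp * np.sin(2 * np.pi * freq * tc + phase)
    theta = release_angle + omega * tc
    xs = radius * np.cos(theta)
    ys = radius * np.sin(theta)

    # straight approach from the last circling position to the platform edge
    q = np.array([xs[-1], ys[-1]])
    vec = np.array(platform) - q
    dist = np.linalg.norm(vec)
    travel = max(dist - 0.5 * PLATFORM_RADIUS, 0.0)
    t_app = travel / speed
    ta = np.arange(SAMPLE_DT, t_app, SAMPLE_DT)
    if t_app > 0 and (len(ta) == 0 or ta[-1] < t_app - 1e-9):
        ta = np.append(ta, t_app)
    frac = (ta * speed) / max(dist, 1e-12)
    xa = q[0] + frac * vec[0]
    ya = q[1] + frac * vec[1]

    t = np.concatenate([tc, t_circle + ta])
    x = np.concatenate([xs, xa])
    y = np.concatenate([ys, ya])

    escaped = True
    if t[-1] > TRIAL_TIMEOUT:
        keep = t <= TRIAL_TIMEOUT
        t, x, y = t[keep], x[keep], y[keep]
        escaped = False
        if len(t) < 2:  # pathological: timeout shorter than two samples
            raise ValueError("trial timeout too short for the sampling rate")
    return {
        "t": t, "x": x, "y": y, "release": release, "platform": platform,
        "escaped": escaped,
    }


def _trial_cipl(path: dict) -> float:
    from .behavior import cipl
    trial = SwimTrial(
        subject_id="_", day=1, trial=1, t=path["t"], x=path["x"], y=path["y"],
        platform_center=path["platform"], platform_radius=PLATFORM_RADIUS,
        release_point=path["release"], pool_radius=POOL_RADIUS,
    )
    return cipl(trial)


def _solve_circle_time(target: float, release_angle: float, speed: float,
                       wobble: tuple[float, float, float]) -> dict:
    """Bisect the circling time so the trial CIPL hits ``target``."""
    t_max = max(TRIAL_TIMEOUT - (RELEASE_RADIUS_FRAC * POOL_RADIUS
                                 + PLATFORM_POLAR[0]) / speed, 0.0)
    lo, hi = 0.0, t_max
    p_lo = _build_path(lo, release_angle, speed, wobble)
    if _trial_cipl(p_lo) >= target:
        return p_lo
    p_hi = _build_path(hi, release_angle, speed, wobble)
    if _trial_cipl(p_hi) <= target:
        return p_hi
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        p_mid = _build_path(mid, release_angle, speed, wobble)
        if _trial_cipl(p_mid) < target:
            lo = mid
        else:
            hi = mid
    return _build_path(0.5 * (lo + hi), release_angle, speed, wobble)


def generate_swim_paths(
    config: CohortConfig,
    subject_effects: dict,
    rng: np.random.Generator | None = None,
) -> list[SwimTrial]:
    """Generate tracked swim trials for every subject, day and trial.

    ``subject_effects`` carries ``subject_ids``, ``groups`` and the target
    per-subject ``learning_index`` (as produced by :func:`generate_cohort`).
    Day-d CIPL targets decay geometrically from the day-1 level to the level
    implied by the learning index; aged subjects' targets are inflated by
    ``1 + behavior_age_deficit``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    subject_ids = subject_effects["subject_ids"]
    groups = subject_effects["groups"]
    li = np.asarray(subject_effects["learning_index"], dtype=float)

    trials: list[SwimTrial] = []
    for i, (sid, grp) in enumerate(zip(subject_ids, groups)):
        c1 = DAY1_CIPL * np.exp(rng.normal(0.0, 0.10))
        if grp == "aged":
            c1 *= 1.0 + config.behavior_age_deficit
        ratio = (1.0 - li[i]) / (1.0 + li[i])  # day-4 / day-1 target ratio
        for day in range(1, config.n_days + 1):
            if config.n_days > 1:
                c_day = c1 * ratio ** ((day - 1) / (config.n_days - 1))
            else:
                c_day = c1
            for trial in range(1, config.trials_per_day + 1):
                target = c_day * np.exp(rng.normal(0.0, 0.08))
                angle = RELEASE_ANGLES[(trial - 1) % len(RELEASE_ANGLES)]
                speed = SWIM_SPEED * np.exp(rng.normal(0.0, 0.05))
                wobble = (0.03 * POOL_RADIUS,
                          rng.uniform(0.1, 0.3),
                          rng.uniform(0.0, 2 * np.pi))
                path = _solve_circle_time(target, angle, speed, wobble)
                trials.append(SwimTrial(
                    subject_id=sid, day=day, trial=trial,
                    t=path["t"], x=path["x"], y=path["y"],
                    platform_center=path["platform"],
                    platform_radius=PLATFORM_RADIUS,
                    release_point=path["release"],
                    pool_radius=POOL_RADIUS, escaped=path["escaped"],
                ))
    return trials


# ---------------------------------------------------------------------------
# persistence

def write_cohort(config: CohortConfig, out_dir: str | Path) -> dict:
    """Simulate and write a cohort to disk (NIfTI + CSV + JSON sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, behavior, subjects, truth = generate_cohort(config)

    volume_paths = []
    for i, sid in enumerate(stack.subject_ids):
        p = out / f"gm_{sid}.nii.gz"
        stack.save_map(stack.data[i], p)
        volume_paths.append(str(p))
    stack.save_mask(out / "mask.nii.gz")
    save_volume(truth.true_pattern, stack.affine, out / "true_pattern.nii.gz")
    subjects.to_csv(out / "subjects.csv", index=False)
    behavior.to_csv(out / "behavior.csv", index=False)
    save_trials(behavior.attrs["trials"], out / "trials.csv",
                out / "pool_geometry.json")
    sidecar = {
        "config": asdict(config),
        "true_scores": truth.true_scores.tolist(),
        "true_learning_index": truth.true_learning_index.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return {
        "volumes": volume_paths,
        "mask": str(out / "mask.nii.gz"),
        "subjects": str(out / "subjects.csv"),
        "behavior": str(out / "behavior.csv"),
        "trials": str(out / "trials.csv"),
        "geometry": str(out / "pool_geometry.json"),
        "ground_truth": str(out / "ground_truth.json"),
    }
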