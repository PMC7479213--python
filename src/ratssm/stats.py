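"""Group statistics for the cohort: rank tests, the mixed-design ANCOVA,
score-behavior regression and the Shapiro-Wilk normality gate."""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "mann_whitney", "u_from_mean_rank", "mixed_ancova",
    "score_behavior_regression", "shapiro_wilk_gate",
    "RankTestResult", "MixedAncovaResult", "RegressionResult", "NormalityGate",
]


@dataclass
class RankTestResult:
    u: float
    mean_rank_a: float
    mean_rank_b: float
    n_a: int
    n_b: int
    p_value: float
    method: str  # 'exact' or 'asymptotic'

    def summary(self) -> str:
        return (
            f"Mann-Whitney U = {self.u:.2f} (mean ranks {self.mean_rank_a:.2f} "
            f"vs {self.mean_rank_b:.2f}, n = {self.n_a}+{self.n_b}), "
            f"two-sided p = {self.p_value:.4g} [{self.method}]"
        )


def mann_whitney(sample_a: np.ndarray, sample_b: np.ndarray) -> RankTestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    U is reported as min(U_a, U_b). The p-value is exact (full enumeration of
    rank assignments) when both samples have n <= 12 and there are no ties,
    otherwise the normal approximation with tie correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2
    u = min(u_a, n_a * n_b - u_a)

    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return RankTestResult(
            u=n_a * n_b / 2, mean_rank_a=float(ranks[:n_a].mean()),
            mean_rank_b=float(ranks[n_a:].mean()), n_a=n_a, n_b=n_b,
            p_value=1.0, method="degenerate",
        )
    has_ties = len(np.unique(combined)) < len(combined)
    if n_a <= 12 and n_b <= 12 and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    return RankTestResult(
        u=float(u), mean_rank_a=float(ranks[:n_a].mean()),
        mean_rank_b=float(ranks[n_a:].mean()), n_a=n_a, n_b=n_b,
        p_value=float(min(res.pvalue, 1.0)), method=method,
    )


def u_from_mean_rank(mean_rank: float, n_group: int, n_other: int) -> float:
    """Reconstruct the (reported) U statistic from one group's mean rank.

    The rank sum R = mean_rank * n_group gives U_group = R - n(n+1)/2; the
    conventionally reported statistic is min(U_group, n1*n2 - U_group).
    Rejects mean ranks whose implied rank sum is not attainable (rank sums
    with midranks are multiples of 1/2 between the n smallest and n largest
    ranks of the pooled sample).
    """
    n, m = int(n_group), int(n_other)
    if n < 1 or m < 1:
        raise ValueError("group sizes must be positive")
    r = mean_rank * n
    if abs(2 * r - round(2 * r)) > 1e-9:
        raise ValueError(f"rank sum {r} is not attainable (not a multiple of 1/2)")
    lo = n * (n + 1) / 2
    hi = n * (2 * (n + m) - n + 1) / 2
    if not (lo - 1e-9 <= r <= hi + 1e-9):
        raise ValueError(f"rank sum {r} outside attainable range [{lo}, {hi}]")
    u_group = r - lo
    return float(min(u_group, n * m - u_group))


@dataclass
class MixedAncovaResult:
    """Split-plot ANCOVA: between-subjects group effect adjusted for a
    baseline covariate, within-subjects day effect and group x day
    interaction.

    The within-subject stratum includes a day x covariate term, so with n
    subjects and d days the error dfs are (1, n-3) between and
    (d-1, (d-1)(n-3)) within.
    """

    f_group: float
    df_group: tuple[int, int]
    p_group: float
    f_day: float
    df_day: tuple[int, int]
    p_day: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    covariate_used: bool

    def summary(self) -> str:
        buf = io.StringIO()
        kind = "mixed-design ANCOVA" if self.covariate_used else "mixed-design ANOVA"
        buf.write(f"{kind}\n")
        for name, f, df, p in (
            ("group", self.f_group, self.df_group, self.p_group),
            ("day", self.f_day, self.df_day, self.p_day),
            ("group x day", self.f_interaction, self.df_interaction,
             self.p_interaction),
        ):
            buf.write(f"  {name}: F({df[0]},{df[1]}) = {f:.2f}, p = {p:.3g}\n")
        return buf.getvalue()


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    return float(resid @ resid)


def mixed_ancova(
    day_means: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray | None = None,
) -> MixedAncovaResult:
    """Mixed-design ANCOVA on a subjects x days response matrix.

    Parameters
    ----------
    day_means
        (n_subjects, n_days) per-day mean responses (e.g. CIPL).
    group
        0/1 between-subjects factor.
    covariate
        Per-subject continuous covariate entered first (e.g. mean visual-task
        performance); a zero-variance covariate falls back to a plain mixed
        ANOVA with a warning.

    Between-subjects stratum: subject means regressed on covariate then
    group; group F on (1, n-3) df. Within-subjects stratum: subject-centered
    responses regressed on day, day x covariate and day x group contrasts;
    day and interaction F on (d-1, (d-1)(n-3)) df. No sphericity correction
    is applied.
    """
    y = np.asarray(day_means, dtype=float)
    g = np.asarray(group, dtype=float)
    if y.ndim != 2:
        raise ValueError("day_means must be subjects x days")
    n, d = y.shape
    if d < 2:
        raise ValueError("need at least 2 days")
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.isnan(y).any():
        raise ValueError("mixed_ancova requires complete data")

    use_cov = covariate is not None
    if use_cov:
        c = np.asarray(covariate, dtype=float)
        if np.ptp(c) == 0:
            warnings.warn("zero-variance covariate; falling back to mixed ANOVA",
                          stacklevel=2)
            use_cov = False
    n_between_params = 3 if use_cov else 2  # intercept + (cov) + group

    # ----- between-subjects stratum on the subject means -----
    m = y.mean(axis=1)
    ones = np.ones(n)
    if use_cov:
        X_r = np.column_stack([ones, c])
        X_f = np.column_stack([ones, c, g])
    else:
        X_r = ones[:, None]
        X_f = np.column_stack([ones, g])
    rss_r, rss_f = _rss(m, X_r), _rss(m, X_f)
    df_between_err = n - n_between_params
    f_group = ((rss_r - rss_f) / 1) / (rss_f / df_between_err)
    df_group = (1, df_between_err)
    p_group = float(sps.f.sf(f_group, *df_group))

    # ----- within-subjects stratum on the subject-centered responses -----
    dev = (y - m[:, None]).ravel()  # stacked, subject-major
    # day contrasts centered over days: zero-mean within every subject
    day_dummies = np.tile(np.eye(d) - 1.0 / d, (n, 1))[:, : d - 1]
    subj = np.repeat(np.arange(n), d)
    X_day = day_dummies
    blocks = [X_day]
    if use_cov:
        blocks.append(day_dummies * c[subj][:, None])
    blocks.append(day_dummies * g[subj][:, None])
    X_full = np.column_stack(blocks)
    X_no_int = np.column_stack(blocks[:-1])

    rss_total = float(dev @ dev)
    rss_day = _rss(dev, X_day)
    rss_no_int = _rss(dev, X_no_int)
    rss_full = _rss(dev, X_full)

    df_within_err = (d - 1) * (n - n_between_params)
    mse = rss_full / df_within_err
    f_day = ((rss_total - rss_day) / (d - 1)) / mse
    f_int = ((rss_no_int - rss_full) / (d - 1)) / mse
    df_within = (d - 1, df_within_err)
    return MixedAncovaResult(
        f_group=float(f_group), df_group=df_group, p_group=p_group,
        f_day=float(f_day), df_day=df_within,
        p_day=float(sps.f.sf(f_day, *df_within)),
        f_interaction=float(f_int), df_interaction=df_within,
        p_interaction=float(sps.f.sf(f_int, *df_within)),
        covariate_used=use_cov,
    )


@dataclass
class RegressionResult:
    r: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    slope: float
    intercept: float

    def summary(self) -> str:
        return (
            f"r = {self.r:.3f}, R^2 = {self.r_squared:.3f}, "
            f"F({self.df[0]},{self.df[1]}) = {self.f_statistic:.2f}, "
            f"p = {self.p_value:.3g}"
        )


def score_behavior_regression(
    network_scores: np.ndarray, learning_indices: np.ndarray
) -> RegressionResult:
    """Simple regression of the learning index on network pattern scores.

    Reports Pearson r, R^2 = r^2 and F = R^2 (n-2) / (1 - R^2) on (1, n-2)
    df with the two-sided p.
    """
    x = np.asarray(network_scores, dtype=float)
    y = np.asarray(learning_indices, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or learning indices")
    r, p = sps.pearsonr(x, y)
    r2 = r * r
    df = (1, n - 2)
    f = np.inf if r2 >= 1.0 else (r2 / 1) / ((1 - r2) / df[1])
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionResult(
        r=float(r), r_squared=float(r2), f_statistic=float(f), df=df,
        p_value=float(p), slope=float(slope), intercept=float(intercept),
    )


@dataclass
class NormalityGate:
    w: float
    p_value: float
    passed: bool

    def summary(self) -> str:
        verdict = "pass" if self.passed else "FAIL"
        return f"Shapiro-Wilk W = {self.w:.3f}, p = {self.p_value:.3g} [{verdict}]"


def shapiro_wilk_gate(values: np.ndarray, alpha: float = 0.05) -> NormalityGate:
    """Shapiro-Wilk normality check used as a gate (warn, never switch method)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk defined for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    passed = bool(p > alpha)
    if not passed:
        warnings.warn(
            f"normality gate failed (W = {w:.3f}, p = {p:.3g}); "
            "proceeding with parametric analysis", stacklevel=2,
        )
    return NormalityGate(w=float(w), p_value=float(p), passed=passed)
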