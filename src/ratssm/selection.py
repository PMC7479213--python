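"""AICc all-subsets selection of the SSM components that separate age groups.

The group indicator (young=0, aged=1) is regressed on subject scores for
every subset of the leading components up to a size cap, each fit scored by
the small-sample-corrected Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1),

with k counting the intercept plus slopes. The minimum-AICc subset defines
the age-related composite pattern: the regression-coefficient-weighted
combination of the selected component patterns, oriented so that the aged
group's mean composite score exceeds the young group's.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ssm import SSMResults

__all__ = ["aicc", "select_components", "covariate_adjusted_test",
           "SelectionResult", "CovariateTestResult"]


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike information criterion.

    Parameters
    ----------
    rss
        Residual sum of squares of the least-squares fit.
    n
        Number of observations.
    k
        Number of regression parameters, intercept included.
    """
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k+1 (n={n}, k={k})")
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares with intercept prepended; returns (coefs, rss, rank)."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coefs
    return coefs, float(resid @ resid), int(rank)


@dataclass
class SelectionResult:
    """Outcome of the all-subsets AICc search.

    ``candidates`` is a table with one row per subset (columns: subset, k,
    rss, aicc); ``subset`` holds 1-based component indices of the winner.
    """

    candidates: pd.DataFrame
    subset: tuple[int, ...]
    coefficients: np.ndarray          # slopes for the winning subset
    intercept: float
    composite_pattern: np.ndarray | None
    composite_scores: np.ndarray
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    flipped: bool = False
    covariate_test: "CovariateTestResult | None" = field(default=None)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("AICc component-subset selection\n")
        buf.write("=" * 46 + "\n")
        head = self.candidates.sort_values("aicc").head(8)
        buf.write(head.to_string(index=False) + "\n")
        subset = "{" + ", ".join(map(str, self.subset)) + "}" if self.subset else "{} (intercept only)"
        buf.write(f"\nwinning subset: {subset}\n")
        if self.subset:
            buf.write(
                f"R^2 = {self.r_squared:.4f}, F({self.df[0]},{self.df[1]}) = "
                f"{self.f_statistic:.2f}, p = {self.p_value:.3g}\n"
            )
        if self.covariate_test is not None:
            buf.write(self.covariate_test.summary())
        return buf.getvalue()


def select_components(
    ssm: SSMResults | np.ndarray,
    group: np.ndarray | None = None,
    max_components: int = 8,
    max_subset_size: int = 4,
) -> SelectionResult:
    """Find the component subset whose scores best predict age group.

    Parameters
    ----------
    ssm
        Fitted :class:`~ratssm.ssm.SSMResults`, or a raw (subjects x
        components) score matrix (then ``group`` is required and no composite
        pattern is formed).
    group
        0/1 response; taken from the stack's labels when ``ssm`` is a fit.
    max_components, max_subset_size
        Bounds of the candidate pool: all subsets of the first
        ``max_components`` scores up to ``max_subset_size``, plus the
        intercept-only model.

    Ties in AICc are broken toward the smaller subset, then lexicographically.
    """
    if isinstance(ssm, SSMResults):
        scores = ssm.scores
        if group is None:
            group = ssm.stack.group_indicator()
        patterns = ssm.patterns
    else:
        scores = np.asarray(ssm, dtype=float)
        patterns = None
    if group is None:
        raise ValueError("group labels required when passing a raw score matrix")
    y = np.asarray(group, dtype=float)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")

    n_comp = min(max_components, scores.shape[1])
    rows = []
    fits: dict[tuple[int, ...], tuple[np.ndarray, float]] = {}
    for size in range(0, max_subset_size + 1):
        for subset in itertools.combinations(range(1, n_comp + 1), size):
            k = size + 1
            if n <= k + 1:
                continue
            X = scores[:, [j - 1 for j in subset]]
            coefs, rss, rank = _ols(y, X)
            if rank < k:
                warnings.warn(f"singular design for subset {subset}; dropped",
                              stacklevel=2)
                continue
            if rss <= 0:
                # perfect fit: AICc -> -inf; represent with tiny floor so the
                # subset still wins and ties break by size
                rss_eff = max(rss, 1e-300)
            else:
                rss_eff = rss
            rows.append({"subset": subset, "k": k, "rss": rss,
                         "aicc": aicc(rss_eff, n, k)})
            fits[subset] = (coefs, rss)

    candidates = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (rows[i]["aicc"], len(rows[i]["subset"]), rows[i]["subset"]),
    )
    best = rows[order[0]]
    subset = best["subset"]
    coefs, rss = fits[subset]
    size = len(subset)

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best["rss"] / tss if size else 0.0
    if size:
        df = (size, n - size - 1)
        if r2 >= 1.0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (r2 / size) / ((1 - r2) / df[1])
            p = float(stats.f.sf(f_stat, *df))
        composite_scores = scores[:, [j - 1 for j in subset]] @ coefs[1:]
    else:
        df = (0, n - 1)
        f_stat, p = 0.0, 1.0
        composite_scores = np.zeros(n)

    composite_pattern = None
    flipped = False
    if size:
        # orient composite so aged (y=1) mean score exceeds young mean
        if composite_scores[y == 1].mean() < composite_scores[y == 0].mean():
            flipped = True
            composite_scores = -composite_scores
            coefs = coefs.copy()
            coefs[1:] = -coefs[1:]
        if patterns is not None:
            composite_pattern = coefs[1:] @ patterns[[j - 1 for j in subset]]

    return SelectionResult(
        candidates=candidates,
        subset=subset,
        coefficients=coefs[1:],
        intercept=float(coefs[0]),
        composite_pattern=composite_pattern,
        composite_scores=composite_scores,
        r_squared=float(min(r2, 1.0)),
        f_statistic=float(f_stat),
        df=df,
        p_value=p,
        flipped=flipped,
    )


@dataclass
class CovariateTestResult:
    """Hierarchical regression with a covariate entered first.

    Step 1 regresses the response on the covariate alone; step 2 adds the
    composite score. ``f_change`` tests the increment with df (1, n-3).
    """

    f_change: float
    df_change: tuple[int, int]
    p_change: float
    covariate_f: float
    covariate_df: tuple[int, int]
    covariate_p: float
    r2_covariate: float
    r2_full: float

    def summary(self) -> str:
        return (
            f"covariate-first hierarchical regression:\n"
            f"  covariate only: F({self.covariate_df[0]},{self.covariate_df[1]}) "
            f"= {self.covariate_f:.2f}, p = {self.covariate_p:.3g}, "
            f"R^2 = {self.r2_covariate:.4f}\n"
            f"  score added:    F_change({self.df_change[0]},{self.df_change[1]}) "
            f"= {self.f_change:.2f}, p = {self.p_change:.3g}, "
            f"R^2 = {self.r2_full:.4f}\n"
        )


def covariate_adjusted_test(
    response: np.ndarray,
    score: np.ndarray,
    covariate: np.ndarray,
) -> CovariateTestResult:
    """Test whether the composite score predicts the response beyond a covariate.

    Used with the group indicator as response and eTIV as covariate: reports
    the covariate-only F with df (1, n-2) and the F-change for adding the
    score, (dR^2/1) / ((1-R^2_full)/(n-3)) with df (1, n-3).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(score, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not np.all(np.isfinite(c)):
        raise ValueError("covariate must be finite")
    if np.ptp(c) == 0:
        raise ValueError("covariate has zero variance")

    tss = float(((y - y.mean()) ** 2).sum())
    _, rss_cov, _ = _ols(y, c[:, None])
    _, rss_full, _ = _ols(y, np.column_stack([c, x]))
    r2_cov = 1.0 - rss_cov / tss
    r2_full = 1.0 - rss_full / tss

    cov_df = (1, n - 2)
    if r2_cov >= 1.0:
        cov_f, cov_p = np.inf, 0.0
    else:
        cov_f = (r2_cov / 1) / ((1 - r2_cov) / cov_df[1])
        cov_p = float(stats.f.sf(cov_f, *cov_df))

    ch_df = (1, n - 3)
    if r2_full >= 1.0:
        # saturated full model: F undefined unless the increment is zero
        # (covariate already explains everything -> nothing left to explain)
        if r2_full - r2_cov <= 1e-12:
            f_change, p_change = 0.0, 1.0
        else:
            f_change, p_change = np.inf, 0.0
    else:
        f_change = ((r2_full - r2_cov) / 1) / ((1 - r2_full) / ch_df[1])
        f_change = max(f_change, 0.0)
        p_change = float(stats.f.sf(f_change, *ch_df))

    return CovariateTestResult(
        f_change=float(f_change),
        df_change=ch_df,
        p_change=p_change,
        covariate_f=float(cov_f),
        covariate_df=cov_df,
        covariate_p=cov_p,
        r2_covariate=float(r2_cov),
        r2_full=float(r2_full),
    )
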