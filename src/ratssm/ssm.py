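"""Scaled Subprofile Model (SSM) principal component analysis.

SSM treats each subject's gray-matter map as a multiplicatively scaled
profile: after a natural-log transform, the subject mean (the global scaling
factor) and the voxelwise group-mean profile are removed, and the remaining
subjects-by-voxels residual matrix is decomposed by SVD into regional
covariance patterns (voxel weights) and subject scores (per-subject pattern
expression). Because a subject's global scale enters the log data as an
additive row constant, row centering makes the decomposition invariant to
arbitrary per-subject rescaling of the input volumes — the property that
defines SSM.

Conventions fixed here (the decomposition itself does not determine them):

* patterns are unit-norm right singular vectors; scores = U @ diag(s), so
  ``scores @ patterns`` reconstructs the residuals;
* each component is oriented so its largest-|weight| voxel is positive;
* components with s_k^2 <= 1e-12 * sum(s^2) are dropped as numerically null.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .data import GrayMatterStack

__all__ = ["SSMPCA", "SSMResults", "log_center"]

_RANK_TOL = 1e-12


def log_center(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-transform and double-center a subjects x voxels matrix.

    Returns ``(residuals, subject_means, group_mean_profile)`` where

    * ``subject_means[s]`` is the mean over voxels of ln(data[s]) — the
      subject's global scaling effect on the log scale;
    * ``group_mean_profile[v]`` is the mean over subjects of the row-centered
      log data at voxel v;
    * ``residuals = ln(data) - subject_means[:, None] - group_mean_profile``.

    Every row mean and column mean of the residuals is zero (<= 1e-10).
    Row centering first then column centering is the standard SSM order; the
    two commute for complete matrices.
    """
    data = np.asarray(data, dtype=float)
    if np.any(data <= 0):
        raise ValueError("log_center requires strictly positive data")
    log_data = np.log(data)
    subject_means = log_data.mean(axis=1)
    row_centered = log_data - subject_means[:, None]
    group_mean_profile = row_centered.mean(axis=0)
    residuals = row_centered - group_mean_profile
    return residuals, subject_means, group_mean_profile


class SSMPCA:
    """SSM model for a gray-matter stack.

    Parameters
    ----------
    stack
        Strictly positive subjects x masked-voxels stack.

    Examples
    --------
    >>> model = SSMPCA(stack)
    >>> res = model.fit()
    >>> res.variance_fraction[0]   # variance explained by component 1
    """

    def __init__(self, stack: GrayMatterStack):
        if stack.n_subjects < 2:
            raise ValueError("SSM requires at least 2 subjects")
        self.stack = stack

    def fit(self) -> "SSMResults":
        residuals, subject_means, group_mean_profile = log_center(self.stack.data)
        # economy SVD in the subject dimension (n << p)
        u, s, vt = np.linalg.svd(residuals, full_matrices=False)
        total = float((s**2).sum())
        if total == 0.0:
            # degenerate: constant profiles; keep zero components
            keep = np.zeros(0, dtype=int)
        else:
            keep = np.nonzero(s**2 > _RANK_TOL * total)[0]
        u, s, vt = u[:, keep], s[keep], vt[keep]
        # deterministic sign: largest-|weight| voxel of each pattern positive
        for k in range(len(s)):
            j = int(np.argmax(np.abs(vt[k])))
            if vt[k, j] < 0:
                vt[k] = -vt[k]
                u[:, k] = -u[:, k]
        scores = u * s
        variance_fraction = (s**2) / total if total > 0 else s**2
        return SSMResults(
            model=self,
            patterns=vt,
            scores=scores,
            singular_values=s,
            variance_fraction=variance_fraction,
            subject_means=subject_means,
            group_mean_profile=group_mean_profile,
        )


@dataclass
class SSMResults:
    """Fitted SSM decomposition.

    Attributes
    ----------
    patterns
        (n_components, n_voxels) unit-norm voxel-weight patterns.
    scores
        (n_subjects, n_components) subject scores; columns are orthogonal and
        ``scores @ patterns`` reconstructs the centered log residuals.
    variance_fraction
        s_k^2 / sum(s^2), summing to 1 over retained components.
    subject_means, group_mean_profile
        The centering terms removed before the SVD; stored so new data can be
        projected into the same space.
    """

    model: SSMPCA
    patterns: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    variance_fraction: np.ndarray
    subject_means: np.ndarray
    group_mean_profile: np.ndarray

    @property
    def stack(self) -> GrayMatterStack:
        return self.model.stack

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def project_scores(self, pattern: np.ndarray, stack: GrayMatterStack | None = None) -> np.ndarray:
        """Project a stack onto a voxel-weight pattern.

        Applies the same log transform and centering (using the training
        group-mean profile) and returns the per-subject inner products with
        the pattern. Projecting the training stack onto component k returns
        ``scores[:, k]``.
        """
        pattern = np.asarray(pattern, dtype=float)
        if stack is None:
            stack = self.stack
        if pattern.shape != (stack.n_voxels,):
            raise ValueError(
                f"pattern has {pattern.shape} weights but the stack mask has "
                f"{stack.n_voxels} voxels"
            )
        log_data = np.log(stack.data)
        row_centered = log_data - log_data.mean(axis=1, keepdims=True)
        residuals = row_centered - self.group_mean_profile
        return residuals @ pattern

    def reconstruct(self) -> np.ndarray:
        """Centered log residual matrix implied by the decomposition."""
        return self.scores @ self.patterns

    def summary(self, max_components: int = 10) -> str:
        n = min(max_components, self.n_components)
        buf = io.StringIO()
        buf.write("Scaled Subprofile Model PCA\n")
        buf.write("=" * 46 + "\n")
        buf.write(
            f"subjects: {self.stack.n_subjects}   masked voxels: "
            f"{self.stack.n_voxels}   components: {self.n_components}\n"
        )
        buf.write(f"{'comp':>4} {'sing.val':>12} {'var.frac':>10} {'cum':>8}\n")
        cum = 0.0
        for k in range(n):
            cum += self.variance_fraction[k]
            buf.write(
                f"{k + 1:>4} {self.singular_values[k]:>12.5g} "
                f"{self.variance_fraction[k]:>10.4f} {cum:>8.4f}\n"
            )
        return buf.getvalue()
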