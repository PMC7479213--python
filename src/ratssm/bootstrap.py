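"""Bootstrap reliability z-maps for the age-composite pattern.

Subjects are resampled with replacement within age group (preserving the
two-group design), the SSM decomposition and the composite construction are
rerun on each replicate with the component-subset indices frozen to the
point estimate (coefficients refit), and each replicate composite is
sign-aligned to the point-estimate composite. The voxelwise z statistic is
the point-estimate weight divided by the bootstrap standard deviation, a
reliability measure for each voxel's contribution to the pattern. Maps are
reported after a two-sided z threshold and a connected-cluster extent
threshold, positive and negative weights clustered separately.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import GrayMatterStack
from .selection import SelectionResult, _ols
from .ssm import SSMPCA

__all__ = ["bootstrap_pattern", "threshold_clusters", "extract_extrema",
           "BootstrapMap", "Z_CAP"]

_SD_FLOOR = 1e-12
Z_CAP = 1e12  # reported where boot_sd hits the floor (no sampling variability)


@dataclass
class BootstrapMap:
    """Voxelwise bootstrap z statistics for a composite pattern."""

    z: np.ndarray                      # per masked voxel
    point_pattern: np.ndarray
    boot_sd: np.ndarray
    n_iterations: int
    seed: int
    n_redraws: int
    capped: np.ndarray                 # True where boot_sd hit the floor
    stack: GrayMatterStack = field(repr=False)
    z_threshold: float = 3.5
    extent: int = 50
    connectivity: int = 1

    def z_volume(self) -> np.ndarray:
        return self.stack.unmask(self.z)

    def clusters(self) -> tuple[np.ndarray, pd.DataFrame]:
        return threshold_clusters(
            self.z_volume(), self.stack.mask,
            z_thr=self.z_threshold, extent=self.extent,
            connectivity=self.connectivity,
        )

    def summary(self) -> str:
        labels, table = self.clusters()
        buf = io.StringIO()
        buf.write(
            f"Bootstrap z-map ({self.n_iterations} iterations, seed "
            f"{self.seed}, {self.n_redraws} degenerate redraws)\n"
        )
        buf.write(
            f"threshold |z| >= {self.z_threshold}, extent >= {self.extent} "
            f"voxels: {len(table)} clusters\n"
        )
        if len(table):
            buf.write(table.to_string(index=False) + "\n")
        return buf.getvalue()


def _composite_for(stack: GrayMatterStack, subset: tuple[int, ...]) -> np.ndarray | None:
    """Refit the composite on a (re)sampled stack with frozen subset indices."""
    res = SSMPCA(stack).fit()
    idx = [j - 1 for j in subset]
    if max(idx) >= res.n_components:
        return None
    y = stack.group_indicator()
    coefs, _, rank = _ols(y, res.scores[:, idx])
    if rank < len(idx) + 1:
        return None
    return coefs[1:] @ res.patterns[idx]


def bootstrap_pattern(
    stack: GrayMatterStack,
    selection: SelectionResult,
    n_iter: int = 500,
    seed: int = 0,
    z_threshold: float = 3.5,
    extent: int = 50,
    connectivity: int = 1,
) -> BootstrapMap:
    """Bootstrap the composite pattern's voxel weights.

    Parameters
    ----------
    stack
        The original stack the selection was fitted on.
    selection
        Point-estimate selection result; its subset is frozen across
        replicates and its composite is the z-map numerator.
    n_iter
        Number of bootstrap replicates (>= 2).
    seed
        Seed of the replicate resampling stream.

    A replicate in which either group collapses to a single unique subject is
    redrawn (counted in ``n_redraws``) since the SSM decomposition of such a
    resample is degenerate.
    """
    if n_iter < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    if selection.composite_pattern is None or not selection.subset:
        raise ValueError("selection has no composite pattern to bootstrap")
    point = np.asarray(selection.composite_pattern, dtype=float)
    rng = np.random.default_rng(seed)

    groups = np.asarray(stack.group_labels)
    group_idx = {g: np.nonzero(groups == g)[0] for g in np.unique(groups)}

    replicates = np.empty((n_iter, stack.n_voxels))
    n_redraws = 0
    it = 0
    while it < n_iter:
        rows = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True)
             for idx in group_idx.values()]
        )
        if any(len(np.unique(rows[np.isin(rows, idx)])) < 2
               for idx in group_idx.values()):
            n_redraws += 1
            continue
        comp = _composite_for(stack.subset(rows), selection.subset)
        if comp is None:
            n_redraws += 1
            continue
        # sign-align the replicate to the point estimate
        if float(comp @ point) < 0:
            comp = -comp
        replicates[it] = comp
        it += 1

    boot_sd = replicates.std(axis=0, ddof=1)
    capped = boot_sd < _SD_FLOOR
    z = point / np.maximum(boot_sd, _SD_FLOOR)
    z = np.clip(z, -Z_CAP, Z_CAP)

    return BootstrapMap(
        z=z, point_pattern=point, boot_sd=boot_sd, n_iterations=n_iter,
        seed=seed, n_redraws=n_redraws, capped=capped, stack=stack,
        z_threshold=z_threshold, extent=extent, connectivity=connectivity,
    )


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, connectivity)


def threshold_clusters(
    z_volume: np.ndarray,
    mask: np.ndarray | None = None,
    z_thr: float = 3.5,
    extent: int = 50,
    connectivity: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Two-sided threshold + extent filter on a z volume.

    Positive (z >= z_thr) and negative (z <= -z_thr) voxels are clustered
    separately (opposite signs never merge) with the given connectivity
    (1 = 6-neighbor faces). Clusters smaller than ``extent`` voxels are
    removed. Returns a labeled int volume (0 = background) and a table with
    columns label, sign, size, peak_z, peak_x, peak_y, peak_z_coord, labels
    assigned in order of decreasing size then peak coordinate.
    """
    z_volume = np.asarray(z_volume, dtype=float)
    if mask is not None:
        z_volume = np.where(np.asarray(mask, dtype=bool), z_volume, 0.0)
    struct = _structure(connectivity)

    entries = []
    for sign, supra in ((1, z_volume >= z_thr), (-1, z_volume <= -z_thr)):
        labeled, n = ndimage.label(supra, structure=struct)
        for lab in range(1, n + 1):
            voxels = labeled == lab
            size = int(voxels.sum())
            if size < extent:
                continue
            vals = np.where(voxels, z_volume, 0.0)
            flat = int(np.argmax(vals * sign))
            peak = np.unravel_index(flat, z_volume.shape)
            entries.append({
                "sign": sign, "size": size,
                "peak_z": float(z_volume[peak]),
                "peak_i": int(peak[0]), "peak_j": int(peak[1]),
                "peak_k": int(peak[2]), "_voxels": voxels,
            })

    entries.sort(key=lambda e: (-e["size"], e["peak_i"], e["peak_j"], e["peak_k"]))
    labels = np.zeros(z_volume.shape, dtype=int)
    rows = []
    for i, e in enumerate(entries, start=1):
        labels[e.pop("_voxels")] = i
        rows.append({"label": i, **e})
    table = pd.DataFrame(
        rows, columns=["label", "sign", "size", "peak_z", "peak_i", "peak_j", "peak_k"]
    )
    return labels, table


def extract_extrema(labels: np.ndarray, z_volume: np.ndarray) -> pd.DataFrame:
    """Per-cluster extreme z value and its voxel, sorted by |z| descending.

    Positive clusters report their maximum, negative clusters their minimum.
    """
    z_volume = np.asarray(z_volume, dtype=float)
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        voxels = labels == lab
        vals = z_volume[voxels]
        sign = 1 if vals.mean() >= 0 else -1
        extreme = vals.max() if sign > 0 else vals.min()
        flat = int(np.argmax(np.where(voxels, z_volume * sign, -np.inf)))
        peak = np.unravel_index(flat, z_volume.shape)
        rows.append({
            "label": int(lab), "sign": sign, "extreme_z": float(extreme),
            "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
        })
    rows.sort(key=lambda r: -abs(r["extreme_z"]))
    return pd.DataFrame(
        rows, columns=["label", "sign", "extreme_z", "peak_i", "peak_j", "peak_k"]
    )
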