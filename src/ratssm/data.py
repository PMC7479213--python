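"""Volume/table I/O and the in-memory gray-matter stack.

Voxel linearization convention: masked voxels are flattened in C (row-major)
order of the 3D grid, i.e. ``volume[mask]`` with numpy defaults. The same
order is used everywhere a per-voxel vector appears (patterns, z-maps), so a
vector round-trips exactly through :func:`GrayMatterStack.unmask` and
:meth:`GrayMatterStack.save_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GrayMatterStack",
    "load_stack",
    "load_subject_table",
    "auto_mask",
    "save_volume",
]

GROUPS = ("young", "aged")


@dataclass
class GrayMatterStack:
    """Subjects x masked-voxels matrix of gray-matter density plus geometry.

    Parameters
    ----------
    data
        (n_subjects, n_masked_voxels) strictly positive matrix; column j is
        the j-th True voxel of ``mask`` in C order.
    mask
        Boolean 3D analysis mask.
    voxel_size_um
        Voxel edge lengths in micrometres, one per axis.
    subject_ids, group_labels
        Parallel per-row identifiers; labels are 'young' or 'aged'.
    affine
        4x4 voxel-to-world affine (defaults to voxel-size scaling).
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size_um: tuple[float, float, float]
    subject_ids: list[str]
    group_labels: list[str]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D volume")
        n_vox = int(self.mask.sum())
        if self.data.ndim != 2 or self.data.shape[1] != n_vox:
            raise ValueError(
                f"data has {self.data.shape[1] if self.data.ndim == 2 else '?'} "
                f"columns but the mask has {n_vox} voxels"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length does not match data rows")
        if len(self.group_labels) != self.data.shape[0]:
            raise ValueError("group_labels length does not match data rows")
        bad = set(self.group_labels) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if np.any(self.data <= 0):
            rows, cols = np.nonzero(self.data <= 0)
            sid = self.subject_ids[rows[0]]
            coord = tuple(int(c) for c in np.argwhere(self.mask)[cols[0]])
            raise ValueError(
                f"non-positive gray matter inside mask: subject {sid!r} at "
                f"voxel {coord} (log transform undefined)"
            )
        if self.affine is None:
            self.affine = np.diag(
                [self.voxel_size_um[0] / 1000.0,
                 self.voxel_size_um[1] / 1000.0,
                 self.voxel_size_um[2] / 1000.0, 1.0]
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def group_indicator(self) -> np.ndarray:
        """0/1 response vector: young -> 0, aged -> 1."""
        return np.array([1.0 if g == "aged" else 0.0 for g in self.group_labels])

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-masked-voxel vector back into a 3D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError("values length does not match mask voxel count")
        vol = np.full(self.grid_shape, fill, dtype=float)
        vol[self.mask] = values
        return vol

    def save_map(self, values: np.ndarray, path: str | Path) -> None:
        """Write a per-voxel vector as a NIfTI volume (zeros outside mask)."""
        save_volume(self.unmask(values), self.affine, path)

    def save_mask(self, path: str | Path) -> None:
        save_volume(self.mask.astype(np.uint8), self.affine, path)

    def subset(self, rows: Sequence[int]) -> "GrayMatterStack":
        """Row-subset (e.g. a bootstrap resample); shares mask and geometry."""
        rows = list(rows)
        return GrayMatterStack(
            data=self.data[rows],
            mask=self.mask,
            voxel_size_um=self.voxel_size_um,
            subject_ids=[self.subject_ids[i] for i in rows],
            group_labels=[self.group_labels[i] for i in rows],
            affine=self.affine,
        )


def save_volume(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_subject_table(path: str | Path) -> pd.DataFrame:
    """Read the subject table CSV (subject_id, group, age, optional eTIV...)."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels in subject table: {sorted(bad)}")
    for grp in GROUPS:
        if not (table["group"] == grp).any():
            raise ValueError(f"subject table has no {grp!r} subjects")
    if "etiv" in table.columns and (table["etiv"] <= 0).any():
        raise ValueError("eTIV must be positive where present")
    return table


def load_stack(
    volume_paths: Sequence[str | Path],
    mask_path: str | Path,
    subject_table_path: str | Path,
) -> tuple[GrayMatterStack, pd.DataFrame]:
    """Load per-subject NIfTI volumes + mask + subject CSV into a stack.

    Volume order must match the subject table row order. All volumes must
    share grid shape and affine (to 1e-4) with the mask.
    """
    table = load_subject_table(subject_table_path)
    if len(volume_paths) != len(table):
        raise ValueError(
            f"{len(volume_paths)} volumes but {len(table)} subject table rows"
        )
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj).astype(bool)
    affine = mask_img.affine

    rows = []
    for sid, p in zip(table["subject_id"], volume_paths):
        img = nib.load(str(p))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(
                f"subject {sid!r}: volume shape {vol.shape} != mask {mask.shape}"
            )
        if not np.allclose(img.affine, affine, atol=1e-4):
            raise ValueError(f"subject {sid!r}: affine/orientation mismatch")
        inside = vol[mask]
        if np.any(inside <= 0):
            coord = tuple(int(c) for c in np.argwhere(mask)[np.argmax(inside <= 0)])
            raise ValueError(
                f"subject {sid!r}: non-positive value inside mask at voxel {coord}"
            )
        rows.append(inside)

    voxel_mm = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    stack = GrayMatterStack(
        data=np.vstack(rows),
        mask=mask,
        voxel_size_um=tuple(float(v) * 1000.0 for v in voxel_mm),
        subject_ids=list(table["subject_id"]),
        group_labels=list(table["group"]),
        affine=affine,
    )
    return stack, table


def auto_mask(volumes: Sequence[np.ndarray], min_gm: float = 0.0) -> np.ndarray:
    """Mask of voxels exceeding ``min_gm`` in *every* subject.

    Guarantees the log transform downstream is defined on every masked voxel.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    mins = np.min(np.stack([np.asarray(v, dtype=float) for v in volumes]), axis=0)
    mask = mins > min_gm
    if not mask.any():
        raise ValueError(f"empty mask: no voxel exceeds {min_gm} in all subjects")
    return mask
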