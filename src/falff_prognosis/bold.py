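"""In-memory container for one subject's 4D BOLD series, with NIfTI-1 I/O.

The canonical layout is ``(x, y, z, t)``; the third spatial axis is the
slice axis used by quality control, and the repetition time (TR, seconds)
is carried alongside the data and recorded in the time-axis header field
when written to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class Bold4D:
    """One subject's masked 4D time series.

    Parameters
    ----------
    voxels : ndarray, shape (x, y, z, t)
        BOLD signal. ``t >= 2`` is required for any temporal statistic.
    tr_seconds : float
        Repetition time in seconds (sampling interval of the series).
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; at least one voxel must be inside it.
    subject_id : str
        Free-form identifier used in reports and file names.
    """

    voxels: np.ndarray
    tr_seconds: float
    mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4D (x, y, z, t); got shape {self.voxels.shape}")
        if self.voxels.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.mask.shape != self.voxels.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial dims {self.voxels.shape[:3]}"
            )
        if not self.mask.any():
            raise ValueError("mask contains no in-brain voxels")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.voxels.shape[3]

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask_matrix(self) -> np.ndarray:
        """Return the in-mask data as a (t, n_voxels) matrix.

        Voxel order follows C-order iteration over the mask, so it is stable
        for a fixed mask and can be inverted with :meth:`unflatten`.
        """
        return self.voxels[self.mask].T.copy()

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        """Scatter per-voxel values (last axis = in-mask voxel) back to the grid."""
        values = np.asarray(values)
        out = np.zeros(values.shape[:-1] + self.mask.shape, dtype=float)
        out[..., self.mask] = values
        return out

    def save(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        """Write the series (and optionally the mask) as NIfTI-1, TR in the zooms."""
        img = nib.Nifti1Image(self.voxels.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, float(self.tr_seconds)))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))
        if mask_path is not None:
            mimg = nib.Nifti1Image(self.mask.astype(np.uint8), affine=np.eye(4))
            nib.save(mimg, str(mask_path))

    @classmethod
    def load(
        cls,
        path: str | Path,
        mask: np.ndarray | str | Path | None = None,
        subject_id: str = "",
        tr_seconds: float | None = None,
    ) -> "Bold4D":
        """Read a NIfTI-1 series; TR is taken from the time-axis zoom unless given."""
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if tr_seconds is None:
            zooms = img.header.get_zooms()
            tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
            if tr_seconds <= 0:
                raise ValueError(f"{path}: no repetition time in header; pass tr_seconds")
        if mask is None:
            mask_arr = np.ones(data.shape[:3], dtype=bool)
        elif isinstance(mask, (str, Path)):
            mask_arr = np.asarray(nib.load(str(mask)).dataobj) > 0
        else:
            mask_arr = np.asarray(mask, dtype=bool)
        if not subject_id:
            subject_id = Path(path).name.split(".")[0]
        return cls(voxels=data, tr_seconds=tr_seconds, mask=mask_arr, subject_id=subject_id)


def check_consistent_masks(scans: list[Bold4D]) -> None:
    """Raise if any scan's mask differs from the first scan's mask."""
    if not scans:
        raise ValueError("no scans provided")
    ref = scans[0].mask
    offenders = [
        s.subject_id or f"scan #{i}"
        for i, s in enumerate(scans)
        if s.mask.shape != ref.shape or not np.array_equal(s.mask, ref)
    ]
    if offenders:
        raise ValueError(f"masks inconsistent with first scan for: {', '.join(offenders)}")
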