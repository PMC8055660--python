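"""Automatic functional-image quality assurance.

Quality of a BOLD run is summarized by a slice-wise temporal
signal-to-noise ratio (tSNR): the ratio of mean signal to temporal standard
deviation per slice, aggregated over slices weighted by the number of brain
voxels each contains. Runs below threshold (default 100) are excluded; when
a subject has several runs, only the highest-tSNR run is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bold import Bold4D
from .errors import PipelineError

logger = logging.getLogger(__name__)

DEFAULT_TSNR_THRESHOLD = 100.0

__all__ = [
    "DEFAULT_TSNR_THRESHOLD",
    "TsnrReport",
    "slice_tsnr",
    "qc_filter",
    "select_best_run",
]


@dataclass
class TsnrReport:
    """Slice-wise tSNR for one run; slice axis is the third spatial axis."""

    subject_id: str
    per_slice_tsnr: np.ndarray  # NaN where no finite voxel tSNR exists
    per_slice_weight: np.ndarray  # brain-voxel count per slice
    weighted_tsnr: float
    threshold: float
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "slice": np.arange(self.per_slice_tsnr.size),
                "tsnr": self.per_slice_tsnr,
                "weight": self.per_slice_weight,
            }
        )
        df["weighted_tsnr"] = self.weighted_tsnr
        df["passed"] = self.passed
        return df


def slice_tsnr(
    scan: Bold4D,
    threshold: float = DEFAULT_TSNR_THRESHOLD,
    method: str = "voxel_mean",
) -> TsnrReport:
    """Slice-wise tSNR, weighted-averaged over slices by brain-voxel count.

    Two readings of "mean signal over standard deviation of the slice time
    course data" are supported:

    * ``voxel_mean`` (default): tSNR per in-mask voxel (temporal mean over
      temporal sd, n-1 denominator), averaged over the voxels of the slice.
      Robust to spatial intensity gradients within a slice.
    * ``pooled``: mean of the slice's spatially-averaged time course over
      its standard deviation.

    Slices without brain voxels are excluded; a slice whose tSNR is
    non-finite (e.g. all-constant time courses) is flagged NaN, logged, and
    excluded from the weighted mean.
    """
    if method not in ("voxel_mean", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    nz = scan.voxels.shape[2]
    per_slice = np.full(nz, np.nan)
    weights = np.zeros(nz)
    for z in range(nz):
        m = scan.mask[:, :, z]
        weights[z] = m.sum()
        if weights[z] == 0:
            continue
        data = scan.voxels[:, :, z, :][m]  # (n_voxels_in_slice, t)
        if method == "voxel_mean":
            mu = data.mean(axis=1)
            sd = data.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                voxel_tsnr = mu / sd
            finite = np.isfinite(voxel_tsnr)
            if not finite.all():
                logger.warning(
                    "%s slice %d: %d voxel(s) with zero temporal variance excluded",
                    scan.subject_id, z, int((~finite).sum()),
                )
            if finite.any():
                per_slice[z] = voxel_tsnr[finite].mean()
        else:
            tc = data.mean(axis=0)
            sd = tc.std(ddof=1)
            per_slice[z] = tc.mean() / sd if sd > 0 else np.nan
        if not np.isfinite(per_slice[z]):
            logger.warning("%s slice %d: tSNR non-finite, excluded from aggregate",
                           scan.subject_id, z)

    usable = np.isfinite(per_slice) & (weights > 0)
    if not usable.any():
        warnings.warn(f"{scan.subject_id}: no usable slices for tSNR")
        weighted = np.nan
        passed = False
    else:
        weighted = float(np.average(per_slice[usable], weights=weights[usable]))
        passed = weighted >= threshold
    return TsnrReport(
        subject_id=scan.subject_id,
        per_slice_tsnr=per_slice,
        per_slice_weight=weights,
        weighted_tsnr=weighted,
        threshold=float(threshold),
        passed=passed,
    )


def qc_filter(
    scans: list[Bold4D],
    threshold: float = DEFAULT_TSNR_THRESHOLD,
    method: str = "voxel_mean",
) -> tuple[list[Bold4D], pd.DataFrame]:
    """Retain scans with weighted tSNR >= threshold; log each exclusion.

    Returns the retained scans (input order preserved) and an exclusion log
    with one row per scan. Raises :class:`PipelineError` if nothing passes.
    """
    if not scans:
        raise ValueError("qc_filter requires at least one scan")
    retained: list[Bold4D] = []
    rows = []
    for scan in scans:
        report = slice_tsnr(scan, threshold=threshold, method=method)
        rows.append(
            {
                "subject_id": scan.subject_id,
                "weighted_tsnr": report.weighted_tsnr,
                "threshold": threshold,
                "retained": report.passed,
            }
        )
        if report.passed:
            retained.append(scan)
        else:
            logger.info("excluding %s: weighted tSNR %.2f < %.2f",
                        scan.subject_id, report.weighted_tsnr, threshold)
    log = pd.DataFrame(rows)
    if not retained:
        raise PipelineError(
            f"all {len(scans)} scans fell below the tSNR threshold {threshold}; "
            "inspect acquisitions or lower the threshold deliberately"
        )
    return retained, log


def select_best_run(runs: list[Bold4D], method: str = "voxel_mean") -> Bold4D:
    """Return the run with the highest weighted tSNR; ties keep the earliest."""
    if not runs:
        raise ValueError("select_best_run requires at least one run")
    tsnrs = [slice_tsnr(r, method=method).weighted_tsnr for r in runs]
    best = int(np.nanargmax(tsnrs))
    # nanargmax returns the first maximal index, the documented tie-break
    if tsnrs.count(tsnrs[best]) > 1:
        logger.info("tSNR tie across runs (%.4f); keeping run %d", tsnrs[best], best)
    return runs[best]
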