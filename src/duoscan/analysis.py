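"""Real-time functional localization and individual-maximum calibration.

The localizer finds the subject's activated sensorimotor region while the
scans are still arriving: each incoming volume is smoothed, and after every
completed block the per-voxel Pearson correlation between the observed
baseline-referenced signal and the expected HRF-convolved task regressor is
updated incrementally (growing window) over the block-local baseline scans
(1-3) and response scans (6-8).  The thresholded, cluster-filtered map yields
the reference ROI, and the maximum ROI-mean BOLD percent change seen during
the localizer is stored as the subject's 100% reference for all later
feedback — the step that makes subjects on scanners with grossly different
signal amplitudes comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hrf import CanonicalHRF
from .scanner import BlockDesign, VolumeSeries, VolumeStream, task_regressor

__all__ = [
    "ActivationMap",
    "RoiMask",
    "CalibrationProfile",
    "RoiTimeSeries",
    "LocalizationFailure",
    "CalibrationError",
    "smooth_volume",
    "IncrementalLocalizer",
    "incremental_localizer",
    "extract_roi",
    "roi_mean_trace",
    "sliding_window_activation",
    "block_responses",
    "calibrate",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class LocalizationFailure(RuntimeError):
    """No voxel cluster survived thresholding — repeat the measurement."""


class CalibrationError(RuntimeError):
    """The calibration reference is undefined (non-positive maximum)."""


def smooth_volume(
    vol: np.ndarray, fwhm_mm: float, voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    """Gaussian-smooth a 3D volume with the stated FWHM (mm); FWHM 0 is the
    identity.  sigma per axis = FWHM / (2 sqrt(2 ln 2)) / voxel size."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm == 0:
        return np.asarray(vol, dtype=float)
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    return ndimage.gaussian_filter(np.asarray(vol, dtype=float), sigma=sigma)


@dataclass
class ActivationMap:
    """Per-voxel correlation map from the growing-window localizer."""

    r: np.ndarray
    baseline_window: tuple[int, int]
    response_window: tuple[int, int]
    n_blocks_used: int
    threshold: float | None = None


@dataclass
class RoiMask:
    """Boolean 3D mask with its extraction provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiTimeSeries:
    """Mean-ROI percent signal change per scan (the only values a site needs
    to transmit)."""

    values_percent: np.ndarray
    scan_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values_percent = np.asarray(self.values_percent, dtype=float)
        self.scan_indices = np.asarray(self.scan_indices, dtype=int)
        if self.values_percent.shape != self.scan_indices.shape:
            raise ValueError("values and scan indices must align")


class IncrementalLocalizer:
    """Growing-window correlation analysis fed one volume at a time.

    Per block, the baseline is the mean over block-local scans in the
    baseline window; the observed signal at the used scans (baseline +
    response windows) is expressed as percent change from that baseline, and
    correlated against the identically-referenced HRF regressor.  Sums are
    accumulated across completed blocks so the map sharpens as the run
    proceeds.
    """

    def __init__(
        self,
        design: BlockDesign,
        tr_seconds: float,
        hrf_params: CanonicalHRF | None = None,
        fwhm_mm: float = 3.0,
        voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    ):
        self.design = design
        self.tr_seconds = tr_seconds
        self.fwhm_mm = fwhm_mm
        self.voxel_size_mm = voxel_size_mm
        self.regressor = task_regressor(design, tr_seconds, hrf_params)
        self._block_buffer: dict[int, np.ndarray] = {}
        self._completed_blocks = 0
        # running sums over pooled used scans (x: regressor, y: per voxel)
        self._n = 0
        self._sx = 0.0
        self._sxx = 0.0
        self._sy: np.ndarray | None = None
        self._syy: np.ndarray | None = None
        self._sxy: np.ndarray | None = None

    def feed(self, scan_index: int, volume: np.ndarray) -> None:
        """Consume one acquired volume (global 1-based index), smoothing it
        on arrival; completes a block when its last scan arrives."""
        vol = smooth_volume(volume, self.fwhm_mm, self.voxel_size_mm)
        block, local = self.design.block_of_scan(scan_index)
        self._block_buffer[local] = vol
        if local == self.design.scans_per_block:
            self._finish_block(block)
            self._block_buffer.clear()

    def _used_locals(self) -> list[int]:
        b0, b1 = self.design.baseline_window
        r0, r1 = self.design.response_window
        return list(range(b0, b1 + 1)) + list(range(r0, r1 + 1))

    def _finish_block(self, block_index: int) -> None:
        d = self.design
        b0, b1 = d.baseline_window
        base_vols = np.stack([self._block_buffer[s] for s in range(b0, b1 + 1)], axis=-1)
        baseline = base_vols.mean(axis=-1)

        used = self._used_locals()
        offset = (block_index - 1) * d.scans_per_block
        xs = self.regressor[[offset + s - 1 for s in used]]
        xs = xs - self.regressor[[offset + s - 1 for s in range(b0, b1 + 1)]].mean()

        with np.errstate(divide="ignore", invalid="ignore"):
            ys = np.stack(
                [100.0 * (self._block_buffer[s] - baseline) / baseline for s in used],
                axis=-1,
            )
        if self._sy is None:
            shape = baseline.shape
            self._sy = np.zeros(shape)
            self._syy = np.zeros(shape)
            self._sxy = np.zeros(shape)
        self._n += len(used)
        self._sx += xs.sum()
        self._sxx += (xs**2).sum()
        self._sy += ys.sum(axis=-1)
        self._syy += (ys**2).sum(axis=-1)
        self._sxy += (ys * xs).sum(axis=-1)
        self._completed_blocks = block_index

    def current_map(self) -> ActivationMap:
        if self._sy is None:
            raise RuntimeError("no completed block yet")
        n = self._n
        cov = n * self._sxy - self._sx * self._sy
        varx = n * self._sxx - self._sx**2
        vary = n * self._syy - self._sy**2
        denom2 = varx * vary
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom2 > 1e-24, cov / np.sqrt(np.maximum(denom2, 1e-300)), np.nan)
        r = np.clip(r, -1.0, 1.0)
        return ActivationMap(
            r=r,
            baseline_window=self.design.baseline_window,
            response_window=self.design.response_window,
            n_blocks_used=self._completed_blocks,
        )


def incremental_localizer(
    volume_stream: VolumeStream | VolumeSeries,
    design: BlockDesign,
    hrf_params: CanonicalHRF | None = None,
    fwhm_mm: float = 3.0,
) -> ActivationMap:
    """Run the growing-window localizer over a causal stream (or a series,
    which is wrapped in one) and return the final map after the last block."""
    if isinstance(volume_stream, VolumeSeries):
        from .scanner import stream as _stream

        volume_stream = _stream(volume_stream)
    series = volume_stream.series
    loc = IncrementalLocalizer(
        design, series.tr_seconds, hrf_params, fwhm_mm, series.voxel_size_mm
    )
    for scan_index, vol in volume_stream:
        loc.feed(scan_index, vol)
    return loc.current_map()


def extract_roi(
    activation: ActivationMap, r_threshold: float = 0.6, min_cluster_voxels: int = 5
) -> RoiMask:
    """Largest 6-connected cluster of voxels with r >= threshold (and at
    least ``min_cluster_voxels`` voxels).  Raises
    :class:`LocalizationFailure` when nothing survives."""
    r = activation.r
    above = np.nan_to_num(r, nan=-2.0) >= r_threshold
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n_labels = ndimage.label(above, structure=structure)
    if n_labels == 0:
        raise LocalizationFailure(
            f"no voxel reached r >= {r_threshold}; repeat the measurement"
        )
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n_labels + 1))
    order = np.argsort(sizes)[::-1]
    best = order[0]
    if sizes[best] < min_cluster_voxels:
        raise LocalizationFailure(
            f"largest cluster has {int(sizes[best])} voxels "
            f"< minimum {min_cluster_voxels}; repeat the measurement"
        )
    mask = labels == best + 1
    activation.threshold = r_threshold
    return RoiMask(
        mask=mask,
        provenance={
            "r_threshold": r_threshold,
            "min_cluster_voxels": min_cluster_voxels,
            "connectivity": 6,
            "cluster_size": int(sizes[best]),
        },
    )


def roi_mean_trace(series: VolumeSeries, roi: RoiMask) -> np.ndarray:
    """Mean raw intensity over the ROI for every scan (length n_scans)."""
    if roi.voxel_count == 0:
        raise ValueError("empty ROI")
    return series.data[roi.mask, :].mean(axis=0)


def sliding_window_activation(
    trace: np.ndarray,
    design: BlockDesign,
    block_index: int,
    units: str = "intensity",
) -> float:
    """Per-block raw response in percent-change units.

    Baseline = mean over the design's baseline window (the 5 scans before
    tapping in the main experiment); response = mean over the response window
    (the 3 scans right after tapping, where the BOLD signal peaks).  Only the
    current block's scans are used — the window slides block by block.

    ``units``: "intensity" converts to percent change against the block
    baseline; "percent" assumes the trace is already in percent units and
    returns response mean minus baseline mean.
    """
    trace = np.asarray(trace, dtype=float)
    need = (block_index - 1) * design.scans_per_block + design.response_window[1]
    if trace.size < need:
        raise ValueError(
            f"trace has {trace.size} scans but block {block_index} needs {need}"
        )
    base_idx = design.window_scans(block_index, design.baseline_window)
    resp_idx = design.window_scans(block_index, design.response_window)
    base = trace[base_idx].mean()
    resp = trace[resp_idx].mean()
    if units == "intensity":
        if base <= 0:
            raise ValueError("non-positive baseline intensity")
        return float(100.0 * (resp - base) / base)
    if units == "percent":
        return float(resp - base)
    raise ValueError(f"unknown units {units!r}")


def block_responses(
    trace: np.ndarray, design: BlockDesign, units: str = "intensity"
) -> np.ndarray:
    """Sliding-window raw response for every block of the design."""
    return np.asarray(
        [
            sliding_window_activation(trace, design, b, units)
            for b in range(1, design.n_blocks + 1)
        ]
    )


@dataclass
class CalibrationProfile:
    """Per-subject reference: the ROI plus the maximum BOLD percent change
    observed in the localizer, defined as 100%."""

    subject_id: str
    roi: RoiMask
    max_bold_percent: float
    baseline_intensity: float
    method: str = "window"

    def __post_init__(self) -> None:
        if self.max_bold_percent <= 0:
            raise CalibrationError("max_bold_percent must be positive")

    def to_json(self, path: str) -> None:
        idx = np.argwhere(self.roi.mask)
        payload = {
            "subject_id": self.subject_id,
            "max_bold_percent": self.max_bold_percent,
            "baseline_intensity": self.baseline_intensity,
            "method": self.method,
            "roi_shape": list(self.roi.mask.shape),
            "roi_voxels": idx.tolist(),
            "roi_provenance": self.roi.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CalibrationProfile":
        with open(path) as fh:
            payload = json.load(fh)
        mask = np.zeros(tuple(payload["roi_shape"]), dtype=bool)
        for x, y, z in payload["roi_voxels"]:
            mask[x, y, z] = True
        return cls(
            subject_id=payload["subject_id"],
            roi=RoiMask(mask=mask, provenance=payload.get("roi_provenance", {})),
            max_bold_percent=payload["max_bold_percent"],
            baseline_intensity=payload["baseline_intensity"],
            method=payload.get("method", "window"),
        )


def calibrate(
    series: VolumeSeries,
    roi: RoiMask,
    design: BlockDesign,
    subject_id: str = "",
    method: str = "window",
) -> CalibrationProfile:
    """Define the subject's 100% reference from a localizer run.

    ``method="window"`` (default): the maximum over blocks of the
    sliding-window response (same 3-scan-mean convention as the main
    experiment, so the window attenuation cancels in later ratios).
    ``method="scan_max"``: the maximum over all scans of the ROI-mean percent
    change against the run-initial baseline (the rest scans before the first
    tapping block — later blocks' local baselines sit in the preceding
    block's HRF undershoot and would bias the reference).
    """
    trace = roi_mean_trace(series, roi)
    baselines = []
    per_block: list[float] = []
    run_base = trace[design.window_scans(1, design.baseline_window)].mean()
    if run_base <= 0:
        raise CalibrationError("non-positive baseline intensity")
    for b in range(1, design.n_blocks + 1):
        base_idx = design.window_scans(b, design.baseline_window)
        base = trace[base_idx].mean()
        if base <= 0:
            raise CalibrationError("non-positive baseline intensity")
        baselines.append(base)
        if method == "window":
            per_block.append(sliding_window_activation(trace, design, b))
        elif method == "scan_max":
            lo = (b - 1) * design.scans_per_block
            hi = lo + design.scans_per_block
            pct = 100.0 * (trace[lo:hi] - run_base) / run_base
            per_block.append(float(pct.max()))
        else:
            raise ValueError(f"unknown calibration method {method!r}")
    max_bold = float(np.max(per_block))
    if max_bold <= 0:
        raise CalibrationError(
            f"maximum ROI response {max_bold:.4f}% is not positive"
        )
    return CalibrationProfile(
        subject_id=subject_id,
        roi=roi,
        max_bold_percent=max_bold,
        baseline_intensity=float(np.mean(baselines)),
        method=method,
    )
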