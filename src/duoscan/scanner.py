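"""Synthetic block-design BOLD scanner.

Generates 4D fMRI volume series for a finger-tapping block design: a
spherical activation blob in an otherwise flat brain, driven by an
HRF-convolved tapping boxcar whose amplitude is the subject's maximal BOLD
percent signal change scaled by a per-block "effort" fraction, plus i.i.d.
Gaussian thermal noise and a slow sinusoidal drift.  Volumes are served one
per TR through a causal stream so downstream real-time analysis can never
peek at scans that have not been "acquired" yet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import nibabel as nib
import numpy as np

from .edl_config import EDLValidationError, ExperimentConfig, SiteConfig
from .hrf import CanonicalHRF, make_hrf

__all__ = [
    "Block",
    "BlockDesign",
    "SubjectProfile",
    "VolumeSeries",
    "VolumeStream",
    "CausalityError",
    "localizer_design",
    "main_design",
    "simulate_run",
    "stream",
    "task_regressor",
]

REGION_UPPER = "U"
REGION_LOWER = "L"


class CausalityError(RuntimeError):
    """A consumer asked for a scan that has not been acquired yet."""


@dataclass(frozen=True)
class Block:
    """One stimulation block: a task label, an optional target region and a
    within-block layout of labeled segments (label, scan count)."""

    task: str
    target_region: str | None
    layout: tuple[tuple[str, int], ...]

    @property
    def n_scans(self) -> int:
        return sum(n for _, n in self.layout)

    def scans_with_label(self, label: str) -> tuple[int, ...]:
        """Block-local 1-based scan indices carrying ``label``."""
        out, pos = [], 0
        for seg, n in self.layout:
            if seg == label:
                out.extend(range(pos + 1, pos + n + 1))
            pos += n
        return tuple(out)


@dataclass(frozen=True)
class BlockDesign:
    """A full run as a sequence of equal-length blocks plus the analysis
    windows (1-based block-local inclusive scan ranges) used downstream."""

    blocks: tuple[Block, ...]
    baseline_window: tuple[int, int]
    response_window: tuple[int, int]

    def __post_init__(self) -> None:
        lengths = {b.n_scans for b in self.blocks}
        if len(lengths) != 1:
            raise ValueError("all blocks must have the same scan count")
        if self.response_window[1] > self.scans_per_block:
            raise ValueError("response window extends past the block")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def scans_per_block(self) -> int:
        return self.blocks[0].n_scans

    @property
    def n_scans(self) -> int:
        return self.n_blocks * self.scans_per_block

    def block_of_scan(self, scan_index: int) -> tuple[int, int]:
        """Map a global 1-based scan index to (block index 1-based, local scan)."""
        if not 1 <= scan_index <= self.n_scans:
            raise IndexError(scan_index)
        b, local = divmod(scan_index - 1, self.scans_per_block)
        return b + 1, local + 1

    def global_scans(self, block_index: int, local_scans: tuple[int, ...]) -> np.ndarray:
        """Global 0-based array indices for block-local 1-based scan indices."""
        offset = (block_index - 1) * self.scans_per_block
        return np.asarray([offset + s - 1 for s in local_scans], dtype=int)

    def window_scans(self, block_index: int, window: tuple[int, int]) -> np.ndarray:
        lo, hi = window
        return self.global_scans(block_index, tuple(range(lo, hi + 1)))


def localizer_design() -> BlockDesign:
    """The functional localizer: five blocks of twelve scans each, laid out
    as 2 scans rest, 2 scans finger tapping, 8 scans rest.  The correlation
    analysis takes its baseline from block-local scans 1-3 and the response
    from scans 6-8, where the hemodynamic response peaks."""
    layout = (("rest", 2), ("tapping", 2), ("rest", 8))
    blocks = tuple(Block("localizer", None, layout) for _ in range(5))
    return BlockDesign(blocks, baseline_window=(1, 3), response_window=(6, 8))


def main_design(config: ExperimentConfig, seed: int) -> BlockDesign:
    """Randomised main-experiment schedule.

    One 15-scan block per run (5 baseline, 2 tapping, 7 rest, 1 feedback; the
    task cue is shown between blocks).  Per task, each target region (U/L)
    appears ``targets_per_region_per_task`` times; block order is a seeded
    permutation.  Baseline window = the 5 pre-tapping scans; response window
    = the 3 scans (6 s at TR 2 s) immediately after tapping, scans 8-10.
    """
    sp = config.schedule_params
    layout = sp.block_layout
    labels = [seg for seg, _ in layout]
    if "tapping" not in labels or "baseline" not in labels:
        raise EDLValidationError("block layout must contain baseline and tapping")

    pairs = [
        (task, region)
        for task in sp.tasks
        for region in (REGION_UPPER, REGION_LOWER)
        for _ in range(sp.targets_per_region_per_task)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    blocks = tuple(Block(pairs[i][0], pairs[i][1], layout) for i in order)

    proto = blocks[0]
    baseline = proto.scans_with_label("baseline")
    tapping = proto.scans_with_label("tapping")
    resp_len = 3  # 6 s of signal at TR 2 s, immediately after tapping
    response = (tapping[-1] + 1, tapping[-1] + resp_len)
    return BlockDesign(blocks, baseline_window=(baseline[0], baseline[-1]),
                       response_window=response)


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters for one simulated subject.

    ``max_amplitude_percent`` is the true maximal BOLD percent signal change
    at the blob centre under full effort; ``controllability`` maps an
    intended effort level in [0, 1] to the realised fraction of that maximum
    (identity by default).
    """

    subject_id: str
    max_amplitude_percent: float = 2.69
    activation_center: tuple[int, int, int] = (32, 32, 15)
    activation_radius: float = 3.0
    noise_sd_percent: float = 0.2
    drift_amplitude_percent: float = 0.1
    drift_period_seconds: float = 120.0
    controllability: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.max_amplitude_percent <= 0:
            raise ValueError("max_amplitude_percent must be positive")
        if self.noise_sd_percent < 0 or self.drift_amplitude_percent < 0:
            raise ValueError("noise/drift amplitudes must be nonnegative")
        if self.drift_period_seconds < 60:
            raise ValueError("drift period must be >= 60 s (slow drift)")

    def realized_fraction(self, effort: float) -> float:
        return effort if self.controllability is None else self.controllability(effort)


@dataclass
class VolumeSeries:
    """A 4D (x, y, z, t) scan series with acquisition metadata."""

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries data must be 4D (x, y, z, t)")
        if np.isnan(self.data).any():
            raise ValueError("VolumeSeries contains NaN")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    def volume(self, scan_index: int) -> np.ndarray:
        """3D volume for a global 1-based scan index."""
        return self.data[..., scan_index - 1]

    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_seconds))
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "VolumeSeries":
        img = nib.load(path)
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            tr_seconds=tr,
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
            affine=np.asarray(img.affine),
        )


def blob_weights(
    shape: tuple[int, int, int], center: tuple[int, int, int], radius: float
) -> np.ndarray:
    """Isotropic Gaussian spatial profile (sigma = radius) truncated at the
    stated radius; 1 at the centre, ~0.61 at the edge, 0 outside."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    w = np.exp(-0.5 * d2 / radius**2)
    w[d2 > radius**2] = 0.0
    return w


def task_regressor(
    design: BlockDesign,
    tr_seconds: float,
    hrf_params: CanonicalHRF | None = None,
    efforts: np.ndarray | None = None,
) -> np.ndarray:
    """Expected fractional activation time course for a design.

    Each block's tapping boxcar is convolved with the canonical HRF and
    normalised so a full-effort block peaks at exactly 1; per-block efforts
    scale each block's contribution and tails superpose linearly.
    """
    kernel = make_hrf(hrf_params, tr_seconds)
    T = design.n_scans
    if efforts is None:
        efforts = np.ones(design.n_blocks)
    efforts = np.asarray(efforts, dtype=float)
    if efforts.shape != (design.n_blocks,):
        raise ValueError("efforts must have one entry per block")

    # unit-effort single-block response, used as the normalisation
    proto = design.blocks[0]
    box = np.zeros(proto.n_scans + len(kernel))
    for s in proto.scans_with_label("tapping"):
        box[s - 1] = 1.0
    norm = np.convolve(box, kernel).max()

    signal = np.zeros(T)
    for b, block in enumerate(design.blocks, start=1):
        taps = design.global_scans(b, block.scans_with_label("tapping"))
        if taps.size == 0:
            continue
        boxcar = np.zeros(T)
        boxcar[taps] = 1.0
        signal += efforts[b - 1] * np.convolve(boxcar, kernel)[:T] / norm
    return signal


def simulate_run(
    design: BlockDesign,
    subject: SubjectProfile,
    site: SiteConfig,
    effort_sequence: np.ndarray | list[float],
    seed: int,
    baseline_intensity: float = 1000.0,
    hrf_params: CanonicalHRF | None = None,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> VolumeSeries:
    """Synthesise one run for one subject at one site.

    Voxels inside the activation blob carry
    ``baseline * (1 + w * amp * regressor / 100)`` where ``w`` is the spatial
    blob weight and ``amp`` the effort-scaled maximal percent change; every
    voxel additionally receives i.i.d. Gaussian noise and a slow sinusoidal
    drift, both expressed in percent of baseline.  Bit-reproducible per seed.
    """
    shape = site.volume_shape
    center, radius = subject.activation_center, subject.activation_radius
    for c, n in zip(center, shape):
        if not (radius <= c <= n - 1 - radius):
            raise ValueError(
                f"activation blob (center {center}, radius {radius}) "
                f"is not fully inside the {shape} volume"
            )
    efforts = np.asarray(
        [subject.realized_fraction(e) for e in np.asarray(effort_sequence, dtype=float)]
    )
    if efforts.shape != (design.n_blocks,):
        raise ValueError("effort_sequence must have one entry per block")

    frac = task_regressor(design, site.tr_seconds, hrf_params, efforts)
    w = blob_weights(shape, center, radius)
    pct = (
        subject.max_amplitude_percent * w[..., None] * frac[None, None, None, :]
    )

    rng = np.random.default_rng(seed)
    T = design.n_scans
    data = baseline_intensity * (1.0 + pct / 100.0)
    if subject.noise_sd_percent > 0:
        data = data + baseline_intensity * (subject.noise_sd_percent / 100.0) * (
            rng.standard_normal((*shape, T))
        )
    if subject.drift_amplitude_percent > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(T) * site.tr_seconds
        drift = np.sin(2 * np.pi * t / subject.drift_period_seconds + phase)
        data = data + baseline_intensity * (subject.drift_amplitude_percent / 100.0) * drift

    return VolumeSeries(data=data, tr_seconds=site.tr_seconds, voxel_size_mm=voxel_size_mm)


class VolumeStream:
    """Causal one-volume-per-TR view of a :class:`VolumeSeries`.

    Iterating yields ``(scan_index, volume)`` with 1-based indices in
    acquisition order; :meth:`get` refuses to return scans that have not been
    yielded yet, enforcing the real-time contract.
    """

    def __init__(self, series: VolumeSeries):
        self.series = series
        self.acquired = 0

    def __iter__(self) -> Iterator[tuple[int, np.ndarray]]:
        for i in range(1, self.series.n_scans + 1):
            self.acquired = i
            yield i, self.series.volume(i)

    def get(self, scan_index: int) -> np.ndarray:
        if scan_index > self.acquired:
            raise CausalityError(
                f"scan {scan_index} requested but only {self.acquired} acquired"
            )
        return self.series.volume(scan_index)


def stream(series: VolumeSeries) -> VolumeStream:
    """Wrap a series in its causal real-time stream."""
    return VolumeStream(series)
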