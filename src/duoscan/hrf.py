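"""Canonical double-gamma hemodynamic response function.

The BOLD response to a brief neural event is modelled as the difference of two
gamma densities: a positive lobe peaking ~6 s after the event and a later
undershoot, scaled down and subtracted.  The same kernel is used both to
synthesise block-design BOLD signals and as the expected-response regressor in
the real-time correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["CanonicalHRF", "make_hrf", "evaluate_hrf"]


@dataclass(frozen=True)
class CanonicalHRF:
    """Parameters of the double-gamma hemodynamic impulse response.

    Attributes
    ----------
    peak_delay, undershoot_delay:
        Time to peak of the positive lobe and of the undershoot, seconds.
    peak_dispersion, undershoot_dispersion:
        Width (gamma scale) of each lobe, seconds.
    undershoot_ratio:
        Amplitude of the undershoot relative to the positive lobe
        (dimensionless; 0 disables the undershoot).
    duration:
        Length of the kernel's support, seconds.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("gamma delays must be positive")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("gamma dispersions must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be nonnegative")
        if self.duration <= self.peak_delay:
            raise ValueError(
                "kernel duration must exceed the peak delay "
                f"({self.duration} s <= {self.peak_delay} s)"
            )


def evaluate_hrf(params: CanonicalHRF, t: np.ndarray) -> np.ndarray:
    """Evaluate the (un-normalised) double-gamma response at times ``t`` (s).

    Negative times map to zero.  Peak amplitude is *not* normalised here;
    :func:`make_hrf` normalises the sampled kernel.
    """
    t = np.asarray(t, dtype=float)
    pos = _gamma_dist.pdf(
        t, a=params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    neg = _gamma_dist.pdf(
        t,
        a=params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = pos - params.undershoot_ratio * neg
    return np.where(t < 0, 0.0, h)


def make_hrf(params: CanonicalHRF | None = None, tr_seconds: float = 2.0) -> np.ndarray:
    """Sample the canonical HRF at the scan repetition time.

    Returns a 1-D kernel sampled at ``t = 0, TR, 2 TR, ... <= duration`` whose
    maximum element is exactly 1.
    """
    if params is None:
        params = CanonicalHRF()
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0.0, params.duration + 0.5 * tr_seconds, tr_seconds)
    t = t[t <= params.duration + 1e-12]
    kernel = evaluate_hrf(params, t)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("sampled kernel has no positive peak; increase duration")
    return kernel / peak
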