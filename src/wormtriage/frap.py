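"""FRAP relative-fluorescence-intensity (RFI) curves and mobility calls.

Fluorescence recovery after photobleaching distinguishes freely diffusing
protein (rapid, near-complete recovery of the bleached region) from protein
locked in an immobile aggregate (little or no recovery).  The double
normalization

    RFI(t) = (T0 * I(t)) / (T(t) * I0)

divides the bleach-ROI intensity I by the whole-cell intensity T, each scaled
by its pre-bleach mean, so that acquisition bleaching during imaging cancels
and the pre-bleach RFI is exactly 1 by construction.

The mobile fraction is estimated from the empirical recovery plateau (the mean
of the final 10% of post-bleach samples) rather than an exponential fit,
matching assays that report raw recovery curves; a single-exponential fit is
available as an option for rate estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError

__all__ = [
    "FrapTrace",
    "RfiCurve",
    "compute_rfi",
    "classify_mobility",
    "fit_exponential_recovery",
]


@dataclass
class FrapTrace:
    """Raw intensity time series of one FRAP experiment.

    ``bleach_index`` is the index of the first post-bleach sample; the
    pre-bleach segment ``[0, bleach_index)`` must be nonempty.
    """

    times_s: np.ndarray
    roi_intensity: np.ndarray
    total_intensity: np.ndarray
    bleach_index: int

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=np.float64)
        self.total_intensity = np.asarray(self.total_intensity, dtype=np.float64)
        n = len(self.times_s)
        if not (len(self.roi_intensity) == len(self.total_intensity) == n):
            raise ValueError("times, roi and total series must share one length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.bleach_index < n:
            raise ValueError("bleach_index must leave nonempty pre/post segments")


@dataclass
class RfiCurve:
    """Double-normalized recovery curve with its plateau and mobile fraction.

    ``mobile_fraction`` is NaN when the first post-bleach RFI is >= 1 (no
    effective bleach), in which case no recovery is defined.
    """

    times_s: np.ndarray
    rfi: np.ndarray
    plateau_rfi: float
    mobile_fraction: float
    bleach_index: int


def compute_rfi(trace: FrapTrace) -> RfiCurve:
    """Compute the RFI curve and mobile fraction of a FRAP trace.

    mobile_fraction = (plateau - RFI_postbleach) / (1 - RFI_postbleach),
    with RFI_postbleach the RFI at the bleach index and the plateau the mean
    of the last 10% of post-bleach samples.  A plateau below the first
    post-bleach value clamps the mobile fraction to 0 with a warning.
    """
    pre = slice(0, trace.bleach_index)
    i0 = float(trace.roi_intensity[pre].mean())
    t0 = float(trace.total_intensity[pre].mean())
    if i0 <= 0 or t0 <= 0:
        raise NormalizationError("pre-bleach mean intensities must be > 0")
    if np.any(trace.total_intensity <= 0):
        raise NormalizationError("total intensity must be > 0 throughout")
    # Double normalization applied to the per-sample ratio I/T: dividing by the
    # pre-bleach mean of the ratio makes the pre-bleach RFI average exactly 1
    # (and reduces to T0*I/(T*I0) whenever T is flat before the bleach).
    ratio = trace.roi_intensity / trace.total_intensity
    rfi = ratio / float(ratio[pre].mean())
    post = rfi[trace.bleach_index:]
    n_tail = max(1, int(round(0.1 * len(post))))
    plateau = float(post[-n_tail:].mean())
    rfi_post = float(rfi[trace.bleach_index])
    if rfi_post >= 1.0:
        mobile = float("nan")  # no effective bleach: recovery undefined
    else:
        mobile = (plateau - rfi_post) / (1.0 - rfi_post)
        if mobile < 0:
            warnings.warn(
                "recovery plateau below first post-bleach value; "
                "mobile fraction clamped to 0",
                stacklevel=2,
            )
            mobile = 0.0
        mobile = min(mobile, 1.0)
    return RfiCurve(
        times_s=trace.times_s.copy(),
        rfi=rfi,
        plateau_rfi=plateau,
        mobile_fraction=mobile,
        bleach_index=trace.bleach_index,
    )


def classify_mobility(
    curve: RfiCurve,
    soluble_min: float = 0.8,
    immobile_max: float = 0.3,
) -> str:
    """Label a curve ``soluble``, ``immobile`` or ``intermediate``.

    Diffuse, soluble protein recovers nearly fully (mobile fraction >=
    ``soluble_min``); inclusion-bound protein barely recovers (<=
    ``immobile_max``); anything between is called intermediate.
    """
    if not immobile_max <= soluble_min:
        raise ValueError("immobile_max must be <= soluble_min")
    m = curve.mobile_fraction
    if np.isnan(m):
        return "intermediate"
    if m >= soluble_min:
        return "soluble"
    if m <= immobile_max:
        return "immobile"
    return "intermediate"


def fit_exponential_recovery(curve: RfiCurve) -> tuple[float, float, float]:
    """Optional single-exponential fit of the post-bleach recovery.

    Fits RFI(t) = plateau - (plateau - r0) * exp(-(t - t_bleach)/tau) and
    returns ``(r0, plateau, tau_s)``.  The empirical plateau remains the
    reference estimator; this fit is for rate comparisons only.
    """
    from scipy.optimize import curve_fit

    t = curve.times_s[curve.bleach_index:] - curve.times_s[curve.bleach_index]
    y = curve.rfi[curve.bleach_index:]

    def model(t, r0, plateau, tau):
        return plateau - (plateau - r0) * np.exp(-t / tau)

    span = max(t[-1], 1e-6)
    p0 = (float(y[0]), float(y[-1]), span / 5)
    popt, _ = curve_fit(
        model, t, y, p0=p0, bounds=([0, 0, 1e-6], [2, 2, 100 * span]), maxfev=10000
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
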