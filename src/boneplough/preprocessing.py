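"""Cleaning and summarising raw dynamometer force traces.

A ploughing trial records normal (Fz) and tangential (Fp) force channels at
1 kHz while the tool strokes through the bone sample.  Instrument error shows
up as isolated spikes, removed with a Hampel filter (rolling median / MAD
outlier replacement).  The engaged, steady-state part of the stroke is then
located and the channels summarised into per-trial means, the quantities the
calibration stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ForceTrace",
    "TrialSummary",
    "NoCutError",
    "hampel_filter",
    "segment_steady_state",
    "summarize_trial",
]

MAD_SCALE = 1.4826  # normal-consistency constant: sigma ~= 1.4826 * MAD


class NoCutError(RuntimeError):
    """Raised when a trace contains no detectable engaged (cutting) region."""


@dataclass
class ForceTrace:
    """One trial's raw force channels on a uniform time grid.

    time in seconds (uniform, strictly increasing); fz/fp in N; metadata keys
    follow the manifest dialect (h_mm, theta_deg, speed_mm_min, replicate,
    trial_id).  ``ground_truth`` is populated by the synthetic generator only.
    """

    time: np.ndarray
    fz: np.ndarray
    fp: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        self.fp = np.asarray(self.fp, dtype=float)
        n = self.time.size
        if n < 3:
            raise ValueError("trace must hold at least 3 samples")
        if self.fz.size != n or self.fp.size != n:
            raise ValueError("channel lengths must match the time grid")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 1e-9:
            raise ValueError("time grid must be uniform to within 1e-9 s")

    @property
    def sampling_hz(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass(frozen=True)
class TrialSummary:
    """Steady-state force summary of one trial."""

    h: float
    theta: float
    Fz_mean: float
    Fp_mean: float
    Fz_sd: float
    Fp_sd: float
    n_samples_used: int
    fp_observed: float
    trial_id: str = ""
    replicate: int = 0


def _rolling_median_mad(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling median and MAD with half-width w; windows truncated at the ends."""
    n = x.size
    med = np.empty(n)
    mad = np.empty(n)
    full = 2 * w + 1
    win = np.lib.stride_tricks.sliding_window_view(x, full)
    m = np.median(win, axis=1)
    med[w : n - w] = m
    mad[w : n - w] = np.median(np.abs(win - m[:, None]), axis=1)
    for i in list(range(w)) + list(range(n - w, n)):
        seg = x[max(0, i - w) : min(n, i + w + 1)]
        mi = np.median(seg)
        med[i] = mi
        mad[i] = np.median(np.abs(seg - mi))
    return med, mad


def hampel_filter(
    series: np.ndarray,
    window: int = 5,
    k: float = 3.0,
    until_converged: bool = False,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Hampel outlier filter: replace points far from the rolling median.

    A sample deviating from the rolling median by more than
    ``k * 1.4826 * MAD`` (MAD over the same window) is replaced by that
    median.  ``window`` is the half-width in samples, so each interior window
    spans ``2*window + 1`` samples; windows are truncated at the series ends
    rather than padded.  When the window MAD is zero, any nonzero deviation is
    flagged.

    The default is the standard single pass.  Replacing an outlier shrinks
    the local MAD, so on noisy signals a second pass can flag further
    borderline samples; ``until_converged=True`` re-applies the pass to a
    fixed point, which makes the operation idempotent on any input.  On
    signals that are clean apart from isolated spikes the single pass is
    already a fixed point.

    Returns ``(filtered, mask)`` where ``mask`` marks every replaced index.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window (half-width) must be >= 1")
    if x.size <= 2 * window:
        raise ValueError(
            f"series length {x.size} too short for half-width {window} "
            f"(need > {2 * window})"
        )
    w = int(window)
    mask = np.zeros(x.size, dtype=bool)
    current = x
    for _ in range(max_iter if until_converged else 1):
        med, mad = _rolling_median_mad(current, w)
        flag = np.abs(current - med) > k * MAD_SCALE * mad
        if until_converged and not flag.any():
            break
        mask |= flag
        current = np.where(flag, med, current)
    return current, mask


def segment_steady_state(
    trace: ForceTrace,
    trim_fraction: float = 0.1,
    threshold_fraction: float = 0.1,
) -> tuple[int, int]:
    """Locate the steady-state window of the engaged stroke.

    Engagement is the longest contiguous run where the normal channel exceeds
    ``threshold_fraction`` of its robust maximum (95th percentile); the run is
    then trimmed to its central ``1 - 2*trim_fraction`` portion, which drops
    the entry/exit ramps.  Returns half-open sample indices ``(start, stop)``.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    fz = trace.fz
    robust_max = np.percentile(fz, 95)
    if robust_max <= 0:
        raise NoCutError("no engaged region: normal force never rises above zero")
    above = fz > threshold_fraction * robust_max
    if not above.any():
        raise NoCutError("no engaged region above the engagement threshold")
    # longest contiguous True run
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    idx = int(np.argmax(stops - starts))
    start, stop = int(starts[idx]), int(stops[idx])
    run = stop - start
    cut = int(np.floor(run * trim_fraction))
    start2, stop2 = start + cut, stop - cut
    if stop2 - start2 < 1:
        raise NoCutError("engaged region too short after trimming")
    return start2, stop2


def summarize_trial(
    trace: ForceTrace,
    window: int = 5,
    k: float = 3.0,
    trim_fraction: float = 0.1,
) -> TrialSummary:
    """Filter both channels, segment the steady state, and summarise.

    The Hampel filter runs on each channel; segmentation uses the filtered
    normal channel; means/SDs (ddof=1) are taken over the retained window.
    ``fp_observed`` is the ratio of the channel means, the per-trial estimate
    of the ploughing coefficient.
    """
    fz_f, _ = hampel_filter(trace.fz, window=window, k=k)
    fp_f, _ = hampel_filter(trace.fp, window=window, k=k)
    clean = ForceTrace(
        time=trace.time,
        fz=fz_f,
        fp=fp_f,
        metadata=trace.metadata,
        ground_truth=trace.ground_truth,
    )
    start, stop = segment_steady_state(clean, trim_fraction=trim_fraction)
    fz_w = fz_f[start:stop]
    fp_w = fp_f[start:stop]
    n = stop - start
    fz_mean = float(np.mean(fz_w))
    fp_mean = float(np.mean(fp_w))
    meta = trace.metadata
    return TrialSummary(
        h=float(meta.get("h_mm", np.nan)),
        theta=float(meta.get("theta_deg", np.nan)),
        Fz_mean=fz_mean,
        Fp_mean=fp_mean,
        Fz_sd=float(np.std(fz_w, ddof=1)) if n > 1 else 0.0,
        Fp_sd=float(np.std(fp_w, ddof=1)) if n > 1 else 0.0,
        n_samples_used=n,
        fp_observed=fp_mean / fz_mean,
        trial_id=str(meta.get("trial_id", "")),
        replicate=int(meta.get("replicate", 0)),
    )
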