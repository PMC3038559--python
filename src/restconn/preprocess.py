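"""Temporal preprocessing of ROI time series.

Signal-level chain applied per subject before connectivity analysis:
drop leading volumes acquired before scanner equilibrium, remove the
linear drift and temporal mean, express the signal as fractional change
about its raw temporal mean, and band-pass to the slow-fluctuation band
(0.01-0.08 Hz) where resting-state synchrony lives.

Spatial operations (smoothing, masking, registration) are out of scope:
the pipeline starts from extracted ROI series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dataset import ROITimeSeriesSet

__all__ = [
    "PreprocessConfig",
    "discard_initial",
    "detrend_and_demean",
    "bandpass",
    "signal_change_ratio",
    "temporal_means",
    "preprocess",
]

logger = logging.getLogger(__name__)

#: Stage order applied by :func:`preprocess`.  The signal-change ratio is
#: formed with the per-ROI temporal mean captured *before* detrending.
PIPELINE_ORDER = ("discard", "detrend", "signal_ratio", "bandpass", "demean")


@dataclass(frozen=True)
class PreprocessConfig:
    """Temporal-preprocessing parameters.

    ``discard_initial`` leading volumes are dropped (scanner
    calibration); the pass band is ``[band_low_hz, band_high_hz]`` and
    must sit strictly below the Nyquist frequency ``1/(2 TR)``.
    """

    discard_initial: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    do_detrend: bool = True
    do_demean: bool = True
    do_signal_ratio: bool = True
    do_bandpass: bool = True
    ratio_percent: bool = False

    def validate(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if not 0 <= self.band_low_hz < self.band_high_hz:
            raise ValueError(
                f"need 0 <= band_low_hz < band_high_hz, got "
                f"[{self.band_low_hz}, {self.band_high_hz}]"
            )
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} Hz must be below the "
                f"Nyquist frequency {nyquist} Hz at TR={tr_seconds} s"
            )
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be non-negative")


def discard_initial(ts: ROITimeSeriesSet, k: int) -> ROITimeSeriesSet:
    """Drop the first ``k`` time points of every subject."""
    if k == 0:
        return ts
    for sid, mat in ts:
        if k >= mat.shape[0]:
            raise ValueError(
                f"cannot discard {k} initial time points from subject "
                f"{sid!r} with only {mat.shape[0]} points"
            )
    return ts.map_subjects(lambda m: m[k:])


def _detrend_matrix(mat: np.ndarray, roi_labels, sid: str) -> np.ndarray:
    sd = mat.std(axis=0)
    degenerate = np.where(sd == 0)[0]
    for j in degenerate:
        warnings.warn(
            f"subject {sid!r}, ROI {roi_labels[j]!r}: constant series; "
            "detrended output is all zeros",
            stacklevel=3,
        )
    # OLS line against the time index, then residual (mean-zero by construction)
    out = sps.detrend(mat, axis=0, type="linear")
    out[:, degenerate] = 0.0
    return out


def detrend_and_demean(ts: ROITimeSeriesSet) -> ROITimeSeriesSet:
    """Subtract the best-fitting line and the temporal mean per ROI."""
    for sid, mat in ts:
        if mat.shape[0] < 3:
            raise ValueError(f"subject {sid!r}: need >= 3 time points to detrend")
    return ts.with_data(
        [_detrend_matrix(mat, ts.roi_labels, sid) for sid, mat in ts]
    )


def demean(ts: ROITimeSeriesSet) -> ROITimeSeriesSet:
    """Remove the per-ROI temporal mean."""
    return ts.map_subjects(lambda m: m - m.mean(axis=0))


def bandpass(
    ts: ROITimeSeriesSet, low_hz: float = 0.01, high_hz: float = 0.08
) -> ROITimeSeriesSet:
    """Zero-phase band-pass (second-order Butterworth, forward-backward).

    Full series length is preserved (filtfilt padding); a mid-band
    sinusoid retains essentially all of its amplitude while components
    well outside the band are suppressed.
    """
    nyquist = ts.nyquist_hz
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] Hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} Hz must be below Nyquist {nyquist} Hz "
            f"at TR={ts.tr_seconds} s"
        )
    b, a = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds)
    # Gustafsson initial conditions: odd-signal padding leaks stop-band
    # energy back in at the edges for series shorter than the low-cutoff
    # period, which these 190-point runs always are.  The temporal mean
    # is removed first — DC is outside any pass band, and the
    # least-squares initial conditions otherwise smear a large offset
    # into the edges.
    return ts.map_subjects(
        lambda m: sps.filtfilt(b, a, m - m.mean(axis=0), axis=0, method="gust")
    )


def temporal_means(ts: ROITimeSeriesSet) -> list[np.ndarray]:
    """Per-subject vector of raw per-ROI temporal means."""
    return [mat.mean(axis=0) for _, mat in ts]


def signal_change_ratio(
    ts: ROITimeSeriesSet,
    means: list[np.ndarray] | None = None,
    percent: bool = False,
    mean_tol: float = 1e-8,
) -> ROITimeSeriesSet:
    """Express each series as fractional change ``(x - mu) / mu``.

    ``mu`` is the per-ROI temporal mean — of the data itself, or, when
    the ratio is taken after drift/mean removal, the stored raw means
    passed via ``means``.  With ``percent=True`` the ratio is scaled by
    100 (the AFNI convention); correlations are invariant to either
    choice.
    """
    if means is None:
        means = temporal_means(ts)
    scale = 100.0 if percent else 1.0
    out = []
    for (sid, mat), mu in zip(ts, means):
        bad = np.where(np.abs(mu) <= mean_tol)[0]
        if bad.size:
            names = ", ".join(ts.roi_labels[j] for j in bad)
            raise ValueError(
                f"subject {sid!r}: temporal mean of ROI(s) {names} is zero "
                "within tolerance; cannot form a signal-change ratio"
            )
        out.append(scale * (mat - mu) / mu)
    return ts.with_data(out)


def preprocess(
    ts: ROITimeSeriesSet, config: PreprocessConfig | None = None
) -> ROITimeSeriesSet:
    """Run the full temporal chain in the fixed order.

    discard -> detrend -> signal-ratio (with pre-detrend means) ->
    band-pass -> demean.  Stages are individually switchable through the
    config; the executed order is logged.
    """
    config = config or PreprocessConfig()
    config.validate(ts.tr_seconds)
    executed = []
    if config.discard_initial:
        ts = discard_initial(ts, config.discard_initial)
        executed.append(f"discard({config.discard_initial})")
    raw_means = temporal_means(ts)
    if config.do_detrend:
        ts = detrend_and_demean(ts)
        executed.append("detrend")
    if config.do_signal_ratio:
        ts = signal_change_ratio(ts, means=raw_means, percent=config.ratio_percent)
        executed.append("signal_ratio")
    if config.do_bandpass:
        ts = bandpass(ts, config.band_low_hz, config.band_high_hz)
        executed.append(f"bandpass({config.band_low_hz}-{config.band_high_hz} Hz)")
    if config.do_demean:
        ts = demean(ts)
        executed.append("demean")
    logger.info("preprocessing chain: %s", " -> ".join(executed) or "none")
    return ts
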