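"""Raw fluorescence → bleach-corrected ΔF/F.

Per unit and trial, ΔF/F at frame *i* is ``(F_i − F_B) / F_B`` with the
background ``F_B`` the mean raw fluorescence over a pre-stimulus window
(default frames [10, 25), i.e. 15 frames before odorant onset).
Photobleaching is then removed by fitting ``F(t) = a·exp(b·t) + c`` to each
ΔF/F trace and subtracting the fit; by default the fit excludes the response
epoch (stimulus plus 5 s), because a large calcium transient inside the fit
window biases the decay-rate estimate — a full-trace mode is available.

The exponential fit is exposed both as a statsmodels-style model
(:class:`BleachModel` → :class:`BleachFit` via ``fit()``) and as the plain
function :func:`fit_bleach`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .traceset import TraceSet

__all__ = ["DffParams", "compute_dff", "BleachModel", "BleachFit", "fit_bleach",
           "subtract_bleach", "correct_bleaching"]

log = logging.getLogger(__name__)


@dataclass
class DffParams:
    """ΔF/F conversion parameters.

    ``background_window`` is a half-open, 0-based frame range strictly before
    the stimulus onset; its mean defines F_B.
    """

    background_window: tuple[int, int] = (10, 25)

    def __post_init__(self):
        self.background_window = tuple(self.background_window)

    def validate(self, stim_onset_frame: int | None = None) -> None:
        lo, hi = self.background_window
        if hi <= lo or lo < 0:
            raise ValueError("background_window must be a non-empty half-open range")
        if stim_onset_frame is not None and hi > stim_onset_frame:
            raise ValueError("background_window must end before stimulus onset")


def compute_dff(raw: TraceSet, params: DffParams | None = None) -> TraceSet:
    """Convert raw fluorescence to ΔF/F.

    Units whose background mean F_B is zero, negative or non-finite in any
    trial cannot be normalized; they are dropped with a log entry (keeping
    them would break pattern comparability across trials).
    """
    if raw.signal_kind != "raw":
        raise ValueError("compute_dff expects raw fluorescence")
    params = params or DffParams()
    params.validate(raw.stim_onset_frame)
    lo, hi = params.background_window
    fb = raw.data[:, lo:hi, :].mean(axis=1)               # (units, stimuli)
    bad = ~np.isfinite(fb) | (fb <= 0)
    keep = np.flatnonzero(~bad.any(axis=1))
    if keep.size < raw.n_units:
        log.warning("compute_dff: dropped %d units with invalid background F_B",
                    raw.n_units - keep.size)
    data = raw.data[keep]
    fb = fb[keep]
    dff = (data - fb[:, None, :]) / fb[:, None, :]
    return dataclasses.replace(
        raw,
        data=dff,
        units=raw.units.iloc[keep].reset_index(drop=True),
        signal_kind="dff",
    )


@dataclass
class BleachFit:
    """Result of an exponential-decay fit ``F(t) = a·exp(b·t) + c``.

    ``b`` is in 1/frame and is expected to be ≤ 0 for photobleaching; a
    positive estimate triggers a warning (possible focus drift) but is kept.
    ``fallback_linear`` flags traces where the exponential fit failed and a
    linear trend (with ``b`` pinned to a small negative constant) was used.
    """

    a: float
    b: float
    c: float
    fit_window: np.ndarray
    residual_rms: float
    fallback_linear: bool = False
    pinned_b: bool = False

    def predict(self, frames) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(frames, dtype=float)) + self.c

    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def summary(self) -> str:
        kind = "linear fallback" if self.fallback_linear else "exponential"
        return (f"BleachFit ({kind}): a={self.a:.4g}, b={self.b:.4g}/frame, "
                f"c={self.c:.4g}, residual RMS={self.residual_rms:.4g} "
                f"({self.fit_window.size} frames)")


class BleachModel:
    """Exponential photobleaching model for a single trace.

    Parameters
    ----------
    trace
        Per-frame ΔF/F (or intensity-change) series.
    fit_window
        Frame indices used for the fit (array of indices or half-open
        ``(lo, hi)`` tuple).  Must contain at least 4 frames.
    """

    def __init__(self, trace, fit_window=None):
        self.trace = np.asarray(trace, dtype=float)
        if fit_window is None:
            idx = np.arange(self.trace.size)
        elif isinstance(fit_window, tuple) and len(fit_window) == 2:
            idx = np.arange(*fit_window)
        else:
            idx = np.asarray(fit_window, dtype=int)
        if idx.size < 4:
            raise ValueError("fit_window must contain at least 4 frames "
                             "(3 parameters + 1)")
        self.fit_window = idx

    def fit(self) -> BleachFit:
        t = self.fit_window.astype(float)
        y = self.trace[self.fit_window]
        # deterministic initialization: amplitude from endpoints, rate from
        # the log-ratio of the first/last thirds, offset from the last value
        third = max(t.size // 3, 1)
        y0, y1 = y[:third].mean(), y[-third:].mean()
        a0 = y[0] - y[-1]
        c0 = y[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            num, den = y0 - c0, y1 - c0
            if np.isfinite(num) and np.isfinite(den) and num * den > 0:
                b0 = np.log(abs(den / num)) / (t[-third:].mean() - t[:third].mean())
            else:
                b0 = -1.0 / max(t[-1] - t[0], 1.0)
        b0 = min(b0, -1e-6)

        def model(tt, a, b, c):
            return a * np.exp(b * tt) + c

        try:
            popt, _ = curve_fit(model, t, y, p0=(a0, b0, c0), maxfev=10000)
            a, b, c = popt
            resid = y - model(t, *popt)
            fit = BleachFit(a, b, c, self.fit_window,
                            float(np.sqrt(np.mean(resid**2))))
        except (RuntimeError, ValueError):
            # non-convergence: linear trend with b pinned small and negative
            slope, intercept = np.polyfit(t, y, 1)
            b = -1e-4
            a = -slope / b * np.exp(-b * t.mean())         # matches slope at center
            c = intercept + slope * t.mean() - a * np.exp(b * t.mean())
            resid = y - (a * np.exp(b * t) + c)
            fit = BleachFit(a, b, c, self.fit_window,
                            float(np.sqrt(np.mean(resid**2))), fallback_linear=True)
            log.warning("BleachModel: exponential fit failed, linear fallback used")
        if fit.b > 0:
            log.warning("BleachModel: fitted b=%.3g > 0 (possible focus drift)", fit.b)
        return fit


def fit_bleach(trace, fit_window=None) -> BleachFit:
    """Least-squares fit of ``a·exp(b·t) + c`` over ``fit_window``."""
    return BleachModel(trace, fit_window).fit()


def response_free_window(ts: TraceSet, post_margin_s: float = 5.0) -> np.ndarray:
    """Frame indices outside [stimulus onset, offset + margin]."""
    hi = ts.stim_offset_frame + int(round(post_margin_s * ts.frame_rate))
    idx = np.arange(ts.n_frames)
    return idx[(idx < ts.stim_onset_frame) | (idx > hi)]


def subtract_bleach(traces: TraceSet, fits, params: DffParams | None = None) -> TraceSet:
    """Subtract fitted bleach curves and re-zero the background window.

    ``fits`` maps ``(unit_index, stimulus_index)`` to a :class:`BleachFit`
    (or is a 2-D object array indexed the same way); a missing fit is an
    error.
    """
    if traces.signal_kind != "dff":
        raise ValueError("subtract_bleach expects ΔF/F traces")
    params = params or DffParams()
    lo, hi = params.background_window
    frames = np.arange(traces.n_frames, dtype=float)
    out = traces.data.copy()
    for u in range(traces.n_units):
        for s in range(traces.n_stimuli):
            try:
                fit = fits[u, s] if not isinstance(fits, dict) else fits[(u, s)]
            except (KeyError, IndexError) as exc:
                raise ValueError(f"missing bleach fit for unit {u}, stimulus {s}") from exc
            if fit is None:
                raise ValueError(f"missing bleach fit for unit {u}, stimulus {s}")
            out[u, :, s] -= fit.predict(frames)
    out -= out[:, lo:hi, :].mean(axis=1, keepdims=True)
    return dataclasses.replace(traces, data=out, signal_kind="dff_corrected")


def _pinned_fit(trace: np.ndarray, pre: np.ndarray, b: float,
                full_window: np.ndarray) -> BleachFit:
    """Linear solve of (a, c) on the pre-stimulus frames with b fixed.

    Used for traces whose late window carries genuine post-odor activity:
    only the pre-stimulus segment is guaranteed response-free, which cannot
    identify the decay rate on its own, so b is borrowed from the clean
    traces of the same recording.
    """
    t = pre.astype(float)
    design = np.column_stack([np.exp(b * t), np.ones_like(t)])
    (a, c), *_ = np.linalg.lstsq(design, trace[pre], rcond=None)
    resid = trace[pre] - design @ np.array([a, c])
    return BleachFit(float(a), b, float(c), pre,
                     float(np.sqrt(np.mean(resid**2))), pinned_b=True)


def correct_bleaching(traces: TraceSet, params: DffParams | None = None,
                      exclude_response: bool = True,
                      post_margin_s: float = 5.0,
                      contamination_sd: float = 2.57):
    """Fit and subtract photobleaching for every unit × trial.

    Returns ``(corrected TraceSet, fits table)``; the table has one row per
    unit × stimulus with the fitted (a, b, c), residual RMS and flags.  With
    ``exclude_response`` (default) the fit window omits the stimulus epoch
    plus ``post_margin_s`` seconds so the response transient does not bias
    the decay estimate; ``exclude_response=False`` fits the full trace.

    Persistent (prolonged/off-type) responses can outlast the excluded
    epoch, in which case the late fit segment is itself response
    contaminated and a free exponential fit would chase the response rather
    than the bleach.  Traces whose late-segment mean exceeds the
    pre-stimulus mean by ``contamination_sd`` × pre-stimulus SD are
    therefore refit with the decay rate b pinned to the median b of the
    recording's uncontaminated traces and (a, c) estimated from the
    pre-stimulus frames alone (``pinned_b`` flag in the output table).
    """
    if traces.signal_kind != "dff":
        raise ValueError("correct_bleaching expects ΔF/F traces")
    params = params or DffParams()
    window = (response_free_window(traces, post_margin_s) if exclude_response
              else np.arange(traces.n_frames))
    pre = np.arange(traces.stim_onset_frame)
    late = window[window >= traces.stim_onset_frame]

    # contamination screen: genuine bleach only lowers the late segment.
    # The noise floor comes from first differences of the pre-stimulus
    # segment (insensitive to the bleach trend itself).
    contaminated = np.zeros((traces.n_units, traces.n_stimuli), dtype=bool)
    if exclude_response and late.size:
        for u in range(traces.n_units):
            for s in range(traces.n_stimuli):
                tr = traces.data[u, :, s]
                sigma = np.diff(tr[pre]).std(ddof=1) / np.sqrt(2.0)
                mean_lift = tr[late].mean() - tr[pre].mean()
                max_lift = tr[late].max() - tr[pre].mean()
                contaminated[u, s] = (mean_lift > contamination_sd * sigma
                                      or max_lift > 2 * contamination_sd * sigma)

    fits = np.empty((traces.n_units, traces.n_stimuli), dtype=object)
    clean_b = []
    for u in range(traces.n_units):
        for s in range(traces.n_stimuli):
            if not contaminated[u, s]:
                fit = BleachModel(traces.data[u, :, s], window).fit()
                fits[u, s] = fit
                clean_b.append(fit.b)
    if contaminated.any():
        pinned = float(np.median(clean_b)) if clean_b else -1e-3
        if not clean_b:
            log.warning("correct_bleaching: no uncontaminated traces; "
                        "pinning b to %.3g", pinned)
        else:
            log.info("correct_bleaching: %d / %d traces response-contaminated; "
                     "b pinned to median of clean fits (%.4g)",
                     int(contaminated.sum()), contaminated.size, pinned)
        for u, s in zip(*np.nonzero(contaminated)):
            fits[u, s] = _pinned_fit(traces.data[:, :, s][u], pre, pinned, window)

    rows = []
    for u in range(traces.n_units):
        for s in range(traces.n_stimuli):
            fit = fits[u, s]
            rows.append(
                {
                    "animal": traces.units["animal"].iloc[u],
                    "unit": traces.units["unit"].iloc[u],
                    "odor": traces.stimuli["odor"].iloc[s],
                    "trial": traces.stimuli["trial"].iloc[s],
                    "a": fit.a, "b": fit.b, "c": fit.c,
                    "residual_rms": fit.residual_rms,
                    "fallback_linear": fit.fallback_linear,
                    "pinned_b": fit.pinned_b,
                }
            )
    corrected = subtract_bleach(traces, fits, params)
    return corrected, pd.DataFrame(rows)
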