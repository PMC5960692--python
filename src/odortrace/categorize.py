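"""Categorization of response dynamics: on / off / prolonged / none.

A response threshold is set per trace as 2.57 × SD of the pre-stimulus
signal (the one-sided normal p < 0.005 level).  The decision tree:

1. If the trace crosses the threshold during the stimulus (at least
   ``min_crossing_frames`` consecutive frames): let M be the maximum ΔF/F in
   the stimulus window.  If the trace falls below ``decay_fraction × M``
   (default 1/e ≈ 37%) at any frame within 5 s after odorant offset the
   response is **on**, otherwise **prolonged**.
2. Otherwise, if the mean ΔF/F in a 1-s window centered 5 s after offset
   exceeds the threshold, the response is **off**.
3. Otherwise **none**.

Thresholds are one-sided positive: purely inhibitory (negative-going)
responses are labeled none.  Per-trial labels are combined into a unit × odor
label by majority across trials, ties broken toward the weaker claim
(none < on < off < prolonged).

``min_crossing_frames`` defaults to 2: with a per-frame false-positive rate
of 0.5% the single-frame rule would spuriously flag ~20% of silent traces
somewhere inside a 50-frame stimulus window, while two consecutive
supra-threshold frames keep the per-trace false-positive rate near 0.1%
without affecting genuine responses; set it to 1 for the literal
single-frame-crossing rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traceset import TraceSet

__all__ = ["CategorizeConfig", "response_threshold", "categorize_response",
           "ResponseCategorizer", "CategorizeResults", "category_fractions"]

log = logging.getLogger(__name__)

LABELS = ("on", "off", "prolonged", "none")
#: tie-break order, weakest claim first
LABEL_STRENGTH = {"none": 0, "on": 1, "off": 2, "prolonged": 3}


@dataclass
class CategorizeConfig:
    threshold_multiplier: float = 2.57
    decay_fraction: float = 1.0 / math.e
    post_eval_delay_s: float = 5.0
    #: frame range for the pre-stimulus SD; defaults to the ΔF/F background window
    pre_window: tuple[int, int] = (10, 25)
    off_eval_width_s: float = 1.0
    min_crossing_frames: int = 2
    #: "any_frame": below decay_fraction·M at any frame within the delay;
    #: "endpoint": only the value at offset + delay is examined
    decay_rule: str = "any_frame"
    #: "window_mean": mean of the off window vs threshold;
    #: "any_crossing": any crossing within the whole post-offset delay
    off_rule: str = "window_mean"

    def __post_init__(self):
        self.pre_window = tuple(self.pre_window)

    def validate(self) -> None:
        if not 0 < self.decay_fraction < 1:
            raise ValueError("decay_fraction must lie in (0, 1)")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.post_eval_delay_s <= 0:
            raise ValueError("post_eval_delay_s must be > 0")
        if self.pre_window[1] - self.pre_window[0] < 2:
            raise ValueError("pre_window needs at least 2 frames")
        if self.min_crossing_frames < 1:
            raise ValueError("min_crossing_frames must be ≥ 1")
        if self.decay_rule not in ("any_frame", "endpoint"):
            raise ValueError("decay_rule must be 'any_frame' or 'endpoint'")
        if self.off_rule not in ("window_mean", "any_crossing"):
            raise ValueError("off_rule must be 'window_mean' or 'any_crossing'")


def response_threshold(trace, cfg: CategorizeConfig | None = None) -> float:
    """``threshold_multiplier × sample SD`` of the pre-stimulus window.

    Uses the n−1 (sample) SD.  A constant pre-stimulus segment yields a
    threshold of 0 with a warning: any positive deflection then counts as a
    crossing.
    """
    cfg = cfg or CategorizeConfig()
    lo, hi = cfg.pre_window
    seg = np.asarray(trace, dtype=float)[lo:hi]
    sd = seg.std(ddof=1)
    if sd == 0:
        log.warning("response_threshold: zero pre-stimulus variance, threshold 0")
    return cfg.threshold_multiplier * sd


def _has_crossing(segment: np.ndarray, threshold: float, min_frames: int) -> bool:
    above = segment > threshold
    if min_frames <= 1:
        return bool(above.any())
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= min_frames:
            return True
    return False


def categorize_response(trace, stim_window: tuple[int, int],
                        cfg: CategorizeConfig | None = None,
                        frame_rate: float = 5.0) -> dict:
    """Label one trace and return the decision diagnostics.

    Returns a dict with ``label``, ``threshold``, ``stim_max`` (max ΔF/F in
    the stimulus window), ``post_value`` (ΔF/F at the post-evaluation point)
    and ``ratio`` (post_value / stim_max).  NaN frames inside the decision
    windows force the label ``none`` with ``flagged=True``.
    """
    cfg = cfg or CategorizeConfig()
    cfg.validate()
    trace = np.asarray(trace, dtype=float)
    onset, offset = stim_window
    delay = int(round(cfg.post_eval_delay_s * frame_rate))
    eval_point = offset + delay
    if eval_point >= trace.size:
        raise ValueError("trace does not cover the stimulus window plus the "
                         "post-evaluation delay")

    half = int(round(cfg.off_eval_width_s * frame_rate)) // 2
    off_lo, off_hi = eval_point - half, eval_point + half + 1
    stim_seg = trace[onset:offset]
    decay_seg = trace[offset + 1 : eval_point + 1]        # (offset, offset+delay]
    off_seg = trace[off_lo:off_hi]
    if (np.isnan(stim_seg).any() or np.isnan(decay_seg).any()
            or np.isnan(off_seg).any()):
        return {"label": "none", "threshold": np.nan, "stim_max": np.nan,
                "post_value": np.nan, "ratio": np.nan, "flagged": True}

    thr = response_threshold(trace, cfg)
    stim_max = float(stim_seg.max())
    post_value = float(trace[eval_point])
    ratio = post_value / stim_max if stim_max != 0 else np.nan

    if _has_crossing(stim_seg, thr, cfg.min_crossing_frames):
        if cfg.decay_rule == "any_frame":
            declined = bool((decay_seg < cfg.decay_fraction * stim_max).any())
        else:
            declined = post_value < cfg.decay_fraction * stim_max
        label = "on" if declined else "prolonged"
    else:
        if cfg.off_rule == "window_mean":
            off_resp = float(off_seg.mean()) > thr
        else:
            off_resp = _has_crossing(decay_seg, thr, cfg.min_crossing_frames)
        label = "off" if off_resp else "none"
    return {"label": label, "threshold": thr, "stim_max": stim_max,
            "post_value": post_value, "ratio": ratio, "flagged": False}


def _majority(labels) -> str:
    counts = {}
    for lb in labels:
        counts[lb] = counts.get(lb, 0) + 1
    top = max(counts.values())
    tied = [lb for lb, n in counts.items() if n == top]
    return min(tied, key=LABEL_STRENGTH.__getitem__)


class ResponseCategorizer:
    """Model: response-dynamics categorization of a ΔF/F TraceSet."""

    def __init__(self, traces: TraceSet, config: CategorizeConfig | None = None):
        if traces.signal_kind == "raw":
            raise ValueError("ResponseCategorizer expects ΔF/F traces")
        self.traces = traces
        self.config = config or CategorizeConfig()
        self.config.validate()

    def fit(self) -> "CategorizeResults":
        ts = self.traces
        rows = []
        for s in range(ts.n_stimuli):
            odor = ts.stimuli["odor"].iloc[s]
            trial = ts.stimuli["trial"].iloc[s]
            for u in range(ts.n_units):
                entry = categorize_response(ts.data[u, :, s], ts.stim_window,
                                            self.config, ts.frame_rate)
                rows.append(
                    {"animal": ts.units["animal"].iloc[u],
                     "unit": ts.units["unit"].iloc[u],
                     "odor": odor, "trial": trial, **entry}
                )
        per_trial = pd.DataFrame(rows)
        per_unit = (
            per_trial.groupby(["animal", "unit", "odor"], sort=False)["label"]
            .agg(_majority)
            .reset_index()
        )
        return CategorizeResults(per_trial, per_unit, self.config)


@dataclass
class CategorizeResults:
    """Per-trial labels with diagnostics and majority unit × odor labels."""

    per_trial: pd.DataFrame
    per_unit_odor: pd.DataFrame
    config: CategorizeConfig = field(default_factory=CategorizeConfig)

    def fractions(self, group_by: str = "odor") -> pd.DataFrame:
        return category_fractions(self, group_by=group_by)

    def summary(self) -> str:
        frac = self.per_unit_odor["label"].value_counts(normalize=True)
        lines = ["Response categorization",
                 f"  unit × odor entries: {len(self.per_unit_odor)}"]
        for lb in LABELS:
            lines.append(f"  {lb:>9}: {frac.get(lb, 0.0):6.1%}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.per_trial.to_csv(path, index=False)


def category_fractions(results: CategorizeResults, group_by: str = "odor") -> pd.DataFrame:
    """Per-group fractions of responding entries in each category.

    Fractions are taken over *responding* entries (label ≠ none) so they sum
    to 1 per group; groups with no responders are excluded (logged).  The
    returned table has one row per group plus ``median`` / ``q1`` / ``q3``
    rows across groups.
    """
    if group_by not in ("animal", "odor", "compartment"):
        raise ValueError("group_by must be 'animal', 'odor' or 'compartment'")
    tab = results.per_unit_odor
    if tab.empty:
        raise ValueError("no categorized entries")
    if group_by == "compartment":
        if "compartment" not in tab.columns:
            raise ValueError("no compartment column in results")
    rows = []
    for g, sub in tab.groupby(group_by, sort=False):
        responding = sub[sub["label"] != "none"]
        if responding.empty:
            log.warning("category_fractions: group %r has no responding entries "
                        "(excluded)", g)
            continue
        counts = responding["label"].value_counts()
        n = len(responding)
        rows.append({group_by: g, "n_responding": n,
                     **{lb: counts.get(lb, 0) / n for lb in ("on", "off", "prolonged")}})
    if not rows:
        raise ValueError("no group has responding entries")
    out = pd.DataFrame(rows)
    stats = out[["on", "off", "prolonged"]]
    for name, agg in (("median", stats.median()), ("q1", stats.quantile(0.25)),
                      ("q3", stats.quantile(0.75))):
        out = pd.concat(
            [out, pd.DataFrame([{group_by: name, "n_responding": np.nan, **agg}])],
            ignore_index=True,
        )
    return out
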