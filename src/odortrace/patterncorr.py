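"""Time-resolved cross-trial population-pattern correlation.

Population activity at a time point is summarized as a pattern vector: one
ΔF/F value per unit, units pooled across animals in a fixed canonical order
(a "pseudo-population").  Two named windows matter throughout: the *odor
response pattern* (5-frame average, t = 1–2 s after onset) and the
*post-odor response pattern* (t = 15–16 s, i.e. 5 s after a 10-s stimulus
ends).

* :func:`corr_matrix` — Pearson r between the single-frame patterns of two
  presentations at every pair of time points, with two-sided p-values from
  the t transform (df = n_units − 2) and a significance mask at α = 0.005.
* :func:`corr_trace` — average correlation of a 1-s reference window against
  every time point (a row-mean of the matrix).
* :func:`bootstrap_corr` — SD envelope of the correlation trace obtained by
  resampling animals with replacement.
* :func:`pairwise_window_corr` — odor-vs-odor, post-vs-post and odor-vs-post
  correlation tables over all odorant × trial pairs; the diagonal of the
  odor-vs-post table quantifies how similar each stimulus' post-odor pattern
  is to its own odor pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traceset import TraceSet

__all__ = ["PatternVector", "CorrMatrix", "CorrTrace", "pattern_at", "corr_matrix",
           "corr_trace", "bootstrap_corr", "pairwise_window_corr",
           "PatternCorrelation", "PatternCorrelationResults",
           "ODOR_WINDOW_S", "POST_WINDOW_S"]

log = logging.getLogger(__name__)

#: named analysis windows, seconds relative to stimulus onset (10-s stimulus)
ODOR_WINDOW_S = (1.0, 2.0)
POST_WINDOW_S = (15.0, 16.0)


@dataclass
class PatternVector:
    """Per-unit ΔF/F averaged over a frame window, for one presentation."""

    values: np.ndarray
    window: tuple[int, int]
    pooling: list
    odor: object
    trial: object


def pattern_at(traces: TraceSet, t_window: tuple[int, int],
               pool=None) -> PatternVector:
    """Population pattern vector over a half-open frame window.

    ``traces`` must hold a single presentation; ``pool`` optionally restricts
    (and orders) the animals included — the default pools every animal in
    canonical order.
    """
    if traces.n_stimuli != 1:
        raise ValueError("pattern_at requires a single-presentation TraceSet")
    ts = traces if pool is None else traces.select_animals(pool)
    lo, hi = t_window
    if not (0 <= lo < hi <= ts.n_frames):
        raise ValueError(f"window {t_window} empty or outside the recording")
    values = ts.data[:, lo:hi, 0].mean(axis=1)
    return PatternVector(values, (lo, hi), list(ts.animals),
                         ts.stimuli["odor"].iloc[0], ts.stimuli["trial"].iloc[0])


@dataclass
class CorrMatrix:
    """times_a × times_b Pearson r with p-values and significance mask."""

    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray                  # True where p < alpha (and r defined)
    alpha: float
    n_units: int
    times_a: np.ndarray
    times_b: np.ndarray
    provenance: dict

    def to_csv(self, path) -> None:
        np.savetxt(path, self.r, delimiter=",")


def _standardize_columns(m: np.ndarray):
    """Column z-scores and a validity mask (zero-variance columns invalid)."""
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    ok = sd > 0
    z = np.zeros_like(m)
    z[:, ok] = (m[:, ok] - mean[ok]) / sd[ok]
    return z, ok


def corr_matrix(traces_a: TraceSet, traces_b: TraceSet,
                alpha: float = 0.005) -> CorrMatrix:
    """Frame-by-frame Pearson correlation between two presentations.

    ``r[i, j]`` correlates the single-frame population pattern of A at frame
    i with that of B at frame j; p-values use the t transform
    ``t = r·sqrt((n−2)/(1−r²))`` with n = number of pooled units.  Cells
    involving a zero-variance pattern are NaN and masked.
    """
    if traces_a.n_stimuli != 1 or traces_b.n_stimuli != 1:
        raise ValueError("corr_matrix requires single-presentation TraceSets")
    if not traces_a.units[["animal", "unit"]].equals(traces_b.units[["animal", "unit"]]):
        raise ValueError("unit sets/ordering differ between the two presentations")
    a = traces_a.matrix()                                 # (units, frames_a)
    b = traces_b.matrix()
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 units for a correlation p-value")
    za, ok_a = _standardize_columns(a)
    zb, ok_b = _standardize_columns(b)
    r = za.T @ zb / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    undefined = ~ok_a[:, None] | ~ok_b[None, :]
    r[undefined] = np.nan
    if undefined.any():
        log.warning("corr_matrix: %d cells undefined (zero-variance pattern)",
                    int(undefined.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[undefined] = np.nan
    mask = np.where(undefined, False, p < alpha)
    return CorrMatrix(r, p, mask, alpha, n, traces_a.times, traces_b.times,
                      {"odor_a": traces_a.stimuli["odor"].iloc[0],
                       "trial_a": traces_a.stimuli["trial"].iloc[0],
                       "odor_b": traces_b.stimuli["odor"].iloc[0],
                       "trial_b": traces_b.stimuli["trial"].iloc[0]})


@dataclass
class CorrTrace:
    """Mean correlation of a reference window (axis A) over all test times."""

    values: np.ndarray
    ref_window: tuple[int, int]
    times: np.ndarray
    boot_mean: np.ndarray | None = None
    boot_sd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.times, "r": self.values}
        if self.boot_mean is not None:
            d["boot_mean"] = self.boot_mean
            d["boot_sd"] = self.boot_sd
        return pd.DataFrame(d)


def corr_trace(m: CorrMatrix, ref_window: tuple[int, int]) -> CorrTrace:
    """Average matrix rows inside ``ref_window`` (NaN cells excluded)."""
    lo, hi = ref_window
    if not (0 <= lo < hi <= m.r.shape[0]):
        raise ValueError(f"ref_window {ref_window} outside matrix axis A")
    block = m.r[lo:hi, :]
    n_bad = int(np.isnan(block).sum())
    if n_bad:
        log.info("corr_trace: excluded %d undefined cells from the average", n_bad)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(block, axis=0)
    return CorrTrace(values, (lo, hi), m.times_b)


def bootstrap_corr(traces_a: TraceSet, traces_b: TraceSet,
                   ref_window: tuple[int, int], n_boot: int = 1000,
                   seed: int | np.random.Generator = 0,
                   alpha: float = 0.005) -> CorrTrace:
    """Correlation trace with a bootstrap SD envelope over animals.

    Each replicate resamples the animals with replacement (same count),
    rebuilds the pooled pseudo-population for both presentations and
    recomputes the correlation trace; the envelope is the per-time mean and
    SD over replicates.  Deterministic under a fixed seed.  With a single
    animal every replicate is identical and the SD is 0.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    animals = traces_a.animals
    observed = corr_trace(corr_matrix(traces_a, traces_b, alpha), ref_window)
    reps = np.empty((n_boot, observed.values.size))
    for i in range(n_boot):
        draw = [animals[j] for j in rng.integers(0, len(animals), len(animals))]
        sub_a = traces_a.select_animals(draw)
        sub_b = traces_b.select_animals(draw)
        reps[i] = corr_trace(corr_matrix(sub_a, sub_b, alpha), ref_window).values
    observed.boot_mean = np.nanmean(reps, axis=0)
    observed.boot_sd = np.nanstd(reps, axis=0, ddof=0)
    return observed


def _window_patterns(traces: TraceSet, window: tuple[int, int]) -> pd.DataFrame:
    """Window-averaged pattern per stimulus; columns keyed by (odor, trial)."""
    lo, hi = window
    cols = {}
    for s in range(traces.n_stimuli):
        key = (traces.stimuli["odor"].iloc[s], traces.stimuli["trial"].iloc[s])
        cols[key] = traces.data[:, lo:hi, s].mean(axis=1)
    return pd.DataFrame(cols)


def pairwise_window_corr(traces: TraceSet,
                         odor_window: tuple[int, int] | None = None,
                         post_window: tuple[int, int] | None = None) -> dict:
    """Odor-vs-odor, post-vs-post and odor-vs-post correlation tables.

    Rows and columns are (odorant, trial) presentations; the diagonal of
    ``odor_vs_post`` measures odor ↔ post-odor pattern similarity per
    stimulus.  Windows default to t = 1–2 s and t = 15–16 s.
    """
    if traces.n_stimuli < 2:
        raise ValueError("need at least two odorant × trial presentations")
    if odor_window is None:
        odor_window = traces.window_frames(*ODOR_WINDOW_S)
    if post_window is None:
        post_window = traces.window_frames(*POST_WINDOW_S)
    odor_pat = _window_patterns(traces, odor_window)
    post_pat = _window_patterns(traces, post_window)
    return {
        "odor_vs_odor": odor_pat.corr(),
        "post_vs_post": post_pat.corr(),
        "odor_vs_post": pd.DataFrame(
            {kb: {ka: odor_pat[ka].corr(post_pat[kb]) for ka in odor_pat}
             for kb in post_pat}
        ),
    }


# --------------------------------------------------------------------------
# model / results wrapper
# --------------------------------------------------------------------------

class PatternCorrelation:
    """Model: cross-trial pattern-correlation analysis of a ΔF/F TraceSet.

    ``fit()`` computes, for every odorant with ≥ 2 trials, the trial-1 vs
    trial-2 time-resolved correlation matrix, the odor- and post-window
    correlation traces with bootstrap envelopes, and the pairwise window
    correlation tables over all presentations.
    """

    def __init__(self, traces: TraceSet, alpha: float = 0.005,
                 odor_window: tuple[int, int] | None = None,
                 post_window: tuple[int, int] | None = None):
        if traces.signal_kind == "raw":
            raise ValueError("PatternCorrelation expects ΔF/F traces")
        self.traces = traces
        self.alpha = alpha
        self.odor_window = odor_window or traces.window_frames(*ODOR_WINDOW_S)
        self.post_window = post_window or traces.window_frames(*POST_WINDOW_S)

    def fit(self, n_boot: int = 1000, seed: int = 0) -> "PatternCorrelationResults":
        ts = self.traces
        matrices, odor_traces, post_traces = {}, {}, {}
        rng = np.random.default_rng(seed)
        for odor in ts.odorants:
            trials = sorted(ts.select_odor(odor).stimuli["trial"].unique())
            if len(trials) < 2:
                log.info("PatternCorrelation: odor %r has < 2 trials, skipped", odor)
                continue
            a = ts.select_stimulus(odor, trials[0])
            b = ts.select_stimulus(odor, trials[1])
            matrices[odor] = corr_matrix(a, b, self.alpha)
            if n_boot > 0:
                odor_traces[odor] = bootstrap_corr(a, b, self.odor_window,
                                                   n_boot, rng, self.alpha)
                post_traces[odor] = bootstrap_corr(a, b, self.post_window,
                                                   n_boot, rng, self.alpha)
            else:
                odor_traces[odor] = corr_trace(matrices[odor], self.odor_window)
                post_traces[odor] = corr_trace(matrices[odor], self.post_window)
        tables = pairwise_window_corr(ts, self.odor_window, self.post_window)
        return PatternCorrelationResults(matrices, odor_traces, post_traces,
                                         tables, self.alpha,
                                         self.odor_window, self.post_window)


@dataclass
class PatternCorrelationResults:
    matrices: dict
    odor_traces: dict
    post_traces: dict
    tables: dict
    alpha: float
    odor_window: tuple[int, int]
    post_window: tuple[int, int]

    def odor_post_diagonal(self) -> pd.Series:
        """Odor ↔ post-odor pattern correlation per (odorant, trial)."""
        t = self.tables["odor_vs_post"]
        return pd.Series(np.diag(t), index=t.index)

    def summary(self) -> str:
        diag = self.odor_post_diagonal()
        lines = [f"Pattern correlation (α = {self.alpha})",
                 f"  odor window frames {self.odor_window}, "
                 f"post window frames {self.post_window}",
                 "  odor ↔ post-odor diagonal:"]
        for (odor, trial), v in diag.items():
            lines.append(f"    {odor} trial {trial}: r = {v:+.3f}")
        return "\n".join(lines)
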