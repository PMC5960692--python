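"""Sliding-window odorant decoding with a permutation chance band.

A ν-SVM (``sklearn.svm.NuSVC``, ν = 0.9, one-vs-one) is trained on
population pattern vectors averaged over a 2-s window starting at a training
time, then used to classify the single-frame patterns of held-out trials at
every test time.  Sliding the training window across the recording and
averaging the classification success over the 10-s stimulus window gives one
summary value per training time; the chance band is the mean and
95th percentile of that summary over label-permuted re-runs (default 250).

Cross-validation
----------------
The default scheme is leave-one-repetition-out: one full stimulus repetition
(one trial of every odorant) is held out per fold, so training folds stay
class-balanced — a requirement of ν = 0.9, which is infeasible for
unbalanced one-vs-one subproblems.  ``cv="resubstitution"`` trains and
tests on the same trials (classification at the training window then
trivially reaches 1 for separable data).  Odorants with a single trial can
never be held out; they stay in every training fold and are evaluated by
resubstitution, flagged in the result.

Label permutations shuffle whole-trial odor labels: across all trials under
resubstitution, within each repetition block under leave-one-repetition-out
(preserving fold balance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import NuSVC

from .traceset import TraceSet

__all__ = ["DecodeConfig", "DecodeResults", "features_at", "decode_from",
           "sliding_decode", "permutation_chance", "SlidingDecoder"]

log = logging.getLogger(__name__)

CV_MODES = ("leave-one-repetition-out", "resubstitution")


@dataclass
class DecodeConfig:
    nu: float = 0.9
    kernel: str = "linear"
    train_window_s: float = 2.0
    #: half-open frame range for the stimulus-average summary; None = stimulus
    eval_window: tuple[int, int] | None = None
    n_permutations: int = 250
    ci_level: float = 95.0
    feature_scaling: str = "zscore"           # or "none"
    cv: str = "leave-one-repetition-out"
    #: None → single-frame test patterns; a width in seconds → windowed test
    test_window_s: float | None = None
    train_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.eval_window is not None:
            self.eval_window = tuple(self.eval_window)

    def validate(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be ≥ 1")
        if self.feature_scaling not in ("zscore", "none"):
            raise ValueError("feature_scaling must be 'zscore' or 'none'")
        if self.cv not in CV_MODES:
            raise ValueError(f"cv must be one of {CV_MODES}")
        if self.train_stride < 1:
            raise ValueError("train_stride must be ≥ 1")
        if not 0 < self.ci_level <= 100:
            raise ValueError("ci_level is a percentage in (0, 100]")


def _width_frames(width_s: float, frame_rate: float) -> int:
    return max(int(round(width_s * frame_rate)), 1)


def features_at(traces: TraceSet, t: int, width_s: float):
    """One labeled sample per trial: patterns averaged over ``[t, t+width)``.

    Returns ``(X, y)`` with X of shape (n_stimuli, n_units) and y the odorant
    labels (the solvent is an ordinary class).
    """
    w = _width_frames(width_s, traces.frame_rate)
    if t < 0 or t + w > traces.n_frames:
        raise ValueError(f"window [{t}, {t + w}) exceeds the recording")
    X = traces.data[:, t : t + w, :].mean(axis=1).T
    y = traces.stimuli["odor"].to_numpy()
    return X, y


def _window_means(data: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window means over frames: out[:, t, :] = mean of [t, t+w)."""
    cs = np.concatenate(
        [np.zeros((data.shape[0], 1, data.shape[2])), np.cumsum(data, axis=1)], axis=1
    )
    return (cs[:, w:, :] - cs[:, :-w, :]) / w


def _folds(trials: np.ndarray, y: np.ndarray, cv: str):
    """(train_idx, test_idx) folds plus indices evaluated by resubstitution."""
    n = trials.size
    if cv == "resubstitution":
        idx = np.arange(n)
        return [(idx, idx)], np.array([], dtype=int)
    counts = pd.Series(y).value_counts()
    single = {c for c, k in counts.items() if k < 2}
    if single:
        log.warning("decode: classes %s have a single trial; evaluated by "
                    "resubstitution", sorted(single))
    lonely = np.array([i for i in range(n) if y[i] in single], dtype=int)
    folds = []
    for rep in np.unique(trials):
        test = np.array([i for i in range(n)
                         if trials[i] == rep and y[i] not in single], dtype=int)
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        folds.append((train, test))
    return folds, lonely


class _Scaler:
    def __init__(self, X: np.ndarray, kind: str):
        if kind == "zscore":
            self.mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.sd = np.where(sd > 0, sd, 1.0)
        else:
            self.mean, self.sd = 0.0, 1.0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _decode_success(train_feats: np.ndarray, test_source: np.ndarray,
                    y: np.ndarray, trials: np.ndarray, cfg: DecodeConfig,
                    test_frames: np.ndarray) -> np.ndarray:
    """Fraction of correctly classified held-out trials per test frame.

    ``train_feats``: (n_stimuli, n_units) training-window features;
    ``test_source``: (n_units, n_frames, n_stimuli) test patterns
    (single-frame or window-averaged).
    """
    folds, lonely = _folds(trials, y, cfg.cv)
    n_frames_eval = test_frames.size
    correct = np.zeros(n_frames_eval)
    total = 0

    def run(train_idx, test_idx):
        nonlocal total
        scaler = _Scaler(train_feats[train_idx], cfg.feature_scaling)
        clf = NuSVC(nu=cfg.nu, kernel=cfg.kernel)
        clf.fit(scaler(train_feats[train_idx]), y[train_idx])
        # (n_test, n_frames_eval, n_units) → flat predict
        pats = test_source[:, test_frames, :][:, :, test_idx]
        flat = scaler(pats.transpose(2, 1, 0).reshape(-1, pats.shape[0]))
        pred = clf.predict(flat).reshape(test_idx.size, n_frames_eval)
        correct[:] += (pred == y[test_idx][:, None]).sum(axis=0)
        total += test_idx.size

    for train_idx, test_idx in folds:
        run(train_idx, test_idx)
    if lonely.size:
        # single-trial classes: resubstitution within their repetition block
        # (training on the full unbalanced trial set is infeasible for ν=0.9)
        for rep in np.unique(trials[lonely]):
            block = np.flatnonzero(trials == rep)
            run(block, lonely[trials[lonely] == rep])
    return correct / total


def decode_from(traces: TraceSet, train_frame: int,
                cfg: DecodeConfig | None = None) -> np.ndarray:
    """Success curve over test times for one training time."""
    cfg = cfg or DecodeConfig()
    cfg.validate()
    _check_classes(traces, cfg)
    X, y = features_at(traces, train_frame, cfg.train_window_s)
    trials = traces.stimuli["trial"].to_numpy()
    test_source = _test_source(traces, cfg)
    return _decode_success(X, test_source, y, trials, cfg,
                           np.arange(test_source.shape[1]))


def _test_source(traces: TraceSet, cfg: DecodeConfig) -> np.ndarray:
    if cfg.test_window_s is None:
        return traces.data
    w = _width_frames(cfg.test_window_s, traces.frame_rate)
    return _window_means(traces.data, w)


def _check_classes(traces: TraceSet, cfg: DecodeConfig) -> None:
    y = traces.stimuli["odor"]
    if y.nunique() < 2:
        raise ValueError("decoding needs at least 2 odorant classes")
    if cfg.cv == "leave-one-repetition-out" and (y.value_counts() >= 2).sum() < 2:
        raise ValueError("held-out decoding needs ≥ 2 classes with ≥ 2 trials")


def _train_frames(traces: TraceSet, cfg: DecodeConfig) -> np.ndarray:
    w = _width_frames(cfg.train_window_s, traces.frame_rate)
    return np.arange(0, traces.n_frames - w + 1, cfg.train_stride)


def _stim_avg_curve(traces: TraceSet, y: np.ndarray, cfg: DecodeConfig,
                    train_frames: np.ndarray, eval_frames: np.ndarray,
                    W: np.ndarray, test_source: np.ndarray) -> np.ndarray:
    trials = traces.stimuli["trial"].to_numpy()
    out = np.empty(train_frames.size)
    for i, tf in enumerate(train_frames):
        succ = _decode_success(W[:, tf, :].T, test_source, y, trials, cfg,
                               eval_frames)
        out[i] = succ.mean()
    return out


def sliding_decode(traces: TraceSet, cfg: DecodeConfig | None = None) -> "DecodeResults":
    """Full (train time × test time) decoding with stimulus-window summary.

    Equivalent to :class:`SlidingDecoder` ``.fit(compute_chance=False)``.
    """
    return SlidingDecoder(traces, cfg).fit(compute_chance=False)


def _n_arrangements(y: np.ndarray, blocks) -> float:
    """Number of distinct label arrangements over the given blocks."""
    total = 1.0
    for block in blocks:
        counts = pd.Series(y[block]).value_counts()
        total *= math.factorial(block.size) / math.prod(
            math.factorial(int(k)) for k in counts
        )
    return total


def permutation_chance(traces: TraceSet, cfg: DecodeConfig | None = None,
                       train_frames: np.ndarray | None = None):
    """Chance distribution of the stimulus-average success per training time.

    Each permutation relabels whole trials and re-runs the identical
    pipeline; returns ``(chance_mean, chance_upper, perm_matrix)`` where
    ``chance_upper`` is the ``ci_level`` percentile (default 95th) of the
    permutation distribution.  Seeded via ``cfg.seed``.
    """
    cfg = cfg or DecodeConfig()
    cfg.validate()
    _check_classes(traces, cfg)
    y = traces.stimuli["odor"].to_numpy()
    trials = traces.stimuli["trial"].to_numpy()
    if train_frames is None:
        train_frames = _train_frames(traces, cfg)
    eval_frames = np.arange(*(cfg.eval_window or traces.stim_window))
    w = _width_frames(cfg.train_window_s, traces.frame_rate)
    W = _window_means(traces.data, w)
    test_source = _test_source(traces, cfg)

    if cfg.cv == "resubstitution":
        blocks = [np.arange(y.size)]
    else:
        blocks = [np.flatnonzero(trials == r) for r in np.unique(trials)]
    n_arr = _n_arrangements(y, blocks)
    if n_arr < cfg.n_permutations:
        log.info("permutation_chance: only %.0f distinct relabelings exist; "
                 "sampling with replacement over arrangements", n_arr)

    rng = np.random.default_rng(cfg.seed)
    perm = np.empty((cfg.n_permutations, train_frames.size))
    for k in range(cfg.n_permutations):
        y_perm = y.copy()
        for block in blocks:
            y_perm[block] = y[block][rng.permutation(block.size)]
        perm[k] = _stim_avg_curve(traces, y_perm, cfg, train_frames,
                                  eval_frames, W, test_source)
    chance_mean = perm.mean(axis=0)
    chance_upper = np.percentile(perm, cfg.ci_level, axis=0)
    return chance_mean, chance_upper, perm


class SlidingDecoder:
    """Model: time-resolved odorant decoding of a ΔF/F TraceSet."""

    def __init__(self, traces: TraceSet, config: DecodeConfig | None = None):
        if traces.signal_kind == "raw":
            raise ValueError("SlidingDecoder expects ΔF/F traces")
        self.traces = traces
        self.config = config or DecodeConfig()
        self.config.validate()
        _check_classes(traces, self.config)

    def fit(self, compute_chance: bool = True,
            train_frames: np.ndarray | None = None) -> "DecodeResults":
        ts, cfg = self.traces, self.config
        y = ts.stimuli["odor"].to_numpy()
        trials = ts.stimuli["trial"].to_numpy()
        if train_frames is None:
            train_frames = _train_frames(ts, cfg)
        else:
            train_frames = np.asarray(train_frames, dtype=int)
        eval_lo, eval_hi = cfg.eval_window or ts.stim_window
        all_frames = np.arange(ts.n_frames)
        w = _width_frames(cfg.train_window_s, ts.frame_rate)
        W = _window_means(ts.data, w)
        test_source = _test_source(ts, cfg)

        success = np.empty((train_frames.size, ts.n_frames))
        for i, tf in enumerate(train_frames):
            success[i] = _decode_success(W[:, tf, :].T, test_source, y, trials,
                                         cfg, all_frames)
        stim_avg = success[:, eval_lo:eval_hi].mean(axis=1)

        chance_mean = chance_upper = perm = None
        if compute_chance:
            chance_mean, chance_upper, perm = permutation_chance(
                ts, cfg, train_frames
            )
        return DecodeResults(success, stim_avg, train_frames, ts.times,
                             (eval_lo, eval_hi), chance_mean, chance_upper,
                             perm, cfg,
                             {"n_units": ts.n_units, "n_stimuli": ts.n_stimuli,
                              "classes": sorted(pd.unique(y))})


@dataclass
class DecodeResults:
    """Per-(train time, test time) success with permutation chance band."""

    success: np.ndarray               # (n_train_times, n_frames)
    stim_avg: np.ndarray              # (n_train_times,)
    train_frames: np.ndarray
    times: np.ndarray
    eval_window: tuple[int, int]
    chance_mean: np.ndarray | None
    chance_upper: np.ndarray | None
    permutations: np.ndarray | None
    config: DecodeConfig = field(default_factory=DecodeConfig)
    provenance: dict = field(default_factory=dict)

    @property
    def train_times_s(self) -> np.ndarray:
        return self.times[self.train_frames]

    def above_chance(self) -> np.ndarray:
        """Boolean per train time: stimulus-average success above the band."""
        if self.chance_upper is None:
            raise ValueError("chance band was not computed")
        return self.stim_avg > self.chance_upper

    def to_frame(self) -> pd.DataFrame:
        d = {"train_time_s": self.train_times_s, "stim_avg": self.stim_avg}
        if self.chance_mean is not None:
            d["chance_mean"] = self.chance_mean
            d["chance_upper"] = self.chance_upper
        return pd.DataFrame(d)

    def summary(self) -> str:
        lines = [
            "Sliding-window ν-SVM decoding "
            f"(ν={self.config.nu}, kernel={self.config.kernel}, cv={self.config.cv})",
            f"  units: {self.provenance.get('n_units')}, "
            f"classes: {self.provenance.get('classes')}",
            f"  train times: {self.train_frames.size}, "
            f"stimulus window frames {self.eval_window}",
            f"  peak stimulus-average success: {self.stim_avg.max():.3f} "
            f"at t = {self.train_times_s[self.stim_avg.argmax()]:+.1f} s",
        ]
        if self.chance_upper is not None:
            frac = self.above_chance().mean()
            lines.append(
                f"  above the {self.config.ci_level:.0f}% permutation bound at "
                f"{frac:.0%} of train times "
                f"({self.config.n_permutations} permutations)"
            )
        return "\n".join(lines)
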