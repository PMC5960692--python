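"""Ground-truth-labeled synthetic population recordings.

Real recordings of this kind — ORN axons, PN dendrites/somata and Kenyon-cell
dendrites/somata responding to a panel of odorants — are not publicly
deposited, so the generator emulates the statistical structure the analyses
assume: odor-specific response patterns across units, GCaMP-like rise/decay
kinetics drawn from an on/off/prolonged/none category mixture, a *tunable*
Pearson correlation ρ between each odorant's population pattern during the
stimulus ("odor response pattern") and 5 s after offset ("post-odor response
pattern"), multiplicative exponential photobleaching, additive Gaussian
noise, per-animal unit grouping, 10-s stimuli at 5 Hz for 35 s, two trials
per odorant and a solvent (mineral-oil) control class.

Pattern-correlation construction
--------------------------------
Per odorant, odor-pattern weights ``a_u`` are drawn for stimulus-responsive
units (zero for off/none units).  Post-pattern weights are then built from
the *final* odor-weight vector (structural zeros included) as::

    z_p = ρ · z(a) + sqrt(1 − ρ²) · z_indep
    p_u = amp_mean + amp_sd · z_p

so the population Pearson correlation between the two weight vectors matches
``post_pattern_corr`` by construction.  A second knob, ``post_trial_corr``,
sets how much of the non-odor-pattern part of the post-odor pattern is shared
between the two trials: 1 gives fully reproducible post-odor patterns
(KC-somata-like), 0 gives trial-unique post-odor patterns (ORN-like, which is
what makes post-offset decoding fall to chance for that preset).

Temporal kernels are differences/products of exponentials chosen so that, in
the noiseless limit, every generated unit satisfies the categorizer's
defining inequalities for its true label (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .traceset import TraceSet

__all__ = ["SynthConfig", "GroundTruth", "generate_traceset", "generate_stack",
           "preset", "PRESET_NAMES", "grid_layout"]

CATEGORIES = ("on", "off", "prolonged", "none")

#: Compartment archetypes mirroring the measured populations.
PRESET_NAMES = ("orn_like", "pn_dendrite_like", "pn_soma_like",
                "kc_dendrite_like", "kc_soma_like")


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording (defaults = study conditions)."""

    n_animals: int = 8
    units_per_animal: int = 25
    odorants: tuple = ("ButL", "ProL", "AceA", "ProA", "MO")
    solvent: str = "MO"
    trials_per_odor: int = 2
    frame_rate: float = 5.0
    n_frames: int = 175
    stim_onset_frame: int = 25
    stim_duration_s: float = 10.0
    #: probabilities over (on, off, prolonged, none), summing to 1
    category_mix: dict = field(
        default_factory=lambda: {"on": 0.50, "off": 0.15, "prolonged": 0.30, "none": 0.05}
    )
    rise_tau_s: float = 0.5
    decay_tau_s: float = 1.5          # "on" category post-offset decay
    prolonged_decay_tau_s: float = 12.0
    post_rise_tau_s: float = 2.0      # rise of the post-odor (off-like) component
    post_pattern_corr: float = 0.5    # ρ between odor and post-odor pattern
    post_trial_corr: float = 1.0      # trial-to-trial reproducibility of post pattern
    response_amp_mean: float = 1.0    # ΔF/F units
    response_amp_sd: float = 0.3
    noise_sd: float = 0.03            # ΔF/F units (scaled by baseline_f0 on raw counts)
    baseline_f0: float = 1000.0
    bleach_a: float = 0.3
    bleach_b: float = -0.01           # per frame, expected ≤ 0
    bleach_c: float = 0.7
    negative_responses: bool = False
    negative_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the violated invariant."""
        mix = self.category_mix
        if set(mix) != set(CATEGORIES):
            raise ValueError(f"category_mix must have keys {CATEGORIES}")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must be non-negative and sum to 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.trials_per_odor < 1:
            raise ValueError("trials_per_odor must be ≥ 1")
        if not abs(self.post_pattern_corr) <= 1:
            raise ValueError("post_pattern_corr must satisfy |ρ| ≤ 1")
        if not 0 <= self.post_trial_corr <= 1:
            raise ValueError("post_trial_corr must lie in [0, 1]")
        offset = self.stim_onset_frame + self.stim_duration_s * self.frame_rate
        if not (0 <= self.stim_onset_frame and offset <= self.n_frames):
            raise ValueError("stimulus window must fit inside the recording")
        if self.n_animals < 1 or self.units_per_animal < 1:
            raise ValueError("need at least one animal and one unit per animal")
        if min(self.rise_tau_s, self.decay_tau_s, self.prolonged_decay_tau_s,
               self.post_rise_tau_s) <= 0:
            raise ValueError("time constants must be positive")

    # YAML round-trip -------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["odorants"] = list(d["odorants"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d["odorants"] = tuple(d["odorants"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True labels and pattern weights behind a synthetic recording.

    ``unit_odor_trial`` has one row per unit × odor × trial with the true
    category, odor-pattern weight and post-odor-pattern weight.
    """

    unit_odor_trial: pd.DataFrame
    bleach_params: tuple
    seed: int

    def weights(self, odor, trial):
        """(odor_weight, post_weight) vectors for one presentation."""
        t = self.unit_odor_trial
        sel = t[(t["odor"] == odor) & (t["trial"] == trial)]
        return sel["odor_weight"].to_numpy(), sel["post_weight"].to_numpy()

    def labels(self, odor):
        t = self.unit_odor_trial
        sel = t[(t["odor"] == odor) & (t["trial"] == t["trial"].min())]
        return sel["category"].to_numpy()

    def to_csv(self, path) -> None:
        self.unit_odor_trial.to_csv(path, index=False)


# --------------------------------------------------------------------------
# temporal envelopes
# --------------------------------------------------------------------------

def _envelopes(cfg: SynthConfig):
    """Category-specific kernels on the recording time base.

    Returns a dict with stimulus envelopes ``S_on``/``S_prolonged``
    (unit odor-window mean), post envelopes ``P_delayed`` (zero until the
    post-window start, unit post-window mean — used for on/prolonged units so
    the categorizer's decay check is untouched) and ``P_off`` (rising at
    offset, unit post-window mean), plus the mean of each stimulus envelope
    over the post window (needed to solve for the post-component amplitude).
    """
    t = (np.arange(cfg.n_frames) - cfg.stim_onset_frame) / cfg.frame_rate
    dur = cfg.stim_duration_s
    post_start = dur + 5.0            # post-odor window: 5 s after offset
    post_lo = cfg.stim_onset_frame + int(round(post_start * cfg.frame_rate))
    post_hi = post_lo + int(round(1.0 * cfg.frame_rate))
    post = slice(post_lo, post_hi)

    def stim_env(decay_tau):
        e = np.zeros_like(t)
        on = (t >= 0) & (t < dur)
        e[on] = 1.0 - np.exp(-t[on] / cfg.rise_tau_s)
        after = t >= dur
        peak = 1.0 - np.exp(-dur / cfg.rise_tau_s)
        e[after] = peak * np.exp(-(t[after] - dur) / decay_tau)
        odor_win = (t >= 1.0) & (t < 2.0)
        return e / e[odor_win].mean()

    s_on = stim_env(cfg.decay_tau_s)
    s_pro = stim_env(cfg.prolonged_decay_tau_s)

    # post component for on/prolonged units: zero before the post window,
    # then shaped exactly like the prolonged stimulus tail.  With the
    # post-component amplitude c = p − a·(tail mean over the post window)
    # this makes a prolonged unit's trace equal p·(tail shape) for every
    # t ≥ post_start — the stimulus-weight contribution cancels, so late
    # activity carries only the post-odor pattern.
    p_del = np.zeros_like(t)
    late = t >= post_start
    p_del[late] = s_pro[late]
    p_del /= p_del[post].mean()

    # post component for off units: rises right after offset, then follows
    # the same tail shape as every other post component from the post window
    # on, so late population patterns are proportional to the post-pattern
    # weights at every late time point
    p_off = np.zeros_like(t)
    mid = (t >= dur) & (t < post_start)
    p_off[mid] = 1.0 - np.exp(-(t[mid] - dur) / cfg.post_rise_tau_s)
    r15 = 1.0 - np.exp(-(post_start - dur) / cfg.post_rise_tau_s)
    s15 = s_pro[np.argmax(t >= post_start)]
    p_off[late] = r15 * s_pro[late] / s15
    p_off /= p_off[post].mean()

    return {
        "S_on": s_on, "S_prolonged": s_pro,
        "P_delayed": p_del, "P_off": p_off,
        "S_on_post": s_on[post].mean(), "S_prolonged_post": s_pro[post].mean(),
        "post_slice": post,
    }


def _category_counts(n: int, mix: dict) -> dict:
    """Largest-remainder apportionment of n units over the category mix."""
    raw = {c: n * mix[c] for c in CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(CATEGORIES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_traceset(cfg: SynthConfig) -> tuple[TraceSet, GroundTruth]:
    """Simulate a raw-fluorescence TraceSet with known ground truth.

    Raw fluorescence is ``baseline_f0 · (1 + ΔF/F kernel) · bleach(t)`` plus
    additive Gaussian noise of SD ``noise_sd · baseline_f0``; the ΔF/F kernel
    of each unit × odor × trial follows its true category, and the population
    post-odor pattern correlates with the odor pattern at the configured ρ.
    Identical seeds give bit-identical output.
    """
    cfg.validate()
    n_units = cfg.n_animals * cfg.units_per_animal
    env = _envelopes(cfg)
    rho = cfg.post_pattern_corr
    q = cfg.post_trial_corr

    ss = np.random.SeedSequence(cfg.seed)
    rng_weights, rng_cat, rng_noise, rng_neg = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    units = pd.DataFrame(
        {
            "animal": np.repeat([f"fly{i:02d}" for i in range(cfg.n_animals)],
                                cfg.units_per_animal),
            "unit": np.tile(np.arange(cfg.units_per_animal), cfg.n_animals),
        }
    )
    stimuli = pd.DataFrame(
        [(o, tr + 1) for o in cfg.odorants for tr in range(cfg.trials_per_odor)],
        columns=["odor", "trial"],
    )

    kernels = np.zeros((n_units, cfg.n_frames, len(stimuli)))
    gt_rows = []
    stim_env = {"on": env["S_on"], "prolonged": env["S_prolonged"]}
    stim_post = {"on": env["S_on_post"], "prolonged": env["S_prolonged_post"]}
    s_max_pro = float(env["S_prolonged"].max())

    for odor in cfg.odorants:
        if odor == cfg.solvent:
            labels = np.array(["none"] * n_units)
            a = np.zeros(n_units)
            p_trials = {tr + 1: np.zeros(n_units) for tr in range(cfg.trials_per_odor)}
        else:
            counts = _category_counts(n_units, cfg.category_mix)
            labels = np.array(
                sum(([c] * counts[c] for c in CATEGORIES), []), dtype=object
            )
            rng_cat.shuffle(labels)

            z_a = rng_weights.standard_normal(n_units)
            a = cfg.response_amp_mean + cfg.response_amp_sd * z_a
            a = np.clip(a, 0.05 * cfg.response_amp_mean, None)
            a[(labels == "off") | (labels == "none")] = 0.0
            if cfg.negative_responses:
                # a minority of stimulus-responsive unit×odor pairs respond
                # with a fluorescence decrease (acid-like inhibition)
                resp = np.flatnonzero((labels == "on") | (labels == "prolonged"))
                flip = resp[rng_neg.random(resp.size) < cfg.negative_fraction]
                a[flip] *= -1.0

            # post weights correlated at ρ with the final odor-weight vector
            sd_a = a.std()
            z_final = (a - a.mean()) / sd_a if sd_a > 0 else np.zeros(n_units)
            z_common = rng_weights.standard_normal(n_units)
            z_trial = [rng_weights.standard_normal(n_units)
                       for _ in range(cfg.trials_per_odor)]

            def build(rho_eff):
                out = {}
                for tr in range(cfg.trials_per_odor):
                    z_indep = np.sqrt(q) * z_common + np.sqrt(1 - q) * z_trial[tr]
                    z_p = rho_eff * z_final + np.sqrt(1 - rho_eff**2) * z_indep
                    p = cfg.response_amp_mean + cfg.response_amp_sd * z_p
                    p[labels == "none"] = 0.0
                    off = labels == "off"
                    p[off] = np.clip(p[off], 0.05 * cfg.response_amp_mean, None)
                    # a prolonged unit stays above decay_fraction (1/e) of its
                    # stimulus max through the post window by definition, so
                    # its post weight has a category-consistent floor
                    pro = labels == "prolonged"
                    p[pro] = np.maximum(p[pro], 0.45 * a[pro] * s_max_pro)
                    out[tr + 1] = p
                return out

            # the structural zeros of off/none units distort the mixture
            # correlation, so the construction coefficient is calibrated by a
            # root solve until the realized weight-vector correlation matches
            # the configured ρ (deterministic: the z draws are fixed)
            def realized(rho_eff):
                ps = build(rho_eff)
                return float(np.mean([np.corrcoef(a, ps[t])[0, 1] for t in ps]))

            lo, hi = -0.999, 0.999
            if realized(hi) <= rho:
                rho_eff = hi
            elif realized(lo) >= rho:
                rho_eff = lo
            else:
                rho_eff = brentq(lambda r: realized(r) - rho, lo, hi, xtol=1e-4)
            p_trials = build(rho_eff)

        for tr in range(cfg.trials_per_odor):
            trial = tr + 1
            s_idx = stimuli.index[
                (stimuli["odor"] == odor) & (stimuli["trial"] == trial)
            ][0]
            p = p_trials[trial]
            k = np.zeros((n_units, cfg.n_frames))
            for cat in ("on", "prolonged"):
                m = labels == cat
                c = p[m] - a[m] * stim_post[cat]
                k[m] = np.outer(a[m], stim_env[cat]) + np.outer(c, env["P_delayed"])
            m = labels == "off"
            k[m] = np.outer(p[m], env["P_off"])
            kernels[:, :, s_idx] = k
            gt_rows.append(
                pd.DataFrame(
                    {
                        "animal": units["animal"],
                        "unit": units["unit"],
                        "odor": odor,
                        "trial": trial,
                        "category": labels,
                        "odor_weight": a,
                        "post_weight": p,
                    }
                )
            )

    frames = np.arange(cfg.n_frames)
    bleach = cfg.bleach_a * np.exp(cfg.bleach_b * frames) + cfg.bleach_c
    raw = cfg.baseline_f0 * (1.0 + kernels) * bleach[None, :, None]
    if cfg.noise_sd > 0:
        raw = raw + rng_noise.normal(0.0, cfg.noise_sd * cfg.baseline_f0, raw.shape)

    ts = TraceSet(raw, units, stimuli, cfg.frame_rate, cfg.stim_onset_frame,
                  cfg.stim_duration_s, signal_kind="raw",
                  meta={"synthetic": True, "seed": cfg.seed})
    gt = GroundTruth(
        pd.concat(gt_rows, ignore_index=True),
        bleach_params=(cfg.bleach_a, cfg.bleach_b, cfg.bleach_c),
        seed=cfg.seed,
    )
    return ts, gt


# --------------------------------------------------------------------------
# image-stack rendering
# --------------------------------------------------------------------------

def grid_layout(n_units: int, frame_shape=(64, 64), size: int = 7, margin: int = 2):
    """Non-overlapping square footprints on a regular grid.

    Returns a list of ``(row, col, size)`` footprint centers usable as the
    layout argument of :func:`generate_stack`.
    """
    h, w = frame_shape
    step = size + margin
    rows = (h - size) // step + 1
    cols = (w - size) // step + 1
    if rows * cols < n_units:
        raise ValueError(
            f"frame {frame_shape} fits only {rows * cols} footprints of size {size}"
        )
    out = []
    for i in range(n_units):
        r, c = divmod(i, cols)
        out.append((r * step + size // 2, c * step + size // 2, size))
    return out


def generate_stack(cfg: SynthConfig, layout, odor=None, trial: int = 1,
                   frame_shape=(64, 64)):
    """Render one synthetic presentation as a fluorescence movie.

    Each entry of ``layout`` is ``(row, col, size)``: a square footprint whose
    pixels all carry the unit's raw trace, so a box average over the footprint
    recovers the trace exactly (up to the stack's own pixel noise, which is
    disabled inside footprints).  The background is bleached baseline plus
    Gaussian pixel noise.  Footprints must not overlap and must lie inside
    the frame.
    """
    from .imaging import ImageStack

    cfg.validate()
    n_units = cfg.n_animals * cfg.units_per_animal
    if len(layout) > n_units:
        raise ValueError("layout places more footprints than generated units")
    h, w = frame_shape
    occupancy = np.zeros((h, w), dtype=bool)
    boxes = []
    for row, col, size in layout:
        half = size // 2
        r0, c0 = row - half, col - half
        r1, c1 = r0 + size, c0 + size
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(f"footprint at ({row},{col}) size {size} exceeds frame")
        if occupancy[r0:r1, c0:c1].any():
            raise ValueError(f"footprint at ({row},{col}) overlaps another footprint")
        occupancy[r0:r1, c0:c1] = True
        boxes.append((r0, r1, c0, c1))

    ts, gt = generate_traceset(cfg)
    if odor is None:
        odor = cfg.odorants[0]
    traces = ts.select_stimulus(odor, trial).matrix()

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[-1])
    frames = np.arange(cfg.n_frames)
    bleach = cfg.bleach_a * np.exp(cfg.bleach_b * frames) + cfg.bleach_c
    stack = np.empty((cfg.n_frames, h, w))
    stack[:] = (cfg.baseline_f0 * bleach)[:, None, None]
    if cfg.noise_sd > 0:
        stack += rng.normal(0.0, cfg.noise_sd * cfg.baseline_f0, stack.shape)
    for i, (r0, r1, c0, c1) in enumerate(boxes):
        stack[:, r0:r1, c0:c1] = traces[i][:, None, None]

    image = ImageStack(stack, frame_rate=cfg.frame_rate,
                       stim_onset_frame=cfg.stim_onset_frame)
    return image, gt


# --------------------------------------------------------------------------
# compartment presets
# --------------------------------------------------------------------------

def preset(name: str, **overrides) -> SynthConfig:
    """Config archetype for one recorded compartment.

    ``orn_like`` / ``pn_*`` presets have post-odor patterns uncorrelated to
    the odor pattern (ρ ≈ 0); ``kc_soma_like`` has a high ρ, an elevated
    prolonged fraction and reproducible post-odor patterns; ``kc_dendrite_like``
    is intermediate.  Category mixes echo the measured fractions: the ORN mix
    uses the reported on/off/prolonged medians (25/44/27%), PN dendrites are
    on-dominated (75%), KC dendrites nearly lack off responses and KC somata
    carry the largest prolonged share.
    """
    presets = {
        "orn_like": dict(
            category_mix={"on": 0.25, "off": 0.44, "prolonged": 0.27, "none": 0.04},
            post_pattern_corr=0.0, post_trial_corr=0.0,
        ),
        "pn_dendrite_like": dict(
            category_mix={"on": 0.75, "off": 0.14, "prolonged": 0.07, "none": 0.04},
            post_pattern_corr=0.0, post_trial_corr=0.4,
        ),
        "pn_soma_like": dict(
            category_mix={"on": 0.70, "off": 0.08, "prolonged": 0.17, "none": 0.05},
            post_pattern_corr=0.0, post_trial_corr=0.8,
        ),
        "kc_dendrite_like": dict(
            category_mix={"on": 0.75, "off": 0.02, "prolonged": 0.18, "none": 0.05},
            post_pattern_corr=0.35, post_trial_corr=0.9,
        ),
        "kc_soma_like": dict(
            category_mix={"on": 0.55, "off": 0.05, "prolonged": 0.35, "none": 0.05},
            post_pattern_corr=0.6, post_trial_corr=0.95,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; valid names: {sorted(presets)}")
    cfg = SynthConfig(**{**presets[name], **overrides})
    cfg.validate()
    return cfg
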