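"""End-to-end orchestration: simulate → preprocess → categorize → correlate →
decode → report.

A :class:`RunConfig` (YAML-serializable) names the enabled stages and the
per-stage settings; :func:`run` executes the stages in order into a run
directory, writing every artifact as delimited text or JSON together with a
manifest (content hash, producing stage, config hash, seed, package version)
so that reruns with an identical config are byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .categorize import CategorizeConfig, ResponseCategorizer
from .decode import DecodeConfig, SlidingDecoder
from .patterncorr import PatternCorrelation
from .synthdata import SynthConfig, generate_traceset, preset
from .traceproc import DffParams, compute_dff, correct_bleaching
from .traceset import TraceSet

__all__ = ["RunConfig", "run", "report"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "categorize", "correlate", "decode")


@dataclass
class RunConfig:
    """Pipeline configuration; sub-configs validate individually."""

    outdir: str = "runs/run"
    stages: tuple = STAGES
    seed: int = 0
    preset: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    dff: DffParams = field(default_factory=DffParams)
    categorize: CategorizeConfig = field(default_factory=CategorizeConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    n_boot: int = 1000
    corr_alpha: float = 0.005
    input_traces: str | None = None   # CSV TraceSet; alternative to simulate
    log_level: str = "INFO"

    def resolved_synth(self) -> SynthConfig:
        if self.preset is not None:
            base = preset(self.preset)
            return dataclasses.replace(base, seed=self.seed)
        return dataclasses.replace(self.synth, seed=self.seed)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.resolved_synth().validate()
        self.dff.validate()
        self.categorize.validate()
        self.decode.validate()

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["synth"]["odorants"] = list(d["synth"]["odorants"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        for key, sub in (("synth", SynthConfig), ("dff", DffParams),
                         ("categorize", CategorizeConfig), ("decode", DecodeConfig)):
            if key in d and isinstance(d[key], dict):
                if key == "synth" and "odorants" in d[key]:
                    d[key]["odorants"] = tuple(d[key]["odorants"])
                d[key] = sub(**d[key])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.entries = []
        self.header = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "status": "running",
        }

    def add(self, path: Path, stage: str) -> None:
        self.entries.append(
            {"file": path.name, "stage": stage, "sha256": _sha256(path)}
        )
        self.write()

    def write(self, status: str | None = None) -> None:
        if status:
            self.header["status"] = status
        with open(self.outdir / "manifest.json", "w") as f:
            json.dump({**self.header, "artifacts": self.entries}, f, indent=1)


def run(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the run directory.

    On a stage failure the pipeline halts, partial artifacts are retained
    and the manifest records the failure point.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = _Manifest(outdir, config)
    config.to_yaml(outdir / "config.yaml")
    manifest.add(outdir / "config.yaml", "init")

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log.info("pipeline: stage %s", stage)
            _STAGE_FUNCS[stage](config, outdir, manifest, state)
        manifest.write(status="complete")
    except Exception as exc:
        manifest.header["failed_stage"] = getattr(exc, "_stage", "unknown")
        manifest.write(status=f"failed: {exc}")
        raise
    return outdir


def _stage(name):
    def deco(fn):
        def wrapped(config, outdir, manifest, state):
            try:
                return fn(config, outdir, manifest, state)
            except Exception as exc:
                exc._stage = name
                raise
        _STAGE_FUNCS[name] = wrapped
        return wrapped
    return deco


_STAGE_FUNCS: dict = {}


@_stage("simulate")
def _simulate(config, outdir, manifest, state):
    cfg = config.resolved_synth()
    ts, gt = generate_traceset(cfg)
    state["raw"] = ts
    ts.to_csv(outdir / "traces_raw.csv")
    gt.to_csv(outdir / "ground_truth.csv")
    manifest.add(outdir / "traces_raw.csv", "simulate")
    manifest.add(outdir / "ground_truth.csv", "simulate")


@_stage("preprocess")
def _preprocess(config, outdir, manifest, state):
    if "raw" not in state:
        if config.input_traces is None:
            raise ValueError("preprocess needs simulated or input traces")
        state["raw"] = TraceSet.from_csv(
            config.input_traces, config.synth.frame_rate,
            config.synth.stim_onset_frame, config.synth.stim_duration_s,
        )
    dff = compute_dff(state["raw"], config.dff)
    corrected, fits = correct_bleaching(dff, config.dff)
    state["dff"] = corrected
    corrected.to_csv(outdir / "traces_dff.csv")
    fits.to_csv(outdir / "bleach_fits.csv", index=False)
    log.info("preprocess: %d units, %d presentations", corrected.n_units,
             corrected.n_stimuli)
    manifest.add(outdir / "traces_dff.csv", "preprocess")
    manifest.add(outdir / "bleach_fits.csv", "preprocess")


def _need_dff(state) -> TraceSet:
    if "dff" not in state:
        raise ValueError("stage requires the preprocess stage output")
    return state["dff"]


@_stage("categorize")
def _categorize(config, outdir, manifest, state):
    res = ResponseCategorizer(_need_dff(state), config.categorize).fit()
    state["categories"] = res
    res.per_trial.to_csv(outdir / "categories.csv", index=False)
    res.fractions("odor").to_csv(outdir / "category_fractions.csv", index=False)
    manifest.add(outdir / "categories.csv", "categorize")
    manifest.add(outdir / "category_fractions.csv", "categorize")


@_stage("correlate")
def _correlate(config, outdir, manifest, state):
    model = PatternCorrelation(_need_dff(state), alpha=config.corr_alpha)
    res = model.fit(n_boot=config.n_boot, seed=config.seed)
    state["correlation"] = res
    for odor, m in res.matrices.items():
        m.to_csv(outdir / f"corr_matrix_{odor}.csv")
        manifest.add(outdir / f"corr_matrix_{odor}.csv", "correlate")
        with open(outdir / f"corr_matrix_{odor}.json", "w") as f:
            json.dump({"alpha": m.alpha, "n_units": m.n_units,
                       **{k: str(v) for k, v in m.provenance.items()}}, f)
        manifest.add(outdir / f"corr_matrix_{odor}.json", "correlate")
        res.odor_traces[odor].to_frame().to_csv(
            outdir / f"corr_trace_odor_{odor}.csv", index=False)
        manifest.add(outdir / f"corr_trace_odor_{odor}.csv", "correlate")
        res.post_traces[odor].to_frame().to_csv(
            outdir / f"corr_trace_post_{odor}.csv", index=False)
        manifest.add(outdir / f"corr_trace_post_{odor}.csv", "correlate")
    for name, tab in res.tables.items():
        tab.to_csv(outdir / f"pairwise_{name}.csv")
        manifest.add(outdir / f"pairwise_{name}.csv", "correlate")


@_stage("decode")
def _decode(config, outdir, manifest, state):
    dcfg = dataclasses.replace(config.decode, seed=config.seed)
    res = SlidingDecoder(_need_dff(state), dcfg).fit()
    state["decode"] = res
    np.savetxt(outdir / "decode_success.csv", res.success, delimiter=",")
    res.to_frame().to_csv(outdir / "decode_stim_avg.csv", index=False)
    with open(outdir / "decode_provenance.json", "w") as f:
        json.dump({**res.provenance, "config": dataclasses.asdict(dcfg),
                   "eval_window": list(res.eval_window)}, f, default=str)
    for name in ("decode_success.csv", "decode_stim_avg.csv",
                 "decode_provenance.json"):
        manifest.add(outdir / name, "decode")


def report(run_dir) -> Path:
    """Render a summary document (markdown + PNGs) from a completed run.

    Sections for missing stage outputs are omitted with a notice.
    """
    from . import plotting
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise ValueError(f"{run_dir} is not a run directory (no manifest)")
    lines = ["# Run report", ""]

    frac_path = run_dir / "category_fractions.csv"
    if frac_path.exists():
        frac = pd.read_csv(frac_path)
        lines += ["## Response categories", "", frac.to_markdown(index=False), ""]
        ax = plotting.plot_category_fractions(frac)
        ax.figure.savefig(run_dir / "report_categories.png", dpi=100)
        plt.close(ax.figure)
    else:
        lines += ["## Response categories", "", "_stage output missing — omitted_", ""]

    pair_path = run_dir / "pairwise_odor_vs_post.csv"
    if pair_path.exists():
        tab = pd.read_csv(pair_path, index_col=0)
        diag = pd.Series(np.diag(tab), index=tab.index)
        lines += ["## Odor ↔ post-odor pattern correlation", "",
                  diag.to_markdown(), ""]
    else:
        lines += ["## Odor ↔ post-odor pattern correlation", "",
                  "_stage output missing — omitted_", ""]

    dec_path = run_dir / "decode_stim_avg.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        above = (dec["stim_avg"] > dec["chance_upper"]).mean() \
            if "chance_upper" in dec else float("nan")
        lines += ["## Decoding", "",
                  f"peak stimulus-average success: {dec['stim_avg'].max():.3f}",
                  f"fraction of train times above chance band: {above:.2f}", ""]
        fig, ax = plt.subplots(figsize=(5, 3))
        if "chance_upper" in dec:
            ax.fill_between(dec["train_time_s"], dec["chance_mean"],
                            dec["chance_upper"], color="0.7")
        ax.plot(dec["train_time_s"], dec["stim_avg"], color="darkgreen")
        ax.set_xlabel("training time (s)")
        ax.set_ylabel("fraction correct")
        fig.savefig(run_dir / "report_decode.png", dpi=100)
        plt.close(fig)
    else:
        lines += ["## Decoding", "", "_stage output missing — omitted_", ""]

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
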