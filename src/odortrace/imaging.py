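"""Image-stack handling and ROI extraction.

Glomerular signals are read out as the mean over a small square box of
pixels centered on the structure (7×7 in the original acquisition geometry);
regions without single-unit resolution (e.g. densely packed dendrites) are
spatially downsampled by treating each contiguous ``b × b`` pixel bin as one
ROI.  Units whose ΔF/F never exceeds an amplitude threshold (default
0.75 ΔF/F) for any odorant are excluded from population analyses.

Pixel coordinates are 0-based ``(row, col)``.  Boxes are centered for odd
sizes; for even sizes the given center is the top-left pixel of the central
2×2 block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traceset import TraceSet

__all__ = ["ImageStack", "RoiSpec", "extract_box_trace", "extract_traces",
           "bin_stack", "filter_active_units"]

log = logging.getLogger(__name__)


@dataclass
class ImageStack:
    """Fluorescence movie: ``(frames, height, width)``."""

    data: np.ndarray
    frame_rate: float
    stim_onset_frame: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("data must be a (frames, height, width) array with ≥1 frame")
        if not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, frame_rate: float, stim_onset_frame: int = 0) -> "ImageStack":
        import tifffile

        return cls(tifffile.imread(path), frame_rate, stim_onset_frame)


@dataclass
class RoiSpec:
    """Square box ROI (``kind="box"``) or spatial-bin tag (``kind="bin"``)."""

    center: tuple
    size: int
    label: str = ""
    kind: str = "box"

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("ROI size must be ≥ 1")
        if self.kind not in ("box", "bin"):
            raise ValueError("kind must be 'box' or 'bin'")

    def bounds(self) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) half-open pixel bounds of the box."""
        row, col = self.center
        half = (self.size - 1) // 2
        r0, c0 = row - half, col - half
        return r0, r0 + self.size, c0, c0 + self.size


def read_roi_specs(path) -> list[RoiSpec]:
    """Read ROI definitions from delimited text (label,row,col,size,kind)."""
    tab = pd.read_csv(path)
    return [
        RoiSpec(center=(int(r.row), int(r.col)), size=int(r.size),
                label=str(r.label), kind=str(r.kind))
        for r in tab.itertuples()
    ]


def write_roi_specs(rois, path) -> None:
    pd.DataFrame(
        [
            {"label": r.label, "row": r.center[0], "col": r.center[1],
             "size": r.size, "kind": r.kind}
            for r in rois
        ]
    ).to_csv(path, index=False)


def extract_box_trace(stack: ImageStack, roi: RoiSpec) -> np.ndarray:
    """Per-frame mean fluorescence over a square pixel box.

    The box must lie fully inside the frame; out-of-bounds boxes are rejected
    rather than silently clipped.
    """
    r0, r1, c0, c1 = roi.bounds()
    h, w = stack.frame_shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"ROI {roi.label!r} box [{r0}:{r1}, {c0}:{c1}] exceeds frame bounds {h}×{w}"
        )
    return stack.data[:, r0:r1, c0:c1].mean(axis=(1, 2))


def extract_traces(stack: ImageStack, rois, odor="stim", trial: int = 1,
                   animal="animal0", stim_duration_s: float = 10.0) -> TraceSet:
    """Extract a single-presentation TraceSet from a list of box ROIs."""
    data = np.stack([extract_box_trace(stack, r) for r in rois])[:, :, None]
    units = pd.DataFrame(
        {"animal": animal, "unit": [r.label or str(i) for i, r in enumerate(rois)]}
    )
    stimuli = pd.DataFrame({"odor": [odor], "trial": [trial]})
    return TraceSet(data, units, stimuli, stack.frame_rate, stack.stim_onset_frame,
                    stim_duration_s, signal_kind="raw")


def bin_stack(stack: ImageStack, bin_width: int, odor="stim", trial: int = 1,
              animal="animal0", stim_duration_s: float = 10.0) -> TraceSet:
    """Spatially downsample: each ``b × b`` pixel bin becomes one unit.

    Tiles start at pixel (0, 0); trailing partial tiles are dropped so every
    unit averages the same number of pixels.  Unit labels encode the tile
    coordinates as ``"bin_r<i>_c<j>"``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be ≥ 1")
    h, w = stack.frame_shape
    if bin_width > h or bin_width > w:
        raise ValueError(f"bin_width {bin_width} larger than frame {h}×{w}")
    nr, nc = h // bin_width, w // bin_width
    trimmed = stack.data[:, : nr * bin_width, : nc * bin_width]
    tiles = trimmed.reshape(stack.n_frames, nr, bin_width, nc, bin_width)
    means = tiles.mean(axis=(2, 4))                       # (frames, nr, nc)
    data = means.reshape(stack.n_frames, nr * nc).T[:, :, None]
    labels = [f"bin_r{i}_c{j}" for i in range(nr) for j in range(nc)]
    units = pd.DataFrame({"animal": animal, "unit": labels})
    stimuli = pd.DataFrame({"odor": [odor], "trial": [trial]})
    return TraceSet(data, units, stimuli, stack.frame_rate, stack.stim_onset_frame,
                    stim_duration_s, signal_kind="raw")


def filter_active_units(traces: TraceSet, amplitude_threshold: float = 0.75,
                        eval_window: tuple[int, int] | None = None) -> TraceSet:
    """Keep units whose ΔF/F exceeds the threshold for at least one odorant.

    A unit is retained iff its maximum single-frame ΔF/F inside the
    evaluation window (default: stimulus onset → end of recording), over any
    stimulus presentation, exceeds ``amplitude_threshold``.  Input must be
    ΔF/F (raw fluorescence is rejected).
    """
    if traces.signal_kind == "raw":
        raise ValueError("filter_active_units requires ΔF/F input, got raw fluorescence")
    lo, hi = eval_window if eval_window is not None else (traces.stim_onset_frame,
                                                          traces.n_frames)
    peak = traces.data[:, lo:hi, :].max(axis=(1, 2))
    keep = np.flatnonzero(peak > amplitude_threshold)
    log.info("filter_active_units: kept %d / %d units (threshold %.3g ΔF/F)",
             keep.size, traces.n_units, amplitude_threshold)
    return traces.select_units(keep)
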