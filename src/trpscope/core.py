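"""Core containers shared across the pipeline.

The pipeline operates on calibrated time-lapse fluorescence movies (``Movie``),
a temporal reference image used for drift correction and F0 normalisation
(``ReferenceImage``), and an ordered stimulus protocol describing when each
agonist (and the terminal depolarising high-K+ solution) was applied
(``StimulusProtocol``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

#: canonical stimulus labels: TRPM3, TRPA1, TRPV1 agonists and high potassium
AGONISTS = ("M3", "A1", "V1")
K_LABEL = "K"
STIM_LABELS = AGONISTS + (K_LABEL,)


@dataclass
class Movie:
    """A calibrated fluorescence movie, T x Y x X or T x Z x Y x X.

    Parameters
    ----------
    data:
        Intensity array in grey-level units; time is always the first axis.
    frame_period_s:
        Seconds between volumes (4 s for a 0.25 Hz acquisition).
    pixel_size_um:
        Lateral pixel size in micrometres per pixel.
    channel:
        Free-text channel label (e.g. ``"GCaMP3"``).
    """

    data: np.ndarray
    frame_period_s: float = 4.0
    pixel_size_um: float = 1.0
    channel: str = "GCaMP3"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"movie must be TxYxX or TxZxYxX, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def with_data(self, data: np.ndarray) -> "Movie":
        """New movie with the same calibration but different pixel data."""
        return Movie(
            data=data,
            frame_period_s=self.frame_period_s,
            pixel_size_um=self.pixel_size_um,
            channel=self.channel,
            meta=dict(self.meta),
        )

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(
            Path(path),
            np.asarray(self.data),
            metadata={
                "frame_period_s": self.frame_period_s,
                "pixel_size_um": self.pixel_size_um,
                "channel": self.channel,
            },
        )

    @classmethod
    def load(
        cls,
        path: str | Path,
        frame_period_s: float = 4.0,
        pixel_size_um: float = 1.0,
        channel: str = "GCaMP3",
    ) -> "Movie":
        with tifffile.TiffFile(Path(path)) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            data=data,
            frame_period_s=float(meta.get("frame_period_s", frame_period_s)),
            pixel_size_um=float(meta.get("pixel_size_um", pixel_size_um)),
            channel=str(meta.get("channel", channel)),
        )


@dataclass
class ReferenceImage:
    """Temporal mean of the first pre-stimulus frames of a z-projected movie."""

    data: np.ndarray
    n_frames_averaged: int = 10


@dataclass(frozen=True)
class StimWindow:
    """One labelled stimulus application window, in frame indices.

    ``start_frame`` is inclusive, ``end_frame`` exclusive.
    """

    label: str
    start_frame: int
    end_frame: int
    agonist: str = ""

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError(f"empty stimulus window {self.label}")
        if self.start_frame < 0:
            raise ValueError("stimulus window starts before frame 0")


@dataclass
class StimulusProtocol:
    """Ordered, non-overlapping stimulus windows.

    The experimental design keeps agonist order constant (M3 -> A1 -> V1),
    with the depolarising high-K+ challenge last. ``pre_frames`` is the number
    of frames immediately before each onset used as the per-stimulus baseline.
    """

    windows: list[StimWindow]
    pre_frames: int = 10

    def __post_init__(self) -> None:
        if self.pre_frames < 3:
            raise ValueError("pre_frames must be >= 3")
        prev_end = None
        for w in self.windows:
            if prev_end is not None and w.start_frame < prev_end:
                raise ValueError("stimulus windows overlap or are out of order")
            prev_end = w.end_frame
        labels = [w.label for w in self.windows]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate stimulus labels")

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    @property
    def has_k(self) -> bool:
        return K_LABEL in self.labels

    def window(self, label: str) -> StimWindow:
        for w in self.windows:
            if w.label == label:
                return w
        raise KeyError(f"no stimulus labelled {label!r}")

    @property
    def first_onset(self) -> int:
        return min(w.start_frame for w in self.windows)

    @property
    def last_end(self) -> int:
        return max(w.end_frame for w in self.windows)

    def pre_window(self, label: str, gap: int = 0) -> tuple[int, int]:
        """Baseline frames for a stimulus: up to ``pre_frames`` frames ending
        at its onset, never reaching back into the previous window (plus a
        recovery ``gap``)."""
        w = self.window(label)
        lo = w.start_frame - self.pre_frames
        for other in self.windows:
            if other.end_frame <= w.start_frame:
                lo = max(lo, other.end_frame + gap)
        lo = max(lo, 0)
        if w.start_frame - lo < 3:
            raise ValueError(
                f"fewer than 3 baseline frames available before {label!r}"
            )
        return lo, w.start_frame

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "pre_frames": self.pre_frames,
            "windows": [
                {
                    "label": w.label,
                    "start_frame": w.start_frame,
                    "end_frame": w.end_frame,
                    "agonist": w.agonist,
                }
                for w in self.windows
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimulusProtocol":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            windows=[StimWindow(**w) for w in doc["windows"]],
            pre_frames=int(doc.get("pre_frames", 10)),
        )


def default_protocol(
    pre: int = 20,
    stim_len: int = 10,
    wash: int = 20,
    labels: Sequence[str] = STIM_LABELS,
) -> StimulusProtocol:
    """Evenly spaced protocol in the canonical order M3 -> A1 -> V1 -> K.

    At the emulated 0.25 Hz sampling, the defaults place ~80 s stimulations
    separated by wash-out periods, compressed relative to the 5-min wash-outs
    of the experiment so synthetic movies stay small.
    """
    windows = []
    t = pre
    agonist_text = {
        "M3": "PS 100 uM + CIM0216 1 uM",
        "A1": "mustard oil 100 uM",
        "V1": "capsaicin 1 uM",
        "K": "high-K+ depolarisation",
    }
    for lab in labels:
        windows.append(
            StimWindow(lab, t, t + stim_len, agonist=agonist_text.get(lab, ""))
        )
        t += stim_len + wash
    return StimulusProtocol(windows=windows, pre_frames=min(10, pre))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
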