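"""Central pipeline configuration: every stage reads its numbers from here."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

from .traces import StimulusSchedule

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Response quantification: 20% dF/F0 threshold, 10-frame baseline, 5-frame
    peak window, stimulus on frames 30-44 of 60 at 2 s/frame.  Imaging:
    3.5 um segmentation spots on 1.5 x 0.43 x 0.43 um voxels.  Mapping:
    support of >= 4 organs (>= 3 for bitter stimulations).
    """

    threshold: float = 0.20
    baseline_len: int = 10
    peak_window: int = 5
    stim_onset_frame: int = 30
    stim_offset_frame: int = 45
    n_frames: int = 60
    frame_interval: float = 2.0
    spot_diameter_um: float = 3.5
    voxel_size: tuple[float, float, float] = (1.5, 0.43, 0.43)
    detection_threshold: float | None = None   # LoG response floor; None = 10% of peak
    min_separation_um: float | None = None     # NMS separation; None = spot diameter
    min_support: int = 4
    bitter_min_support: int = 3
    include_off_for_mapping: bool = True
    max_dist: float | None = None              # mapping gate; None = data-derived
    seed: int = 0
    note: str = ""

    def schedule(self) -> StimulusSchedule:
        return StimulusSchedule(onset_frame=self.stim_onset_frame,
                                offset_frame=self.stim_offset_frame,
                                n_frames=self.n_frames,
                                baseline_len=self.baseline_len,
                                peak_window=self.peak_window,
                                frame_interval=self.frame_interval)

    # -- flat key-value serialization ---------------------------------------

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                lines.append(f"{f.name} = " + ",".join(repr(x) for x in v))
            elif isinstance(v, str):
                lines.append(f"{f.name} = {v!r}")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def to_file(self, path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"line {lineno}: unknown parameter {key!r}")
            kwargs[key] = _parse_value(key, raw)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_text().encode()).hexdigest()[:12]


def _parse_value(key: str, raw: str):
    if raw == "None":
        return None
    if raw in ("True", "False"):
        return raw == "True"
    if raw.startswith(("'", '"')) and raw.endswith(("'", '"')):
        return raw[1:-1]
    if "," in raw:
        return tuple(float(x) for x in raw.split(","))
    if key in ("baseline_len", "peak_window", "stim_onset_frame",
               "stim_offset_frame", "n_frames", "min_support",
               "bitter_min_support", "seed"):
        return int(raw)
    try:
        return float(raw)
    except ValueError:
        return raw
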