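"""The movie -> pooled-statistics and table -> pooled-statistics workflows.

Stages run in a fixed order (drift -> align -> segment -> extract -> dF/F ->
classify -> QC -> pool -> map), every intermediate lands as a TSV next to a
machine-readable ``summary.json``, and every output is reproducible from the
configuration plus the seed: the config hash is embedded in the summary and
the log.  The nuclear channel of an organ's first recording anchors
segmentation; the same spot set is reused for every tastant of that organ so
that cell identities are consistent within the organ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .config import PipelineConfig
from .errors import PipelineError
from .imaging import (Recording, align_channels, drift_correct, extract_traces,
                      segment_nuclei)
from .mapping import ReferenceMap, accumulate_support, build_local_frame, \
    match_to_reference
from .multimodality import per_organ_summary, pool_responses
from .panel import TastePanel, default_panel
from .traces import analyze_trace, records_to_frame

__all__ = ["OrganInput", "PipelineResult", "run_pipeline"]


@dataclass
class OrganInput:
    """One organ's recordings, keyed by the tastant each was stimulated with."""

    organ_id: str
    recordings: Mapping[str, Recording]
    series_id: str | None = None


@dataclass
class PipelineResult:
    records: pd.DataFrame
    summary: dict
    spots_by_organ: dict = field(default_factory=dict)
    mapped: list = field(default_factory=list)
    discarded: list = field(default_factory=list)


def _stage(log: list[str], name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.append(f"{name}: FAILED ({exc})")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.append(f"{name}: ok")
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig,
                 organs: Sequence[OrganInput] | None = None,
                 records=None,
                 reference: ReferenceMap | None = None,
                 panel: TastePanel | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full analysis on recordings or on an existing response table.

    Exactly one of ``organs`` (TIFF-level input) or ``records`` (table-level
    input) must be given.  With ``reference`` set and organs available, the
    cross-animal mapping stage runs as well.  ``out_dir`` (optional) receives
    all intermediate TSVs, ``summary.json`` and ``log.txt``.
    """
    if (organs is None) == (records is None):
        raise ValueError("provide exactly one of organs= or records=")
    panel = default_panel() if panel is None else panel
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash: {config.config_hash()}"]
    schedule = config.schedule()
    spots_by_organ: dict[str, object] = {}
    discarded: list[str] = []

    if organs is not None:
        rows = []
        for organ in organs:
            tastants = list(organ.recordings)
            corrected: dict[str, Recording] = {}
            with _stage(log, f"drift[{organ.organ_id}]"):
                for tastant in tastants:
                    res = drift_correct(organ.recordings[tastant])
                    if res.discard:
                        discarded.append(f"{organ.organ_id}/{tastant}")
                        continue
                    corrected[tastant] = res.recording
            with _stage(log, f"align[{organ.organ_id}]"):
                for tastant in list(corrected):
                    corrected[tastant], _ = align_channels(corrected[tastant])
            if not corrected:
                continue
            with _stage(log, f"segment[{organ.organ_id}]"):
                first = corrected[next(iter(corrected))]
                spots = segment_nuclei(
                    first, spot_diameter_um=config.spot_diameter_um,
                    threshold=config.detection_threshold,
                    min_separation_um=config.min_separation_um)
                spots_by_organ[organ.organ_id] = spots
                if out is not None:
                    tio.write_spots(out / f"spots_{organ.organ_id}.tsv", spots)
            with _stage(log, f"extract[{organ.organ_id}]"):
                traces = {t: extract_traces(corrected[t], spots, tastant=t)
                          for t in corrected}
                if out is not None:
                    for t, trs in traces.items():
                        tio.write_traces(out / f"traces_{organ.organ_id}_{t}.tsv",
                                         trs)
            with _stage(log, f"classify[{organ.organ_id}]"):
                for tastant, trs in traces.items():
                    for raw in trs:
                        _, record = analyze_trace(
                            raw, schedule, config.threshold,
                            organ_id=organ.organ_id, tastant=tastant,
                            series_id=organ.series_id)
                        rows.append(record)
        records_frame = records_to_frame(rows)
    else:
        records_frame = (records.copy() if isinstance(records, pd.DataFrame)
                         else records_to_frame(records))
        log.append("imaging stages: skipped (table input)")

    if out is not None:
        tio.write_records(out / "records.tsv", records_frame)

    with _stage(log, "pool"):
        summary_stats = pool_responses(records_frame, panel=panel,
                                       threshold=config.threshold)
        per_organ, means = per_organ_summary(records_frame,
                                             threshold=config.threshold)

    mapped = []
    if reference is not None and spots_by_organ:
        with _stage(log, "map"):
            assignments = {}
            for organ_id, spots in spots_by_organ.items():
                frame = build_local_frame(spots.cell_ids(), spots.centroids())
                assignments[organ_id] = match_to_reference(
                    frame, reference, max_dist=config.max_dist)
            mapped = accumulate_support(
                assignments, records_frame, panel=panel,
                threshold=config.threshold,
                min_support=config.min_support,
                bitter_min_support=config.bitter_min_support)
            if out is not None:
                tio.write_mapped_responses(out / "mapped_responses.tsv", mapped)

    summary = {
        "config_hash": config.config_hash(),
        "threshold": config.threshold,
        "n_records": int(len(records_frame)),
        "n_responding_cells": summary_stats.n_responding_cells,
        "n_uni": summary_stats.n_uni,
        "n_multi": summary_stats.n_multi,
        "frac_uni": summary_stats.frac_uni,
        "frac_multi": summary_stats.frac_multi,
        "mean_responses_per_organ": float(means["n_responses"]) if len(per_organ) else None,
        "mean_responding_cells_per_organ": (float(means["n_responding_cells"])
                                            if len(per_organ) else None),
        "mean_sucrose_cells_per_organ": (float(means["n_sucrose_cells"])
                                         if len(per_organ) else None),
        "n_mapped": sum(1 for m in mapped if m.mapped),
        "discarded_recordings": sorted(discarded),
    }
    summary = {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
               for k, v in summary.items()}
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True),
            encoding="utf-8")
        (out / "log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return PipelineResult(records=records_frame, summary=summary,
                          spots_by_organ=spots_by_organ, mapped=mapped,
                          discarded=discarded)
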