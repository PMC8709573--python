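"""File formats: TIFF hyperstacks, TSV/CSV tables, and the XLSX importer.

Recordings travel as 16-bit multi-page TIFF hyperstacks in TCZYX order with a
JSON sidecar (same stem, ``.json``) holding voxel sizes, frame interval,
channel roles and the stimulus schedule.  All tables are UTF-8 TSV/CSV with
explicit headers.  XLSX is import-only, for spreadsheets laid out like the
published source-data workbooks (one or more response-list sheets whose
header row contains ``cell_name_in_prep``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .behavior import ChoiceCounts
from .errors import SchemaError, UnknownTastantError
from .imaging import RawTrace, Recording, Spot, SpotSet
from .mapping import MappedResponse, ReferenceMap
from .panel import TastePanel, default_panel
from .traces import ResponseRecord, frame_to_records, records_to_frame

__all__ = [
    "write_recording", "read_recording",
    "write_spots", "read_spots",
    "write_traces", "read_traces",
    "write_records", "read_records",
    "write_reference_map", "read_reference_map",
    "write_mapped_responses",
    "write_choice_counts", "read_choice_counts",
    "import_source_data", "ImportIssue",
]


# --- recordings -------------------------------------------------------------

def write_recording(path, recording: Recording) -> None:
    """16-bit TCZYX TIFF plus a JSON sidecar with geometry and roles."""
    path = Path(path)
    data = np.clip(np.round(recording.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": "TCZYX"})
    sidecar = {
        "voxel_size_um": list(recording.voxel_size),
        "frame_interval_s": recording.frame_interval,
        "channels": recording.channels,
        "stimulus": list(recording.stimulus) if recording.stimulus else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1,
                                                    sort_keys=True),
                                         encoding="utf-8")


def read_recording(path) -> Recording:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim != 5:
        raise SchemaError(f"{path}: expected a 5D TCZYX stack, got {data.shape}")
    meta_path = path.with_suffix(".json")
    voxel = (1.5, 0.43, 0.43)
    interval, channels, stimulus = 2.0, {"nuclear": 0, "calcium": 1}, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        voxel = tuple(meta.get("voxel_size_um", voxel))
        interval = meta.get("frame_interval_s", interval)
        channels = meta.get("channels", channels)
        stimulus = tuple(meta["stimulus"]) if meta.get("stimulus") else None
    return Recording(intensities=data, voxel_size=voxel, frame_interval=interval,
                     channels=channels, stimulus=stimulus)


# --- spots and traces -------------------------------------------------------

def write_spots(path, spots: SpotSet) -> None:
    rows = [{"cell_id": s.cell_id, "z_um": s.centroid_um[0],
             "y_um": s.centroid_um[1], "x_um": s.centroid_um[2],
             "radius_um": s.radius_um} for s in spots]
    pd.DataFrame(rows, columns=["cell_id", "z_um", "y_um", "x_um",
                                "radius_um"]).to_csv(path, sep="\t", index=False)


def read_spots(path, volume_shape=(0, 0, 0),
               voxel_size=(1.5, 0.43, 0.43)) -> SpotSet:
    frame = pd.read_csv(path, sep="\t")
    spots = [Spot(cell_id=str(r.cell_id), centroid_um=(r.z_um, r.y_um, r.x_um),
                  radius_um=r.radius_um) for r in frame.itertuples()]
    return SpotSet(spots, tuple(volume_shape), tuple(voxel_size))


def write_traces(path, traces: Sequence[RawTrace]) -> None:
    """Wide TSV: one ``frame`` column plus one column per cell."""
    if not traces:
        raise ValueError("no traces to write")
    table = {"frame": np.arange(len(traces[0].values))}
    for tr in traces:
        table[tr.cell_id] = tr.values
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)


def read_traces(path, tastant: str = "") -> list[RawTrace]:
    frame = pd.read_csv(path, sep="\t")
    return [RawTrace(cell_id=c, values=frame[c].to_numpy(dtype=float),
                     tastant=tastant)
            for c in frame.columns if c != "frame"]


# --- response records -------------------------------------------------------

def write_records(path, records) -> None:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)


def read_records(path) -> list[ResponseRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))


# --- mapping ----------------------------------------------------------------

def write_reference_map(path, reference: ReferenceMap) -> None:
    pd.DataFrame({"identity": reference.identities,
                  "x": reference.coords[:, 0],
                  "y": reference.coords[:, 1],
                  "z": reference.coords[:, 2]}).to_csv(path, sep="\t", index=False)


def read_reference_map(path) -> ReferenceMap:
    frame = pd.read_csv(path, sep="\t")
    return ReferenceMap(identities=tuple(frame["identity"].astype(str)),
                        coords=frame[["x", "y", "z"]].to_numpy(dtype=float))


def write_mapped_responses(path, mapped: Sequence[MappedResponse]) -> None:
    rows = [{"map_cell_name": m.identity, "tastant": m.tastant,
             "response_class": m.response_class, "support": m.support,
             "min_support": m.min_support, "mapped": m.mapped} for m in mapped]
    pd.DataFrame(rows, columns=["map_cell_name", "tastant", "response_class",
                                "support", "min_support",
                                "mapped"]).to_csv(path, sep="\t", index=False)


# --- behavior ---------------------------------------------------------------

def write_choice_counts(path, counts: Iterable[ChoiceCounts]) -> None:
    rows = [{"genotype": c.genotype, "substrate": c.substrate,
             "timepoint": c.timepoint, "n_test": c.n_test,
             "n_plain": c.n_plain, "n_middle": c.n_middle} for c in counts]
    pd.DataFrame(rows, columns=["genotype", "substrate", "timepoint", "n_test",
                                "n_plain", "n_middle"]).to_csv(path, index=False)


def read_choice_counts(path) -> list[ChoiceCounts]:
    frame = pd.read_csv(path)
    out = []
    for r in frame.to_dict("records"):
        out.append(ChoiceCounts(
            n_test=int(r["n_test"]), n_plain=int(r["n_plain"]),
            n_middle=int(r.get("n_middle", 0) or 0),
            timepoint=None if pd.isna(r.get("timepoint")) else float(r["timepoint"]),
            genotype=None if pd.isna(r.get("genotype")) else str(r["genotype"]),
            substrate=None if pd.isna(r.get("substrate")) else str(r["substrate"])))
    return out


# --- XLSX source-data importer ---------------------------------------------

@dataclass(frozen=True)
class ImportIssue:
    sheet: str
    row: int      # 1-based spreadsheet row
    message: str


_SCHEMAS = {
    # response-list sheets of the grouped-stimulation workbook (sheets 2-3)
    "fig2_sd1": {"mandatory": ("cell_name_in_prep", "tastant", "amplitude")},
    # response list of the series-stimulation workbook
    "fig2_sd2": {"mandatory": ("cell_name_in_prep", "tastant", "amplitude")},
    # mapped-response workbook
    "fig3_sd1": {"mandatory": ("map_cell_name", "tastant")},
}

_ORGAN_COLUMNS = ("organ_id", "organ", "prep", "preparation", "animal", "larva")
_CLASS_ALIASES = {"on": "on", "early": "on", "off": "off_late", "late": "off_late",
                  "off_late": "off_late", "deactivation": "deactivation",
                  "drop": "deactivation", "none": "none"}


def _find_header(sheet_frame: pd.DataFrame, mandatory: Sequence[str]) -> int | None:
    key = mandatory[0]
    for i in range(min(len(sheet_frame), 20)):
        row = [str(v).strip().casefold() for v in sheet_frame.iloc[i]]
        if key in row:
            return i
    return None


def import_source_data(path, schema: str, panel: TastePanel | None = None
                       ) -> tuple[list[ResponseRecord], list[ImportIssue]]:
    """Import a source-data style XLSX workbook into typed response records.

    The workbook may hold a summary sheet plus one or more response-list
    sheets; a sheet is parsed when some row within its first 20 rows contains
    the mandatory columns of ``schema`` (``fig2_sd1``, ``fig2_sd2`` or
    ``fig3_sd1``).  Tastant labels are normalized against ``panel``;
    unparseable rows are reported with their spreadsheet row numbers instead
    of aborting the import, but a missing mandatory column or an unknown
    tastant label raises.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of "
                          f"{sorted(_SCHEMAS)}")
    panel = default_panel() if panel is None else panel
    mandatory = _SCHEMAS[schema]["mandatory"]
    book = pd.read_excel(path, sheet_name=None, header=None, engine="openpyxl")
    records: list[ResponseRecord] = []
    issues: list[ImportIssue] = []
    parsed_any = False
    for sheet_name, raw in book.items():
        if raw.empty:
            continue
        header_row = _find_header(raw, mandatory)
        if header_row is None:
            continue
        parsed_any = True
        header = [str(v).strip() for v in raw.iloc[header_row]]
        frame = raw.iloc[header_row + 1:].copy()
        frame.columns = header
        frame = frame.dropna(how="all")
        cols = {c.casefold(): c for c in frame.columns}
        missing = [m for m in mandatory if m not in cols]
        if missing:
            raise SchemaError(f"sheet {sheet_name!r}: missing mandatory "
                              f"column(s) {missing}")
        organ_col = next((cols[c] for c in _ORGAN_COLUMNS if c in cols), None)
        unknown_tastants: set[str] = set()
        for offset, (_, row) in enumerate(frame.iterrows()):
            sheet_row = header_row + 2 + offset  # 1-based incl. header
            try:
                tastant_raw = str(row[cols["tastant"]]).strip()
                if panel is not None:
                    try:
                        tastant = panel.normalize(tastant_raw)
                    except UnknownTastantError:
                        unknown_tastants.add(tastant_raw)
                        continue
                else:
                    tastant = tastant_raw
                if schema == "fig3_sd1":
                    cell = str(row[cols["map_cell_name"]]).strip()
                    amplitude = float(row[cols["amplitude"]]) if "amplitude" in cols else 0.0
                    map_name = cell
                else:
                    cell = str(row[cols["cell_name_in_prep"]]).strip()
                    amplitude = float(row[cols["amplitude"]])
                    map_name = (str(row[cols["map_cell_name"]]).strip()
                                if "map_cell_name" in cols
                                and pd.notna(row[cols["map_cell_name"]]) else None)
                if not cell or cell.lower() == "nan":
                    raise ValueError("empty cell name")
                cls = "on"
                if "response_class" in cols and pd.notna(row[cols["response_class"]]):
                    raw_cls = str(row[cols["response_class"]]).strip().casefold()
                    if raw_cls not in _CLASS_ALIASES:
                        raise ValueError(f"unknown response class {raw_cls!r}")
                    cls = _CLASS_ALIASES[raw_cls]
                organ = (str(row[organ_col]).strip() if organ_col is not None
                         and pd.notna(row[organ_col]) else sheet_name)
                series = (str(row[cols["series"]]).strip()
                          if "series" in cols and pd.notna(row[cols["series"]])
                          else None)
                records.append(ResponseRecord(
                    organ_id=organ, cell_name_in_prep=cell, tastant=tastant,
                    amplitude=amplitude, response_class=cls, qc="pass",
                    series_id=series, map_cell_name=map_name))
            except (ValueError, TypeError, KeyError) as exc:
                issues.append(ImportIssue(sheet=sheet_name, row=sheet_row,
                                          message=str(exc)))
        if unknown_tastants:
            raise UnknownTastantError(sorted(unknown_tastants))
    if not parsed_any:
        raise SchemaError(
            f"{path}: no sheet matches schema {schema!r} "
            f"(no header row with {mandatory[0]!r} found)")
    return records, issues
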