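"""Pooling of quantified responses into uni-/multimodality statistics.

A cell is "responding" when at least one tastant elicits an above-threshold,
QC-passing activation; cells are unimodal when their responded set (within
their own organ) has size 1 and multimodal otherwise.  Fractions are pooled
over all responding cells across organs.  By default only canonical ON
responses count (the convention behind pooled tuning statistics); OFF/late
activations can be included via ``include_off`` for mapping-style exports.
Deactivations never count as responses here -- they are tracked separately by
the mapping stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import UnknownTastantError
from .panel import TastePanel
from .traces import DEFAULT_THRESHOLD, records_to_frame

__all__ = [
    "TuningSummary",
    "pool_responses",
    "group_overlap",
    "combination_frequencies",
    "per_organ_summary",
]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return records_to_frame(records)


def _responding(frame: pd.DataFrame, panel: TastePanel | None,
                threshold: float, include_off: bool) -> pd.DataFrame:
    """QC-passing above-threshold activation records, tastants normalized."""
    required = {"organ_id", "cell_name_in_prep", "tastant", "amplitude",
                "response_class"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    if "qc" in frame.columns:
        frame = frame[frame["qc"].astype(str) == "pass"]
    classes = ("on", "off_late") if include_off else ("on",)
    frame = frame[frame["response_class"].isin(classes)]
    frame = frame[frame["amplitude"].astype(float) >= threshold]
    if panel is not None:
        unknown = [t for t in frame["tastant"].unique() if t not in panel]
        if unknown:
            raise UnknownTastantError(unknown)
        frame = frame.assign(tastant=frame["tastant"].map(panel.normalize))
    # one response per (organ, cell, tastant) even if several trials repeat it
    return frame.drop_duplicates(subset=["organ_id", "cell_name_in_prep", "tastant"])


@dataclass
class TuningSummary:
    """Uni/multimodality counts and fractions over pooled responding cells."""

    n_responding_cells: int
    n_uni: int
    n_multi: int
    responded_sets: Mapping[tuple[str, str], frozenset] = field(default_factory=dict)
    per_organ: pd.DataFrame | None = None
    combination_freqs: pd.DataFrame | None = None

    @property
    def frac_uni(self) -> float:
        return self.n_uni / self.n_responding_cells if self.n_responding_cells else float("nan")

    @property
    def frac_multi(self) -> float:
        return self.n_multi / self.n_responding_cells if self.n_responding_cells else float("nan")

    @property
    def mean_frac_uni_per_organ(self) -> float:
        """Unweighted mean of per-organ unimodal fractions (the per-animal view)."""
        if self.per_organ is None or self.per_organ.empty:
            return float("nan")
        return float(self.per_organ["frac_uni"].mean())


def pool_responses(records, panel: TastePanel | None = None,
                   threshold: float = DEFAULT_THRESHOLD,
                   include_off: bool = False) -> TuningSummary:
    """Pool responding cells across organs into a tuning summary."""
    frame = _responding(_as_frame(records), panel, threshold, include_off)
    sets: dict[tuple[str, str], frozenset] = {}
    for (organ, cell), grp in frame.groupby(["organ_id", "cell_name_in_prep"]):
        sets[(str(organ), str(cell))] = frozenset(grp["tastant"])
    n_uni = sum(1 for s in sets.values() if len(s) == 1)
    n_multi = sum(1 for s in sets.values() if len(s) >= 2)

    organ_rows = []
    for organ in sorted({k[0] for k in sets}):
        organ_sets = {k: s for k, s in sets.items() if k[0] == organ}
        nu = sum(1 for s in organ_sets.values() if len(s) == 1)
        nm = len(organ_sets) - nu
        organ_rows.append({
            "organ_id": organ,
            "n_responding_cells": len(organ_sets),
            "n_responses": int(sum(len(s) for s in organ_sets.values())),
            "n_uni": nu, "n_multi": nm,
            "frac_uni": nu / len(organ_sets),
            "frac_multi": nm / len(organ_sets),
        })
    per_organ = pd.DataFrame(organ_rows, columns=[
        "organ_id", "n_responding_cells", "n_responses", "n_uni", "n_multi",
        "frac_uni", "frac_multi"])
    combos = _combination_table(sets, panel) if panel is not None else None
    return TuningSummary(n_responding_cells=len(sets), n_uni=n_uni,
                         n_multi=n_multi, responded_sets=sets,
                         per_organ=per_organ, combination_freqs=combos)


def group_overlap(records, panel: TastePanel, group_a: str, group_b: str,
                  threshold: float = DEFAULT_THRESHOLD,
                  include_off: bool = False) -> tuple[float, float, float]:
    """Exclusive and overlap fractions between two stimulus groups.

    Among cells responding to at least one of the two groups, returns
    (frac_a_only, frac_b_only, frac_both); the three fractions sum to 1.
    """
    a = panel.normalize(group_a)
    b = panel.normalize(group_b)
    frame = _responding(_as_frame(records), panel, threshold, include_off)
    frame = frame[frame["tastant"].isin([a, b])]
    sets: dict[tuple[str, str], set] = {}
    for (organ, cell), grp in frame.groupby(["organ_id", "cell_name_in_prep"]):
        sets[(organ, cell)] = set(grp["tastant"])
    total = len(sets)
    if total == 0:
        raise ValueError(f"no cells respond to {a!r} or {b!r}: fractions undefined")
    n_both = sum(1 for s in sets.values() if {a, b} <= s)
    n_a = sum(1 for s in sets.values() if s == {a})
    n_b = sum(1 for s in sets.values() if s == {b})
    return n_a / total, n_b / total, n_both / total


def _combination_table(sets: Mapping[tuple[str, str], frozenset],
                       panel: TastePanel) -> pd.DataFrame:
    """Unordered modality-category pair tallies among multimodal cells."""
    multi = [s for s in sets.values() if len(s) >= 2]
    counts: dict[tuple[str, str], int] = {}
    for s in multi:
        for pair in itertools.combinations(sorted(s), 2):
            key = tuple(sorted(panel.category(t) for t in pair))
            counts[key] = counts.get(key, 0) + 1
    rows = [{"category_a": k[0], "category_b": k[1], "count": v,
             "frequency": v / len(multi) if multi else float("nan")}
            for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["category_a", "category_b", "count",
                                       "frequency"])


def combination_frequencies(records, panel: TastePanel,
                            threshold: float = DEFAULT_THRESHOLD,
                            include_off: bool = False) -> pd.DataFrame:
    """Frequency of modality-category pairs among multimodal cells.

    Every unordered tastant pair in a multimodal cell's responded set
    contributes one tally to its category pair; frequencies are normalized by
    the number of multimodal cells (a cell responding to three tastants
    contributes three pairs, so frequencies can exceed 1 in principle).
    """
    frame = _responding(_as_frame(records), panel, threshold, include_off)
    sets: dict[tuple[str, str], frozenset] = {}
    for (organ, cell), grp in frame.groupby(["organ_id", "cell_name_in_prep"]):
        sets[(organ, cell)] = frozenset(grp["tastant"])
    return _combination_table(sets, panel)


def per_organ_summary(records, threshold: float = DEFAULT_THRESHOLD,
                      sucrose_label: str = "sucrose",
                      include_off: bool = False
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-organ response tallies and their means.

    Returns a per-organ table of (above-threshold responses, responding
    cells, sucrose-responding cells) and the across-organ means.
    """
    frame = _responding(_as_frame(records), None, threshold, include_off)
    rows = []
    for organ, grp in frame.groupby("organ_id"):
        cells = grp["cell_name_in_prep"].nunique()
        sucrose = grp.loc[grp["tastant"] == sucrose_label,
                          "cell_name_in_prep"].nunique()
        rows.append({"organ_id": organ, "n_responses": len(grp),
                     "n_responding_cells": cells, "n_sucrose_cells": sucrose})
    per_organ = pd.DataFrame(rows, columns=["organ_id", "n_responses",
                                            "n_responding_cells",
                                            "n_sucrose_cells"])
    means = per_organ[["n_responses", "n_responding_cells",
                       "n_sucrose_cells"]].mean()
    means.name = "mean_per_organ"
    return per_organ, means
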