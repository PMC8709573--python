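"""Cross-animal cell-identity mapping anchored on the landmark cluster.

Cell identities cannot be compared across animals in raw stage coordinates:
every preparation sits at its own position, orientation and slight scale.
Each organ is therefore re-expressed in a local frame built from its own
geometry: the origin is the main-cloud centroid, the first axis points toward
the centroid of the four anterior-lateral landmark cells, the remaining axes
come from the principal components of the cloud (signs fixed
deterministically, third axis by right-handedness), and coordinates are
divided by the RMS cloud radius.  The construction is invariant to rigid
motion and uniform scaling.

Spots in the local frame are assigned to named reference identities by
optimal bipartite matching; pairs farther than ``max_dist`` stay unassigned.
A (identity, tastant) activation is considered mapped once it is supported by
at least 4 distinct organs (3 for bitter stimulations, which were sampled
less densely); deactivations accumulate support separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import InsufficientSpotsError
from .panel import TastePanel
from .traces import DEFAULT_THRESHOLD, records_to_frame

__all__ = [
    "ReferenceMap",
    "LocalFrame",
    "MappedResponse",
    "build_local_frame",
    "detect_landmarks",
    "match_to_reference",
    "accumulate_support",
    "default_max_dist",
]

MIN_SUPPORT = 4
BITTER_MIN_SUPPORT = 3


@dataclass(frozen=True)
class ReferenceMap:
    """Named identities at normalized coordinates.

    Identity labels follow the positional naming scheme (C=central, V=ventral,
    D=dorsal, P=posterior, A=anterior, M=medial, L=lateral; e.g. PM1, CDL2),
    plus the ALN1-4 landmarks.
    """

    identities: tuple[str, ...]
    coords: np.ndarray  # (n, 3) normalized

    def __post_init__(self):
        object.__setattr__(self, "coords",
                           np.asarray(self.coords, dtype=float).reshape(-1, 3))
        if len(self.identities) != len(self.coords):
            raise ValueError("identities and coordinates must align")
        if len(set(self.identities)) != len(self.identities):
            raise ValueError("identity labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self):
        return len(self.identities)


@dataclass(frozen=True)
class LocalFrame:
    """An organ's spots in its landmark-anchored, scale-normalized frame."""

    cell_ids: tuple[str, ...]
    coords: np.ndarray            # (n, 3) normalized
    landmark_ids: tuple[str, ...]
    origin_um: np.ndarray         # main-cloud centroid in organ coordinates
    axes: np.ndarray              # (3, 3) rows e1, e2, e3
    scale_um: float               # RMS cloud radius

    def cloud(self) -> np.ndarray:
        lm = set(self.landmark_ids)
        return self.coords[[i for i, c in enumerate(self.cell_ids) if c not in lm]]


def detect_landmarks(positions: np.ndarray) -> np.ndarray:
    """Indices of the landmark cluster: the tightest 4-spot cluster maximally
    displaced from the centroid of the remaining spots.

    Each spot seeds a candidate cluster of itself plus its 3 nearest
    neighbors; the winning candidate maximizes
    displacement x isolation / (1 + spread), where displacement is the
    distance from the cluster centroid to the remaining spots' centroid,
    isolation the gap between the cluster and its nearest non-member, and
    spread the cluster's RMS radius.  The landmark group is displaced from,
    tight, and separated from the main cloud; cloud quadruples fail on at
    least the isolation term.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 8:
        raise InsufficientSpotsError(
            f"need >= 8 spots to separate a 4-cell landmark cluster, got {n}")
    d = cdist(positions, positions)
    best_score, best = -np.inf, None
    for i in range(n):
        members = np.argsort(d[i])[:4]
        rest_idx = np.setdiff1d(np.arange(n), members)
        cluster = positions[members]
        spread = float(np.sqrt(((cluster - cluster.mean(0)) ** 2).sum(1).mean()))
        disp = float(np.linalg.norm(cluster.mean(0) - positions[rest_idx].mean(0)))
        isolation = float(d[np.ix_(members, rest_idx)].min())
        score = disp * isolation / (1.0 + spread)
        if score > best_score:
            best_score, best = score, np.sort(members)
    return best


def _fix_sign(axis: np.ndarray, centered: np.ndarray) -> np.ndarray:
    """Deterministic sign for a principal axis: positive standardized third
    moment (skewness) of the projections.  Organs are chiral enough in
    practice for the skewness to be well away from zero, which makes the
    sign stable under positional jitter; near-symmetric clouds fall back to
    the largest-|projection| spot being positive (deterministic, though not
    jitter-stable -- no rule can be for a symmetric cloud)."""
    proj = centered @ axis
    sd = float(proj.std())
    if sd > 0:
        skew = float(np.mean((proj / sd) ** 3))
        if abs(skew) > 0.05:
            return axis if skew > 0 else -axis
    j = int(np.argmax(np.abs(proj)))
    return axis if proj[j] >= 0 else -axis


def build_local_frame(cell_ids: Sequence[str], positions_um: np.ndarray,
                      landmark_ids: Sequence[str] | None = None) -> LocalFrame:
    """Build the landmark-anchored, scale-normalized frame of one organ.

    ``landmark_ids`` names the 4 landmark cells when known (e.g. from the
    generator); otherwise they are detected with :func:`detect_landmarks`.
    """
    cell_ids = tuple(str(c) for c in cell_ids)
    positions = np.asarray(positions_um, dtype=float).reshape(-1, 3)
    if len(cell_ids) != len(positions):
        raise ValueError("cell ids and positions must align")
    if len(cell_ids) < 8:
        raise InsufficientSpotsError(
            f"need >= 8 spots to build a frame, got {len(cell_ids)}")
    if landmark_ids is None:
        lm_idx = detect_landmarks(positions)
        landmark_ids = tuple(cell_ids[i] for i in lm_idx)
    else:
        landmark_ids = tuple(str(c) for c in landmark_ids)
        if len(landmark_ids) != 4:
            raise ValueError("exactly 4 landmark ids expected")
        lm_idx = np.array([cell_ids.index(c) for c in landmark_ids])

    lm_mask = np.zeros(len(cell_ids), dtype=bool)
    lm_mask[lm_idx] = True
    cloud = positions[~lm_mask]
    origin = cloud.mean(axis=0)
    lm_centroid = positions[lm_mask].mean(axis=0)
    e1 = lm_centroid - origin
    norm = np.linalg.norm(e1)
    if norm == 0:
        raise ValueError("landmark centroid coincides with the cloud centroid")
    e1 = e1 / norm

    centered = cloud - origin
    perp = centered - np.outer(centered @ e1, e1)
    cov = perp.T @ perp
    evals, evecs = np.linalg.eigh(cov)
    e2 = evecs[:, int(np.argmax(evals))]
    e2 = e2 - (e2 @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e2 = _fix_sign(e2, centered)
    e3 = np.cross(e1, e2)  # right-handed
    axes = np.vstack([e1, e2, e3])

    scale = float(np.sqrt((centered ** 2).sum(axis=1).mean()))
    if scale == 0:
        raise ValueError("degenerate cloud: zero RMS radius")
    coords = (positions - origin) @ axes.T / scale
    return LocalFrame(cell_ids=cell_ids, coords=coords,
                      landmark_ids=landmark_ids, origin_um=origin, axes=axes,
                      scale_um=scale)


def default_max_dist(reference: ReferenceMap) -> float:
    """Half the median nearest-neighbor distance among reference identities."""
    d = cdist(reference.coords, reference.coords)
    np.fill_diagonal(d, np.inf)
    return 0.5 * float(np.median(d.min(axis=1)))


def _rotate_about_first_axis(coords: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    out = coords.copy()
    out[:, 1] = c * coords[:, 1] - s * coords[:, 2]
    out[:, 2] = s * coords[:, 1] + c * coords[:, 2]
    return out


def _assignment_cost(coords: np.ndarray, ref_coords: np.ndarray,
                     max_dist: float):
    d = cdist(coords, ref_coords)
    n = d.shape[0]
    cost = np.hstack([d, np.full((n, n), float(max_dist))])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum()), d, rows, cols


def match_to_reference(frame: LocalFrame, reference: ReferenceMap,
                       max_dist: float | None = None,
                       refine_rotation: bool = True) -> dict[str, str]:
    """Optimal one-to-one assignment of an organ's spots to reference identities.

    Minimizes total normalized distance with an unassignment option at cost
    ``max_dist`` (default :func:`default_max_dist`); a spot whose best use in
    the global optimum would cost more than ``max_dist`` stays unassigned.

    The orientation of the local frame about the landmark axis rests on the
    cloud's second and third moments, which a handful of jittered cell
    positions can rotate; with ``refine_rotation`` the residual rotation
    about that axis is resolved against the reference by minimizing the
    assignment cost over a deterministic angle grid (coarse 7.5 deg sweep,
    then a 1.5 deg local refinement; zero rotation wins ties).

    Returns {cell_id: identity}.
    """
    if len(reference) == 0:
        raise ValueError("empty reference map")
    if max_dist is None:
        max_dist = default_max_dist(reference)
    # lexicographic identity order makes tie-breaking deterministic
    order = np.argsort(np.asarray(reference.identities))
    ids = [reference.identities[i] for i in order]
    ref_coords = reference.coords[order]

    angles = [0.0]
    if refine_rotation:
        angles += [math.radians(a) for a in np.arange(7.5, 360.0, 7.5)]
    best = None
    best_angle = 0.0
    for angle in angles:
        total, d, rows, cols = _assignment_cost(
            _rotate_about_first_axis(frame.coords, angle), ref_coords, max_dist)
        if best is None or total < best[0] - 1e-12:
            best = (total, d, rows, cols)
            best_angle = angle
    if refine_rotation:
        for fine in np.arange(-6.0, 6.1, 1.5):
            if fine == 0.0:
                continue
            angle = best_angle + math.radians(fine)
            total, d, rows, cols = _assignment_cost(
                _rotate_about_first_axis(frame.coords, angle), ref_coords,
                max_dist)
            if total < best[0] - 1e-12:
                best = (total, d, rows, cols)
    _, d, rows, cols = best
    assignment: dict[str, str] = {}
    for r, c in zip(rows, cols):
        if c < len(ids) and d[r, c] <= max_dist:
            assignment[frame.cell_ids[r]] = ids[c]
    return assignment


@dataclass(frozen=True)
class MappedResponse:
    identity: str
    tastant: str
    response_class: str    # "activation" or "deactivation"
    support: int           # distinct organs showing the response
    min_support: int

    @property
    def mapped(self) -> bool:
        return self.support >= self.min_support


def accumulate_support(assignments: Mapping[str, Mapping[str, str]],
                       records, panel: TastePanel | None = None,
                       threshold: float = DEFAULT_THRESHOLD,
                       min_support: int = MIN_SUPPORT,
                       bitter_min_support: int = BITTER_MIN_SUPPORT
                       ) -> list[MappedResponse]:
    """Count per-(identity, tastant) support across organs.

    ``assignments`` maps organ_id -> {cell_name_in_prep: identity}.
    Activations pool ON and OFF/late responses; deactivations are accumulated
    separately.  Support is the number of distinct organs, so organ order is
    irrelevant.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if "qc" in frame.columns:
        frame = frame[frame["qc"].astype(str) == "pass"]
    organs: dict[tuple[str, str, str], set] = {}
    for row in frame.to_dict("records"):
        organ = str(row["organ_id"])
        cell = str(row["cell_name_in_prep"])
        identity = assignments.get(organ, {}).get(cell)
        if identity is None:
            continue
        cls = row["response_class"]
        amp = float(row["amplitude"])
        if cls in ("on", "off_late") and amp >= threshold:
            kind = "activation"
        elif cls == "deactivation" and amp <= -threshold:
            kind = "deactivation"
        else:
            continue
        tastant = panel.normalize(row["tastant"]) if panel is not None else str(row["tastant"])
        organs.setdefault((identity, tastant, kind), set()).add(organ)

    out = []
    for (identity, tastant, kind), organ_set in sorted(organs.items()):
        need = min_support
        if panel is not None and panel.is_bitter(tastant):
            need = bitter_min_support
        out.append(MappedResponse(identity=identity, tastant=tastant,
                                  response_class=kind, support=len(organ_set),
                                  min_support=need))
    return out
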