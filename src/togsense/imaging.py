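"""Volumetric two-channel recording handling: drift, alignment, segmentation.

A recording is a (frame, channel, z, y, x) intensity grid with two channels:
a static nuclear reporter used for registration and segmentation, and a
calcium reporter whose per-cell mean intensity becomes the response trace.
Axis order is (z, y, x) throughout; voxel indices are 0-based and physical
coordinates are micrometres with the origin at the center of voxel (0, 0, 0).

The drift model is rigid translation only.  Per-frame shifts are estimated by
maximizing the (mean-subtracted) cross-correlation with a reference frame,
with an optional 3-point parabolic per-axis sub-voxel refinement of the
correlation peak.  Nuclear segmentation is scale-matched 3D blob detection: a
Laplacian-of-Gaussian filter at sigma = diameter / (2 sqrt 3), corrected for
voxel anisotropy, followed by greedy non-maximum suppression at a minimum
centroid separation in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import DegenerateInputError

__all__ = [
    "Recording",
    "DriftTrack",
    "Spot",
    "SpotSet",
    "RawTrace",
    "DriftCorrection",
    "estimate_drift",
    "apply_drift",
    "drift_correct",
    "align_channels",
    "segment_nuclei",
    "extract_traces",
]

DEFAULT_SPOT_DIAMETER_UM = 3.5
#: residual (voxels) above which a drift-corrected recording is flagged discard
DRIFT_RESIDUAL_LIMIT = 2.0


@dataclass
class Recording:
    """Two-channel time-lapse volume plus acquisition geometry."""

    intensities: np.ndarray          # (T, C, Z, Y, X), non-negative
    voxel_size: tuple[float, float, float] = (1.5, 0.43, 0.43)  # um (z, y, x)
    frame_interval: float = 2.0      # seconds
    channels: dict = field(default_factory=lambda: {"nuclear": 0, "calcium": 1})
    stimulus: tuple[int, int] | None = None  # (onset frame, offset frame)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 5:
            raise ValueError("intensities must be 5D (frame, channel, z, y, x)")
        if self.intensities.shape[1] != 2:
            raise ValueError("exactly 2 channels required")
        if self.intensities.min() < 0:
            raise ValueError("intensities must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.stimulus is not None and self.n_frames < self.stimulus[1]:
            raise ValueError("n_frames must cover the stimulus offset")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[2:]

    def channel(self, role: str) -> np.ndarray:
        """The (T, Z, Y, X) stack of one channel role."""
        return self.intensities[:, self.channels[role]]


@dataclass(frozen=True)
class DriftTrack:
    """Per-frame rigid translation (voxels, z/y/x) relative to a reference."""

    shifts: np.ndarray  # (T, 3)
    reference_frame: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shifts", np.asarray(self.shifts, dtype=float))
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must be (n_frames, 3)")


@dataclass(frozen=True)
class Spot:
    cell_id: str
    centroid_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float = DEFAULT_SPOT_DIAMETER_UM / 2


@dataclass
class SpotSet:
    spots: list[Spot]
    volume_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __len__(self):
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def centroids(self) -> np.ndarray:
        return np.array([s.centroid_um for s in self.spots], dtype=float).reshape(-1, 3)

    def cell_ids(self) -> list[str]:
        return [s.cell_id for s in self.spots]


@dataclass(frozen=True)
class RawTrace:
    """Per-frame mean calcium-channel intensity of one segmented cell."""

    cell_id: str
    values: np.ndarray
    tastant: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


# ---------------------------------------------------------------------------
# cross-correlation machinery
# ---------------------------------------------------------------------------

def _signed_freq_index(n: int) -> np.ndarray:
    """Circular index -> signed shift: 0, 1, ..., n//2, -(n - n//2 - 1), ..., -1."""
    idx = np.arange(n)
    return np.where(idx <= n // 2, idx, idx - n)


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2 * c0 + cp1
    if denom >= 0:  # not a local max; keep the integer estimate
        return 0.0
    delta = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _cross_correlate_shift(ref: np.ndarray, mov: np.ndarray,
                           max_shift: Sequence[float] | None = None,
                           subvoxel: bool = True) -> np.ndarray:
    """Translation t (per axis, voxels) such that ``mov`` ~= ``ref`` shifted by t."""
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    if not np.any(ref) or not np.any(mov):
        raise DegenerateInputError("flat volume: cannot estimate a shift")
    cc = np.fft.ifftn(np.fft.fftn(ref) * np.conj(np.fft.fftn(mov))).real
    # cc[k] = sum_x ref(x) mov(x - k); mov = ref shifted by +t peaks at k = -t
    shape = cc.shape
    if max_shift is None:
        max_shift = [s // 2 - 1 if s > 3 else s // 2 for s in shape]
    max_shift = np.broadcast_to(np.asarray(max_shift, dtype=float), (len(shape),))
    mask = np.ones(shape, dtype=bool)
    for ax, (n, ms) in enumerate(zip(shape, max_shift)):
        signed = _signed_freq_index(n)
        sel = np.abs(signed) <= ms
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        mask &= sel[tuple(sl)]
    cc_masked = np.where(mask, cc, -np.inf)
    peak = np.unravel_index(int(np.argmax(cc_masked)), shape)
    k = np.array([_signed_freq_index(n)[i] for n, i in zip(shape, peak)], dtype=float)
    if subvoxel:
        for ax, n in enumerate(shape):
            im1 = list(peak); ip1 = list(peak)
            im1[ax] = (peak[ax] - 1) % n
            ip1[ax] = (peak[ax] + 1) % n
            k[ax] += _parabolic_offset(cc[tuple(im1)], cc[tuple(peak)], cc[tuple(ip1)])
    return -k


def estimate_drift(recording: Recording, channel: str = "nuclear",
                   reference_frame: int = 0,
                   max_shift: Sequence[float] | None = None,
                   subvoxel: bool = True) -> DriftTrack:
    """Per-frame rigid translation of ``channel`` relative to a reference frame."""
    stack = recording.channel(channel)
    if not (0 <= reference_frame < recording.n_frames):
        raise ValueError(f"reference frame {reference_frame} out of range")
    ref = stack[reference_frame]
    if not np.any(ref - ref.mean()):
        raise DegenerateInputError("reference frame is flat")
    shifts = np.zeros((recording.n_frames, 3))
    for t in range(recording.n_frames):
        if t == reference_frame:
            continue
        shifts[t] = _cross_correlate_shift(ref, stack[t], max_shift=max_shift,
                                           subvoxel=subvoxel)
    return DriftTrack(shifts=shifts, reference_frame=reference_frame)


def apply_drift(recording: Recording, track: DriftTrack) -> Recording:
    """Translate every frame (both channels) by the negated track vector.

    Out-of-range voxels are filled with 0.  Integer shifts are lossless in
    the interior; fractional shifts use linear interpolation.
    """
    if track.shifts.shape[0] != recording.n_frames:
        raise ValueError("track length does not match recording")
    data = recording.intensities
    out = np.empty_like(data)
    for t in range(recording.n_frames):
        shift = -track.shifts[t]
        if np.allclose(shift, 0):
            out[t] = data[t]
            continue
        for c in range(data.shape[1]):
            out[t, c] = ndimage.shift(data[t, c], shift, order=1,
                                      mode="constant", cval=0.0, prefilter=False)
    out = np.clip(out, 0, None)
    return replace_recording(recording, intensities=out)


def replace_recording(recording: Recording, **kwargs) -> Recording:
    fields = dict(
        intensities=recording.intensities,
        voxel_size=recording.voxel_size,
        frame_interval=recording.frame_interval,
        channels=dict(recording.channels),
        stimulus=recording.stimulus,
    )
    fields.update(kwargs)
    return Recording(**fields)


@dataclass(frozen=True)
class DriftCorrection:
    recording: Recording
    track: DriftTrack
    residual: float      # max |residual shift| (voxels) after correction
    discard: bool        # True when the residual exceeds DRIFT_RESIDUAL_LIMIT


def drift_correct(recording: Recording, channel: str = "nuclear",
                  reference_frame: int = 0,
                  max_shift: Sequence[float] | None = None,
                  subvoxel: bool = True) -> DriftCorrection:
    """Estimate, apply, and verify drift correction.

    Recordings whose residual per-frame shift after correction exceeds
    :data:`DRIFT_RESIDUAL_LIMIT` voxels are flagged for discard, mirroring
    manual practice of dropping recordings that fail motion rectification.
    """
    track = estimate_drift(recording, channel, reference_frame, max_shift, subvoxel)
    corrected = apply_drift(recording, track)
    residual_track = estimate_drift(corrected, channel, reference_frame,
                                    max_shift, subvoxel=False)
    residual = float(np.abs(residual_track.shifts).max())
    return DriftCorrection(recording=corrected, track=track, residual=residual,
                           discard=residual > DRIFT_RESIDUAL_LIMIT)


def align_channels(recording: Recording,
                   max_shift: Sequence[float] | None = None
                   ) -> tuple[Recording, tuple[float, float]]:
    """Estimate and correct a constant x-y offset of the calcium channel.

    The offset between the time-averaged, z-projected channels is estimated
    by cross-correlation and the calcium channel is shifted back by it.
    Returns the aligned recording and the estimated (dy, dx) offset in
    pixels.  The estimate is invariant to global intensity scaling of either
    channel.
    """
    nuc = recording.channel("nuclear").mean(axis=(0, 1))
    cal = recording.channel("calcium").mean(axis=(0, 1))
    if not np.any(nuc - nuc.mean()) or not np.any(cal - cal.mean()):
        raise DegenerateInputError("flat channel: cannot align")
    offset = _cross_correlate_shift(nuc, cal, max_shift=max_shift, subvoxel=True)
    data = recording.intensities.copy()
    ci = recording.channels["calcium"]
    shift3 = np.array([0.0, -offset[0], -offset[1]])
    if not np.allclose(shift3, 0):
        for t in range(recording.n_frames):
            data[t, ci] = ndimage.shift(data[t, ci], shift3, order=1,
                                        mode="constant", cval=0.0, prefilter=False)
    data = np.clip(data, 0, None)
    return replace_recording(recording, intensities=data), (float(offset[0]),
                                                            float(offset[1]))


# ---------------------------------------------------------------------------
# segmentation and trace extraction
# ---------------------------------------------------------------------------

def segment_nuclei(recording: Recording, channel: str = "nuclear",
                   spot_diameter_um: float = DEFAULT_SPOT_DIAMETER_UM,
                   threshold: float | None = None,
                   min_separation_um: float | None = None,
                   refine: bool = True) -> SpotSet:
    """Detect nuclear blobs at a fixed physical scale.

    The time-averaged nuclear channel is filtered with a negated
    Laplacian-of-Gaussian at sigma = spot_diameter / (2 sqrt 3) micrometres
    (per-axis sigma in voxels follows the voxel size); local maxima above
    ``threshold`` (default: 10% of the peak response) survive a greedy
    non-maximum suppression at ``min_separation_um`` (default: one spot
    diameter).  Higher response wins; exact ties break by lexicographic
    centroid order.  An empty volume yields an empty spot set.
    """
    if spot_diameter_um <= 0:
        raise ValueError("spot diameter must be positive")
    voxel = np.asarray(recording.voxel_size, dtype=float)
    vol = recording.channel(channel).mean(axis=0)
    sigma_um = spot_diameter_um / (2 * math.sqrt(3))
    sigma_vox = sigma_um / voxel
    response = -ndimage.gaussian_laplace(vol, sigma_vox)
    if threshold is None:
        peak_resp = float(response.max())
        if peak_resp <= 0:
            return SpotSet([], recording.volume_shape, tuple(recording.voxel_size))
        threshold = 0.1 * peak_resp
    coords = peak_local_max(response, min_distance=1, threshold_abs=threshold,
                            exclude_border=False)
    if coords.size == 0:
        return SpotSet([], recording.volume_shape, tuple(recording.voxel_size))

    # greedy NMS: strongest response first, lexicographic centroid on ties
    resp_vals = response[tuple(coords.T)]
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -resp_vals))
    min_sep = spot_diameter_um if min_separation_um is None else min_separation_um
    accepted: list[np.ndarray] = []
    accepted_um: list[np.ndarray] = []
    for i in order:
        c_um = coords[i] * voxel
        if all(np.linalg.norm(c_um - a) >= min_sep for a in accepted_um):
            accepted.append(coords[i])
            accepted_um.append(c_um)
    centroids = []
    for c in accepted:
        c = c.astype(float)
        if refine:
            for ax in range(3):
                i = int(c[ax])
                if 0 < i < response.shape[ax] - 1:
                    idx_m = list(map(int, c)); idx_p = list(map(int, c))
                    idx_0 = list(map(int, c))
                    idx_m[ax] -= 1; idx_p[ax] += 1
                    c[ax] = i + _parabolic_offset(response[tuple(idx_m)],
                                                  response[tuple(idx_0)],
                                                  response[tuple(idx_p)])
        centroids.append(c * voxel)
    centroids.sort(key=tuple)
    width = max(3, len(str(len(centroids))))
    spots = [Spot(cell_id=f"cell_{i + 1:0{width}d}", centroid_um=tuple(c),
                  radius_um=spot_diameter_um / 2)
             for i, c in enumerate(centroids)]
    return SpotSet(spots, recording.volume_shape, tuple(recording.voxel_size))


def _sphere_mask_indices(centroid_um: np.ndarray, radius_um: float,
                         shape: tuple[int, int, int],
                         voxel: np.ndarray) -> tuple[np.ndarray, ...]:
    lo = np.maximum(np.ceil((centroid_um - radius_um) / voxel).astype(int), 0)
    hi = np.minimum(np.floor((centroid_um + radius_um) / voxel).astype(int),
                    np.asarray(shape) - 1)
    if np.any(lo > hi):
        return (np.array([], dtype=int),) * 3
    zz, yy, xx = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)],
                             indexing="ij")
    d2 = ((zz * voxel[0] - centroid_um[0]) ** 2
          + (yy * voxel[1] - centroid_um[1]) ** 2
          + (xx * voxel[2] - centroid_um[2]) ** 2)
    keep = d2 <= radius_um ** 2
    return zz[keep], yy[keep], xx[keep]


def extract_traces(recording: Recording, spots: SpotSet,
                   channel: str = "calcium", tastant: str = "") -> list[RawTrace]:
    """Mean intensity per frame over each spot's sphere of voxel centers."""
    stack = recording.channel(channel)
    voxel = np.asarray(recording.voxel_size, dtype=float)
    out = []
    for spot in spots:
        zz, yy, xx = _sphere_mask_indices(np.asarray(spot.centroid_um),
                                          spot.radius_um,
                                          recording.volume_shape, voxel)
        if zz.size == 0:
            raise ValueError(
                f"spot {spot.cell_id!r} at {spot.centroid_um} um contains no "
                f"voxel centers (radius {spot.radius_um} um)")
        out.append(RawTrace(cell_id=spot.cell_id,
                            values=stack[:, zz, yy, xx].mean(axis=1),
                            tastant=tastant))
    return out
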