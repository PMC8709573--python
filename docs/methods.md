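# Methods

## Scope and data model

`togsense` quantifies taste-evoked calcium responses in the *Drosophila*
larval terminal organ ganglion (TOG) from two-channel time-lapse volumes and
carries the results through response classification, taste-multimodality
statistics, cross-animal cell mapping, and the two-choice behavioral
preference analysis. The in-memory unit of every pooled statistic is the
`ResponseRecord`: one (organ, cell, tastant) with a signed ΔF/F₀ amplitude, a
response class, and a QC verdict.

Axis order is (z, y, x) everywhere. Voxel indices are 0-based; physical
coordinates are micrometres with the origin at the center of voxel (0, 0, 0).
The default acquisition geometry is 25 z-slices of 1.5 µm (37.5 µm depth), a
~55 µm lateral field of view on a 128-pixel grid (0.43 µm lateral voxels),
and 60 stacks at 2 s/stack with the stimulus on frames 30–44 (60 s pre-wash,
30 s stimulation, 30 s wash).

## Imaging stages

**Drift.** The drift model is rigid translation only — no rotation or
deformation. Per-frame shifts of the nuclear channel are estimated against a
reference frame by maximizing the mean-subtracted cross-correlation, computed
over the full FFT correlation surface so that (i) the search can be windowed
to a maximum plausible shift and (ii) the integer peak can be refined per
axis by a 3-point parabolic fit (optional, default on, clipped to ±0.5
voxel). Correction translates both channels by the negated track using linear
interpolation (lossless for integer shifts in the interior; border voxels are
zero-filled). `drift_correct` re-estimates the shift after correction and
flags the recording for discard when the residual exceeds 2 voxels,
mirroring the practice of dropping recordings whose motion cannot be
rectified.

**Channel alignment.** A constant x–y offset between the time-averaged,
z-projected channels is estimated by the same normalized cross-correlation
and applied to the calcium channel. The estimate is invariant to global
intensity scaling of either channel.

**Segmentation.** Nuclei are detected at a single physical scale: the
time-averaged nuclear channel is filtered with a negated
Laplacian-of-Gaussian at σ = d/(2√3) for spot diameter d = 3.5 µm (per-axis σ
in voxels follows the voxel size), local maxima above a threshold (default:
10 % of the peak response; exposed because the original acquisition
software's quality cutoff is not public) survive a greedy non-maximum
suppression at one spot diameter of separation in micrometres. Higher
response wins; exact ties break by lexicographic centroid order, making the
operation deterministic. Centroids are refined per axis by the same 3-point
parabolic fit. A hand-written NMS is used instead of a generic multiscale
blob detector because the scale is fixed, the voxels anisotropic, and the
tie-break contractual.

**Trace extraction.** A cell's trace is the per-frame mean of the calcium
channel over voxels whose centers fall within a 1.75 µm sphere around the
centroid (anisotropy-aware). With the default geometry any interior point
covers at least one voxel center; a sphere covering none raises an error
naming the spot.

## Trace quantification

* **Normalization.** ΔF/F₀ = (Fₜ − F₀)/F₀ with F₀ the mean of the 10 frames
  before stimulus onset. F₀ ≤ 0 makes the trace unusable and raises.
* **Amplitude.** The post-onset maximum is located over frames [onset, 60)
  (earliest frame on ties); the amplitude is the mean of a 5-frame window
  centered on it. The window is shifted as needed to stay inside the
  response epoch holding the peak — [onset, 60) for stimulus-window peaks,
  [offset, 60) for later peaks — so that a step response at onset or an
  OFF/late response starting at offset is read off its own plateau rather
  than diluted with pre-response baseline. Among the window rules compatible
  with "5 frames near the maximum", this one is exact on plateau responses
  and keeps the noisy-amplitude error within 3·σ/√5 in ≥ 95 % of trials at
  σ = amplitude/6 (a max-of-windows rule is biased upward by selection;
  naive centering dilutes offset-adjacent peaks).
* **Classes.** ON: first crossing of +0.20 ΔF/F₀ within the stimulus window
  and amplitude ≥ 0.20; OFF/late: first crossing at or after offset
  (late activation and OFF responses are one class — nothing in the data
  defines a boundary between them); deactivation: no positive crossing and a
  stimulus-window minimum ≤ −0.20 (the drop criterion is taken symmetric to
  the rise criterion, since no separate numeric criterion is established);
  otherwise none. Positive classes take precedence over deactivation.
  Deactivation records carry the (negative) stimulus-window minimum as their
  amplitude.
* **QC.** A trace fails with `baseline_exceeds_amplitude` when the baseline
  peak-to-peak range reaches |amplitude| — "baseline variance" is
  operationalized as a range because a variance (squared units) is not
  commensurable with an amplitude — and with `unstable_baseline` when the
  fitted linear baseline trend accumulates at least half the response
  threshold over the baseline window. Artifact and delocalized-fluorescence
  exclusions are inherently by-eye; a `manual_exclude` flag stands in for
  them. Failed records are excluded from all pooling.

## Multimodality statistics

A cell is *responding* when ≥ 1 tastant gives a QC-passing activation with
amplitude ≥ 0.20. Pooled tuning statistics count ON responses only (the
canonical-signal convention); `include_off=True` adds OFF/late activations
and is the default for mapping-style exports. Deactivations never count as
responses in pooling. Unimodal = responded-set of size 1 within the cell's
own organ; fractions are pooled over all responding cells across organs, and
the per-organ table additionally reports each organ's own fractions (the
pooled fraction equals the cell-count-weighted combination of the per-organ
fractions; both orientations are reported because per-animal averages and the
pooled split need not agree). Combination frequencies tally every unordered
modality-category pair in a multimodal cell's responded set, normalized by
the number of multimodal cells.

## Cross-animal mapping

The published mapping was performed manually; this module is a reproducible
automatic surrogate that treats the manual map as one realization.

* **Local frame.** Origin: centroid of the non-landmark cloud. First axis:
  toward the centroid of the 4 anterior-lateral landmark cells (given
  explicitly or detected as the 4-spot cluster maximizing displacement ×
  isolation / (1 + spread) — the landmark group is displaced from, separated
  from, and tighter than any main-cloud quadruple). Second axis: dominant
  principal component of the cloud perpendicular to the first, its sign fixed
  by the positive standardized third moment (skewness) of the projections —
  organs are chiral enough in practice for this to be decisive; a symmetric
  cloud falls back to a deterministic but jitter-sensitive rule, since no
  sign rule can be stable on a symmetric cloud. Third axis by
  right-handedness. Coordinates divide by the RMS cloud radius. The frame is
  exactly invariant to rigid motion and uniform scaling.
* **Matching.** Optimal bipartite assignment (Hungarian algorithm) between
  spot and reference coordinates, with per-spot unassignment available at
  cost `max_dist` (default: half the median nearest-neighbor distance among
  reference identities). Because the frame's orientation about the landmark
  axis rests on second/third moments that a handful of jittered positions can
  rotate, the residual rotation about that axis is resolved against the
  reference by minimizing assignment cost over a deterministic angle grid
  (7.5° sweep plus a 1.5° local refinement; zero rotation wins ties). This
  also absorbs a sign flip (180°).
* **Support.** An (identity, tastant) activation (ON or OFF/late) is *mapped*
  when observed in ≥ 4 distinct organs; bitter stimulations, sampled less
  densely, require ≥ 3. The "at least four" reading is adopted (consistent
  with the bitter exception). Deactivations accumulate support separately —
  the machinery behind neuron-level deactivation profiles. Support counts
  are sets of organ ids, hence invariant to organ order.

## Behavior

PI = (n_test − n_plain)/(n_test + n_plain + n_middle); middle-stripe animals
enter the denominator only, so they shrink |PI| monotonically. Time courses
report mean ± SEM (sample SD / √N) per genotype per timepoint. The group
comparison is a two-sided Mann-Whitney U with midrank ties: exact by full
enumeration of all C(n+m, n) labelings when n + m ≤ 16, with the two-sided
p defined as the fraction of labelings with |U − nm/2| ≥ |observed|;
otherwise a normal approximation with tie-corrected variance and 0.5
continuity correction, clipped to (0, 1]. Midranks are used for tied
replicate PIs. A one-way fixed-effects F statistic is provided as a
convenience secondary, since omnibus comparisons of the same replicate
groups are often reported alongside.

## Synthetic data generator

The generator emulates the study conditions: ~30 taste neurons plus 4
landmark cells in a 37.5 × 55 × 55 µm organ, stimulated per animal with a
five-tastant series, 60 frames at 2 s/frame with the stimulus on frames
30–44.

* **Tuning.** Each (cell, tastant) draws a class from
  {ON 0.12, OFF/late 0.03, deactivation 0.02, none 0.83} — chosen to give
  roughly 19 above-threshold responses and 13 responding cells per organ
  over a five-tastant series, the observed density — with amplitudes uniform
  on [0.25, 0.8] ΔF/F₀ and decay constants uniform on [5, 15] frames.
  Baseline fluorescence (100) and noise levels are free parameters of the
  generator, not measured values: the source recordings' baseline and noise
  statistics are not published.
* **Kernels.** ON: step at onset (1-frame rise), plateau through the
  stimulus, exponential decay after offset. OFF/late: the same kernel
  shifted to stimulus offset. Deactivation: negative boxcar during the
  stimulus. These are the simplest shapes satisfying the class taxonomy.
* **Recordings.** Cells render as isotropic Gaussian blobs with FWHM 3.5 µm,
  matching the segmentation spot diameter, so the detection scale is
  self-consistent. Drift is applied by re-rendering blobs at the shifted
  positions, making injected integer drifts exactly recoverable. Noise is
  i.i.d. Gaussian per voxel; bleach is a linear multiplicative decay
  (default 0; nonzero bleach exercises the unstable-baseline QC rule).
* **Organ shape.** The cloud fills an anisotropic ellipsoid with a
  pronounced dorso-ventral asymmetry, and draws are resampled until the
  realized 30-point configuration carries a decisive principal-frame
  signature (eigenvalue gap ≥ 1.35 perpendicular to the landmark axis,
  |skewness| ≥ 0.35 along the dominant one). Cross-animal mapping — manual
  or automatic — presupposes organs whose asymmetry is anatomically
  unambiguous; a small sample from an asymmetric envelope occasionally is
  not, and such draws would make any orientation convention unstable.
* **Behavior.** Per-plate counts are one trinomial draw
  (p_test, 1 − p_test − p_middle, p_middle) over n larvae.

What the generator does **not** emulate: optics (no PSF, no deconvolution
artifacts), non-rigid tissue motion, correlated or multiplicative noise,
overlapping nuclei, trial-to-trial response variability within an animal,
and any larval locomotion beyond the trinomial choice. Tests passing on this
synthetic data therefore validate the quantification logic and its
statistical behavior under the stated noise model — not robustness to
optical or biological artifacts, which the manual-override QC flag exists
for.

## Numerical choices and degenerate inputs

* Ties at the trace maximum break to the earliest frame; segmentation NMS
  ties break lexicographically by centroid; reference identities are matched
  in lexicographic order; zero rotation wins matching ties.
* Parabolic refinements are skipped (offset 0) when the 3-point stencil is
  not concave, and clipped to ±0.5 sample.
* Flat volumes/channels raise `DegenerateInputError`; an empty volume yields
  an empty spot set (not an error); fewer than 8 spots cannot anchor a local
  frame; probabilities outside the simplex and inconsistent frame windows
  raise configuration errors.
* Simulation problem sizes in the test suite (organ counts, trace counts,
  Monte-Carlo repetitions) are chosen so the full suite completes in a few
  minutes on one core while keeping the binomial assertions comfortably away
  from their thresholds.

## Known limitations

* The drift search is global translation per frame; slow non-rigid
  deformation shows up as residual error and, past 2 voxels, as a discard
  flag rather than being corrected.
* The automatic landmark detector and frame construction assume the 4-cell
  landmark cluster is present, isolated, and displaced; preparations where
  ALNs are occluded need landmark ids supplied explicitly.
* The XLSX importer targets the documented layout of the published
  source-data workbooks (a header row containing `cell_name_in_prep` or
  `map_cell_name`); other spreadsheet layouts need reshaping first.
* Exact Mann-Whitney enumeration grows combinatorially; above n + m = 16 the
  tie-corrected normal approximation is used (agreement within 0.02 at
  n = m = 10 in tests).
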