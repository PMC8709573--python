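"""Landmark-anchored local frames, identity matching, support accumulation."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from togsense.errors import InsufficientSpotsError
from togsense.mapping import (LocalFrame, ReferenceMap, accumulate_support,
                              build_local_frame, default_max_dist,
                              detect_landmarks, match_to_reference)
from togsense.panel import default_panel
from togsense.synthetic import SimulationConfig, perturb_positions, \
    simulate_organ_truth
from togsense.traces import ResponseRecord


def frame_of(truth, use_known_landmarks=True):
    ids = [c.cell_id for c in truth.cells]
    lm = [c.cell_id for c in truth.landmarks] if use_known_landmarks else None
    return build_local_frame(ids, truth.positions(), landmark_ids=lm)


def random_proper_rotation(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestLocalFrame:
    def test_invariant_to_rigid_motion_and_scale(self, organ_truth):
        f = frame_of(organ_truth)
        rng = np.random.default_rng(0)
        q = random_proper_rotation(rng)
        moved = (organ_truth.positions() @ q.T) * 1.3 + np.array([40.0, -7.0, 12.0])
        f2 = build_local_frame([c.cell_id for c in organ_truth.cells], moved,
                               landmark_ids=[c.cell_id for c in
                                             organ_truth.landmarks])
        assert np.abs(f.coords - f2.coords).max() < 1e-6

    def test_mirrored_organ_keeps_landmark_side(self, organ_truth):
        f = frame_of(organ_truth)
        mirrored = organ_truth.positions().copy()
        mirrored[:, 2] *= -1
        fm = build_local_frame([c.cell_id for c in organ_truth.cells], mirrored,
                               landmark_ids=[c.cell_id for c in
                                             organ_truth.landmarks])
        lm_ids = set(c.cell_id for c in organ_truth.landmarks)
        idx = [i for i, c in enumerate(organ_truth.cells) if c.cell_id in lm_ids]
        assert f.coords[idx, 0].mean() > 0
        assert fm.coords[idx, 0].mean() > 0

    def test_landmark_autodetection_matches_truth(self, organ_truth):
        auto = frame_of(organ_truth, use_known_landmarks=False)
        assert sorted(auto.landmark_ids) == sorted(
            c.cell_id for c in organ_truth.landmarks)

    def test_detects_landmarks_under_jitter_and_rotation(self, organ_truth):
        rng = np.random.default_rng(3)
        want = sorted(c.cell_id for c in organ_truth.landmarks)
        for _ in range(15):
            p = perturb_positions(organ_truth, rng, jitter_sd_um=1.2, rotate=True)
            got = detect_landmarks(p.positions())
            assert sorted(p.cells[i].cell_id for i in got) == want

    def test_too_few_spots_rejected(self):
        with pytest.raises(InsufficientSpotsError):
            build_local_frame(["a", "b", "c"], np.zeros((3, 3)))


class TestMatching:
    def test_reference_matched_to_itself_is_identity(self, organ_truth):
        f = frame_of(organ_truth)
        ref = ReferenceMap(tuple(f.cell_ids), f.coords)
        assignment = match_to_reference(f, ref)
        assert assignment == {c: c for c in f.cell_ids}

    def test_empty_reference_rejected(self, organ_truth):
        f = frame_of(organ_truth)
        with pytest.raises(ValueError):
            match_to_reference(f, ReferenceMap((), np.zeros((0, 3))))

    def _brute_force(self, coords, ref_coords, ids, max_dist):
        """Enumerate every partial injective assignment; unassigned costs max_dist."""
        n = len(coords)
        d = cdist(coords, ref_coords)
        best_cost, best = np.inf, {}
        for k in range(n + 1):
            for spots in itertools.combinations(range(n), k):
                for perm in itertools.permutations(range(len(ids)), k):
                    cost = sum(d[s, p] for s, p in zip(spots, perm))
                    cost += (n - k) * max_dist
                    valid = all(d[s, p] <= max_dist for s, p in zip(spots, perm))
                    if valid and cost < best_cost - 1e-12:
                        best_cost = cost
                        best = {s: ids[p] for s, p in zip(spots, perm)}
        return best

    def test_displaced_spot_left_unassigned_matches_brute_force(self):
        rng = np.random.default_rng(4)
        ref_coords = rng.normal(size=(5, 3))
        ids = tuple(f"id{i}" for i in range(5))
        ref = ReferenceMap(ids, ref_coords)
        coords = ref_coords + rng.normal(0, 0.01, ref_coords.shape)
        coords[2] += 10.0  # push one spot far beyond any gate
        frame = LocalFrame(tuple(f"s{i}" for i in range(5)), coords, (),
                           np.zeros(3), np.eye(3), 1.0)
        max_dist = default_max_dist(ref)
        got = match_to_reference(frame, ref, max_dist=max_dist)
        assert "s2" not in got
        assert got == {f"s{i}": f"id{i}" for i in range(5) if i != 2}
        oracle = self._brute_force(coords, ref_coords, list(ids), max_dist)
        assert got == {f"s{s}": ident for s, ident in oracle.items()}

    def test_jittered_organs_mostly_correctly_assigned(self, organ_truth):
        f = frame_of(organ_truth)
        ref = ReferenceMap(tuple(f.cell_ids), f.coords)
        d = cdist(f.coords, f.coords)
        np.fill_diagonal(d, np.inf)
        gate = float(np.median(d.min(axis=0)))
        rng = np.random.default_rng(5)
        correct = total = 0
        for _ in range(50):
            p = perturb_positions(organ_truth, rng,
                                  jitter_sd_um=0.25 * d.min() * f.scale_um,
                                  rotate=True)
            f2 = frame_of(p)
            a = match_to_reference(f2, ref, max_dist=gate)
            total += len(f.cell_ids)
            correct += sum(a.get(c) == c for c in f.cell_ids)
        assert correct / total >= 0.95


def _mk_record(organ, cell, tastant, amplitude=0.5, cls="on"):
    return ResponseRecord(organ_id=organ, cell_name_in_prep=cell,
                          tastant=tastant, amplitude=amplitude,
                          response_class=cls)


class TestSupport:
    def test_four_organ_activation_is_mapped(self):
        assignments = {f"o{i}": {"cell": "PM1"} for i in range(4)}
        records = [_mk_record(f"o{i}", "cell", "sucrose") for i in range(4)]
        (m,) = accumulate_support(assignments, records, panel=default_panel())
        assert m.identity == "PM1" and m.support == 4 and m.mapped

    def test_three_organ_bitter_is_mapped(self):
        assignments = {f"o{i}": {"cell": "PM1"} for i in range(3)}
        records = [_mk_record(f"o{i}", "cell", "quinine") for i in range(3)]
        (m,) = accumulate_support(assignments, records, panel=default_panel())
        assert m.support == 3 and m.min_support == 3 and m.mapped

    def test_two_organ_support_is_not_mapped(self):
        assignments = {f"o{i}": {"cell": "PM1"} for i in range(2)}
        records = [_mk_record(f"o{i}", "cell", "sucrose") for i in range(2)]
        (m,) = accumulate_support(assignments, records, panel=default_panel())
        assert not m.mapped

    def test_deactivations_accumulate_separately(self):
        assignments = {f"o{i}": {"cell": "CDL2"} for i in range(5)}
        records = ([_mk_record(f"o{i}", "cell", "citric acid", -0.4,
                               "deactivation") for i in range(5)]
                   + [_mk_record(f"o{i}", "cell", "citric acid") for i in range(4)])
        out = accumulate_support(assignments, records, panel=default_panel())
        kinds = {(m.response_class, m.support, m.mapped) for m in out}
        assert ("deactivation", 5, True) in kinds
        assert ("activation", 4, True) in kinds

    def test_support_invariant_to_organ_order(self):
        panel = default_panel()
        assignments = {f"o{i}": {"cell": "PM1"} for i in range(5)}
        records = [_mk_record(f"o{i}", "cell", "sucrose") for i in range(5)]
        a = accumulate_support(assignments, records, panel=panel)
        b = accumulate_support(dict(reversed(list(assignments.items()))),
                               list(reversed(records)), panel=panel)
        assert a == b

    def test_off_late_counts_toward_activation_support(self):
        assignments = {f"o{i}": {"cell": "PM1"} for i in range(4)}
        records = [_mk_record(f"o{i}", "cell", "sucrose", cls="off_late")
                   for i in range(4)]
        (m,) = accumulate_support(assignments, records, panel=default_panel())
        assert m.response_class == "activation" and m.mapped


class TestEndToEndRecovery:
    def test_multi_organ_response_recovery(self, organ_truth):
        """>= 90% of (identity, tastant) responses present in >= 4 of 7 organs
        are recovered as mapped at 0.15 normalized-unit jitter."""
        from togsense.synthetic import SimulationConfig, simulate_trace_table
        from togsense.traces import analyze_trace

        panel_tastants = ["sucrose", "quinine", "NaCl 1M", "valine",
                          "citric acid"]
        cfg = SimulationConfig(seed=21, noise_sd=5.0)
        truth0 = simulate_organ_truth(cfg, panel_tastants,
                                      rng=np.random.default_rng(21))
        f0 = frame_of(truth0)
        ref = ReferenceMap(tuple(f0.cell_ids), f0.coords)
        d = cdist(f0.coords, f0.coords)
        np.fill_diagonal(d, np.inf)
        gate = float(np.median(d.min(axis=0)))

        rng = np.random.default_rng(22)
        assignments, all_records = {}, []
        for i in range(7):
            organ_id = f"organ{i}"
            organ = perturb_positions(truth0, rng, jitter_sd_um=0.15 * f0.scale_um,
                                      rotate=True, organ_id=organ_id)
            traces, _ = simulate_trace_table(cfg, panel_tastants, truth=organ,
                                             rng=rng)
            for t in traces:
                _, record = analyze_trace(t, cfg.schedule(), organ_id=organ_id,
                                          tastant=t.tastant)
                all_records.append(record)
            f = frame_of(organ)
            assignments[organ_id] = match_to_reference(f, ref, max_dist=gate)

        mapped = accumulate_support(assignments, all_records,
                                    panel=default_panel())
        mapped_set = {(m.identity, m.tastant) for m in mapped
                      if m.mapped and m.response_class == "activation"}
        truth_resp = truth0.taste_cells
        true_pairs = {(c.cell_id, t) for c in truth_resp for t in panel_tastants
                      if c.tuning[t].response_class in ("on", "off_late")
                      and abs(c.tuning[t].amplitude) >= 0.2}
        assert true_pairs, "simulation produced no above-threshold responses"
        recovered = sum(1 for pair in true_pairs if pair in mapped_set)
        assert recovered / len(true_pairs) >= 0.90
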