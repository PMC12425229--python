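"""Tracker: embedding, cost matrix, assignment optimality, lifecycle, metrics."""

import itertools
import warnings

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from phagoscope import detect_eval
from phagoscope.detect_eval import Detection
from phagoscope.io_cellular import BoundingBox
from phagoscope.synthgen import GroundTruth, SynthConfig, generate_sequence
from phagoscope.tracker import (
    SENTINEL,
    FeatureVector,
    Track,
    TrackerConfig,
    TrackerState,
    build_cost_matrix,
    cosine_similarity,
    embed_cell,
    hungarian,
    step,
    track_sequence,
    tracking_metrics,
    truth_detections,
)
from conftest import truth_tracking_inputs


def D(x, y, s=10, conf=1.0):
    return Detection(box=BoundingBox(x, y, x + s, y + s), confidence=conf)


def _blob_image(puncta, size=40, body=(40, 40, 0)):
    img = np.zeros((size, size, 3))
    mask = np.zeros((size, size), bool)
    rr, cc = draw_disk((size // 2, size // 2), size // 2 - 5)
    mask[rr, cc] = True
    img[mask] = body
    for center, radius, channels in puncta:
        rr, cc = draw_disk(center, radius, shape=(size, size))
        for ch in channels:
            img[rr, cc, ch] += 150.0
    return img, mask


class TestEmbedding:
    def test_identical_crops_identical_vectors(self):
        img, mask = _blob_image([((15, 15), 3, (0, 1))])
        a, b = embed_cell(img, mask), embed_cell(img.copy(), mask.copy())
        np.testing.assert_array_equal(a.values, b.values)
        assert cosine_similarity(a, b) == pytest.approx(1.0)
        assert np.linalg.norm(a.values) == pytest.approx(1.0)

    def test_gain_robustness(self):
        """Doubling uniform gain leaves the histograms (range-normalized) alone."""
        img, mask = _blob_image([((15, 15), 3, (0, 1))])
        assert cosine_similarity(embed_cell(img, mask), embed_cell(img * 2, mask)) >= 0.9

    def test_disjoint_punctum_patterns_dissimilar(self):
        """Yellow puncta vs one large red-only punctum fall below the matching gate."""
        a_img, mask = _blob_image([((15, 15), 3, (0, 1)), ((22, 18), 3, (0, 1))])
        b_img, _ = _blob_image([((25, 25), 6, (0,))])
        sim = cosine_similarity(embed_cell(a_img, mask), embed_cell(b_img, mask))
        assert sim < 0.8

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            embed_cell(np.zeros((5, 5, 3)), np.zeros((5, 5), bool))


class TestCostMatrix:
    def _track(self, x, y, feat, status="active", s=10):
        return Track(track_id=0, status=status, last_feature=feat,
                     last_centroid=np.array([y + s / 2, x + s / 2]),
                     last_box=BoundingBox(x, y, x + s, y + s))

    def test_identical_pair_costs_zero(self):
        f = FeatureVector(np.array([1.0, 0.0]))
        cfg = TrackerConfig(gate_radius=50)
        tr = self._track(10, 10, f)
        c = build_cost_matrix([tr], [D(10, 10)], [f], cfg)
        assert c[0, 0] == pytest.approx(0.0)
        tr_inactive = self._track(10, 10, f, status="inactive")
        c2 = build_cost_matrix([tr_inactive], [D(10, 10)], [f], cfg)
        assert c2[0, 0] == pytest.approx(cfg.inactive_surcharge)

    def test_gating(self):
        f = FeatureVector(np.array([1.0, 0.0]))
        c = build_cost_matrix([self._track(0, 0, f)], [D(200, 200)], [f],
                              TrackerConfig(gate_radius=50))
        assert c[0, 0] == SENTINEL

    def test_formula_oracle(self, rng):
        """Entries equal an independent term-by-term recomputation."""
        cfg = TrackerConfig(gate_radius=80.0)
        feats = [FeatureVector(rng.random(6)) for _ in range(3)]
        tracks = [self._track(int(x), int(y), f)
                  for (x, y), f in zip(rng.integers(0, 60, (3, 2)), feats)]
        dets = [D(int(x), int(y)) for x, y in rng.integers(0, 60, (4, 2))]
        dfeats = [FeatureVector(rng.random(6)) for _ in range(4)]
        got = build_cost_matrix(tracks, dets, dfeats, cfg)
        for i, tr in enumerate(tracks):
            for j, (det, f) in enumerate(zip(dets, dfeats)):
                cy = (det.box.y0 + det.box.y1) / 2
                cx = (det.box.x0 + det.box.x1) / 2
                d = np.hypot(*(tr.last_centroid - [cy, cx]))
                if d > 80:
                    assert got[i, j] == SENTINEL
                    continue
                expect = (cfg.w_spatial * d / 80
                          + cfg.w_feature * (1 - cosine_similarity(tr.last_feature, f)) / 2
                          + cfg.w_overlap * (1 - detect_eval.box_iou(tr.last_box, det.box)))
                assert got[i, j] == pytest.approx(expect)


def brute_force_assignment(cost):
    """Exhaustive minimum over all maximal sentinel-free assignments."""
    n, m = cost.shape
    best, best_len = None, -1
    rows = list(range(n))
    k = min(n, m)
    for rsub in itertools.combinations(rows, k):
        for csub in itertools.permutations(range(m), k):
            pairs = [(r, c) for r, c in zip(rsub, csub) if np.isfinite(cost[r, c])]
            total = sum(cost[r, c] for r, c in pairs)
            if len(pairs) > best_len or (len(pairs) == best_len and total < best):
                best, best_len = total, len(pairs)
    return best_len, best


class TestHungarian:
    @pytest.mark.parametrize("cost,expected", [
        ([[0.0]], [(0, 0)]),
        ([[1.0, 2.0], [2.0, 1.0]], [(0, 0), (1, 1)]),
    ])
    def test_small_cases(self, cost, expected):
        assert hungarian(np.array(cost)) == expected

    def test_all_sentinel_empty(self):
        assert hungarian(np.full((3, 3), SENTINEL)) == []

    def test_random_matches_brute_force(self, rng):
        for _ in range(60):
            n, m = rng.integers(1, 6, 2)
            cost = rng.random((n, m)).round(4)
            cost[rng.random((n, m)) < 0.2] = SENTINEL
            got = hungarian(cost)
            got_total = sum(cost[r, c] for r, c in got)
            bf_len, bf_total = brute_force_assignment(cost)
            assert len(got) == bf_len
            assert got_total == pytest.approx(bf_total)


def _single_cell_gt(n_frames=5):
    gt = GroundTruth()
    for t in range(n_frames):
        gt.track_of[(t, 0)] = 0
    return gt


class TestLifecycle:
    def test_stationary_cell_one_track(self):
        f = FeatureVector(np.array([1.0, 0.0]))
        dets = [[D(10, 10)]] * 5
        feats = [[f]] * 5
        tracks = track_sequence(dets, feats)
        assert len(tracks) == 1
        assert tracks[0].links == [(t, 0) for t in range(5)]
        assert tracks[0].status == "active"

    def test_reappearance_resumes_track(self):
        """A cell absent at t2 resumes its original track id at t3."""
        f = FeatureVector(np.array([1.0, 0.0]))
        dets = [[D(10, 10)], [D(11, 10)], [], [D(11, 11)], [D(12, 11)]]
        feats = [[f], [f], [], [f], [f]]
        tracks = track_sequence(dets, feats)
        assert len(tracks) == 1
        assert [t for t, _ in tracks[0].links] == [0, 1, 3, 4]

    def test_division_links_child_to_parent(self):
        """Generator division: one predicted track per daughter, lineage recorded."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seq, gt = generate_sequence(SynthConfig(seed=0, division_prob=0.25))
        assert gt.divisions
        tracks = track_sequence(*truth_tracking_inputs(seq))
        children = [tr for tr in tracks if tr.parent_track_id is not None]
        assert children, "no division child was linked"
        m = tracking_metrics(tracks, gt)
        assert m["identity_switches"] == 0 and m["fragmentation"] == 0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            track_sequence([], [])

    def test_no_detections_no_tracks(self):
        assert track_sequence([[], [], []], [[], [], []]) == []

    def test_determinism(self, default_sequence):
        seq, _ = default_sequence
        inputs = truth_tracking_inputs(seq)
        a = track_sequence(*inputs)
        b = track_sequence(*inputs)
        assert [(t.track_id, t.links) for t in a] == [(t.track_id, t.links) for t in b]

    def test_step_conservation(self, default_sequence):
        """Each frame's detections are exactly partitioned among match kinds."""
        seq, _ = default_sequence
        dets, feats, refs = truth_tracking_inputs(seq)
        state = TrackerState()
        for t in range(5):
            links_before = {tr.track_id: len(tr.links) for tr in state.tracks}
            n_tracks_before = len(state.tracks)
            state = step(state, dets[t], feats[t], t, refs=refs[t])
            extended = sum(1 for tr in state.tracks[:n_tracks_before]
                           if len(tr.links) > links_before.get(tr.track_id, 0))
            new = len(state.tracks) - n_tracks_before
            assert extended + new == len(dets[t])

    def test_duplicate_refs_rejected(self):
        f = FeatureVector(np.array([1.0]))
        with pytest.raises(ValueError, match="duplicate"):
            step(TrackerState(), [D(0, 0), D(20, 20)], [f, f], 0, refs=[1, 1])


class TestMetricsAndWeights:
    def _swap_setup(self):
        """Two cells with distinct appearance swap positions between t0 and t1."""
        f1 = FeatureVector(np.array([1.0, 0.0]))
        f2 = FeatureVector(np.array([0.0, 1.0]))
        dets = [[D(10, 10), D(40, 10)], [D(40, 10), D(10, 10)]]
        feats = [[f1, f2], [f1, f2]]  # cell A (f1) moved to (40,10)
        gt = GroundTruth()
        gt.track_of.update({(0, 0): 100, (0, 1): 101, (1, 0): 100, (1, 1): 101})
        return dets, feats, gt

    def test_feature_weight_rescues_swap(self):
        dets, feats, gt = self._swap_setup()
        cfg = TrackerConfig(w_spatial=0.4, w_feature=0.6, w_overlap=0.0, gate_radius=100)
        m = tracking_metrics(track_sequence(dets, feats, config=cfg), gt)
        assert m["identity_switches"] == 0

    def test_position_only_swaps_identities(self):
        dets, feats, gt = self._swap_setup()
        cfg = TrackerConfig(w_spatial=0.8, w_feature=0.0, w_overlap=0.2, gate_radius=100)
        m = tracking_metrics(track_sequence(dets, feats, config=cfg), gt)
        assert m["identity_switches"] == 2

    def test_perfect_tracking_metrics(self, default_sequence):
        seq, gt = default_sequence
        m = tracking_metrics(track_sequence(*truth_tracking_inputs(seq)), gt)
        assert m["identity_switches"] == 0
        assert m["fragmentation"] == 0

    def test_fragmentation_counts_splits(self):
        gt = _single_cell_gt()
        a = Track(track_id=0, links=[(0, 0), (1, 0)])
        b = Track(track_id=1, links=[(2, 0), (3, 0), (4, 0)])
        m = tracking_metrics([a, b], gt)
        assert m["fragmentation"] == 1
        assert m["track_purity"] == 1.0

    def test_unknown_link_errors(self):
        with pytest.raises(ValueError, match="absent"):
            tracking_metrics([Track(track_id=0, links=[(0, 99)])], _single_cell_gt())

    def test_nearest_neighbor_equivalence(self):
        """With w_feature = 0 and well-separated cells, assignment is nearest-neighbor."""
        f = FeatureVector(np.array([1.0]))
        cfg = TrackerConfig(w_spatial=1.0, w_feature=0.0, w_overlap=0.0, gate_radius=100)
        positions = [(10, 10), (60, 10), (10, 60)]
        dets = [[D(x, y) for x, y in positions],
                [D(x + 2, y + 1) for x, y in positions]]
        feats = [[f] * 3] * 2
        tracks = track_sequence(dets, feats, config=cfg)
        assert sorted(tr.links for tr in tracks) == [[(0, i), (1, i)] for i in range(3)]

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrackerConfig(w_spatial=0.5, w_feature=0.5, w_overlap=0.5)
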