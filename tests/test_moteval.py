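"""Tracking/detection evaluation: identity measures against an exhaustive
bipartite-pairing oracle, coverage boundaries, ID switches, AP against
hand-computed precision-recall curves, table summaries, and the joint
optimization objective with its seeded search harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from colonytrack.boxes import BoundingBox, iou
from colonytrack.detect import Detection
from colonytrack.moteval import (
    average_precision,
    evaluate_tracking,
    id_measures,
    id_switches,
    objective,
    round_half_up,
    summarize,
    track_coverage,
    tune,
)


def _box(x, y, w=10.0, h=10.0):
    return BoundingBox(x, y, w, h)


def _random_tracks(rng, n_tracks, n_slices, jitter=0.0):
    out = {}
    for tid in range(n_tracks):
        x, y = rng.uniform(0, 80, size=2)
        start = int(rng.integers(0, n_slices // 2))
        length = int(rng.integers(1, n_slices - start + 1))
        out[tid] = {
            s: _box(x + rng.uniform(-jitter, jitter), y + rng.uniform(-jitter, jitter))
            for s in range(start, start + length)
        }
    return out


def _oracle_idtp(gt, hyp, thr):
    """Exhaustive maximum of total matched frames over all injective
    pairings of ground-truth and hypothesis trajectories."""
    gids, hids = sorted(gt), sorted(hyp)
    overlap = {
        (g, h): sum(1 for f in gt[g].keys() & hyp[h].keys() if iou(gt[g][f], hyp[h][f]) >= thr)
        for g in gids
        for h in hids
    }
    best = 0
    k = min(len(gids), len(hids))
    for r in range(k + 1):
        for gsub in itertools.combinations(gids, r):
            for hperm in itertools.permutations(hids, r):
                best = max(best, sum(overlap[g, h] for g, h in zip(gsub, hperm)))
    return best


class TestIdMeasures:
    def test_identical_tracks_perfect_scores(self):
        gt = {0: {s: _box(0, 0) for s in range(5)}, 1: {s: _box(40, 40) for s in range(5)}}
        idtp, idfp, idfn = id_measures(gt, gt)
        assert (idtp, idfp, idfn) == (10, 0, 0)
        scores = evaluate_tracking(gt, gt)
        assert scores.idf1 == 1.0 and scores.id_switches == 0

    def test_empty_hypotheses(self):
        gt = {0: {s: _box(0, 0) for s in range(7)}}
        idtp, idfp, idfn = id_measures(gt, {})
        assert (idtp, idfp, idfn) == (0, 0, 7)
        assert evaluate_tracking(gt, {}).idf1 == 0.0

    def test_identity_swap_matches_exhaustive_optimum(self):
        """Two objects whose hypothesis ids swap mid-stack: the global
        pairing keeps whichever assignment covers more frames."""
        gt = {0: {s: _box(0, 0) for s in range(10)}, 1: {s: _box(40, 40) for s in range(10)}}
        hyp = {
            7: {**{s: _box(0, 0) for s in range(6)}, **{s: _box(40, 40) for s in range(6, 10)}},
            8: {**{s: _box(40, 40) for s in range(6)}, **{s: _box(0, 0) for s in range(6, 10)}},
        }
        idtp, _, _ = id_measures(gt, hyp)
        assert idtp == _oracle_idtp(gt, hyp, 0.5) == 12

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_bipartite_pairing_oracle(self, seed):
        """Randomized scenarios (<= 5 tracks, <= 20 slices): the Hungarian
        trajectory pairing equals the exhaustive maximum."""
        rng = np.random.default_rng(seed)
        gt = _random_tracks(rng, int(rng.integers(1, 6)), 20)
        hyp = _random_tracks(rng, int(rng.integers(1, 6)), 20, jitter=3.0)
        idtp, idfp, idfn = id_measures(gt, hyp)
        assert idtp == _oracle_idtp(gt, hyp, 0.5)
        assert idfn == sum(len(t) for t in gt.values()) - idtp
        assert idfp == sum(len(t) for t in hyp.values()) - idtp


class TestCoverage:
    def test_full_coverage_mostly_tracked(self):
        track = {s: _box(0, 0) for s in range(10)}
        assert track_coverage(track, set(range(10))) == "mostly_tracked"

    def test_no_coverage_mostly_lost(self):
        track = {s: _box(0, 0) for s in range(10)}
        assert track_coverage(track, set()) == "mostly_lost"

    def test_half_coverage_partially_tracked(self):
        track = {s: _box(0, 0) for s in range(10)}
        assert track_coverage(track, set(range(5))) == "partially_tracked"

    @pytest.mark.parametrize("matched,expected", [(8, "mostly_tracked"), (2, "mostly_lost"), (3, "partially_tracked")])
    def test_boundary_conventions(self, matched, expected):
        track = {s: _box(0, 0) for s in range(10)}
        assert track_coverage(track, set(range(matched))) == expected

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            track_coverage({}, set())

    def test_categories_partition_objects(self):
        rng = np.random.default_rng(5)
        gt = _random_tracks(rng, 4, 15)
        hyp = _random_tracks(rng, 3, 15, jitter=4.0)
        s = evaluate_tracking(gt, hyp)
        assert s.mostly_tracked + s.partially_tracked + s.mostly_lost == s.n_objects == 4


class TestIdSwitches:
    def test_identical_no_switches(self):
        gt = {0: {s: _box(0, 0) for s in range(10)}}
        assert id_switches(gt, gt) == 0

    def test_single_handover_counts_once(self):
        gt = {0: {s: _box(0, 0) for s in range(10)}}
        hyp = {
            1: {s: _box(0, 0) for s in range(5)},
            2: {s: _box(0, 0) for s in range(5, 10)},
        }
        assert id_switches(gt, hyp) == 1

    def test_mid_stack_swap_counts_for_both_objects(self):
        gt = {0: {s: _box(0, 0) for s in range(10)}, 1: {s: _box(40, 40) for s in range(10)}}
        hyp = {
            1: {**{s: _box(0, 0) for s in range(5)}, **{s: _box(40, 40) for s in range(5, 10)}},
            2: {**{s: _box(40, 40) for s in range(5)}, **{s: _box(0, 0) for s in range(5, 10)}},
        }
        assert id_switches(gt, hyp) == 2


class TestAveragePrecision:
    def test_exact_detections_ap_one(self):
        gt = [(0, _box(0, 0), "cell"), (0, _box(30, 30), "colony")]
        dets = [
            Detection(_box(0, 0), "cell", 0.3, 0),
            Detection(_box(30, 30), "colony", 0.8, 0),
        ]
        ev = average_precision(dets, gt)
        assert ev.per_class["cell"]["ap"] == 1.0
        assert ev.per_class["colony"]["ap"] == 1.0

    def test_no_detections_ap_zero(self):
        gt = [(0, _box(0, 0), "cell")]
        ev = average_precision([], gt)
        assert ev.per_class["cell"]["ap"] == 0.0
        assert ev.map50 == 0.0

    def test_spurious_lower_ranked_detection_keeps_ap_one(self):
        """PR points (1.0, 1.0) then (0.5, 1.0): all-point AP stays 1.0."""
        gt = [(0, _box(0, 0), "cell")]
        dets = [
            Detection(_box(0, 0), "cell", 0.9, 0),
            Detection(_box(60, 60), "cell", 0.8, 0),
        ]
        ev = average_precision(dets, gt)
        assert ev.per_class["cell"]["ap"] == 1.0
        assert ev.per_class["cell"]["precision"] == 0.5
        assert ev.per_class["cell"]["recall"] == 1.0

    def test_hand_enumerated_pr_curve(self):
        """2 GT, 3 detections ranked (hit, miss, hit): PR points
        (r=.5, p=1), (r=.5, p=.5), (r=1, p=2/3) -> AP = .5*1 + .5*(2/3)."""
        gt = [(0, _box(0, 0), "cell"), (0, _box(30, 30), "cell")]
        dets = [
            Detection(_box(0, 0), "cell", 0.9, 0),
            Detection(_box(60, 60), "cell", 0.8, 0),
            Detection(_box(30, 30), "cell", 0.7, 0),
        ]
        ev = average_precision(dets, gt)
        assert ev.per_class["cell"]["ap"] == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_confusion_matrix_background_row_and_column(self):
        gt = [(0, _box(0, 0), "colony"), (0, _box(30, 30), "cell")]
        dets = [Detection(_box(0, 0), "cluster", 0.9, 0)]  # misclassified hit
        ev = average_precision(dets, gt)
        assert ev.confusion.loc["cluster", "colony"] == 1
        assert ev.confusion.loc["background", "cell"] == 1
        # row sums equal prediction counts
        assert ev.confusion.sum(axis=1)["cluster"] == 1


# Published per-dataset tracking scores of the four-stack reference
# evaluation; the summary averages of these are the fixed points the
# summarize operation must reproduce.
REFERENCE_SCORES = pd.DataFrame(
    [
        ("123", "cluster", 91, 49, 24, 18, 0.682, 0.670, 0.695),
        ("124", "cluster", 103, 78, 14, 11, 0.764, 0.696, 0.847),
        ("125", "cluster", 80, 51, 17, 12, 0.749, 0.713, 0.789),
        ("127", "cluster", 112, 64, 37, 11, 0.715, 0.690, 0.739),
        ("123", "colony", 28, 15, 12, 1, 0.831, 0.927, 0.752),
        ("124", "colony", 14, 14, 0, 0, 0.887, 0.839, 0.940),
        ("125", "colony", 31, 10, 17, 4, 0.704, 0.800, 0.629),
        ("127", "colony", 39, 21, 17, 1, 0.799, 0.835, 0.766),
        ("123", "all", 119, 64, 36, 19, 0.730, 0.746, 0.715),
        ("124", "all", 117, 93, 14, 10, 0.788, 0.719, 0.872),
        ("125", "all", 111, 62, 36, 13, 0.744, 0.751, 0.738),
        ("127", "all", 150, 85, 54, 11, 0.748, 0.739, 0.753),
    ],
    columns=[
        "dataset", "cls", "n_objects", "mostly_tracked", "partially_tracked",
        "mostly_lost", "idf1", "idp", "idr",
    ],
)


class TestSummarize:
    def test_reference_class_averages(self):
        s = summarize(REFERENCE_SCORES).set_index("cls")
        assert s.loc["colony", "idf1_rounded"] == 0.805
        assert s.loc["cluster", "idf1_rounded"] == 0.728
        assert s.loc["colony", "idp_rounded"] == 0.850
        assert s.loc["cluster", "idr_rounded"] == 0.768
        assert s.loc["colony", "mostly_tracked"] == 15.0
        assert s.loc["colony", "mostly_lost"] == 1.50
        assert s.loc["all", "mostly_tracked"] == 76.0
        assert s.loc["all", "partially_tracked"] == 35.0
        assert s.loc["all", "mostly_lost"] == 13.25

    def test_shares_from_averaged_counts(self):
        s = summarize(REFERENCE_SCORES).set_index("cls")
        assert s.loc["all", "mt_percent_rounded"] == 61.2
        assert s.loc["all", "pt_percent_rounded"] == 28.2

    def test_single_dataset_is_identity(self):
        one = REFERENCE_SCORES[REFERENCE_SCORES["dataset"] == "123"]
        s = summarize(one).set_index("cls")
        assert s.loc["colony", "idf1"] == pytest.approx(0.831)
        assert s.loc["colony", "n_objects"] == 28

    def test_inconsistent_class_sets_rejected(self):
        broken = REFERENCE_SCORES.drop(index=4)  # dataset 123 loses colony row
        with pytest.raises(ValueError):
            summarize(broken)


class TestObjective:
    def _scores(self, idf1, mt, pt, n):
        from types import SimpleNamespace

        return SimpleNamespace(
            idf1=idf1, mostly_tracked=mt, partially_tracked=pt, n_objects=n
        )

    def test_perfect_tracking(self):
        assert objective(self._scores(1.0, 5, 0, 5)) == 1.0

    def test_half_half(self):
        assert objective(self._scores(0.5, 1, 1, 4)) == 0.25

    def test_reference_product(self):
        # 0.752 x (76 + 35) / 124.25
        val = objective(self._scores(0.752, 76, 35, 124.25))
        assert val == pytest.approx(0.752 * 111 / 124.25, abs=1e-12)
        assert round(val, 4) == 0.6718

    def test_no_objects_rejected(self):
        with pytest.raises(ValueError):
            objective(self._scores(1.0, 0, 0, 0))


class TestTune:
    def test_constant_objective_history_length(self):
        best, hist = tune({"x": (0.0, 1.0)}, lambda p: 1.0, n_iter=10, seed=0)
        assert len(hist) == 10
        assert all(v == 1.0 for _, v in hist)

    def test_seeded_determinism(self):
        f = lambda p: -((p["x"] - 0.3) ** 2)
        a = tune({"x": (0.0, 1.0)}, f, n_iter=20, seed=5)
        b = tune({"x": (0.0, 1.0)}, f, n_iter=20, seed=5)
        assert a == b

    def test_recovers_known_optimum_2d(self):
        """Unimodal objective on a 2-parameter box: 100 random draws land
        within tolerance of the known maximum at (0.3, 0.7)."""
        f = lambda p: -((p["x"] - 0.3) ** 2) - ((p["y"] - 0.7) ** 2)
        best, hist = tune({"x": (0.0, 1.0), "y": (0.0, 1.0)}, f, n_iter=100, seed=1)
        assert abs(best["x"] - 0.3) < 0.15 and abs(best["y"] - 0.7) < 0.15

    def test_integer_and_choice_dimensions(self):
        space = {"g": (0, 5), "mode": ["a", "b"]}
        best, hist = tune(space, lambda p: p["g"], n_iter=30, seed=2)
        assert best["g"] == 5
        assert all(isinstance(p["g"], int) and p["mode"] in ("a", "b") for p, _ in hist)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            tune({}, lambda p: 0.0, n_iter=5, seed=0)


def test_round_half_up_ties_go_up():
    assert round_half_up(0.7275, 3) == 0.728
    assert round_half_up(0.8045, 3) == 0.805
    assert round_half_up(11.5, 0) == 12.0
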