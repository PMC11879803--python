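"""Tracking and detection evaluation.

Identity measures (IDF1/IDP/IDR) follow the MOT-challenge definition: a
single global minimum-cost bipartite matching between whole ground-truth
and hypothesis trajectories (with dummy partners for unmatched tracks)
maximizes the number of frame-level matches; IDTP is that maximum, IDFN
and IDFP are the leftover ground-truth and hypothesis frames.

Coverage (mostly tracked > 80% of a trajectory, mostly lost <= 20%,
partially tracked in between) and ID switches use CLEAR-style sequential
frame matching that prefers the previous frame's assignment, as the
standard MOT toolchain does.

Detector evaluation provides per-class AP at a single IoU threshold
(all-point interpolated precision-recall area), mAP50, and a confusion
matrix with a background row/column.

``summarize`` averages per-dataset scores the way the assay's evaluation
tables are printed: arithmetic column means, with percentage shares
derived from the averaged counts (per-dataset share averaging does not
reproduce the printed values). Note the mostly-lost share can differ in
the last digit from 100 - MT% - PT% under rounding; both views are
derivable from the emitted unrounded columns.

``objective`` is the joint hyperparameter-search target: IDF1 times the
fraction of objects at least partially tracked, emphasizing recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .boxes import BoundingBox, iou
from .classes import CLASS_NAMES
from .detect import Detection

__all__ = [
    "MOTScores",
    "DetectionEval",
    "id_measures",
    "sequential_matching",
    "track_coverage",
    "id_switches",
    "evaluate_tracking",
    "average_precision",
    "summarize",
    "objective",
    "tune",
    "round_half_up",
]

TrackFrames = Mapping[int, Mapping[int, BoundingBox]]  # id -> {slice -> box}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding for table reproduction (3.5 -> 4)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MOTScores:
    """Identity and coverage metrics for one evaluation dataset."""

    idtp: int
    idfp: int
    idfn: int
    idf1: float
    idp: float
    idr: float
    n_objects: int
    mostly_tracked: int
    partially_tracked: int
    mostly_lost: int
    id_switches: int
    cls: str = "all"


def _frame_overlap(
    g: Mapping[int, BoundingBox], h: Mapping[int, BoundingBox], thr: float
) -> int:
    """Number of frames where the two trajectories overlap at IoU >= thr."""
    return sum(1 for f in g.keys() & h.keys() if iou(g[f], h[f]) >= thr)


def id_measures(
    gt_tracks: TrackFrames, hyp_tracks: TrackFrames, iou_threshold: float = 0.5
) -> tuple[int, int, int]:
    """(IDTP, IDFP, IDFN) from the optimal global trajectory pairing."""
    gids = sorted(gt_tracks)
    hids = sorted(hyp_tracks)
    n_g, n_h = len(gids), len(hids)
    len_g = {g: len(gt_tracks[g]) for g in gids}
    len_h = {h: len(hyp_tracks[h]) for h in hids}
    total_g = sum(len_g.values())
    total_h = sum(len_h.values())
    if n_g == 0 and n_h == 0:
        return 0, 0, 0

    # Square cost matrix with dummy partners: pairing (g, h) costs the
    # frames of either that go unmatched; a dummy pairing costs the whole
    # trajectory. Minimizing total cost maximizes total matched frames.
    size = n_g + n_h
    big = float(total_g + total_h + 1)
    cost = np.full((size, size), 0.0)
    cost[:n_g, :n_h] = big  # overwritten below
    for i, g in enumerate(gids):
        for j, h in enumerate(hids):
            m = _frame_overlap(gt_tracks[g], hyp_tracks[h], iou_threshold)
            cost[i, j] = len_g[g] + len_h[h] - 2 * m
        cost[i, n_h:] = big
        cost[i, n_h + i] = len_g[g]
    for j, h in enumerate(hids):
        cost[n_g:, j] = big
        cost[n_g + j, j] = len_h[h]
    rows, cols = linear_sum_assignment(cost)
    min_cost = float(cost[rows, cols].sum())
    idtp = round((total_g + total_h - min_cost) / 2)
    return idtp, total_h - idtp, total_g - idtp


def sequential_matching(
    gt_tracks: TrackFrames, hyp_tracks: TrackFrames, iou_threshold: float = 0.5
) -> dict[int, dict[int, int]]:
    """CLEAR-style frame-by-frame correspondence.

    Returns {frame -> {gt_id -> hyp_id}}. At each frame, matches carried
    over from the previous frame are kept whenever both boxes are present
    and still overlap at the threshold; remaining boxes are matched by
    minimum-cost assignment on 1 - IoU.
    """
    frames = sorted(
        {f for t in gt_tracks.values() for f in t}
        | {f for t in hyp_tracks.values() for f in t}
    )
    prev: dict[int, int] = {}
    out: dict[int, dict[int, int]] = {}
    for f in frames:
        g_here = {g: t[f] for g, t in gt_tracks.items() if f in t}
        h_here = {h: t[f] for h, t in hyp_tracks.items() if f in t}
        current: dict[int, int] = {}
        # keep previous assignments first
        for g, h in prev.items():
            if g in g_here and h in h_here and iou(g_here[g], h_here[h]) >= iou_threshold:
                current[g] = h
        free_g = sorted(g for g in g_here if g not in current)
        used_h = set(current.values())
        free_h = sorted(h for h in h_here if h not in used_h)
        if free_g and free_h:
            mat = np.array(
                [[1.0 - iou(g_here[g], h_here[h]) for h in free_h] for g in free_g]
            )
            rows, cols = linear_sum_assignment(mat)
            for r, c in zip(rows, cols):
                if 1.0 - mat[r, c] >= iou_threshold:
                    current[free_g[r]] = free_h[c]
        out[f] = current
        prev = current
    return out


def track_coverage(
    gt_track: Mapping[int, BoundingBox], matched_frames: set[int]
) -> str:
    """Coverage category of one ground-truth trajectory.

    r = matched frames / trajectory frames; r >= 0.8 -> mostly_tracked,
    r <= 0.2 -> mostly_lost, otherwise partially_tracked.
    """
    if not gt_track:
        raise ValueError("empty ground-truth track")
    r = len(matched_frames & set(gt_track)) / len(gt_track)
    if r >= 0.8:
        return "mostly_tracked"
    if r <= 0.2:
        return "mostly_lost"
    return "partially_tracked"


def id_switches(
    gt_tracks: TrackFrames, hyp_tracks: TrackFrames, iou_threshold: float = 0.5
) -> int:
    """Count events where a ground-truth object's matched hypothesis id
    changes between consecutive matched frames."""
    matching = sequential_matching(gt_tracks, hyp_tracks, iou_threshold)
    switches = 0
    for g in gt_tracks:
        last: int | None = None
        for f in sorted(matching):
            if g in matching[f]:
                h = matching[f][g]
                if last is not None and h != last:
                    switches += 1
                last = h
    return switches


def evaluate_tracking(
    gt_tracks: TrackFrames,
    hyp_tracks: TrackFrames,
    iou_threshold: float = 0.5,
    cls: str = "all",
) -> MOTScores:
    """All identity and coverage metrics for one dataset."""
    idtp, idfp, idfn = id_measures(gt_tracks, hyp_tracks, iou_threshold)
    denom = 2 * idtp + idfp + idfn
    idf1 = 2 * idtp / denom if denom else 0.0
    idp = idtp / (idtp + idfp) if idtp + idfp else 0.0
    idr = idtp / (idtp + idfn) if idtp + idfn else 0.0
    matching = sequential_matching(gt_tracks, hyp_tracks, iou_threshold)
    mt = pt = ml = 0
    for g, t in gt_tracks.items():
        matched = {f for f, m in matching.items() if g in m}
        cat = track_coverage(t, matched)
        if cat == "mostly_tracked":
            mt += 1
        elif cat == "partially_tracked":
            pt += 1
        else:
            ml += 1
    return MOTScores(
        idtp=idtp,
        idfp=idfp,
        idfn=idfn,
        idf1=idf1,
        idp=idp,
        idr=idr,
        n_objects=len(gt_tracks),
        mostly_tracked=mt,
        partially_tracked=pt,
        mostly_lost=ml,
        id_switches=id_switches(gt_tracks, hyp_tracks, iou_threshold),
        cls=cls,
    )


@dataclass
class DetectionEval:
    """Per-class detector metrics at one IoU threshold."""

    per_class: dict[str, dict[str, float]]
    map50: float
    confusion: pd.DataFrame


def _ap_all_point(recall: np.ndarray, precision: np.ndarray) -> float:
    """Area under the precision-recall curve with the monotone precision
    envelope (all-point interpolation)."""
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def average_precision(
    detections: Sequence[Detection],
    gt_boxes: Sequence[tuple[int, BoundingBox, str]],
    iou_threshold: float = 0.5,
    classes: Sequence[str] = CLASS_NAMES,
) -> DetectionEval:
    """Confidence-ranked greedy AP per class, mAP, and confusion matrix.

    ``gt_boxes`` are (slice_index, box, label) triples. Each ground-truth
    box is matched at most once. mAP averages over classes that have
    ground truth. The confusion matrix assigns each detection to its
    best-IoU ground-truth class (class-agnostic, each GT consumed once)
    or to background; rows are predictions, columns are truth.
    """
    per_class: dict[str, dict[str, float]] = {}
    aps = []
    for cls in classes:
        cls_gt = [(i, (sl, b)) for i, (sl, b, lbl) in enumerate(gt_boxes) if lbl == cls]
        cls_det = sorted(
            (d for d in detections if d.label == cls),
            key=lambda d: (-d.confidence, d.bbox.y_min, d.bbox.x_min),
        )
        n_gt = len(cls_gt)
        matched_gt: set[int] = set()
        tp = np.zeros(len(cls_det))
        for k, det in enumerate(cls_det):
            best, best_iou = None, iou_threshold
            for gi, (sl, box) in cls_gt:
                if sl != det.slice_index or gi in matched_gt:
                    continue
                ov = iou(det.bbox, box)
                if ov >= best_iou:
                    best, best_iou = gi, ov
            if best is not None:
                matched_gt.add(best)
                tp[k] = 1.0
        if n_gt == 0:
            per_class[cls] = {
                "precision": 0.0, "recall": 0.0, "ap": 0.0,
                "n_gt": 0, "n_det": len(cls_det),
            }
            continue
        cum_tp = np.cumsum(tp)
        cum_fp = np.cumsum(1.0 - tp)
        recall = cum_tp / n_gt
        precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
        ap = _ap_all_point(recall, precision) if len(cls_det) else 0.0
        per_class[cls] = {
            "precision": float(precision[-1]) if len(cls_det) else 0.0,
            "recall": float(recall[-1]) if len(cls_det) else 0.0,
            "ap": ap,
            "n_gt": n_gt,
            "n_det": len(cls_det),
        }
        aps.append(ap)

    labels = list(classes) + ["background"]
    conf = pd.DataFrame(0, index=labels, columns=labels)
    remaining = {i for i in range(len(gt_boxes))}
    for det in sorted(detections, key=lambda d: (-d.confidence, d.bbox.y_min, d.bbox.x_min)):
        best, best_iou = None, iou_threshold
        for gi in remaining:
            sl, box, lbl = gt_boxes[gi]
            if sl != det.slice_index:
                continue
            ov = iou(det.bbox, box)
            if ov >= best_iou:
                best, best_iou = gi, ov
        if best is not None:
            remaining.discard(best)
            conf.loc[det.label, gt_boxes[best][2]] += 1
        else:
            conf.loc[det.label, "background"] += 1
    for gi in remaining:
        conf.loc["background", gt_boxes[gi][2]] += 1

    return DetectionEval(
        per_class=per_class,
        map50=float(np.mean(aps)) if aps else 0.0,
        confusion=conf,
    )


_SUMMARY_COLS = [
    "n_objects", "mostly_tracked", "partially_tracked", "mostly_lost",
    "idf1", "idp", "idr",
]


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Average per-dataset tracking scores into the printed table shape.

    ``table`` needs columns dataset, cls, plus the score columns. For
    each class, every score column is averaged arithmetically across
    datasets; coverage shares (percent) are derived from the averaged
    counts. Emits unrounded means plus half-up 3-decimal (scores) /
    1-decimal (percent) display columns.
    """
    missing = {"dataset", "cls", *_SUMMARY_COLS} - set(table.columns)
    if missing:
        raise ValueError(f"summary input missing columns: {sorted(missing)}")
    class_sets = table.groupby("dataset")["cls"].apply(frozenset)
    if len(set(class_sets)) > 1:
        raise ValueError("datasets carry inconsistent class sets")
    rows = []
    for cls, grp in table.groupby("cls", sort=False):
        means = grp[_SUMMARY_COLS].mean()
        n = float(means["n_objects"])
        row = {"dataset": "Average", "cls": cls, **means.to_dict()}
        for share, col in (
            ("mt_percent", "mostly_tracked"),
            ("pt_percent", "partially_tracked"),
            ("ml_percent", "mostly_lost"),
        ):
            row[share] = 100.0 * means[col] / n if n else float("nan")
            row[share + "_rounded"] = round_half_up(row[share], 1) if n else float("nan")
        for col in ("idf1", "idp", "idr"):
            row[col + "_rounded"] = round_half_up(float(means[col]), 3)
        rows.append(row)
    return pd.DataFrame(rows)


def objective(scores: MOTScores) -> float:
    """Joint optimization target: IDF1 x fraction of objects at least
    partially tracked. In [0, 1]; favors recall of unique objects."""
    if scores.n_objects <= 0:
        raise ValueError("objective undefined without ground-truth objects")
    tracked = scores.mostly_tracked + scores.partially_tracked
    return scores.idf1 * tracked / scores.n_objects


ParamSpace = Mapping[str, tuple[float, float] | Sequence]


def tune(
    param_space: ParamSpace,
    evaluate: Callable[[dict], float],
    n_iter: int = 100,
    seed: int = 0,
    sampler: Callable[[np.random.Generator, ParamSpace], dict] | None = None,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Seeded random search over detector + tracker hyperparameters.

    ``param_space`` maps a name to a (low, high) range (float, or int if
    both bounds are ints) or to a discrete sequence of choices. A custom
    ``sampler`` may be plugged in (e.g. an adapter to a TPE backend);
    the default draws uniformly. Returns (best_params, history) where
    history is the full [(params, objective)] sequence; ties keep the
    earliest draw. Deterministic given seed and a deterministic evaluate.
    """
    if not param_space:
        raise ValueError("empty parameter space")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)

    def default_sampler(r: np.random.Generator, space: ParamSpace) -> dict:
        params = {}
        for name, spec in space.items():
            if (
                isinstance(spec, tuple)
                and len(spec) == 2
                and all(isinstance(v, (int, float)) for v in spec)
            ):
                lo, hi = spec
                if isinstance(lo, int) and isinstance(hi, int):
                    params[name] = int(r.integers(lo, hi + 1))
                else:
                    params[name] = float(r.uniform(lo, hi))
            else:
                params[name] = spec[int(r.integers(0, len(spec)))]
        return params

    draw = sampler or default_sampler
    history: list[tuple[dict, float]] = []
    best_params, best_value = None, -np.inf
    for _ in range(n_iter):
        params = draw(rng, param_space)
        value = float(evaluate(params))
        history.append((params, value))
        if value > best_value:
            best_params, best_value = params, value
    assert best_params is not None
    return best_params, history
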