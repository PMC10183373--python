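"""Instance evaluation metrics and naive bounding-box tracking.

Two distinct Jaccard-index uses, never conflated:

* *volumetric* best JI per ground-truth instance (segmentation quality):
  for ground-truth label ``i``, ``JI_i = max_j |T_i ∩ P_j| / |T_i ∪ P_j|``
  over predicted labels, with ΔCM the physical distance between the
  centroids of ``T_i`` and the argmax prediction;
* *bounding-box* JI for detection accuracy: predicted and ground-truth
  instances map to each other by highest box JI, mutual single pairs are
  true positives, multiple predictions on one ground truth are false
  positives, and ground truths that are multiply matched or unmatched are
  false negatives.

Tracking links instances frame-to-frame greedily by maximal bounding-box
JI; a track that disappears while overlapping the first boxes of two or
more new tracks records those as children (division candidate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh, bounding_box
from .volume import Volume

__all__ = [
    "InstanceMatch",
    "MatchResult",
    "Track",
    "best_ji_map",
    "detection_match",
    "bbox_ji",
    "track_bboxes",
    "cell_counts",
    "velocity_distribution",
]


@dataclass
class InstanceMatch:
    """Best volumetric match for one ground-truth instance."""

    gt_label: int
    matched_pred_label: int | None
    best_ji: float
    delta_cm: float | None  # µm; None when nothing matched


@dataclass
class MatchResult:
    """Per-instance volumetric matches plus detection tallies."""

    matches: list[InstanceMatch] = field(default_factory=list)
    n: int = 0
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def tp_fraction(self) -> float:
        return self.tp / self.n if self.n else float("nan")


@dataclass(eq=False)
class Track:
    """One tracked identity: per-frame (frame_index, instance_id, centroid, bbox)."""

    track_id: int
    parent_track_id: int | None = None
    frames: list[int] = field(default_factory=list)
    instance_ids: list[int] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    bboxes: list[tuple] = field(default_factory=list)

    def add(self, frame: int, instance_id: int, centroid, bbox) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frame indices must be strictly increasing")
        self.frames.append(frame)
        self.instance_ids.append(instance_id)
        self.centroids.append(np.asarray(centroid, dtype=float))
        self.bboxes.append(bbox)

    @property
    def last_frame(self) -> int:
        return self.frames[-1]


# ---------------------------------------------------------------------------
# volumetric best JI


def best_ji_map(gt: Volume, pred: Volume) -> MatchResult:
    """Best volumetric JI and ΔCM per ground-truth label.

    Uses a sparse contingency table over the joint labels, equivalent to
    all-pairs intersection counting.  Argmax ties break to the lower
    predicted label.  ΔCM is computed between unweighted voxel-centre
    means, in physical units.
    """
    g = np.asarray(gt.data)
    p = np.asarray(pred.data)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    gt_labels = np.unique(g[g > 0])
    pred_labels = np.unique(p[p > 0])
    gt_sizes = {int(l): int((g == l).sum()) for l in gt_labels}
    pred_sizes = {int(l): int((p == l).sum()) for l in pred_labels}

    both = (g > 0) & (p > 0)
    inter: dict[tuple[int, int], int] = {}
    if both.any():
        pairs = g[both].astype(np.int64) * (p.max() + 1) + p[both].astype(np.int64)
        uniq, counts = np.unique(pairs, return_counts=True)
        for u, c in zip(uniq, counts):
            inter[(int(u // (p.max() + 1)), int(u % (p.max() + 1)))] = int(c)

    spacing = np.asarray(gt.spacing)
    result = MatchResult(n=len(gt_labels))
    for gl in gt_labels:
        gl = int(gl)
        best_ji, best_pl = 0.0, None
        for pl in pred_labels:
            pl = int(pl)
            i = inter.get((gl, pl), 0)
            if i == 0:
                continue
            ji = i / (gt_sizes[gl] + pred_sizes[pl] - i)
            if ji > best_ji + 1e-15 or (abs(ji - best_ji) <= 1e-15 and
                                        best_pl is not None and pl < best_pl):
                best_ji, best_pl = ji, pl
        if best_pl is None:
            result.matches.append(InstanceMatch(gl, None, 0.0, None))
            continue
        cg = np.argwhere(g == gl).mean(axis=0) * spacing
        cp = np.argwhere(p == best_pl).mean(axis=0) * spacing
        result.matches.append(InstanceMatch(gl, best_pl, float(best_ji),
                                            float(np.linalg.norm(cg - cp))))
    return result


# ---------------------------------------------------------------------------
# bounding-box detection


def bbox_ji(box_a, box_b) -> float:
    """Jaccard index of two axis-aligned boxes ``(min_corner, max_corner)``."""
    amin, amax = (np.asarray(v, dtype=float) for v in box_a)
    bmin, bmax = (np.asarray(v, dtype=float) for v in box_b)
    lo = np.maximum(amin, bmin)
    hi = np.minimum(amax, bmax)
    if np.any(hi <= lo):
        return 0.0
    inter = float(np.prod(hi - lo))
    va = float(np.prod(amax - amin))
    vb = float(np.prod(bmax - bmin))
    union = va + vb - inter
    return inter / union if union > 0 else 0.0


def _argmax_map(boxes_from, boxes_to) -> list[int | None]:
    """For each source box the index of the highest-JI target (None if all 0)."""
    out: list[int | None] = []
    for bf in boxes_from:
        best, best_j = None, 0.0
        for j, bt in enumerate(boxes_to):
            ji = bbox_ji(bf, bt)
            if ji > best_j + 1e-15:
                best, best_j = j, ji
        out.append(best)
    return out


def detection_match(gt_boxes: list, pred_boxes: list) -> tuple[int, int, int]:
    """(TP, FP, FN) from bidirectional highest-bbox-JI mapping.

    Mutual single pairs count TP; every prediction in a group of several
    mapping the same ground truth counts FP; all non-TP ground truths
    count FN (multiply matched, unmatched, or in non-mutual pairs).
    Zero-JI mappings count as unmapped.
    """
    pred_to_gt = _argmax_map(pred_boxes, gt_boxes)
    gt_to_pred = _argmax_map(gt_boxes, pred_boxes)
    preds_on_gt: dict[int, list[int]] = {}
    for j, i in enumerate(pred_to_gt):
        if i is not None:
            preds_on_gt.setdefault(i, []).append(j)
    gts_on_pred: dict[int, list[int]] = {}
    for i, j in enumerate(gt_to_pred):
        if j is not None:
            gts_on_pred.setdefault(j, []).append(i)
    tp = 0
    fp = 0
    for i, js in preds_on_gt.items():
        if len(js) > 1:
            fp += len(js)
        elif gt_to_pred[i] == js[0] and len(gts_on_pred[js[0]]) == 1:
            tp += 1  # singly mapped to each other, both ways
    fn = len(gt_boxes) - tp
    return tp, fp, fn


# ---------------------------------------------------------------------------
# tracking


def _mesh_record(mesh: TriMesh):
    return mesh.centroid(), bounding_box(mesh)


def track_bboxes(frames: list[list[TriMesh]], j_min: float = 0.1) -> list[Track]:
    """Greedy frame-to-frame linking of meshes by bounding-box overlap.

    Links with box JI below ``j_min`` are not made; unlinked instances
    start new tracks.  When a track ends and its last box overlaps the
    first boxes of two or more tracks born the next frame, those tracks
    record it as their parent (division candidate).
    """
    if not frames:
        raise ValueError("need at least one frame")
    tracks: list[Track] = []
    active: list[Track] = []
    for t, meshes in enumerate(frames):
        records = [_mesh_record(m) for m in meshes]
        links: list[tuple[float, int, int]] = []
        for a, tr in enumerate(active):
            for b, (_, box) in enumerate(records):
                ji = bbox_ji(tr.bboxes[-1], box)
                if ji >= j_min:
                    links.append((ji, a, b))
        links.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ji, a, b in links:
            if a in used_a or b in used_b:
                continue
            used_a.add(a)
            used_b.add(b)
            active[a].add(t, meshes[b].instance_id, records[b][0], records[b][1])
        newborn: list[Track] = []
        for b, mesh in enumerate(meshes):
            if b in used_b:
                continue
            tr = Track(track_id=len(tracks))
            tr.add(t, mesh.instance_id, records[b][0], records[b][1])
            tracks.append(tr)
            newborn.append(tr)
        ended = [tr for a, tr in enumerate(active) if a not in used_a]
        for tr in ended:
            children = [nb for nb in newborn
                        if bbox_ji(tr.bboxes[-1], nb.bboxes[0]) > 0.0]
            if len(children) >= 2:
                for ch in children:
                    ch.parent_track_id = tr.track_id
        active = [tr for a, tr in enumerate(active) if a in used_a] + newborn
    return tracks


def cell_counts(tracks: list[Track], n_frames: int) -> np.ndarray:
    """Number of tracks active (having an entry) at each frame."""
    counts = np.zeros(n_frames, dtype=int)
    for tr in tracks:
        for f in tr.frames:
            if 0 <= f < n_frames:
                counts[f] += 1
    return counts


def velocity_distribution(tracks: list[Track], frame_interval_minutes: float = 1.0) -> np.ndarray:
    """Speeds (µm/min) over all consecutive frame pairs of all tracks."""
    if frame_interval_minutes <= 0:
        raise ValueError("frame interval must be positive")
    speeds: list[float] = []
    for tr in tracks:
        for k in range(1, len(tr.frames)):
            dt_frames = tr.frames[k] - tr.frames[k - 1]
            d = np.linalg.norm(tr.centroids[k] - tr.centroids[k - 1])
            speeds.append(d / (dt_frames * frame_interval_minutes))
    return np.asarray(speeds)
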