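"""Scoring tracking output against simulator ground truth.

The question the metrics answer is the one that matters for multi-plant
separation: did every tracker stay locked to the root it was seeded on, all
the way through every interaction?

A one-time global plant-to-root assignment is fixed at the seed slice by
maximum overlap (Hungarian matching). Label accuracy is then the fraction of
truth-foreground pixels carrying the correct plant label. A *swap* is a
change in the truth-root identity a plant's material majority-overlaps,
evaluated on clean slices (slices outside ground-truth contact episodes):
during deep coalescence the truth's nearest-centre split can transiently
shift a perfectly-behaved tracker's majority, which is not an identity
failure, so identity is audited where it is unambiguous — before and after
each interaction. Each interaction is flagged successful when both involved
plants carry the same truth-root identity immediately after the episode as
immediately before it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .simulate import GroundTruth
from .volume_io import RootVolume

__all__ = ["TrackingMetrics", "evaluate"]


@dataclass
class TrackingMetrics:
    """Outcome of one tracking run scored against ground truth."""

    assignment: dict[int, int]  # plant_id -> truth root index
    per_root_accuracy: dict[int, float]  # truth root -> fraction correctly labelled
    overall_accuracy: float
    swap_count: int
    swap_slices: list[int]
    lost_plants: list[int]  # plants with no labelled pixels on some clean slice
    interactions: list[dict]  # per-episode success flags

    @property
    def interaction_successes(self) -> int:
        return sum(1 for i in self.interactions if i["success"])

    def to_json(self) -> dict:
        return {
            "assignment": {str(k): v for k, v in self.assignment.items()},
            "per_root_accuracy": {str(k): v for k, v in self.per_root_accuracy.items()},
            "overall_accuracy": self.overall_accuracy,
            "swap_count": self.swap_count,
            "swap_slices": self.swap_slices,
            "lost_plants": self.lost_plants,
            "interactions": self.interactions,
        }


def _majority_root(plant_mask: np.ndarray, truth_slice: np.ndarray) -> int | None:
    """Truth root index the plant's pixels mostly overlap (None when off-foreground)."""
    vals = truth_slice[plant_mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        return None
    counts = np.bincount(vals)
    return int(np.argmax(counts))


def evaluate(result: RootVolume | np.ndarray, truth: GroundTruth) -> TrackingMetrics:
    """Score a tracked label volume against the simulator's ground truth."""
    labels = result.labels if isinstance(result, RootVolume) else np.asarray(result)
    if labels.shape != truth.labels.shape:
        raise ValueError(
            f"result shape {labels.shape} does not match truth shape {truth.labels.shape}"
        )
    plant_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    n_roots = truth.n_roots
    if not plant_ids:
        raise ValueError("result volume contains no plant labels")

    # one-time assignment fixed at the seed slice (maximum overlap)
    overlap = np.zeros((len(plant_ids), n_roots))
    t0 = truth.labels[0]
    for pi, p in enumerate(plant_ids):
        pm = labels[0] == p
        for r in range(1, n_roots + 1):
            overlap[pi, r - 1] = np.count_nonzero(pm & (t0 == r))
    rows, cols = linear_sum_assignment(-overlap)
    assignment = {plant_ids[i]: int(j + 1) for i, j in zip(rows, cols)}

    # per-root accuracy over the whole volume
    root_to_plant = {r: p for p, r in assignment.items()}
    per_root_accuracy = {}
    total_correct = 0
    total_fg = 0
    for r in range(1, n_roots + 1):
        fg = truth.labels == r
        n_fg = int(fg.sum())
        p = root_to_plant.get(r)
        correct = int(np.count_nonzero(labels[fg] == p)) if p is not None else 0
        per_root_accuracy[r] = correct / n_fg if n_fg else 1.0
        total_correct += correct
        total_fg += n_fg
    overall = total_correct / total_fg if total_fg else 1.0

    # identity audit on clean slices
    contact = truth.contact_slices(margin=1)
    clean = np.flatnonzero(~contact)
    swap_count = 0
    swap_slices: list[int] = []
    lost: set[int] = set()
    last_majority: dict[int, int] = {}
    for z in clean:
        tz = truth.labels[z]
        for p in plant_ids:
            pm = labels[z] == p
            if not pm.any():
                lost.add(p)
                continue
            maj = _majority_root(pm, tz)
            if maj is None:
                continue
            prev = last_majority.get(p)
            if prev is not None and maj != prev:
                swap_count += 1
                swap_slices.append(int(z))
            last_majority[p] = maj

    # per-interaction success: identity equal on the clean slices flanking the episode
    interactions = []
    for (s, e, pair) in truth.interaction_log:
        involved = [root_to_plant.get(r) for r in pair]
        before = {}
        after = {}
        pre = [z for z in clean if z < s]
        post = [z for z in clean if z > e]
        ok = True
        for p in involved:
            if p is None:
                ok = False
                continue
            bz = pre[-1] if pre else None
            az = post[0] if post else None
            before[p] = _majority_root(labels[bz] == p, truth.labels[bz]) if bz is not None else None
            after[p] = _majority_root(labels[az] == p, truth.labels[az]) if az is not None else None
            if bz is not None and az is not None:
                if before[p] is None or after[p] is None or before[p] != after[p]:
                    ok = False
        interactions.append(
            {
                "slice_start": int(s),
                "slice_end": int(e),
                "roots": list(pair),
                "success": bool(ok),
            }
        )

    return TrackingMetrics(
        assignment=assignment,
        per_root_accuracy=per_root_accuracy,
        overall_accuracy=overall,
        swap_count=swap_count,
        swap_slices=swap_slices,
        lost_plants=sorted(lost),
        interactions=interactions,
    )
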