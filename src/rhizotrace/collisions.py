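"""Detecting cross-plant contacts and resolving them with the push/push-back rule.

A collision exists while two targets of *different* plants share image
territory: their interiors overlap or are 8-adjacent. Same-plant contacts are
ordinary merges and never collisions. While a collision is open, each
involved field's interface points are classified against the region predicted
by rigidly aligning its frozen pre-collision shape record (ICP): points lying
strictly inside the predicted region indicate the front has been pushed
inwards by the neighbour, and the field is authorized to push back — reclaim
pixels of the predicted region currently interior to the other field,
switching the other function's sign there. Points outside the predicted
region mean ordinary growth and evolve normally.

Per contested pixel the four outcomes are: claimed by neither predicted shape
(normal evolution, ownership stands); claimed by one field's shape with that
field authorized (it reclaims the pixel, the other is pushed back); claimed by
both shapes (neither front can be pushed — the pixel is frozen at its
pre-resolution owner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .levelset import LevelSetField, extract_interface
from .shapes import ShapeRegistry

__all__ = [
    "CollisionEvent",
    "PointState",
    "CollisionManager",
    "detect_collisions",
    "classify_points",
    "resolve_push",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class CollisionEvent:
    """One contact episode between two targets of different plants."""

    target_pair: tuple[int, int]
    plant_pair: tuple[int, int]
    slice_start: int
    slice_end: int | None = None
    contested_pixels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plant_pair[0] == self.plant_pair[1]:
            raise ValueError("a collision event requires targets of different plants")

    @property
    def open(self) -> bool:
        return self.slice_end is None

    def to_json(self) -> dict:
        return {
            "targets": list(self.target_pair),
            "plants": list(self.plant_pair),
            "slice_start": self.slice_start,
            "slice_end": self.slice_end,
            "contested_pixels": {str(k): v for k, v in self.contested_pixels.items()},
        }


@dataclass(frozen=True)
class PointState:
    """One interface point labelled against its ICP-predicted region."""

    location: tuple[float, float]
    inside_predicted: bool

    @property
    def state(self) -> str:
        return "inside_predicted" if self.inside_predicted else "outside_predicted"


def _in_contact(a: np.ndarray, b: np.ndarray) -> bool:
    """Shared interior pixels or 8-adjacency."""
    if (a & b).any():
        return True
    return bool((ndimage.binary_dilation(a, _STRUCT8) & b).any())


def detect_collisions(
    fields: Sequence[LevelSetField], slice_index: int = 0
) -> list[CollisionEvent]:
    """One event per contacting cross-plant pair on the current slice.

    Contact means interiors sharing negative level-set values at a location,
    or 8-adjacent interiors (so the mechanism triggers before actual fusion).
    Same-plant contacts are never reported.
    """
    events = []
    active = [f for f in fields if not f.empty]
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            if a.plant_id == b.plant_id:
                continue
            if _in_contact(a.mask, b.mask):
                shared = int((a.mask & b.mask).sum())
                ev = CollisionEvent(
                    (a.target_id, b.target_id),
                    (a.plant_id, b.plant_id),
                    slice_start=slice_index,
                )
                ev.contested_pixels[slice_index] = shared
                events.append(ev)
    return events


def _min_boundary_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum distance from any pixel of b to the nearest pixel of a."""
    if not a.any() or not b.any():
        return np.inf
    dist_to_a = ndimage.distance_transform_edt(~a)
    return float(dist_to_a[b].min())


def classify_points(
    fld: LevelSetField, predicted: np.ndarray
) -> list[PointState]:
    """Label every interface point of a field against its predicted region.

    A point is ``inside_predicted`` only when strictly interior to the
    predicted mask (its pixel survives a one-pixel erosion), so an interface
    coincident with the predicted outline classifies as outside and evolves
    normally; a dented arc classifies inside and gains push authorization.
    """
    interior = ndimage.binary_erosion(predicted, _STRUCT8, border_value=0)
    states = []
    h, w = predicted.shape
    for contour in extract_interface(fld):
        rows = np.clip(np.rint(contour[:, 0]).astype(int), 0, h - 1)
        cols = np.clip(np.rint(contour[:, 1]).astype(int), 0, w - 1)
        inside = interior[rows, cols]
        states.extend(
            PointState((float(r), float(c)), bool(s))
            for (r, c), s in zip(contour, inside)
        )
    return states


def _keep_components_touching(mask: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Drop connected components of mask disjoint from anchor (largest kept if none touch)."""
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n <= 1:
        return mask
    touching = np.unique(labels[anchor & (labels > 0)])
    if touching.size == 0:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        touching = np.array([1 + int(np.argmax(sizes))])
    return np.isin(labels, touching)


def resolve_push(
    a: LevelSetField,
    b: LevelSetField,
    states_a: Sequence[PointState],
    states_b: Sequence[PointState],
    predicted_a: np.ndarray,
    predicted_b: np.ndarray,
    growth_margin: int | None = 6,
) -> tuple[LevelSetField, LevelSetField, int]:
    """Apply the four-scenario push/push-back rule table to a colliding pair.

    A field whose interface has points inside its predicted region is
    authorized to reclaim pixels of the predicted region currently interior
    to the other field (the other's sign is switched positive there). Where
    *both* predicted shapes claim the same location, neither front can be
    pushed: the pixel is frozen at its pre-resolution owner. Elsewhere the
    fronts evolve normally. Returns the two updated fields and the
    contested-pixel count for the event log.

    ``growth_margin`` bounds how far (in pixels) a collided field may extend
    beyond its own predicted region, keeping each level set locked near its
    recorded shape while the collision lasts; ``None`` disables the cap. After
    reclamation each field keeps only interior components connected to its
    predicted region, so no orphan fragment is left straddling the
    neighbour's root.
    """
    auth_a = any(s.inside_predicted for s in states_a)
    auth_b = any(s.inside_predicted for s in states_b)
    has_pred_a = predicted_a.any()
    has_pred_b = predicted_b.any()
    # scenario (i): both shapes claim the location -> frozen at current owner
    frozen = predicted_a & predicted_b
    take_a = (predicted_a & b.mask & ~frozen) if auth_a else np.zeros_like(b.mask)
    take_b = (predicted_b & a.mask & ~frozen) if auth_b else np.zeros_like(a.mask)

    new_a = (a.mask | take_a) & ~take_b
    new_b = (b.mask | take_b) & ~take_a

    if growth_margin is not None:
        if has_pred_a:
            allowed = ndimage.binary_dilation(predicted_a, _STRUCT8, iterations=growth_margin)
            new_a &= allowed
        if has_pred_b:
            allowed = ndimage.binary_dilation(predicted_b, _STRUCT8, iterations=growth_margin)
            new_b &= allowed
    if has_pred_a:
        new_a = _keep_components_touching(new_a, predicted_a)
    if has_pred_b:
        new_b = _keep_components_touching(new_b, predicted_b)

    contested = int(((predicted_a & b.mask) | (predicted_b & a.mask)).sum())
    a2 = LevelSetField(a.target_id, a.plant_id, new_a)
    b2 = LevelSetField(b.target_id, b.plant_id, new_b)
    return a2, b2, contested


class CollisionManager:
    """Tracks open collision events across slices and freezes shape records.

    An event opens on the first slice a cross-plant pair is in contact and
    closes on the first slice the two interiors are neither overlapping nor
    8-adjacent and their minimum boundary distance exceeds the separation
    margin; the pair separating and re-touching later yields a distinct
    second event.
    """

    def __init__(self, registry: ShapeRegistry, separation_margin: float = 2.0):
        self.registry = registry
        self.separation_margin = separation_margin
        self.open_events: dict[tuple[int, int], CollisionEvent] = {}
        self.closed_events: list[CollisionEvent] = []

    def collided_targets(self) -> set[int]:
        out: set[int] = set()
        for pair in self.open_events:
            out.update(pair)
        return out

    def update(self, fields: Sequence[LevelSetField], slice_index: int) -> list[CollisionEvent]:
        """Open events for new contacts; freeze the involved shape records."""
        fresh = detect_collisions(fields, slice_index)
        for ev in fresh:
            key = ev.target_pair
            if key in self.open_events:
                self.open_events[key].contested_pixels[slice_index] = ev.contested_pixels[slice_index]
            else:
                self.open_events[key] = ev
                for tid in key:
                    self.registry.freeze(tid)
        return list(self.open_events.values())

    def close_separated(self, fields: Sequence[LevelSetField], slice_index: int) -> list[CollisionEvent]:
        """Close events whose targets are clearly separated (or gone); unfreeze shapes."""
        by_id = {f.target_id: f for f in fields}
        closed = []
        for key in list(self.open_events):
            ta, tb = key
            fa, fb = by_id.get(ta), by_id.get(tb)
            gone = fa is None or fb is None or fa.empty or fb.empty
            if not gone:
                if _in_contact(fa.mask, fb.mask):
                    continue
                if _min_boundary_distance(fa.mask, fb.mask) <= self.separation_margin:
                    continue
            ev = self.open_events.pop(key)
            ev.slice_end = slice_index
            self.closed_events.append(ev)
            closed.append(ev)
        # unfreeze targets with no remaining open event
        still = self.collided_targets()
        for ev in closed:
            for tid in ev.target_pair:
                if tid not in still:
                    self.registry.unfreeze(tid)
        return closed

    @property
    def all_events(self) -> list[CollisionEvent]:
        return self.closed_events + list(self.open_events.values())
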