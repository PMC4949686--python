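"""Top-down tracking of multiple plants' root cross-sections through a stack.

Each plant owns a group of trackers, seeded from user-supplied points. The
stack is processed slice by slice from the top: every active target's
level-set field is initialized from its previous interior, evolved under the
multi-phase exclusion rule, and — when a cross-plant collision is open — the
push/push-back refinement re-assigns contested pixels using the frozen
pre-collision shape of each target. Targets split into same-plant children
when their interior breaks into several connected components, merge freely
with targets of the same plant, and terminate when their interior vanishes or
their appearance diverges from the reference for several consecutive slices.

The result is a labelled volume (one integer label per plant) plus a run
report: per-slice target counts and areas, the collision log, terminations
and parameter settings. Tracking is fully deterministic: identical inputs and
parameters produce identical volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
from scipy import ndimage

from .collisions import CollisionManager, classify_points, resolve_push
from .levelset import (
    AppearanceModel,
    EvolveParams,
    LevelSetField,
    evolve,
    interface_points,
)
from .shapes import ShapeRegistry, icp_align, predicted_region
from .volume_io import ImageStack, RootVolume, SeedConfig

__all__ = ["TrackParams", "Target", "TrackerState", "initialize", "step", "run"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class TrackParams:
    """All tunables of the tracking pipeline (see docs/methods.md).

    ``shape_constraint`` switches the collision mechanism: when False the
    tracker runs as a plain multi-phase tracker (exclusion only), the
    baseline configuration of the with/without comparison.
    """

    shape_constraint: bool = True
    separation_margin: float = 2.0
    seed_radius: float = 3.0
    seed_max_iter: int = 40
    max_iter: int = 10
    curvature_passes: int = 1
    n_bins: int = 64
    divergence_threshold: float = 0.1
    term_patience: int = 3
    icp_max_iter: int = 50
    icp_tol: float = 0.05
    icp_trim: float | None = None
    collision_growth_margin: int = 6

    def evolve_params(self, max_iter: int | None = None) -> EvolveParams:
        return EvolveParams(
            max_iter=self.max_iter if max_iter is None else max_iter,
            curvature_passes=self.curvature_passes,
            n_bins=self.n_bins,
            divergence_threshold=self.divergence_threshold,
        )


@dataclass
class Target:
    """One tracked root cross-section with its lifecycle metadata."""

    target_id: int
    plant_id: int
    field: LevelSetField
    model: AppearanceModel
    status: str = "active"  # active | terminated | merged
    birth_slice: int = 0
    parent_target: int | None = None
    seed_point: tuple[int, int, int] | None = None
    reject_streak: int = 0

    @property
    def active(self) -> bool:
        return self.status == "active"


@dataclass
class TrackerState:
    """Mutable state of one tracking run."""

    stack: ImageStack
    params: TrackParams
    targets: list[Target]
    registry: ShapeRegistry
    manager: CollisionManager
    volume: RootVolume
    slice_index: int = -1  # last processed slice
    pending: list[Target] = dc_field(default_factory=list)
    report: dict = dc_field(default_factory=dict)
    next_target_id: int = 1
    # per (event, target) warm-start ICP transform from the previous slice
    last_alignment: dict = dc_field(default_factory=dict)

    def active_targets(self) -> list[Target]:
        return sorted((t for t in self.targets if t.active), key=lambda t: t.target_id)


def _seed_field_and_model(
    stack: ImageStack, seed: tuple[int, int, int], target_id: int, plant_id: int,
    params: TrackParams,
) -> tuple[LevelSetField, AppearanceModel]:
    z, y, x = seed
    img = stack.slices[z].astype(np.float64)
    vr = _value_range(stack)
    fld = LevelSetField.from_disc(target_id, plant_id, img.shape, (y, x), params.seed_radius)
    seed_mean = float(img[fld.mask].mean())
    slice_bg = float(np.median(img))  # soil dominates the cross-section
    if abs(seed_mean - slice_bg) < 0.05 * (vr[1] - vr[0]):
        warnings.warn(
            f"seed {seed} of plant {plant_id}: intensity indistinguishable from "
            "the slice background — the seed may lie off-root; target created anyway",
            stacklevel=2,
        )
    model = AppearanceModel.from_region(
        img, fld.mask, n_bins=params.n_bins,
        divergence_threshold=params.divergence_threshold, value_range=vr,
    )
    return fld, model


def _value_range(stack: ImageStack) -> tuple[float, float]:
    if np.issubdtype(stack.slices.dtype, np.integer):
        info = np.iinfo(stack.slices.dtype)
        return (float(info.min), float(info.max))
    return (float(stack.slices.min()), float(stack.slices.max()))


def initialize(stack: ImageStack, seeds: SeedConfig, params: TrackParams | None = None) -> TrackerState:
    """Create one target per seed point; targets activate at their seed slice."""
    if params is None:
        params = TrackParams()
    if not seeds.entries:
        raise ValueError("seed configuration contains no plants")
    seeds.validate_against(stack)
    registry = ShapeRegistry()
    manager = CollisionManager(registry, separation_margin=params.separation_margin)
    dtype = np.uint16 if max(seeds.plant_ids) < 2**16 else np.uint32
    volume = RootVolume(
        np.zeros((stack.depth, stack.height, stack.width), dtype=dtype),
        provenance={},
    )
    state = TrackerState(stack, params, [], registry, manager, volume)
    for entry in seeds.entries:
        for pt in entry.points:
            tid = state.next_target_id
            state.next_target_id += 1
            fld, model = _seed_field_and_model(stack, pt, tid, entry.plant_id, params)
            tgt = Target(tid, entry.plant_id, fld, model, birth_slice=pt[0], seed_point=pt)
            state.pending.append(tgt)
            volume.provenance[tid] = {"plant_id": entry.plant_id, "seed": list(pt)}
    state.report = {
        "per_slice": [],
        "terminations": [],
        "merges": [],
        "splits": [],
        "clipped_predictions": 0,
        "mode": "shape_constraint_on" if params.shape_constraint else "shape_constraint_off",
    }
    return state


def _evolve_all(state: TrackerState, img: np.ndarray, fresh: set[int]) -> None:
    params = state.params
    for t in state.active_targets():
        others = [o.field for o in state.active_targets() if o.target_id != t.target_id]
        ep = params.evolve_params(max_iter=params.seed_max_iter if t.target_id in fresh else None)
        if t.target_id in fresh:
            ep.divergence_threshold = 1.0  # appearance model immature at the seed slice
            new = evolve(t.field, img, others, t.model, ep)
            if not new.empty:
                t.model.refresh(img, new.mask)
        else:
            new = evolve(t.field, img, others, t.model, ep)
        t.field = new


def _supported_interface(
    t: Target, img: np.ndarray, grad: np.ndarray, bg_level: float
) -> np.ndarray:
    """Interface points backed by an image edge.

    Inside a coalesced blob the dividing line between two fields runs through
    uniform root material and carries no intensity gradient; aligning the
    frozen shape to it would pin the prediction to the arbitrary ownership
    boundary instead of the root's physical outline. Points whose local
    gradient falls below a quarter of the object/background contrast are
    therefore excluded from the ICP target set (all points are kept when too
    few survive).
    """
    pts = interface_points(t.field)
    edges = np.linspace(*t.model.value_range, t.model.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fg_mean = float((t.model.reference_hist * centers).sum())
    contrast = abs(fg_mean - bg_level)
    h, w = img.shape
    rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
    supported = grad[rows, cols] > 0.25 * contrast
    if supported.sum() < max(10, 0.1 * len(pts)):
        return pts
    return pts[supported]


def _resolve_collisions(state: TrackerState, img: np.ndarray, z: int) -> None:
    params = state.params
    by_id = {t.target_id: t for t in state.active_targets()}
    # edge-height estimate: Sobel magnitude of the lightly smoothed slice
    smoothed = ndimage.gaussian_filter(img, 1.0)
    grad = np.hypot(ndimage.sobel(smoothed, 0), ndimage.sobel(smoothed, 1)) / 4.0
    bg_level = float(np.median(img))
    for key in sorted(state.manager.open_events):
        ev = state.manager.open_events[key]
        ta, tb = key
        a, b = by_id.get(ta), by_id.get(tb)
        if a is None or b is None or a.field.empty or b.field.empty:
            continue
        preds, states = {}, {}
        for t in (a, b):
            if state.registry.has(t.target_id):
                rec = state.registry.get(t.target_id)
                # warm-start from the previous slice of this collision: for a
                # front straddling both roots, centroid initialization would
                # bias the alignment toward the junction
                warm = state.last_alignment.get((key, t.target_id))
                tr = icp_align(rec, _supported_interface(t, img, grad, bg_level),
                               max_iter=params.icp_max_iter, tol=params.icp_tol,
                               initial=warm, trim=params.icp_trim)
                state.last_alignment[(key, t.target_id)] = tr
                pred = predicted_region(rec, tr, t.field.mask.shape)
                if pred.clipped:
                    state.report["clipped_predictions"] += 1
                preds[t.target_id] = pred.mask
                states[t.target_id] = classify_points(t.field, pred.mask)
            else:  # target born mid-collision: no pre-collision shape, no push authority
                preds[t.target_id] = np.zeros_like(t.field.mask)
                states[t.target_id] = []
        fa, fb, contested = resolve_push(
            a.field, b.field, states[ta], states[tb], preds[ta], preds[tb],
            growth_margin=params.collision_growth_margin,
        )
        a.field, b.field = fa, fb
        ev.contested_pixels[z] = max(ev.contested_pixels.get(z, 0), contested)


def _split_targets(state: TrackerState, z: int) -> None:
    collided = state.manager.collided_targets()
    for t in list(state.active_targets()):
        if t.field.empty or t.target_id in collided:
            continue
        labels, n = ndimage.label(t.field.mask, structure=_STRUCT8)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        t.field = LevelSetField(t.target_id, t.plant_id, labels == keep)
        for comp in range(1, n + 1):
            if comp == keep:
                continue
            tid = state.next_target_id
            state.next_target_id += 1
            child = Target(
                tid, t.plant_id,
                LevelSetField(tid, t.plant_id, labels == comp),
                AppearanceModel(
                    t.model.reference_hist.copy(), t.model.n_bins,
                    t.model.divergence_threshold, t.model.value_range,
                ),
                birth_slice=z, parent_target=t.target_id,
            )
            state.targets.append(child)
            state.volume.provenance[tid] = {
                "plant_id": t.plant_id, "parent_target": t.target_id, "birth_slice": z,
            }
            state.report["splits"].append({"slice": z, "parent": t.target_id, "child": tid})


def _merge_same_plant(state: TrackerState, z: int) -> None:
    changed = True
    while changed:
        changed = False
        active = state.active_targets()
        for i, t in enumerate(active):
            for u in active[i + 1:]:
                if t.plant_id != u.plant_id or t.field.empty or u.field.empty:
                    continue
                touch = (t.field.mask & u.field.mask).any() or (
                    ndimage.binary_dilation(t.field.mask, _STRUCT8) & u.field.mask
                ).any()
                if touch:
                    t.field = LevelSetField(
                        t.target_id, t.plant_id, t.field.mask | u.field.mask
                    )
                    u.status = "merged"
                    state.report["merges"].append(
                        {"slice": z, "into": t.target_id, "from": u.target_id}
                    )
                    changed = True
                    break
            if changed:
                break


def _terminate_and_record(state: TrackerState, img: np.ndarray, z: int) -> None:
    params = state.params
    collided = state.manager.collided_targets()
    for t in state.active_targets():
        if t.field.empty:
            t.status = "terminated"
            state.report["terminations"].append(
                {"slice": z, "target": t.target_id, "reason": "interior vanished"}
            )
            continue
        div = t.model.divergence(img, t.field.mask)
        t.reject_streak = t.reject_streak + 1 if div > params.divergence_threshold else 0
        if t.reject_streak >= params.term_patience:
            t.status = "terminated"
            state.report["terminations"].append(
                {"slice": z, "target": t.target_id, "reason": "appearance divergence"}
            )
            continue
        if t.target_id not in collided:
            state.registry.record(t.field, z)
            t.model.refresh(img, t.field.mask)


def step(state: TrackerState) -> TrackerState:
    """Advance the tracker by one slice (mutates and returns ``state``)."""
    z = state.slice_index + 1
    if z >= state.stack.depth:
        raise ValueError("stack exhausted")
    img = state.stack.slices[z].astype(np.float64)

    fresh: set[int] = set()
    for t in list(state.pending):
        if t.birth_slice == z:
            state.targets.append(t)
            state.pending.remove(t)
            fresh.add(t.target_id)

    _evolve_all(state, img, fresh)
    fields = [t.field for t in state.active_targets() if not t.field.empty]
    state.manager.update(fields, z)
    if state.params.shape_constraint:
        _resolve_collisions(state, img, z)
    fields = [t.field for t in state.active_targets() if not t.field.empty]
    for ev in state.manager.close_separated(fields, z):
        for tid in ev.target_pair:
            state.last_alignment.pop((ev.target_pair, tid), None)
    _split_targets(state, z)
    _merge_same_plant(state, z)
    _terminate_and_record(state, img, z)

    lab = state.volume.labels[z]
    areas = {}
    for t in state.active_targets():
        lab[t.field.mask] = t.plant_id
        areas[t.target_id] = t.field.area
    state.report["per_slice"].append(
        {"slice": z, "n_active": len(state.active_targets()), "areas": areas}
    )
    state.slice_index = z
    return state


def run(
    stack: ImageStack, seeds: SeedConfig, params: TrackParams | None = None
) -> tuple[RootVolume, dict]:
    """Track all plants through the whole stack; returns the labelled volume and report.

    Deterministic: two runs on identical inputs produce identical volumes.
    """
    state = initialize(stack, seeds, params)
    while state.slice_index < stack.depth - 1:
        step(state)
    state.report["collisions"] = [ev.to_json() for ev in state.manager.all_events]
    state.report["n_targets"] = len(state.targets)
    state.report["params"] = asdict(state.params)
    return state.volume, state.report
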