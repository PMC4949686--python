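"""Pre-collision shape records and iterative-closest-point co-registration.

While a root cross-section is tracked free of contact, the outline of its
level-set interface is recorded every slice as a 2D point set, each record
replacing the last. When two cross-sections from different plants collide,
the most recent record — captured before the collision — is frozen and reused
throughout the entire interaction: the record is rigidly aligned to the
current interface with ICP, and the rasterized aligned outline becomes the
region the shape is predicted to occupy. The shape of a root cross-section is
assumed approximately constant during the period of contact, so a rigid
(rotation + translation) alignment suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon

from .levelset import LevelSetField, extract_interface

__all__ = [
    "ShapeRecord",
    "RigidTransform",
    "ShapeRegistry",
    "record_shape",
    "icp_align",
    "predicted_region",
    "PredictedRegion",
]


@dataclass(frozen=True)
class ShapeRecord:
    """The interface outline of one target captured at one slice.

    ``contours`` keeps each closed boundary component separately (needed for
    rasterization); ``points`` is their concatenation, used by ICP. Records
    are immutable: during a collision the same frozen record serves every
    slice of the interaction.
    """

    contours: tuple[np.ndarray, ...]
    target_id: int
    slice_index_recorded: int

    def __post_init__(self) -> None:
        if self.points.shape[0] < 3:
            raise ValueError("a shape record needs at least 3 outline points")

    @property
    def points(self) -> np.ndarray:
        return np.vstack(self.contours)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class RigidTransform:
    """2D rotation + translation with the post-alignment RMS residual in pixels."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float
    n_iter: int = 0
    residual_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (2, 2):
            raise ValueError("rotation must be 2x2")
        if not np.allclose(R @ R.T, np.eye(2), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @property
    def angle_deg(self) -> float:
        R = np.asarray(self.rotation)
        return float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(2), np.zeros(2), 0.0)


def record_shape(fld: LevelSetField, slice_index: int) -> ShapeRecord:
    """Capture the current interface outline of a field as a shape record."""
    contours = extract_interface(fld)
    return ShapeRecord(tuple(c.copy() for c in contours), fld.target_id, slice_index)


class ShapeRegistry:
    """Most-recent shape record per target, with freezing during collisions.

    ``record`` replaces the stored record for a target; while a target is
    frozen (an open collision involves it) recording raises, so the
    pre-collision record survives the whole interaction.
    """

    def __init__(self) -> None:
        self._records: dict[int, ShapeRecord] = {}
        self._frozen: set[int] = set()

    def record(self, fld: LevelSetField, slice_index: int) -> ShapeRecord:
        if fld.target_id in self._frozen:
            raise RuntimeError(
                f"target {fld.target_id} is in an active collision; "
                "its pre-collision shape record is frozen"
            )
        rec = record_shape(fld, slice_index)
        self._records[fld.target_id] = rec
        return rec

    def get(self, target_id: int) -> ShapeRecord:
        if target_id not in self._records:
            raise KeyError(f"no shape record stored for target {target_id}")
        return self._records[target_id]

    def has(self, target_id: int) -> bool:
        return target_id in self._records

    def freeze(self, target_id: int) -> None:
        self._frozen.add(target_id)

    def unfreeze(self, target_id: int) -> None:
        self._frozen.discard(target_id)

    def is_frozen(self, target_id: int) -> bool:
        return target_id in self._frozen

    def adopt(self, old_target_id: int, new_target_id: int) -> None:
        """Reassign a record to a child target (used when targets split)."""
        if old_target_id in self._records:
            rec = self._records[old_target_id]
            self._records[new_target_id] = ShapeRecord(
                rec.contours, new_target_id, rec.slice_index_recorded
            )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit mapping src onto dst (reflections rejected)."""
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    H = (src - src_c).T @ (dst - dst_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    t = dst_c - R @ src_c
    return R, t


def icp_align(
    record: ShapeRecord | np.ndarray,
    current: np.ndarray,
    max_iter: int = 50,
    tol: float = 0.05,
    initial: RigidTransform | None = None,
    trim: float | None = None,
) -> RigidTransform:
    """Align a recorded outline to the current interface with ICP.

    Alternates nearest-neighbour correspondence (KD-tree) with the
    closed-form least-squares rigid fit. Initialization matches the two
    centroids unless ``initial`` supplies a warm-start transform (e.g. the
    alignment found on the previous slice of an ongoing collision). With
    ``trim`` set, correspondences farther than that many pixels are excluded
    from the fit (provided enough survive), so an unrelated nearby boundary
    cannot drag the alignment off its own object. The RMS nearest-neighbour
    residual over all points is non-increasing across iterations in the
    untrimmed case; iteration stops when it improves by less than ``tol``
    pixels or after ``max_iter`` rounds, and the best transform seen is
    returned.
    """
    src = record.points if isinstance(record, ShapeRecord) else np.asarray(record, dtype=np.float64)
    dst = np.asarray(current, dtype=np.float64)
    if src.shape[0] < 3 or dst.shape[0] < 3:
        raise ValueError("ICP needs at least 3 points in each set")
    for pts, name in ((src, "record"), (dst, "current")):
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise ValueError(f"{name} point set is degenerate (collinear)")

    tree = cKDTree(dst)
    if initial is not None:
        R = np.asarray(initial.rotation, dtype=np.float64)
        t = np.asarray(initial.translation, dtype=np.float64)
    else:
        R = np.eye(2)
        t = dst.mean(axis=0) - src.mean(axis=0)
    def _residual_and_matches(R, t):
        moved = src @ R.T + t
        dists, idx = tree.query(moved)
        keep = np.ones(len(src), dtype=bool)
        if trim is not None:
            sel = dists <= trim
            if sel.sum() >= max(3, 0.2 * len(src)):
                keep = sel
        rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
        return rms, idx, keep

    history: list[float] = []
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    prev = np.inf
    for _ in range(max_iter + 1):
        rms, idx, keep = _residual_and_matches(R, t)
        history.append(rms)
        if best is None or rms < best[0]:
            best = (rms, R.copy(), np.array(t, dtype=np.float64))
        if prev - rms < tol:
            break
        prev = rms
        R, t = _kabsch(src[keep], dst[idx[keep]])
    residual, R_best, t_best = best
    return RigidTransform(R_best, t_best, residual,
                          n_iter=len(history) - 1,
                          residual_history=tuple(history))


class PredictedRegion(NamedTuple):
    mask: np.ndarray
    clipped: bool


def predicted_region(
    record: ShapeRecord,
    transform: RigidTransform,
    frame_shape: tuple[int, int],
) -> PredictedRegion:
    """Rasterize the transformed outline: the region the shape predicts it occupies.

    A transform carrying the outline outside the frame is clipped to the
    frame and flagged, so the run report can note the truncation.
    """
    mask = np.zeros(frame_shape, dtype=bool)
    clipped = False
    for contour in record.contours:
        pts = transform.apply(contour)
        if (
            pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5
            or pts[:, 0].max() > frame_shape[0] - 0.5
            or pts[:, 1].max() > frame_shape[1] - 0.5
        ):
            clipped = True
        rr, cc = polygon(pts[:, 0], pts[:, 1], shape=frame_shape)
        mask[rr, cc] = True
    return PredictedRegion(mask, clipped)
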