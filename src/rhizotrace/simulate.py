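"""Synthetic interacting-root phantoms with per-slice ground truth.

Root cross-sections are modelled as constant-radius discs performing a random
walk down the stack: each disc moves a fixed step between consecutive slices,
with its heading perturbed by a uniform draw within +/- max_turn degrees, and
is reflected specularly off the frame walls so it stays fully inside the
scene. The limited frame makes the discs interact repeatedly, which is the
point: the phantoms exercise identity maintenance under coalescence while the
true per-pixel root identity is known exactly.

Defaults match the study conditions this generator emulates: 2 discs of
radius 20 px stepping 6 px per slice with heading changes within +/-16 deg,
in a 320x320 px frame over 500 slices, 12 independent stacks per suite.
Rendering intensities (background 50, foreground 200, Gaussian noise sd 10 on
an 8-bit scale) are this package's choice, made so the appearance model is
exercised non-trivially; ground-truth label maps are aligned with the
pre-noise rendering. Pixels covered by several discs are labelled with the
root whose centre is nearer (ties to the lower root index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .volume_io import ImageStack, SeedConfig, SeedEntry

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_stack",
    "simulate_suite",
    "iter_suite",
    "seeds_from_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Phantom-generator parameters (pixel units, degrees)."""

    n_roots: int = 2
    radius: float = 20.0
    step: float = 6.0
    max_turn: float = 16.0
    frame: tuple[int, int] = (320, 320)
    n_slices: int = 500
    n_stacks: int = 12
    rng_seed: int = 0
    fg_intensity: float = 200.0
    bg_intensity: float = 50.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.step < 0:
            raise ValueError("step must be non-negative")
        if not (0 <= self.max_turn <= 180):
            raise ValueError("max_turn must be in [0, 180] degrees")
        if min(self.frame) <= 2 * self.radius + 1:
            raise ValueError("frame too small to contain a disc")
        if self.n_slices < 1 or self.n_roots < 1 or self.n_stacks < 1:
            raise ValueError("n_slices, n_roots and n_stacks must be >= 1")


@dataclass
class GroundTruth:
    """Per-slice truth for one simulated stack.

    ``labels`` holds the root index (1-based) per pixel, 0 = background;
    ``centres`` is (n_slices, n_roots, 2) float (row, col); ``headings`` the
    per-slice heading in degrees (after any wall reflection); ``turns`` the
    raw per-slice heading perturbation draws in degrees (slice 0 is zero);
    ``interaction_log`` lists contact episodes as
    (start_slice, end_slice, (root_i, root_j)) with inclusive ends.
    """

    labels: np.ndarray
    centres: np.ndarray
    headings: np.ndarray
    turns: np.ndarray
    interaction_log: list[tuple[int, int, tuple[int, int]]]
    config: SimConfig
    seed: int

    @property
    def n_roots(self) -> int:
        return self.centres.shape[1]

    def contact_slices(self, margin: int = 0) -> np.ndarray:
        """Boolean per-slice flag: any pair of roots in contact (optionally dilated)."""
        flags = np.zeros(self.labels.shape[0], dtype=bool)
        for (s, e, _pair) in self.interaction_log:
            lo = max(0, s - margin)
            hi = min(len(flags) - 1, e + margin)
            flags[lo: hi + 1] = True
        return flags


def _reflect_step(
    pos: np.ndarray, heading: float, step: float, lo: float, hi_r: float, hi_c: float
) -> tuple[np.ndarray, float]:
    """Advance one full step, specularly reflecting the heading off the walls.

    The heading component driving the wall violation is flipped *before*
    moving, so consecutive centres are always exactly ``step`` apart.
    """
    for _ in range(4):  # at most two flips (corner) ever needed
        dr = step * np.sin(np.radians(heading))
        dc = step * np.cos(np.radians(heading))
        nr, nc = pos[0] + dr, pos[1] + dc
        if nr < lo or nr > hi_r:
            heading = -heading
            continue
        if nc < lo or nc > hi_c:
            heading = 180.0 - heading
            continue
        return np.array([nr, nc]), ((heading + 180.0) % 360.0) - 180.0
    raise RuntimeError("reflection failed; frame too small for step")  # pragma: no cover


def _render(centres: np.ndarray, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one slice: (pre-noise foreground mask is labels > 0)."""
    h, w = config.frame
    yy, xx = np.mgrid[0:h, 0:w]
    label = np.zeros((h, w), dtype=np.uint8)
    best_d2 = np.full((h, w), np.inf)
    r2 = config.radius**2
    for i, (cy, cx) in enumerate(centres, start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= r2
        closer = inside & (d2 < best_d2)
        label[closer] = i
        best_d2[closer] = d2[closer]
    return label, best_d2


def _contact(centres: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Pairs of discs overlapping or 8-adjacent (boundary gap <= sqrt(2) px)."""
    pairs = []
    n = centres.shape[0]
    thresh = 2 * radius + np.sqrt(2.0)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centres[i] - centres[j]) <= thresh:
                pairs.append((i + 1, j + 1))
    return pairs


def simulate_stack(config: SimConfig | None = None, seed: int | None = None) -> tuple[ImageStack, GroundTruth]:
    """Generate one greyscale phantom stack with aligned ground truth.

    Deterministic given the seed (``config.rng_seed`` unless overridden).
    Initial centres are uniform with pairwise distance > 2 * radius and at
    least ``radius`` from every wall; initial headings uniform in [0, 360).
    """
    if config is None:
        config = SimConfig()
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    h, w = config.frame
    lo = config.radius
    hi_r, hi_c = h - 1 - config.radius, w - 1 - config.radius

    # initial placement: rejection-sample non-touching discs
    centres0 = []
    for _ in range(10000):
        cand = np.array([rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)])
        if all(np.linalg.norm(cand - c) > 2 * config.radius for c in centres0):
            centres0.append(cand)
        if len(centres0) == config.n_roots:
            break
    else:
        raise ValueError("could not place non-overlapping initial discs")
    headings = rng.uniform(0.0, 360.0, size=config.n_roots)

    centres = np.empty((config.n_slices, config.n_roots, 2))
    all_headings = np.empty((config.n_slices, config.n_roots))
    turns = np.zeros((config.n_slices, config.n_roots))
    centres[0] = np.array(centres0)
    all_headings[0] = headings
    for z in range(1, config.n_slices):
        for i in range(config.n_roots):
            turn = rng.uniform(-config.max_turn, config.max_turn)
            turns[z, i] = turn
            heading = all_headings[z - 1, i] + turn
            pos, heading = _reflect_step(
                centres[z - 1, i], heading, config.step, lo, hi_r, hi_c
            )
            centres[z, i] = pos
            all_headings[z, i] = heading

    labels = np.empty((config.n_slices, h, w), dtype=np.uint8)
    images = np.empty((config.n_slices, h, w), dtype=np.uint8)
    for z in range(config.n_slices):
        lab, _ = _render(centres[z], config)
        labels[z] = lab
        img = np.where(lab > 0, config.fg_intensity, config.bg_intensity)
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        images[z] = np.clip(img, 0, 255).astype(np.uint8)

    # contact episodes from centre geometry
    log: list[tuple[int, int, tuple[int, int]]] = []
    open_ev: dict[tuple[int, int], int] = {}
    for z in range(config.n_slices):
        pairs = set(_contact(centres[z], config.radius))
        for pair in pairs:
            open_ev.setdefault(pair, z)
        for pair in list(open_ev):
            if pair not in pairs:
                log.append((open_ev.pop(pair), z - 1, pair))
    for pair, start in open_ev.items():
        log.append((start, config.n_slices - 1, pair))
    log.sort()

    truth = GroundTruth(labels, centres, all_headings, turns, log, config, seed)
    return ImageStack(images), truth


def iter_suite(config: SimConfig | None = None) -> Iterator[tuple[ImageStack, GroundTruth]]:
    """Lazily generate the suite's independent stacks (seed + stack index streams)."""
    if config is None:
        config = SimConfig()
    children = np.random.SeedSequence(config.rng_seed).spawn(config.n_stacks)
    for child in children:
        stack_seed = int(child.generate_state(1)[0] % (2**31))
        yield simulate_stack(config, seed=stack_seed)


def simulate_suite(config: SimConfig | None = None) -> list[tuple[ImageStack, GroundTruth]]:
    """All ``config.n_stacks`` independent stacks as a list (see :func:`iter_suite`)."""
    return list(iter_suite(config))


def seeds_from_truth(truth: GroundTruth) -> SeedConfig:
    """One plant per simulated root, seeded at its slice-0 centre."""
    entries = []
    for i in range(truth.n_roots):
        cy, cx = truth.centres[0, i]
        entries.append(SeedEntry(i + 1, ((0, int(round(cy)), int(round(cx))),)))
    return SeedConfig(entries)
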