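"""Border-unit feed-forward input from position and environment geometry.

The band within 12 cm of each of the four allocentric walls is split into 8
"bricks" per wall, each covering 12.5% of the environment extent along that
wall.  The 32 bricks are ordered clockwise around the perimeter starting at
the south-west corner of the west wall:

    bricks  0-7   west wall,  south -> north
    bricks  8-15  north wall, west -> east
    bricks 16-23  east wall,  north -> south
    bricks 24-31  south wall, east -> west

Border unit ``j`` fires (uniform input 0.1) whenever the rat occupies any of
the four consecutive bricks ``{j, j+1, j+2, j+3} mod 32``, so each unit's
field covers half of one wall's length, with some fields wrapping a corner.
Brick edges are recomputed from the current geometry, so deforming a wall
rescales its bricks proportionally and displacing a wall displaces them.

Inserted walls contribute additional brick surfaces on both faces: a face
seen to the east of the rat behaves as an east boundary, with brick edges at
the same along-wall positions as the corresponding outer-wall bricks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import E, N, S, W, EnvironmentGeometry

N_BRICKS = 32
N_UNITS = 32
BRICKS_PER_WALL = 8
SPAN = 4  # consecutive bricks per unit
BORDER_DEPTH_CM = 12.0
BORDER_INPUT = 0.1

_WALL_OF_BRICK = np.repeat([W, N, E, S], BRICKS_PER_WALL)


@dataclass(frozen=True)
class _BrickSurface:
    """One rectangular-ish brick region attached to a wall face."""

    brick_id: int
    direction: int
    along_lo: float  # interval along the wall's own axis, cm
    along_hi: float
    # For outer walls the face coordinate is implied by direction; for
    # inserted walls it is the wall's own position and `side` selects the face.
    face_pos: float | None = None  # None => outer wall
    face_extent: tuple[float, float] | None = None  # clip of the wall segment
    side: int = 0  # -1: active region below/west of face; +1: above/east

    def length(self) -> float:
        lo, hi = self.along_lo, self.along_hi
        if self.face_extent is not None:
            lo = max(lo, self.face_extent[0])
            hi = min(hi, self.face_extent[1])
        return max(hi - lo, 0.0)


class BrickPartition:
    """The labelled brick set for a given environment geometry."""

    def __init__(self, env: EnvironmentGeometry, depth_cm: float = BORDER_DEPTH_CM):
        self.env = env
        self.depth_cm = depth_cm
        self.surfaces: list[_BrickSurface] = []
        self._build()

    # ---------------------------------------------------------------- build

    def _wall_length(self, direction: int) -> float:
        env = self.env
        if env.is_track:
            return env.width_cm if direction in (N, S) else 0.0
        for seg in env.outer_walls():
            if seg.direction == direction:
                return seg.length
        raise KeyError(direction)

    def _build(self) -> None:
        env = self.env
        if env.is_track:
            # end regions only: 8 degenerate bricks per end sharing the full band
            for k in range(BRICKS_PER_WALL):
                self.surfaces.append(_BrickSurface(16 + k, E, 0.0, 0.0))
                self.surfaces.append(_BrickSurface(0 + k, W, 0.0, 0.0))
            return
        for direction in (W, N, E, S):
            L = self._wall_length(direction)
            for k in range(BRICKS_PER_WALL):
                lo, hi = self._brick_interval(direction, k, L)
                self.surfaces.append(
                    _BrickSurface(self._brick_id(direction, k), direction, lo, hi)
                )
        for (a, b) in env.inserted_walls:
            self._add_inserted(a, b)

    @staticmethod
    def _brick_id(direction: int, k: int) -> int:
        base = {W: 0, N: 8, E: 16, S: 24}[direction]
        return base + k

    def _brick_interval(self, direction: int, k: int, L: float):
        """Along-wall interval of brick k in the clockwise ordering, in the
        wall's own coordinate (y for W/E walls, x for N/S walls)."""
        f0, f1 = k / 8.0, (k + 1) / 8.0
        if direction in (W, N):  # W: south->north in y; N: west->east in x
            return f0 * L, f1 * L
        # E: north->south; S: east->west  => reversed coordinate
        return (1.0 - f1) * L, (1.0 - f0) * L

    def _add_inserted(self, a, b) -> None:
        horizontal = abs(b[1] - a[1]) <= abs(b[0] - a[0])
        lo_ext = min(a[0], b[0]) if horizontal else min(a[1], b[1])
        hi_ext = max(a[0], b[0]) if horizontal else max(a[1], b[1])
        pos = (a[1] + b[1]) / 2.0 if horizontal else (a[0] + b[0]) / 2.0
        if horizontal:
            # face below acts as a north boundary, face above as a south one
            pairs = [(N, -1), (S, +1)]
        else:
            # face west of the wall acts as an east boundary, east face as west
            pairs = [(E, -1), (W, +1)]
        for direction, side in pairs:
            L = self._wall_length(direction)
            for k in range(BRICKS_PER_WALL):
                lo, hi = self._brick_interval(direction, k, L)
                if min(hi, hi_ext) <= max(lo, lo_ext):
                    continue  # brick interval does not overlap the wall extent
                self.surfaces.append(
                    _BrickSurface(
                        self._brick_id(direction, k),
                        direction,
                        lo,
                        hi,
                        face_pos=pos,
                        face_extent=(lo_ext, hi_ext),
                        side=side,
                    )
                )

    # ------------------------------------------------------------- membership

    def brick_membership(self, xy: np.ndarray) -> np.ndarray:
        """(n, 32) boolean matrix: point in any surface of brick b."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        out = np.zeros((len(x), N_BRICKS), dtype=bool)
        env = self.env
        depth = self.depth_cm
        if env.is_track:
            for s in self.surfaces:
                if s.direction == E:
                    out[:, s.brick_id] |= x >= env.width_cm - depth
                else:
                    out[:, s.brick_id] |= x <= depth
            return out
        dists = env.wall_distances(xy)
        for s in self.surfaces:
            along = y if s.direction in (W, E) else x
            if s.face_pos is None:
                if s.direction == E and env.kind == "right_trapezoid":
                    # along-coordinate measured on the slanted wall's own axis
                    along = self._slant_param(xy)
                in_depth = dists[:, s.direction] <= depth
                mask = in_depth & (along >= s.along_lo) & (along < s.along_hi + 1e-9)
            else:
                perp = x if s.direction in (W, E) else y
                lo_e, hi_e = s.face_extent
                d = s.face_pos - perp if s.side == -1 else perp - s.face_pos
                mask = (
                    (d > 0)
                    & (d <= depth)
                    & (along >= max(s.along_lo, lo_e))
                    & (along < min(s.along_hi, hi_e) + 1e-9)
                )
            out[:, s.brick_id] |= mask
        return out

    def _slant_param(self, xy: np.ndarray) -> np.ndarray:
        """Arc-length coordinate along the slanted east wall, 0 at its north end."""
        env = self.env
        a = np.array([env.trapezoid_short_wall_cm, env.height_cm])  # north end
        b = np.array([env.width_cm, 0.0])  # south end
        ab = b - a
        L = float(np.hypot(*ab))
        t = ((xy - a) @ ab) / L  # arc length from north end
        # reversed ordering (N->S) is already encoded in the brick intervals,
        # which use the W/E convention south->north; flip to match
        return L - t

    def unit_input(self, xy: np.ndarray, amplitude: float = BORDER_INPUT) -> np.ndarray:
        """(n, 32) border-unit feed-forward input: amplitude where the point
        lies in any brick of the unit's 4-brick span, else 0."""
        bricks = self.brick_membership(xy)
        active = np.zeros_like(bricks)
        for j in range(N_UNITS):
            span = [(j + k) % N_BRICKS for k in range(SPAN)]
            active[:, j] = bricks[:, span].any(axis=1)
        return active.astype(float) * amplitude


def brick_partition(env: EnvironmentGeometry, depth_cm: float = BORDER_DEPTH_CM) -> BrickPartition:
    """Construct the 32-brick perimeter partition for the environment."""
    return BrickPartition(env, depth_cm=depth_cm)


def border_input(
    env_or_partition, point, amplitude: float = BORDER_INPUT
) -> np.ndarray:
    """32-vector (or (n, 32) matrix) of border-unit inputs at the point(s)."""
    part = (
        env_or_partition
        if isinstance(env_or_partition, BrickPartition)
        else BrickPartition(env_or_partition)
    )
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    if not part.env.contains(pt).all():
        raise ValueError("point outside the environment")
    out = part.unit_input(pt, amplitude=amplitude)
    return out[0] if np.asarray(point).ndim == 1 else out


def border_field_coverage(env: EnvironmentGeometry, unit_id: int) -> float:
    """Fraction of one wall's length covered by the unit's active band.

    The unit's four bricks each cover 12.5% of their own wall, so for a
    square arena every unit returns exactly 0.5.
    """
    if not 0 <= unit_id < N_UNITS:
        raise ValueError("unit_id out of range")
    part = BrickPartition(env)
    span = {(unit_id + k) % N_BRICKS for k in range(SPAN)}
    arc = sum(
        s.length() for s in part.surfaces if s.brick_id in span and s.face_pos is None
    )
    # normalize by the wall holding the majority of the span
    walls = [_WALL_OF_BRICK[b] for b in span]
    major = max(set(walls), key=walls.count)
    wall_len = part._wall_length(major)
    return arc / wall_len
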