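"""Environment geometry, synthetic trajectories and boundary-contact labelling.

Coordinates are continuous centimetres with the origin at the south-west
corner; x increases eastward, y northward. Rate-map pixels are half-open
``[k*pixel, (k+1)*pixel)`` squares (default 2.5 cm) indexed ``[row, col]``
with row 0 at the south edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# Allocentric wall codes used throughout the package.  The order fixes the
# deterministic priority used to break exact corner ties.
WALL_LABELS = ("N", "S", "E", "W")
LABEL_NONE = -1
N, S, E, W = 0, 1, 2, 3

_OPPOSITE = {N: S, S: N, E: W, W: E}


def opposite_wall(wall: int) -> int:
    """Return the wall code of the opposing boundary."""
    return _OPPOSITE[wall]


@dataclass(frozen=True)
class WallSegment:
    """A straight wall piece with an allocentric direction label.

    ``direction`` is the direction of travel the wall blocks: the north wall
    bounds northward travel.  Inserted (internal) walls carry two labelled
    faces and are represented by two ``WallSegment`` instances sharing
    geometry, one per face.
    """

    direction: int
    p0: tuple[float, float]
    p1: tuple[float, float]
    outer: bool = True
    # For inserted walls: +1 if the blocked region is on the side where the
    # inward normal points, used by border bricks.  Unused for outer walls.
    face_sign: int = 0

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])


@dataclass(frozen=True)
class EnvironmentGeometry:
    """Polygonal arena: rectangle, right trapezoid or linear track.

    The right trapezoid has parallel north/south walls: the south wall has
    length ``width_cm``, the north wall ``trapezoid_short_wall_cm``; the west
    wall is vertical and the east wall slants between the two.  The linear
    track is one-dimensional (y == 0 everywhere) with east/west end walls.
    """

    kind: str
    width_cm: float
    height_cm: float = 0.0
    trapezoid_short_wall_cm: float | None = None
    inserted_walls: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = ()
    pixel_cm: float = 2.5

    def __post_init__(self):
        if self.kind not in ("rectangle", "right_trapezoid", "linear_track"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.width_cm <= 0:
            raise ValueError("width_cm must be positive")
        if self.kind != "linear_track" and self.height_cm <= 0:
            raise ValueError("height_cm must be positive")
        if self.kind == "right_trapezoid":
            if self.trapezoid_short_wall_cm is None:
                raise ValueError("right_trapezoid requires trapezoid_short_wall_cm")
            if not 0 < self.trapezoid_short_wall_cm < self.width_cm:
                raise ValueError("trapezoid short wall must be shorter than width_cm")
        for (x0, y0), (x1, y1) in self.inserted_walls:
            mid = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
            for p in ((x0, y0), (x1, y1), mid):
                if not self._contains_scalar(p[0], p[1], tol=1e-9):
                    raise ValueError(f"inserted wall endpoint {p} outside arena")

    # ------------------------------------------------------------------ shape

    @property
    def is_track(self) -> bool:
        return self.kind == "linear_track"

    def _east_x_at(self, y):
        """x-coordinate of the east boundary at height y (slanted for trapezoids)."""
        if self.kind == "right_trapezoid":
            frac = np.asarray(y) / self.height_cm
            return self.width_cm + frac * (self.trapezoid_short_wall_cm - self.width_cm)
        return self.width_cm

    def _contains_scalar(self, x: float, y: float, tol: float = 0.0) -> bool:
        if self.is_track:
            return -tol <= x <= self.width_cm + tol and abs(y) <= tol + 1e-9
        if not (-tol <= y <= self.height_cm + tol):
            return False
        return -tol <= x <= float(self._east_x_at(min(max(y, 0.0), self.height_cm))) + tol

    def contains(self, xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Vectorized point-in-environment test for an (n, 2) array."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        if self.is_track:
            return (x >= -tol) & (x <= self.width_cm + tol) & (np.abs(y) <= tol)
        ok = (y >= -tol) & (y <= self.height_cm + tol) & (x >= -tol)
        ex = self._east_x_at(np.clip(y, 0.0, self.height_cm))
        return ok & (x <= ex + tol)

    def center(self) -> tuple[float, float]:
        if self.is_track:
            return (self.width_cm / 2.0, 0.0)
        if self.kind == "right_trapezoid":
            # centroid of the trapezoid
            a, b, h = self.width_cm, self.trapezoid_short_wall_cm, self.height_cm
            cy = h * (2 * b + a) / (3 * (a + b))
            cx = float(self._east_x_at(cy)) / 2.0
            return (cx, cy)
        return (self.width_cm / 2.0, self.height_cm / 2.0)

    # ------------------------------------------------------------------ walls

    def outer_walls(self) -> list[WallSegment]:
        w, h = self.width_cm, self.height_cm
        if self.is_track:
            return [
                WallSegment(E, (w, 0.0), (w, 0.0)),
                WallSegment(W, (0.0, 0.0), (0.0, 0.0)),
            ]
        if self.kind == "right_trapezoid":
            s = self.trapezoid_short_wall_cm
            return [
                WallSegment(N, (0.0, h), (s, h)),
                WallSegment(S, (0.0, 0.0), (w, 0.0)),
                WallSegment(E, (w, 0.0), (s, h)),  # slanted, bounds eastward travel
                WallSegment(W, (0.0, 0.0), (0.0, h)),
            ]
        return [
            WallSegment(N, (0.0, h), (w, h)),
            WallSegment(S, (0.0, 0.0), (w, 0.0)),
            WallSegment(E, (w, 0.0), (w, h)),
            WallSegment(W, (0.0, 0.0), (0.0, h)),
        ]

    def wall_distances(self, xy: np.ndarray) -> np.ndarray:
        """Perpendicular distance from each point to each outer wall.

        Returns an (n, 4) array ordered N, S, E, W.  For the trapezoid the
        east distance is measured perpendicular to the slanted segment.  For
        the linear track the north/south columns are +inf.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        out = np.full((len(x), 4), np.inf)
        if self.is_track:
            out[:, E] = self.width_cm - x
            out[:, W] = x
            return np.abs(out, out=out, where=np.isfinite(out))
        out[:, N] = self.height_cm - y
        out[:, S] = y
        out[:, W] = x
        if self.kind == "right_trapezoid":
            # signed distance to the slant line through (width, 0) -> (short, height)
            dx = self.trapezoid_short_wall_cm - self.width_cm
            dy = self.height_cm
            nrm = math.hypot(dx, dy)
            # inward normal points away from the wall; distance is positive inside
            out[:, E] = ((self.width_cm - x) * dy + y * dx) / nrm
        else:
            out[:, E] = self.width_cm - x
        return np.abs(out)

    def segment_blocked(self, p0, p1) -> bool:
        """True if the step from p0 to p1 crosses an inserted wall."""
        for (a, b) in self.inserted_walls:
            if _segments_intersect(p0, p1, a, b):
                return True
        return False

    # ----------------------------------------------------------------- raster

    @property
    def raster_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the pixel raster covering the bounding box."""
        ncol = int(math.ceil(self.width_cm / self.pixel_cm - 1e-9))
        if self.is_track:
            return (1, ncol)
        nrow = int(math.ceil(self.height_cm / self.pixel_cm - 1e-9))
        return (nrow, ncol)

    def pixel_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) pixel indices, clipped to the raster."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        nrow, ncol = self.raster_shape
        col = np.clip((xy[:, 0] / self.pixel_cm).astype(int), 0, ncol - 1)
        if self.is_track:
            row = np.zeros(len(col), dtype=int)
        else:
            row = np.clip((xy[:, 1] / self.pixel_cm).astype(int), 0, nrow - 1)
        return row, col

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "pixel_cm": self.pixel_cm,
        }
        if self.trapezoid_short_wall_cm is not None:
            d["trapezoid_short_wall_cm"] = self.trapezoid_short_wall_cm
        if self.inserted_walls:
            d["inserted_walls"] = [
                [[float(v) for v in p] for p in seg] for seg in self.inserted_walls
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentGeometry":
        allowed = {
            "kind", "width_cm", "height_cm", "trapezoid_short_wall_cm",
            "inserted_walls", "pixel_cm",
        }
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown environment keys: {sorted(unknown)}")
        d = dict(d)
        if "inserted_walls" in d:
            d["inserted_walls"] = tuple(
                (tuple(seg[0]), tuple(seg[1])) for seg in d["inserted_walls"]
            )
        return cls(**d)


def make_environment(
    kind: str = "rectangle",
    width_cm: float = 150.0,
    height_cm: float = 150.0,
    trapezoid_short_wall_cm: float | None = None,
    inserted_walls=(),
    pixel_cm: float = 2.5,
) -> EnvironmentGeometry:
    """Build a labelled environment geometry.

    ``rectangle``: ``width_cm`` east-west by ``height_cm`` north-south.
    ``right_trapezoid``: south wall ``width_cm`` long, north wall
    ``trapezoid_short_wall_cm``, separated by ``height_cm``; east wall slants.
    ``linear_track``: ``width_cm`` long, y fixed at 0.
    """
    return EnvironmentGeometry(
        kind=kind,
        width_cm=width_cm,
        height_cm=height_cm if kind != "linear_track" else 0.0,
        trapezoid_short_wall_cm=trapezoid_short_wall_cm,
        inserted_walls=tuple((tuple(a), tuple(b)) for a, b in inserted_walls),
        pixel_cm=pixel_cm,
    )


def _segments_intersect(p, q, a, b) -> bool:
    def orient(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    d1 = orient(a, b, p)
    d2 = orient(a, b, q)
    d3 = orient(p, q, a)
    d4 = orient(p, q, b)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    return False


# ============================================================== trajectories


@dataclass
class Trajectory:
    """Time-stamped positions at a fixed timestep with derived kinematics."""

    times_s: np.ndarray
    positions_cm: np.ndarray  # (n, 2)
    dt_s: float

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def displacements_cm(self) -> np.ndarray:
        """Per-sample displacement vector of the step that arrived here (first = 0)."""
        d = np.zeros_like(self.positions_cm)
        d[1:] = np.diff(self.positions_cm, axis=0)
        return d

    @property
    def speeds_cm_per_s(self) -> np.ndarray:
        return np.hypot(*self.displacements_cm.T) / self.dt_s

    @property
    def headings_deg(self) -> np.ndarray:
        d = self.displacements_cm
        h = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        return np.mod(h, 360.0)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times_s, "x": self.positions_cm[:, 0], "y": self.positions_cm[:, 1]}
        )

    def save_csv(self, path) -> None:
        self.to_table().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("t", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"trajectory table missing column {col!r}")
        t = df["t"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.003
        return cls(times_s=t, positions_cm=df[["x", "y"]].to_numpy(float), dt_s=dt)


SPEED_MAX_CM_PER_S = 40.0


def random_walk(
    env: EnvironmentGeometry,
    duration_s: float,
    dt_s: float = 0.003,
    seed=None,
    sigma_speed_cm_per_ms: float = 0.001,
    sigma_heading_deg_per_ms: float = 1.5,
    noise_per: str = "step",
    max_redraws: int = 1000,
) -> Trajectory:
    """Bounded random walk starting stationary at the arena centre.

    Gaussian increments are applied to speed and heading each timestep; speed
    is clipped to [0, 40] cm/s.  A step that would leave the arena or cross an
    inserted wall has fresh heading noise added (up to ``max_redraws`` times,
    then the heading is reflected).

    ``noise_per`` selects how the per-millisecond sigmas map onto the 3 ms
    timestep: ``"step"`` draws one increment per step with sigma scaled
    linearly by dt in ms; ``"ms"`` treats each millisecond as an independent
    increment (sigma scaled by sqrt(dt in ms)).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    ms = dt_s * 1000.0
    if noise_per == "step":
        sig_speed = sigma_speed_cm_per_ms * 1000.0  # cm/s per step
        sig_head = sigma_heading_deg_per_ms * ms
    elif noise_per == "ms":
        sig_speed = sigma_speed_cm_per_ms * 1000.0 * math.sqrt(ms) / ms
        sig_head = sigma_heading_deg_per_ms * math.sqrt(ms)
    else:
        raise ValueError("noise_per must be 'step' or 'ms'")

    n = int(round(duration_s / dt_s)) + 1
    xs = np.empty(n)
    ys = np.empty(n)
    x, y = env.center()
    xs[0], ys[0] = x, y
    speed = 0.0
    heading = rng.uniform(0.0, 360.0)
    has_inserted = bool(env.inserted_walls)
    track = env.is_track

    speed_noise = rng.normal(0.0, sig_speed, size=n - 1)
    head_noise = rng.normal(0.0, sig_head, size=n - 1)

    # analytic fast-path bounds for rectangles
    rect = env.kind == "rectangle"
    w, h = env.width_cm, env.height_cm

    for k in range(n - 1):
        speed = min(max(speed + speed_noise[k], 0.0), SPEED_MAX_CM_PER_S)
        heading += head_noise[k]
        d = speed * dt_s
        ok = False
        for _ in range(max_redraws):
            rad = math.radians(heading)
            nx_ = x + d * math.cos(rad)
            ny_ = 0.0 if track else y + d * math.sin(rad)
            if rect:
                ok = 0.0 <= nx_ <= w and 0.0 <= ny_ <= h
            else:
                ok = env._contains_scalar(nx_, ny_, tol=1e-9)
            if ok and has_inserted and env.segment_blocked((x, y), (nx_, ny_)):
                ok = False
            if ok:
                break
            heading += rng.normal(0.0, sig_head)
        if not ok:
            heading += 180.0
            nx_, ny_ = x, y  # stay put this step
        x, y = nx_, ny_
        xs[k + 1], ys[k + 1] = x, y

    times = np.arange(n) * dt_s
    return Trajectory(times_s=times, positions_cm=np.column_stack([xs, ys]), dt_s=dt_s)


def track_laps(
    length_cm: float,
    duration_s: float,
    speed_cm_per_s: float = 20.0,
    dt_s: float = 0.003,
) -> Trajectory:
    """End-to-end laps on a linear track at exactly the given speed.

    The path starts at the west end heading east and reflects at each end;
    positions fold into [0, length].  Every inter-sample displacement equals
    ``speed * dt``, except at the (rare) reversal samples where the distance
    travelled is split across the fold and the net displacement is smaller.
    """
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    n = int(round(duration_s / dt_s)) + 1
    s = np.arange(n) * (speed_cm_per_s * dt_s)
    period = 2.0 * length_cm
    s = np.mod(s, period)
    x = np.where(s <= length_cm, s, period - s)
    times = np.arange(n) * dt_s
    return Trajectory(
        times_s=times, positions_cm=np.column_stack([x, np.zeros(n)]), dt_s=dt_s
    )


# ===================================================== boundary-contact labels


@dataclass
class BoundaryContactLabels:
    """Per-sample most-recently-contacted boundary (codes N,S,E,W or -1 none)."""

    labels: np.ndarray
    threshold_cm: float = 12.0

    def __len__(self) -> int:
        return len(self.labels)


def label_boundary_contacts(
    traj: Trajectory,
    env: EnvironmentGeometry,
    threshold_cm: float = 12.0,
    include_inserted: bool = False,
) -> BoundaryContactLabels:
    """Label each sample with the boundary most recently approached within
    ``threshold_cm``.

    Samples before the first contact are labelled -1.  When several walls are
    inside the threshold the nearest wins; on an exact distance tie the wall
    contacted first is kept, and on simultaneous entry the fixed N,S,E,W
    priority applies.  By default only outer walls count as boundaries;
    ``include_inserted`` adds inserted-wall faces (labelled by the direction
    of travel each face blocks).
    """
    xy = traj.positions_cm
    dists = env.wall_distances(xy)  # (n, 4)
    if include_inserted and env.inserted_walls:
        for (a, b) in env.inserted_walls:
            d = _point_segment_distance(xy, a, b)
            horizontal = abs(b[1] - a[1]) <= abs(b[0] - a[0])
            if horizontal:
                yw = (a[1] + b[1]) / 2.0
                below = xy[:, 1] < yw  # wall is north of these points
                dists[:, N] = np.where(below, np.minimum(dists[:, N], d), dists[:, N])
                dists[:, S] = np.where(~below, np.minimum(dists[:, S], d), dists[:, S])
            else:
                xw = (a[0] + b[0]) / 2.0
                west = xy[:, 0] < xw  # wall is east of these points
                dists[:, E] = np.where(west, np.minimum(dists[:, E], d), dists[:, E])
                dists[:, W] = np.where(~west, np.minimum(dists[:, W], d), dists[:, W])

    in_band = dists <= threshold_cm
    any_band = in_band.any(axis=1)
    # nearest in-band wall with N,S,E,W priority on exact ties
    masked = np.where(in_band, dists, np.inf)
    cand = np.argmin(masked, axis=1)  # argmin takes first index on ties => priority
    cand_dist = masked[np.arange(len(cand)), cand]

    labels = np.full(len(xy), LABEL_NONE, dtype=np.int8)
    cur = LABEL_NONE
    for i in range(len(xy)):
        if any_band[i]:
            c = cand[i]
            if cur != LABEL_NONE and in_band[i, cur] and dists[i, cur] <= cand_dist[i]:
                pass  # tie (or closer): the wall contacted first is kept
            else:
                cur = int(c)
        labels[i] = cur
    return BoundaryContactLabels(labels=labels, threshold_cm=threshold_cm)


def _point_segment_distance(xy: np.ndarray, a, b) -> np.ndarray:
    """Distance from points to the segment ab."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    ap = xy - a
    tt = np.clip((ap @ ab) / max(float(ab @ ab), 1e-300), 0.0, 1.0)
    proj = a + tt[:, None] * ab
    return np.hypot(*(xy - proj).T)


def recency_bias_map(
    labels: BoundaryContactLabels,
    traj: Trajectory,
    env: EnvironmentGeometry,
    heading_bins: int = 8,
):
    """Per-pixel probability of having most recently contacted each boundary.

    Returns ``(prob, counts, joint)`` where ``prob`` is (rows, cols, 4) with
    per-pixel probabilities summing to 1 over visited pixels (NaN where a
    pixel was never visited by a labelled sample), ``counts`` the raw
    per-pixel labelled-sample counts, and ``joint`` a (heading_bins, 4) joint
    count table over (heading bin, boundary).
    """
    lab = labels.labels
    keep = lab != LABEL_NONE
    nrow, ncol = env.raster_shape
    counts = np.zeros((nrow, ncol, 4))
    row, col = env.pixel_of(traj.positions_cm[keep])
    lk = lab[keep]
    np.add.at(counts, (row, col, lk), 1.0)
    tot = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = counts / tot[:, :, None]
    prob[tot == 0] = np.nan

    hb = np.floor(traj.headings_deg[keep] / (360.0 / heading_bins)).astype(int)
    hb = np.clip(hb, 0, heading_bins - 1)
    joint = np.zeros((heading_bins, 4))
    np.add.at(joint, (hb, lk), 1.0)
    return prob, counts, joint
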