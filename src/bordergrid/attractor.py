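"""Periodic attractor sheets generating path-integrated grid activity.

Each grid module is a toroidal sheet of ``size**2`` units built from 2x2
tiles of movement-direction preferences.  Units receive a velocity-modulated
excitatory drive and shifted radial inhibition from their neighbours; the
stochastic spiking and leaky integration produce a hexagonal bump lattice
that translates with movement at a rate proportional to the module gain.

Recurrent input is evaluated with FFT circular convolutions: presynaptic
activations are grouped by preferred direction and convolved with the
inhibition disc rolled 2 units along that direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULTS, DynamicsConstants

# preferred-direction codes and their (east, north) unit vectors
DIR_N, DIR_E, DIR_S, DIR_W = 0, 1, 2, 3
_DIR_VEC = {
    DIR_N: (0.0, 1.0),
    DIR_E: (1.0, 0.0),
    DIR_S: (0.0, -1.0),
    DIR_W: (-1.0, 0.0),
}
# sheet-lattice step (drow, dcol) used for the inhibition-centre shift;
# rows increase northward, columns eastward
_DIR_STEP = {
    DIR_N: (1, 0),
    DIR_E: (0, 1),
    DIR_S: (-1, 0),
    DIR_W: (0, -1),
}

N_MODULES = 5
G1 = 0.45
SCALE_FACTOR = math.sqrt(2.0)


def module_gain(m: int, g1: float = G1) -> float:
    """Velocity gain of module m (1-based): ``g1 * 2**(-(m-1)/2)``.

    Module 1 is the smallest-scale (largest-gain) module; consecutive gains
    differ by a factor of sqrt(2) = 1.41..., producing a geometric series of
    grid scales with ratio ~1.42.
    """
    if not 1 <= m <= N_MODULES:
        raise ValueError(f"module index {m} out of range 1..{N_MODULES}")
    return g1 * 2.0 ** (-(m - 1) / 2.0)


def velocity_input(d_cm: float, theta_deg: float, phi_deg: float, gain: float,
                   gamma: float = 0.6) -> float:
    """Scalar movement drive ``gamma + gain * d * cos(theta - phi)``."""
    if d_cm < 0:
        raise ValueError("d_cm must be non-negative")
    return gamma + gain * d_cm * math.cos(math.radians(theta_deg - phi_deg))


@dataclass(frozen=True)
class GridModuleConfig:
    index: int = 1              # 1-based module index
    size: int = 128             # sheet side; size**2 units
    gain: float | None = None   # defaults to module_gain(index)
    gamma: float = 0.6
    inhib_radius: float = 12.0
    inhib_weight: float = -0.02
    inhib_shift: int = 2
    beta: float = 0.1

    def __post_init__(self):
        if self.size % 2 != 0:
            raise ValueError("sheet side must be even (2x2 direction tiles)")
        if self.gain is None:
            object.__setattr__(self, "gain", module_gain(self.index))


def direction_layout(size: int) -> np.ndarray:
    """Preferred-direction code per sheet unit, tiled 2x2.

    Within each tile (rows increase northward): NW unit prefers N, NE prefers
    E, SW prefers W, SE prefers S.
    """
    dirs = np.empty((size, size), dtype=np.int8)
    dirs[1::2, 0::2] = DIR_N
    dirs[1::2, 1::2] = DIR_E
    dirs[0::2, 0::2] = DIR_W
    dirs[0::2, 1::2] = DIR_S
    return dirs


def inhibition_disc(size: int, radius: float) -> np.ndarray:
    """Boolean torus-distance disc (inclusive radius) centred at (0, 0)."""
    idx = np.arange(size)
    d = np.minimum(idx, size - idx).astype(float)
    dist2 = d[:, None] ** 2 + d[None, :] ** 2
    return dist2 <= radius * radius + 1e-9


def inhibition_out_degree(config: GridModuleConfig) -> int:
    """Number of units each unit inhibits (identical for all units)."""
    return int(inhibition_disc(config.size, config.inhib_radius).sum())


def natural_wavelength(radius: float) -> float:
    """Sheet-pattern wavelength favoured by a uniform inhibition disc.

    The disc's 2-D Fourier transform is proportional to J1(kR)/(kR); pattern
    growth peaks where that factor is most negative, at kR ~= 5.136.
    """
    return 2.0 * math.pi * radius / 5.136


def _lattice_axis_nearest_east(k1, k2) -> float:
    """Orientation (deg) of the direct-lattice (bump-lattice) axis nearest
    east for a pattern built from wavevector rows k1, k2.

    The bump lattice is the direct lattice dual to the wavevector set; its
    nearest-neighbour directions sit ~30 deg from the plane-wave directions.
    """
    K = np.array([k1, k2], dtype=float)
    A = 2.0 * math.pi * np.linalg.inv(K).T  # columns? rows a1, a2 via inv
    a1, a2 = A[:, 0], A[:, 1]
    best = None
    for v in (a1, a2, a1 + a2, a1 - a2):
        ang = math.degrees(math.atan2(v[1], v[0]))
        ang = (ang + 90.0) % 180.0 - 90.0  # fold axes into (-90, 90]
        if best is None or abs(ang) < abs(best):
            best = ang
    return best


def commensurate_wavevectors(size: int, wavelength: float,
                             orientation_deg: float) -> list[tuple[int, int]]:
    """Integer torus wavevectors (kx, ky) of the hexagonal mode whose bump
    lattice best matches the requested wavelength and axis orientation.

    A plane wave is periodic on the sheet only for integer wavevectors, so
    stable pattern orientations are quantized.  ``orientation_deg`` is the
    desired grid (lattice) axis nearest east — the quantity rate-map
    autocorrelogram peaks measure — which sits ~30 deg from the plane-wave
    direction.  Candidate integer triads near the target magnitude are
    scored by lattice-axis error plus a wavelength penalty.
    """
    mag = size / wavelength
    c120, s120 = math.cos(math.radians(120.0)), math.sin(math.radians(120.0))
    best = None
    lo, hi = int(math.floor(mag * 0.75)), int(math.ceil(mag * 1.3))
    for kx in range(-hi, hi + 1):
        for ky in range(-hi, hi + 1):
            r = math.hypot(kx, ky)
            if not lo <= r <= hi or r == 0:
                continue
            k1 = (kx, ky)
            k2 = (round(kx * c120 - ky * s120), round(kx * s120 + ky * c120))
            if k2 == (0, 0) or k1 == k2:
                continue
            axis = _lattice_axis_nearest_east(k1, k2)
            err = abs(axis - orientation_deg) + 60.0 * abs(r - mag) / mag
            if best is None or err < best[0]:
                best = (err, k1, k2)
    _, k1, k2 = best
    k3 = (-(k1[0] + k2[0]), -(k1[1] + k2[1]))
    return [k1, k2, k3]


def hex_template(size: int, wavelength: float, orientation_deg: float) -> np.ndarray:
    """Weak hexagonal seed pattern: three plane waves ~60 deg apart whose
    wavevectors are snapped to the integer torus lattice, so the seeded
    lattice is strictly periodic on the sheet (no wrap seams)."""
    cols, rows = np.meshgrid(np.arange(size), np.arange(size))
    out = np.zeros((size, size))
    for kx, ky in commensurate_wavevectors(size, wavelength, orientation_deg):
        out += np.cos(2.0 * math.pi * (kx * cols + ky * rows) / size)
    return out / 3.0


class GridModule:
    """One toroidal attractor sheet with its recurrent structure."""

    def __init__(self, config: GridModuleConfig):
        self.config = config
        n = config.size
        self.dirs = direction_layout(n)  # codes 0..3 = N,E,S,W
        self.masks = [(self.dirs == d).astype(np.float32)
                      for d in (DIR_N, DIR_E, DIR_S, DIR_W)]
        # east/north components of each unit's preferred direction
        self.ux = np.zeros((n, n))
        self.uy = np.zeros((n, n))
        for d, (ex, ny) in _DIR_VEC.items():
            sel = self.dirs == d
            self.ux[sel] = ex
            self.uy[sel] = ny
        disc = inhibition_disc(n, config.inhib_radius).astype(float)
        disc *= config.inhib_weight
        khat = []
        for d in (DIR_N, DIR_E, DIR_S, DIR_W):
            dr, dc = _DIR_STEP[d]
            k = np.roll(disc, (config.inhib_shift * dr, config.inhib_shift * dc),
                        axis=(0, 1))
            khat.append(np.fft.rfft2(k))
        self._khat_stack = np.stack(khat).astype(np.complex64)
        self._dir_stack = np.zeros((4, n, n), dtype=np.float32)
        # direction code -> index into the N,E,S,W drive table
        self._dir_index = np.array([0, 1, 2, 3], dtype=np.intp)[self.dirs]
        self.a = np.zeros((n, n), dtype=np.float32)
        self.s = np.zeros((n, n), dtype=np.float32)

    @property
    def n_units(self) -> int:
        return self.config.size ** 2

    def recurrent_input(self, a: np.ndarray | None = None) -> np.ndarray:
        """Summed shifted-disc inhibition each unit receives given activations."""
        import scipy.fft as sfft

        if a is None:
            a = self.a
        stack = self._dir_stack
        for d in range(4):
            np.multiply(a, self.masks[d], out=stack[d])
        f = sfft.rfft2(stack, axes=(-2, -1))
        f *= self._khat_stack
        return sfft.irfft2(f.sum(axis=0), s=a.shape, axes=(-2, -1))

    def velocity_drive(self, dx_cm: float, dy_cm: float) -> np.ndarray:
        """Per-unit movement input gamma + g * (displacement . preferred dir)."""
        c = self.config
        table = np.array(
            [c.gamma + c.gain * dy_cm, c.gamma + c.gain * dx_cm,
             c.gamma - c.gain * dy_cm, c.gamma - c.gain * dx_cm],
            dtype=np.float32)  # N, E, S, W
        return table[self._dir_index]

    def total_input(self, dx_cm: float, dy_cm: float,
                    extra: np.ndarray | None = None) -> np.ndarray:
        b = self.velocity_drive(dx_cm, dy_cm) + self.recurrent_input()
        if extra is not None:
            b = b + extra
        return b

    def step(self, dx_cm: float, dy_cm: float,
             extra: np.ndarray | None = None,
             rng: np.random.Generator | None = None,
             rate_based: bool = False,
             const: DynamicsConstants = DEFAULTS) -> np.ndarray:
        """Advance one timestep; returns the spike (or spike-probability) field."""
        b = self.total_input(dx_cm, dy_cm, extra)
        kdt = np.float32(const.kappa * const.dt_s)
        p = np.clip(kdt * (b - np.float32(self.config.beta)), 0.0, 1.0)
        if rate_based:
            s = p
        else:
            s = (rng.random(b.shape) < p).astype(np.float32)
        self.a = self.a * np.float32(const.decay) + np.float32(const.alpha) * s
        self.s = s
        return s

    def initialize(self, seed=None, orientation_deg: float = -7.5,
                   template_amp: float = 0.3, noise_amp: float = 0.1,
                   base: float = 0.05,
                   wavelength: float | None = None) -> None:
        """Seed the sheet with weak noise plus a hexagonal template so the
        settled pattern's axis lies near ``orientation_deg``."""
        rng = np.random.default_rng(seed)
        n = self.config.size
        lam = wavelength or natural_wavelength(self.config.inhib_radius)
        t = hex_template(n, lam, orientation_deg)
        a0 = base * (1.0 + template_amp * t + noise_amp * rng.random((n, n)))
        self.a = np.maximum(a0, 0.0).astype(np.float32)

    def settle(self, duration_s: float = 2.0, seed=None,
               orientation_deg: float = -7.5, rate_based: bool = False,
               const: DynamicsConstants = DEFAULTS, check: bool = False,
               initialize: bool = True) -> np.ndarray:
        """Run zero-velocity dynamics from the biased initialization until the
        sheet relaxes into its hexagonal bump-lattice attractor state."""
        rng = np.random.default_rng(seed)
        if initialize:
            self.initialize(seed=rng, orientation_deg=orientation_deg)
        steps = int(round(duration_s / const.dt_s))
        for _ in range(steps):
            self.step(0.0, 0.0, rng=rng, rate_based=rate_based, const=const)
        if check:
            from .metrics import gridness, grid_scale

            ac = sheet_autocorrelation(self.a)
            try:
                scale_px = grid_scale(ac, pixel_cm=1.0)
                score = gridness(ac, scale_px, pixel_cm=1.0)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"settling failed to form a grid: {exc}") from exc
            if score <= 0:
                raise RuntimeError(
                    f"settling failed: sheet gridness {score:.3f} <= 0"
                )
        return self.a


def sheet_autocorrelation(a: np.ndarray) -> np.ndarray:
    """Periodic (circular) autocorrelation of a sheet activation pattern,
    normalized to 1 at zero lag, centred."""
    x = a - a.mean()
    f = np.fft.rfft2(x)
    ac = np.fft.irfft2(f * np.conj(f), s=x.shape)
    ac /= ac.flat[0] if ac.flat[0] != 0 else 1.0
    return np.fft.fftshift(ac)


def track_bump_shift(a0: np.ndarray, a1: np.ndarray,
                     max_shift: float | None = None) -> tuple[float, float]:
    """Sub-pixel translation (drow, dcol) taking pattern a0 to a1, via the
    circular cross-correlation peak.

    For periodic lattice patterns the shift is only defined modulo a lattice
    vector; ``max_shift`` restricts the peak search to lags within that torus
    radius of zero so incremental tracking follows the continuous drift.
    """
    from scipy.ndimage import maximum_position

    f0 = np.fft.rfft2(a0 - a0.mean())
    f1 = np.fft.rfft2(a1 - a1.mean())
    cc = np.fft.irfft2(np.conj(f0) * f1, s=a0.shape)
    n = a0.shape[0]
    if max_shift is not None:
        idx = np.arange(n)
        d = np.minimum(idx, n - idx).astype(float)
        far = d[:, None] ** 2 + d[None, :] ** 2 > max_shift * max_shift
        r, c = maximum_position(np.where(far, -np.inf, cc))
    else:
        r, c = maximum_position(cc)

    def _subpix(m, i, j):
        def val(ii, jj):
            return m[ii % n, jj % n]

        dr = 0.5 * (val(i + 1, j) - val(i - 1, j)) / max(
            2 * val(i, j) - val(i + 1, j) - val(i - 1, j), 1e-12)
        dc = 0.5 * (val(i, j + 1) - val(i, j - 1)) / max(
            2 * val(i, j) - val(i, j + 1) - val(i, j - 1), 1e-12)
        return dr, dc

    dr, dc = _subpix(cc, r, c)
    rr, cc_ = r + dr, c + dc
    if rr > n / 2:
        rr -= n
    if cc_ > n / 2:
        cc_ -= n
    return rr, cc_
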