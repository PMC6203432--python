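"""Coupled network engine: border, grid and place layers with competitive
Hebbian learning and the familiarization / testing protocols.

Per-timestep update order (fixed; two runs with equal seeds are identical):

1. advance position (trajectory sample k);
2. border drive and velocity input computed from the step just taken;
3. total inputs for every population from the *previous* activations;
4. stochastic spikes (or expected rates in rate-based mode);
5. leaky activation integration;
6. Hebbian weight update from the new activations (when learning is on).

The competitive rule ``w += lam * a_post * ((xi - w) a_pre - w * sum_other)``
reduces, with the sum restricted to presynaptic units holding nonzero
weights, to ``w += lam * a_post * (xi * a_pre - w * A)`` where ``A`` is the
summed activation of nonzero-weight afferents; incoming totals converge to
``xi``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .arena import EnvironmentGeometry, Trajectory, random_walk
from .attractor import GridModule, GridModuleConfig, module_gain
from .border import BrickPartition, N_UNITS as N_BORDER
from .constants import DEFAULTS, DynamicsConstants
from .place import PlaceLayer, init_place_layer


@dataclass
class NetworkConfig:
    """Structural and protocol configuration of the full model."""

    n_modules: int = 5
    module_indices: tuple | None = None  # default 1..n_modules
    sheet_size: int = 128
    g1: float = 0.45
    orientation_deg: float = -7.5
    template_wavelength: float = 14.68  # relaxed pattern wavelength for R=12
    n_place: int = 64
    n_place_afferents: int = 500
    border_depth_cm: float = 12.0
    border_amplitude: float = 0.1
    w_bg_init_max: float = 0.025
    rate_based: bool = False
    record_grid_per_module: int = 30
    settle_s: float = 2.0
    const: DynamicsConstants = field(default_factory=lambda: DEFAULTS)

    @classmethod
    def desk(cls, **overrides) -> "NetworkConfig":
        """Scaled-down profile for tests: 2 modules, 96-unit sheets,
        deterministic rate-based dynamics."""
        base = dict(n_modules=2, sheet_size=96, rate_based=True,
                    record_grid_per_module=20)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrialRecord:
    """Spike/position records of one simulated trial.

    In rate-based runs ``rate_maps`` additionally holds per-unit expected-rate
    maps (accumulated per-step spike probabilities over pixel occupancy, Hz),
    which are free of Bernoulli sampling noise.
    """

    traj: Trajectory
    spike_times: dict  # unit key -> np.ndarray of spike times (s)
    env: EnvironmentGeometry
    duration_s: float
    rate_maps: dict | None = None

    def units(self, kind: str | None = None):
        keys = list(self.spike_times)
        if kind is not None:
            keys = [k for k in keys if k[0] == kind]
        return keys

    def rate_map_of(self, unit):
        """Expected-rate RateMap for a recorded unit (rate-based runs)."""
        from .metrics import RateMap, smooth_map

        if self.rate_maps is None or unit not in self.rate_maps:
            raise KeyError(f"no accumulated rate map for {unit}")
        acc, occ = self.rate_maps[unit]
        visited = occ > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = acc / (occ * self.traj.dt_s)
        raw[~visited] = np.nan
        return RateMap(rate=smooth_map(raw, visited), rate_raw=raw,
                       occupancy_s=occ * self.traj.dt_s, visited=visited,
                       pixel_cm=self.env.pixel_cm)


class Network:
    """The coupled border / grid / place network."""

    def __init__(self, config: NetworkConfig | None = None, seed=None):
        self.config = config or NetworkConfig()
        cfg = self.config
        root = np.random.default_rng(seed)
        # named substreams so the path can be held fixed while spiking varies
        self.rng_wiring = np.random.default_rng(root.integers(2 ** 63))
        self.rng_spiking = np.random.default_rng(root.integers(2 ** 63))
        self.rng_recording = np.random.default_rng(root.integers(2 ** 63))

        indices = tuple(cfg.module_indices or range(1, cfg.n_modules + 1))
        self.module_indices = indices
        self.modules = [
            GridModule(GridModuleConfig(index=m, size=cfg.sheet_size,
                                        gain=module_gain(m, cfg.g1)))
            for m in indices
        ]
        self.n_grid = sum(m.n_units for m in self.modules)
        self._slices = []
        off = 0
        for m in self.modules:
            self._slices.append(slice(off, off + m.n_units))
            off += m.n_units

        self.w_bg = self.rng_wiring.uniform(
            0.0, cfg.w_bg_init_max, size=(N_BORDER, self.n_grid))
        # n_place = 0 disables the place layer entirely (grid-only runs)
        self.place = init_place_layer(
            self.n_grid, seed=self.rng_wiring, n_place=cfg.n_place,
            n_afferents=cfg.n_place_afferents) if cfg.n_place else None
        self.a_border = np.zeros(N_BORDER)
        self.a_grid = np.zeros(self.n_grid)

        self.env: EnvironmentGeometry | None = None
        self.partition: BrickPartition | None = None
        self.state_cache: dict = {}
        self.familiar_w_bg: np.ndarray | None = None
        self.familiar_w_gp: np.ndarray | None = None
        self.recorded_grid: list | None = None

    # ------------------------------------------------------------- plumbing

    def set_environment(self, env: EnvironmentGeometry) -> None:
        """Install the arena: border bricks are recomputed from the geometry,
        so deformations rescale/displace border fields; weights are kept."""
        self.env = env
        self.partition = BrickPartition(env, depth_cm=self.config.border_depth_cm)

    def _gather_grid_activations(self) -> np.ndarray:
        return np.concatenate([m.a.ravel() for m in self.modules])

    def settle(self, seed=None) -> None:
        """Relax every module into its hexagonal attractor state (2 s, zero
        velocity, no learning), orientation-biased initialization."""
        cfg = self.config
        rng = np.random.default_rng(seed) if seed is not None else self.rng_spiking
        for m in self.modules:
            m.initialize(seed=rng, orientation_deg=cfg.orientation_deg,
                         wavelength=cfg.template_wavelength)
            m.settle(duration_s=cfg.settle_s, seed=rng,
                     orientation_deg=cfg.orientation_deg,
                     rate_based=cfg.rate_based, const=cfg.const,
                     initialize=False)
        self.a_grid = self._gather_grid_activations()

    def choose_recorded_units(self, per_module: int | None = None) -> list:
        """Pick the grid units whose spikes are recorded (fixed thereafter)."""
        k = per_module or self.config.record_grid_per_module
        units = []
        for mi, m in enumerate(self.modules):
            flat = self.rng_recording.choice(m.n_units, size=k, replace=False)
            units.extend(("g", mi, int(f)) for f in np.sort(flat))
        self.recorded_grid = units
        return units

    # ------------------------------------------------------------- dynamics

    def _step(self, disp, border_vec, learning: bool, rng) -> tuple:
        """One timestep of the full network; returns per-population spikes."""
        cfg = self.config
        const = cfg.const
        rate_based = cfg.rate_based
        kdt = const.kappa * const.dt_s

        # --- total inputs from previous activations
        b_border = border_vec
        b_grid_parts = []
        if self.a_border.any():
            active_b = np.nonzero(self.a_border)[0]
            border_drive = (self.a_border[active_b] @ self.w_bg[active_b]
                            ).astype(np.float32)
            for m, sl in zip(self.modules, self._slices):
                b = m.total_input(disp[0], disp[1],
                                  extra=border_drive[sl].reshape(m.a.shape))
                b_grid_parts.append(b)
        else:
            for m in self.modules:
                b_grid_parts.append(m.total_input(disp[0], disp[1]))
        if self.place is not None:
            pre_place = self.a_grid[self.place.afferents]
            b_place = (np.einsum("ij,ij->i", pre_place, self.place.w)
                       + self.place.inhib_weight * self.place.a.sum())
        else:
            b_place = np.zeros(0)

        # --- spikes
        p_border = np.clip(kdt * (b_border - const.beta_border), 0.0, 1.0)
        p_place = np.clip(kdt * (b_place - const.beta_place), 0.0, 1.0)
        if rate_based:
            s_border, s_place = p_border, p_place
        else:
            s_border = (rng.random(p_border.shape) < p_border).astype(float)
            s_place = (rng.random(p_place.shape) < p_place).astype(float)
        s_grid_parts = []
        p_grid_parts = []
        kdt32 = np.float32(kdt)
        decay32 = np.float32(const.decay)
        alpha32 = np.float32(const.alpha)
        for m, b in zip(self.modules, b_grid_parts):
            p = np.clip(kdt32 * (b - np.float32(m.config.beta)), 0.0, 1.0)
            s = p if rate_based else (rng.random(p.shape) < p).astype(np.float32)
            m.a = m.a * decay32 + alpha32 * s
            m.s = s
            s_grid_parts.append(s)
            p_grid_parts.append(p)

        # --- integrate the non-grid populations
        self.a_border = self.a_border * const.decay + const.alpha * s_border
        if self.place is not None:
            self.place.a = self.place.a * const.decay + const.alpha * s_place
        self.a_grid = self._gather_grid_activations()

        # --- Hebbian learning from the new activations.  The multiplicative
        # decay keeps weights strictly positive, so the competition sum over
        # nonzero-weight afferents is the plain total; no clamp is needed.
        if learning:
            lam = const.lam
            if self.a_border.any():
                A = self.a_border.sum()
                active = np.nonzero(self.a_border)[0]
                self.w_bg *= 1.0 - (lam * A) * self.a_grid
                self.w_bg[active] += (
                    (lam * const.xi_border_grid) * self.a_border[active, None]
                    * self.a_grid)
            if self.place is not None and self.place.a.any():
                pre = self.a_grid[self.place.afferents]
                A_p = pre.sum(axis=1)
                lp = lam * self.place.a
                self.place.w *= 1.0 - (lp * A_p)[:, None]
                self.place.w += (lam * const.xi_grid_place) * self.place.a[:, None] * pre

        return s_grid_parts, p_grid_parts, s_place, p_place

    def _run(self, traj: Trajectory, learning: bool, record: bool,
             cache_states: bool, spike_seed=None) -> TrialRecord | None:
        cfg = self.config
        env = self.env
        if env is None:
            raise RuntimeError("set_environment() before running")
        rng = (np.random.default_rng(spike_seed) if spike_seed is not None
               else self.rng_spiking)
        rec_rng = np.random.default_rng(rng.integers(2 ** 63))
        disp = traj.displacements_cm
        border_all = self.partition.unit_input(
            traj.positions_cm, amplitude=cfg.border_amplitude)
        row, col = env.pixel_of(traj.positions_cm)

        rec_units = []
        spikes: dict = {}
        if record:
            if self.recorded_grid is None:
                self.choose_recorded_units()
            rec_units = list(self.recorded_grid)
            # per-module flat indices of recorded units for vector gathers
            rec_by_module = [
                np.array([u[2] for u in rec_units if u[1] == mi], dtype=int)
                for mi in range(len(self.modules))
            ]
            rec_keys = [u for mi in range(len(self.modules))
                        for u in rec_units if u[1] == mi]
            n_rec = len(rec_keys)
            grid_spike_steps: list[list[int]] = [[] for _ in range(n_rec)]
            n_place = self.place.n_units if self.place is not None else 0
            place_spike_steps: list[list[int]] = [[] for _ in range(n_place)]
            acc_maps = occ_map = None
            if cfg.rate_based:
                shape = env.raster_shape
                acc_maps = np.zeros((n_rec + n_place,) + shape)
                occ_map = np.zeros(shape)

        cache = self.state_cache if cache_states else None
        times = traj.times_s
        last_px = (int(row[0]), int(col[0]))
        for k in range(1, len(traj)):
            s_grid, p_grid, s_place, p_place = self._step(
                disp[k], border_all[k], learning, rng)
            if record:
                if cfg.rate_based:
                    # dynamics are deterministic; recorded spikes are Bernoulli
                    # draws from the per-step probabilities
                    pg = np.concatenate([
                        p_grid[mi].ravel()[idx]
                        for mi, idx in enumerate(rec_by_module)])
                    fired = np.nonzero(rec_rng.random(pg.shape) < pg)[0]
                    pfired = np.nonzero(rec_rng.random(p_place.shape) < p_place)[0]
                    acc_maps[:, row[k], col[k]] += np.concatenate([pg, p_place])
                    occ_map[row[k], col[k]] += 1.0
                else:
                    sg = np.concatenate([
                        s_grid[mi].ravel()[idx]
                        for mi, idx in enumerate(rec_by_module)])
                    fired = np.nonzero(sg)[0]
                    pfired = np.nonzero(s_place)[0]
                for i in fired:
                    grid_spike_steps[i].append(k)
                for j in pfired:
                    place_spike_steps[j].append(k)
            if cache is not None:
                px = (int(row[k]), int(col[k]))
                if px != last_px:
                    # snapshot on pixel exit: the most recent state seen there
                    cache[last_px] = self.a_grid.astype(np.float16)
                    last_px = px
        if cache is not None:
            cache[last_px] = self.a_grid.astype(np.float16)
        if record:
            for u, steps in zip(rec_keys, grid_spike_steps):
                spikes[u] = times[np.asarray(steps, dtype=int)]
            for j, steps in enumerate(place_spike_steps):
                spikes[("p", j)] = times[np.asarray(steps, dtype=int)]
            rate_maps = None
            if acc_maps is not None:
                keys = rec_keys + [("p", j) for j in range(n_place)]
                rate_maps = {u: (acc_maps[i], occ_map)
                             for i, u in enumerate(keys)}
            return TrialRecord(
                traj=traj, spike_times=spikes, env=env,
                duration_s=float(times[-1] - times[0]), rate_maps=rate_maps)
        return None

    # ------------------------------------------------------------ protocols

    def familiarize(self, env: EnvironmentGeometry, duration_s: float = 3600.0,
                    path_seed=None, spike_seed=None,
                    record: bool = False) -> TrialRecord | None:
        """Settle (no learning), then explore with learning on; caches a grid
        sheet snapshot per visited pixel and freezes the familiar weights."""
        self.set_environment(env)
        self.settle()
        traj = random_walk(env, duration_s, dt_s=self.config.const.dt_s,
                           seed=path_seed)
        out = self._run(traj, learning=True, record=record, cache_states=True,
                        spike_seed=spike_seed)
        self.familiar_w_bg = self.w_bg.copy()
        self.familiar_w_gp = self.place.w.copy() if self.place is not None else None
        return out

    def restore_familiar(self) -> None:
        if self.familiar_w_bg is None:
            raise RuntimeError("no familiarization to restore")
        self.w_bg = self.familiar_w_bg.copy()
        if self.place is not None:
            self.place.w = self.familiar_w_gp.copy()

    def reset_state_from_cache(self, position_cm) -> None:
        """Reinstate the cached grid sheet state closest to the position."""
        if not self.state_cache:
            raise RuntimeError("empty position-state cache")
        env = self.env
        r0, c0 = env.pixel_of(np.asarray([position_cm]))
        r0, c0 = int(r0[0]), int(c0[0])
        key = min(self.state_cache,
                  key=lambda rc: (rc[0] - r0) ** 2 + (rc[1] - c0) ** 2)
        flat = self.state_cache[key].astype(float)
        for m, sl in zip(self.modules, self._slices):
            m.a = flat[sl].reshape(m.a.shape).copy()
        self.a_grid = self._gather_grid_activations()
        self.a_border[:] = 0.0
        if self.place is not None:
            self.place.a[:] = 0.0

    def test_trial(self, env: EnvironmentGeometry, duration_s: float = 1800.0,
                   path_seed=None, spike_seed=None) -> TrialRecord:
        """Post-familiarization test: weights restored, grid state reinstated
        from the start-pixel cache, learning off, spikes recorded."""
        self.restore_familiar()
        self.set_environment(env)
        traj = random_walk(env, duration_s, dt_s=self.config.const.dt_s,
                           seed=path_seed)
        self.reset_state_from_cache(traj.positions_cm[0])
        return self._run(traj, learning=False, record=True, cache_states=False,
                         spike_seed=spike_seed)

    def run_trajectory(self, env: EnvironmentGeometry, traj: Trajectory,
                       learning: bool = False, record: bool = True,
                       spike_seed=None) -> TrialRecord | None:
        """Run an arbitrary pre-built trajectory (e.g. linear-track laps)."""
        self.set_environment(env)
        return self._run(traj, learning=learning, record=record,
                         cache_states=learning, spike_seed=spike_seed)


# ------------------------------------------------- free-standing primitives


def total_input_grid(velocity_drive, recurrent, border_drive=None):
    """Grid-unit total input: velocity + recurrent (+ border afferents)."""
    b = velocity_drive + recurrent
    if border_drive is not None:
        b = b + border_drive
    return b


def spike_step(b, beta, rng=None, const: DynamicsConstants = DEFAULTS,
               rate_based: bool = False):
    """Bernoulli spiking: P(spike) = clip(kappa * (b - beta) * dt, 0, 1)."""
    p = np.clip(const.kappa * (np.asarray(b, float) - beta) * const.dt_s, 0.0, 1.0)
    if rate_based:
        return p
    return (rng.random(p.shape) < p).astype(float)


def integrate_activation(a, s, const: DynamicsConstants = DEFAULTS):
    """Leaky integration ``a' = a - a dt/c + alpha s`` (= 0.9 a + 0.5 s)."""
    return np.asarray(a, float) * const.decay + const.alpha * np.asarray(s, float)


def hebbian_update(w, a_pre, a_post, xi, lam: float = DEFAULTS.lam):
    """One competitive Hebbian step onto each postsynaptic unit.

    ``w``: (n_pre, n_post); ``a_pre``: (n_pre,); ``a_post``: (n_post,).
    The competition sum runs over presynaptic units with nonzero weights.
    Returns the updated (clamped non-negative) weights.
    """
    w = np.asarray(w, float).copy()
    a_pre = np.asarray(a_pre, float)
    a_post = np.asarray(a_post, float)
    A = a_pre @ (w > 0)
    w += lam * a_post * (xi * a_pre[:, None] - w * A)
    return np.maximum(w, 0.0)
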