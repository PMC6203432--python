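"""Deterministic synthetic inputs with known ground truth, for tests and
oracle checks."""

from __future__ import annotations

import math

import numpy as np

from .arena import Trajectory

FIXTURE_KINDS = ("hex_map", "shifted_pair", "compressed_pair", "toy_path",
                 "two_phase_mixture")


def hex_rate_pattern(shape: tuple, spacing_cm: float, pixel_cm: float = 2.5,
                     orientation_deg: float = 0.0,
                     phase_cm: tuple = (0.0, 0.0), peak_hz: float = 10.0) -> np.ndarray:
    """Ideal hexagonal firing-rate map: thresholded sum of three plane waves.

    ``spacing_cm`` is the lattice constant (centre-to-centre field distance),
    related to the plane-wave wavelength by a factor 2/sqrt(3).
    """
    rows, cols = shape
    y = (np.arange(rows)[:, None] + 0.5) * pixel_cm - phase_cm[1]
    x = (np.arange(cols)[None, :] + 0.5) * pixel_cm - phase_cm[0]
    k = 4.0 * math.pi / (math.sqrt(3.0) * spacing_cm)
    z = np.zeros(shape)
    for i in range(3):
        ang = math.radians(orientation_deg + 60.0 * i + 30.0)
        z = z + np.cos(k * (math.cos(ang) * x + math.sin(ang) * y))
    z = np.maximum(z, 0.0)
    return peak_hz * z / z.max()


def make_fixtures(kind: str, seed: int = 0, **kwargs):
    """Build a synthetic test input; returns ``(data, meta)``.

    Kinds: ``hex_map`` (grid map with known scale), ``shifted_pair`` (two
    maps offset by a known translation), ``compressed_pair`` (map plus its
    known uniform compression), ``toy_path`` (tiny hand-built trajectory),
    ``two_phase_mixture`` (a pure-phase-shift map and the two-phase average
    that mimics a whole-trial map under deformation).
    """
    rng = np.random.default_rng(seed)
    if kind == "hex_map":
        spacing = kwargs.get("spacing_cm", 50.0)
        shape = kwargs.get("shape", (60, 60))
        ori = kwargs.get("orientation_deg", float(rng.uniform(0, 60)))
        phase = kwargs.get("phase_cm",
                           tuple(rng.uniform(0, spacing, size=2)))
        m = hex_rate_pattern(shape, spacing, orientation_deg=ori, phase_cm=phase)
        return m, {"scale_cm": spacing, "orientation_deg": ori, "phase_cm": phase}
    if kind == "shifted_pair":
        delta = kwargs.get("delta_cm", 5.0)
        dimension = kwargs.get("dimension", "x")
        base, meta = make_fixtures("hex_map", seed, **kwargs)
        shift = (delta, 0.0) if dimension == "x" else (0.0, delta)
        phase = (meta["phase_cm"][0] + shift[0], meta["phase_cm"][1] + shift[1])
        other = hex_rate_pattern(base.shape, meta["scale_cm"],
                                 orientation_deg=meta["orientation_deg"],
                                 phase_cm=phase)
        meta = dict(meta, delta_cm=delta, dimension=dimension)
        return (base, other), meta
    if kind == "compressed_pair":
        factor = kwargs.get("factor", 0.7)
        spacing = kwargs.get("spacing_cm", 50.0)
        shape = kwargs.get("shape", (40, 40))
        ori = kwargs.get("orientation_deg", float(rng.uniform(0, 60)))
        fam = hex_rate_pattern(shape, spacing, orientation_deg=ori)
        new_cols = int(round(shape[1] * factor))
        # deformed map: familiar pattern sampled on compressed x coordinates
        rows = shape[0]
        y = (np.arange(rows)[:, None] + 0.5) * 2.5
        x = (np.arange(new_cols)[None, :] + 0.5) * 2.5 / factor
        k = 4.0 * math.pi / (math.sqrt(3.0) * spacing)
        z = np.zeros((rows, new_cols))
        for i in range(3):
            ang = math.radians(ori + 60.0 * i + 30.0)
            z = z + np.cos(k * (math.cos(ang) * x + math.sin(ang) * y))
        deformed = 10.0 * np.maximum(z, 0.0) / max(z.max(), 1e-9)
        meta = {"factor": factor, "scale_cm": spacing,
                "fam_len_cm": shape[1] * 2.5, "def_len_cm": new_cols * 2.5}
        return (fam, deformed), meta
    if kind == "toy_path":
        # five samples marching from the north band to the south band
        pts = np.array([[50.0, 95.0], [50.0, 70.0], [50.0, 45.0],
                        [50.0, 20.0], [50.0, 8.0]])
        traj = Trajectory(times_s=np.arange(5) * 0.003, positions_cm=pts,
                          dt_s=0.003)
        return traj, {"env": {"kind": "rectangle", "width_cm": 100.0,
                              "height_cm": 100.0}}
    if kind == "two_phase_mixture":
        delta = kwargs.get("delta_cm", 15.0)
        spacing = kwargs.get("spacing_cm", 50.0)
        shape = kwargs.get("shape", (40, 28))
        ori = kwargs.get("orientation_deg", 0.0)
        a = hex_rate_pattern(shape, spacing, orientation_deg=ori)
        b = hex_rate_pattern(shape, spacing, orientation_deg=ori,
                             phase_cm=(delta, 0.0))
        return (a, (a + b) / 2.0), {"delta_cm": delta, "scale_cm": spacing}
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
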