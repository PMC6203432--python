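"""Spatial-map analysis: rate maps, correlograms, grid scale and gridness.

Rate maps live on 2.5 cm pixels indexed ``[row, col]`` with row 0 at the
south edge.  Unvisited pixels are NaN and excluded from every correlation;
correlograms carry a validity mask requiring at least 20 overlapping pixels
per lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage import measure

from .arena import EnvironmentGeometry, Trajectory

MIN_OVERLAP_PIXELS = 20
SMOOTH_SIGMA_PX = 1.5
SMOOTH_SUPPORT_PX = 9


class GridUndefinedError(ValueError):
    """Raised when a grid statistic cannot be computed (e.g. < 6 peaks)."""


# ------------------------------------------------------------------ rate maps


@dataclass
class RateMap:
    """Firing-rate map (Hz) with occupancy and visited mask."""

    rate: np.ndarray          # smoothed (or raw if smooth=False), NaN unvisited
    rate_raw: np.ndarray      # unsmoothed spike-count / occupancy
    occupancy_s: np.ndarray
    visited: np.ndarray
    pixel_cm: float = 2.5
    spike_count: int = 0

    @property
    def shape(self):
        return self.rate.shape

    def masked(self) -> np.ndarray:
        out = self.rate.copy()
        out[~self.visited] = np.nan
        return out


def smoothing_kernel(sigma_px: float = SMOOTH_SIGMA_PX,
                     support_px: int = SMOOTH_SUPPORT_PX) -> np.ndarray:
    """Isotropic Gaussian kernel on a square support, normalized to sum 1."""
    r = support_px // 2
    ax = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(ax ** 2) / (2.0 * sigma_px ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_map(values: np.ndarray, valid: np.ndarray | None = None,
               sigma_px: float = SMOOTH_SIGMA_PX,
               support_px: int = SMOOTH_SUPPORT_PX) -> np.ndarray:
    """Gaussian smoothing with the kernel renormalized over valid pixels, so
    map edges and masked holes are unbiased.  Invalid pixels stay NaN."""
    k = smoothing_kernel(sigma_px, support_px)
    if valid is None:
        valid = np.isfinite(values)
    v = np.where(valid, values, 0.0)
    num = ndimage.convolve(v, k, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def spike_sample_indices(traj: Trajectory, spike_times_s: np.ndarray) -> np.ndarray:
    """Index of the trajectory sample nearest each spike time."""
    t = np.asarray(spike_times_s, dtype=float)
    idx = np.rint((t - traj.times_s[0]) / traj.dt_s).astype(int)
    return np.clip(idx, 0, len(traj) - 1)


def rate_map_from_counts(occ_counts: np.ndarray, spk_counts: np.ndarray,
                         dt_s: float, pixel_cm: float = 2.5,
                         smooth: bool = True) -> RateMap:
    """Build a rate map from per-pixel sample and spike counts."""
    visited = occ_counts > 0
    occupancy = occ_counts * dt_s
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = spk_counts / occupancy
    raw[~visited] = np.nan
    rate = smooth_map(raw, visited) if smooth else raw.copy()
    return RateMap(rate=rate, rate_raw=raw, occupancy_s=occupancy,
                   visited=visited, pixel_cm=pixel_cm,
                   spike_count=int(spk_counts.sum()))


def rate_map(traj: Trajectory, spike_times_s, env: EnvironmentGeometry,
             smooth: bool = True, sample_mask: np.ndarray | None = None,
             spike_samples: np.ndarray | None = None) -> RateMap:
    """Per-pixel mean firing rate: spike count / occupancy time, smoothed.

    ``sample_mask`` restricts the map to a subset of trajectory samples (the
    boundary-conditioned maps); spikes are then kept only if their nearest
    sample is included.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    shape = env.raster_shape
    row, col = env.pixel_of(traj.positions_cm)
    if spike_samples is None:
        spike_samples = spike_sample_indices(traj, np.asarray(spike_times_s, float))
    if sample_mask is not None:
        keep_occ = sample_mask
        keep_spk = sample_mask[spike_samples]
        spike_samples = spike_samples[keep_spk]
    else:
        keep_occ = slice(None)
    occ = np.zeros(shape)
    np.add.at(occ, (row[keep_occ], col[keep_occ]), 1.0)
    spk = np.zeros(shape)
    np.add.at(spk, (row[spike_samples], col[spike_samples]), 1.0)
    return rate_map_from_counts(occ, spk, traj.dt_s, env.pixel_cm, smooth=smooth)


# --------------------------------------------------------------- correlograms


@dataclass
class Correlogram:
    """Pearson r at integer-pixel lags with a valid-lag mask.

    ``r`` has shape (2*rows-1, 2*cols-1) for input maps of equal shape; the
    zero-lag entry sits at ``center``.
    """

    r: np.ndarray
    valid: np.ndarray
    n_overlap: np.ndarray
    center: tuple[int, int]
    pixel_cm: float = 2.5

    def lag_grids_cm(self):
        rows = (np.arange(self.r.shape[0]) - self.center[0]) * self.pixel_cm
        cols = (np.arange(self.r.shape[1]) - self.center[1]) * self.pixel_cm
        return rows, cols


def _as_map_array(m) -> np.ndarray:
    if isinstance(m, RateMap):
        return m.masked()
    return np.asarray(m, dtype=float)


def correlogram(map_a, map_b=None, min_overlap: int = MIN_OVERLAP_PIXELS,
                pixel_cm: float | None = None) -> Correlogram:
    """Cross-correlogram (autocorrelogram if ``map_b`` is None/identical):
    Pearson r between overlapping valid pixels at every integer-pixel lag.

    Lags with fewer than ``min_overlap`` overlapping pixels, or with zero
    variance in the overlap, are masked invalid.
    """
    if pixel_cm is None:
        pixel_cm = map_a.pixel_cm if isinstance(map_a, RateMap) else 2.5
    a = _as_map_array(map_a)
    b = a if map_b is None else _as_map_array(map_b)
    ma = np.isfinite(a)
    mb = np.isfinite(b)
    A = np.where(ma, a, 0.0)
    B = np.where(mb, b, 0.0)
    fa, fb = ma.astype(float), mb.astype(float)

    def xc(f, g):
        # sum_u f(u) g(u - lag); full output, lag 0 at index (shape_g - 1)
        return fftconvolve(f, g[::-1, ::-1], mode="full")

    n = xc(fa, fb)
    sa = xc(A, fb)
    sb = xc(fa, B)
    saa = xc(A * A, fb)
    sbb = xc(fa, B * B)
    sab = xc(A, B)

    n = np.rint(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        va = n * saa - sa * sa
        vb = n * sbb - sb * sb
        r = cov / np.sqrt(va * vb)
    valid = (n >= min_overlap) & (va > 1e-12) & (vb > 1e-12) & np.isfinite(r)
    r = np.where(valid, np.clip(r, -1.0, 1.0), np.nan)
    # orient lags as the displacement of map_b relative to map_a: a copy of A
    # translated by +d peaks at lag +d
    r = r[::-1, ::-1]
    valid = valid[::-1, ::-1]
    n = n[::-1, ::-1]
    center = (a.shape[0] - 1, a.shape[1] - 1)
    return Correlogram(r=r, valid=valid, n_overlap=n.astype(int),
                       center=center, pixel_cm=pixel_cm)


def correlogram_brute(a: np.ndarray, b: np.ndarray,
                      min_overlap: int = MIN_OVERLAP_PIXELS) -> np.ndarray:
    """Direct per-lag Pearson computation (oracle for tests; O(lags * pixels))."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ra, ca = a.shape
    rb, cb = b.shape
    out = np.full((ra + rb - 1, ca + cb - 1), np.nan)
    for dr in range(-(ra - 1), rb):
        for dc in range(-(ca - 1), cb):
            # overlap of a(u) and b displaced by lag: b(u + lag) vs a(u)
            r0, r1 = max(0, dr), min(rb, ra + dr)
            c0, c1 = max(0, dc), min(cb, ca + dc)
            if r1 <= r0 or c1 <= c0:
                continue
            bv = b[r0:r1, c0:c1]
            av = a[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            ok = np.isfinite(av) & np.isfinite(bv)
            if ok.sum() < min_overlap:
                continue
            x, y = av[ok], bv[ok]
            sx, sy = x.std(), y.std()
            if sx < 1e-9 or sy < 1e-9:
                continue
            out[dr + ra - 1, dc + ca - 1] = np.corrcoef(x, y)[0, 1]
    return out


# ------------------------------------------------------- peaks, scale, gridness


def _corr_array(c) -> tuple[np.ndarray, tuple[int, int], float]:
    if isinstance(c, Correlogram):
        return c.r, c.center, c.pixel_cm
    arr = np.asarray(c, float)
    return arr, (arr.shape[0] // 2, arr.shape[1] // 2), 1.0


def autocorr_peaks(autocorr, pixel_cm: float | None = None):
    """Centres of mass of positive-r blobs surrounding the central blob,
    sorted by (distance from center, angle from east).

    Returns a list of ``(distance_cm, angle_deg, (row, col))`` tuples.
    """
    arr, center, pc = _corr_array(autocorr)
    if pixel_cm is not None:
        pc = pixel_cm
    pos = np.isfinite(arr) & (arr > 0)
    labels = measure.label(pos, connectivity=2)
    central = labels[center]
    peaks = []
    for reg in measure.regionprops(labels, intensity_image=np.where(pos, arr, 0.0)):
        if reg.label == central:
            continue
        r_cm, c_cm = reg.centroid_weighted
        dy = (r_cm - center[0]) * pc
        dx = (c_cm - center[1]) * pc
        dist = math.hypot(dx, dy)
        ang = math.degrees(math.atan2(dy, dx))
        peaks.append((dist, ang, (r_cm, c_cm)))
    peaks.sort(key=lambda p: (round(p[0], 9), p[1]))
    return peaks


def grid_scale(autocorr, pixel_cm: float | None = None) -> float:
    """Mean distance from the correlogram centre to the centres of mass of
    the six closest surrounding positive-r blobs, in cm."""
    peaks = autocorr_peaks(autocorr, pixel_cm)
    if len(peaks) < 6:
        raise GridUndefinedError(
            f"only {len(peaks)} surrounding autocorrelogram peaks (need 6)")
    return float(np.mean([p[0] for p in peaks[:6]]))


def grid_orientation(autocorr, pixel_cm: float | None = None) -> float:
    """Angle (deg, signed) of the grid axis nearest east, from the six inner
    autocorrelogram peaks."""
    peaks = autocorr_peaks(autocorr, pixel_cm)
    if len(peaks) < 6:
        raise GridUndefinedError("fewer than 6 autocorrelogram peaks")
    angs = np.array([p[1] for p in peaks[:6]])
    # fold axes into (-90, 90] and pick the one closest to east
    folded = (angs + 90.0) % 180.0 - 90.0
    return float(folded[np.argmin(np.abs(folded))])


def _odd_crop(arr: np.ndarray, center: tuple[int, int]):
    rad_r = min(center[0], arr.shape[0] - 1 - center[0])
    rad_c = min(center[1], arr.shape[1] - 1 - center[1])
    out = arr[center[0] - rad_r:center[0] + rad_r + 1,
              center[1] - rad_c:center[1] + rad_c + 1]
    return out, (rad_r, rad_c)


def gridness(autocorr, scale_cm: float, pixel_cm: float | None = None) -> float:
    """Rotational-symmetry score of the annulus-masked autocorrelogram:
    min(r60, r120) - max(r30, r90, r150)."""
    arr, center, pc = _corr_array(autocorr)
    if pixel_cm is not None:
        pc = pixel_cm
    arr, center = _odd_crop(arr, center)
    rows = (np.arange(arr.shape[0]) - center[0]) * pc
    cols = (np.arange(arr.shape[1]) - center[1]) * pc
    dist = np.hypot(rows[:, None], cols[None, :])
    annulus = (dist >= 0.5 * scale_cm) & (dist <= 1.5 * scale_cm)
    if not annulus.any():
        raise GridUndefinedError("empty gridness annulus")
    base = np.where(np.isfinite(arr), arr, np.nan)
    corrs = {}
    for ang in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(np.nan_to_num(base), ang, reshape=False, order=1,
                             mode="constant", cval=0.0)
        rot_ok = ndimage.rotate(np.isfinite(base).astype(float), ang,
                                reshape=False, order=1, mode="constant",
                                cval=0.0) > 0.99
        ok = annulus & np.isfinite(base) & rot_ok
        if ok.sum() < MIN_OVERLAP_PIXELS:
            raise GridUndefinedError("too few annulus pixels after rotation")
        x, y = base[ok], rot[ok]
        if x.std() < 1e-12 or y.std() < 1e-12:
            corrs[ang] = 0.0
        else:
            corrs[ang] = float(np.corrcoef(x, y)[0, 1])
    return min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])


def field_length(autocorr, dimension: str, pixel_cm: float | None = None) -> float:
    """Extent (cm) of the correlogram's central peak along ``'x'`` or ``'y'``:
    the span of the contiguous blob of pixels above 10% of the maximum."""
    arr, center, pc = _corr_array(autocorr)
    if pixel_cm is not None:
        pc = pixel_cm
    finite = np.isfinite(arr)
    if not finite.any():
        raise GridUndefinedError("empty correlogram")
    thresh = 0.1 * np.nanmax(arr)
    above = finite & (arr > thresh)
    labels = measure.label(above, connectivity=2)
    lab = labels[center]
    if lab == 0:
        raise GridUndefinedError("centre pixel below the 10% threshold")
    rr, cc = np.nonzero(labels == lab)
    if dimension in ("x", "ew", "col"):
        return float((cc.max() - cc.min()) * pc)
    if dimension in ("y", "ns", "row"):
        return float((rr.max() - rr.min()) * pc)
    raise ValueError("dimension must be 'x' or 'y'")


def firing_rates(rmap: RateMap, n_spikes: int, duration_s: float):
    """(peak_hz, mean_hz): max of the smoothed map over visited pixels, and
    total spikes / trial duration."""
    peak = float(np.nanmax(np.where(rmap.visited, rmap.rate, np.nan)))
    return peak, n_spikes / duration_s


def include_cell(gridness_familiar_trials) -> bool:
    """Inclusion rule: mean gridness across familiar trials strictly > 0.4.

    Accepts one or two values (a missing familiar trial falls back to the
    available one)."""
    vals = [g for g in np.atleast_1d(gridness_familiar_trials) if np.isfinite(g)]
    if not vals:
        raise ValueError("no gridness values supplied")
    return bool(np.mean(vals) > 0.4)
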