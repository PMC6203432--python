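"""Deformation statistics: boundary-conditioned rate maps with
occupancy-matched subsampling, grid shift, alignment tests, rescaling
factors, boundary-tethered rate-map prediction and population-vector
correlations.

Conventions: map arrays are indexed ``[row, col]`` (row 0 south); the
east-west dimension is ``"x"`` (columns), north-south is ``"y"`` (rows).
Boundary codes follow :mod:`bordergrid.arena` (N, S, E, W).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import arena
from .arena import E, N, S, W, EnvironmentGeometry, Trajectory, opposite_wall
from .metrics import (MIN_OVERLAP_PIXELS, Correlogram, RateMap, correlogram,
                      rate_map, rate_map_from_counts, smooth_map,
                      spike_sample_indices)

DIM_OF_WALL = {E: "x", W: "x", N: "y", S: "y"}
WALL_PAIRS = {"x": (E, W), "y": (N, S)}


# ------------------------------------------------------------ subsampling


def _pixel_ids(traj: Trajectory, env: EnvironmentGeometry) -> np.ndarray:
    row, col = env.pixel_of(traj.positions_cm)
    return row * env.raster_shape[1] + col


def _per_pixel_counts(pix: np.ndarray, mask: np.ndarray, n_pix: int) -> np.ndarray:
    return np.bincount(pix[mask], minlength=n_pix)


def _subsample_to_targets(pix: np.ndarray, mask: np.ndarray,
                          targets: np.ndarray, rng) -> np.ndarray:
    """Keep, per pixel, a uniform random subset of the masked samples of size
    ``targets[pixel]`` (without replacement).  Returns the reduced mask."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return mask.copy()
    p = pix[idx]
    order = np.lexsort((rng.random(len(idx)), p))
    p_sorted = p[order]
    # rank of each sample within its pixel group
    first = np.r_[True, p_sorted[1:] != p_sorted[:-1]]
    group_start = np.maximum.accumulate(np.where(first, np.arange(len(idx)), 0))
    rank = np.arange(len(idx)) - group_start
    keep_sorted = rank < targets[p_sorted]
    out = np.zeros_like(mask)
    out[idx[order[keep_sorted]]] = True
    return out


@dataclass
class BoundaryRateMaps:
    """One rate map per most-recently-contacted boundary (None if never
    contacted), plus the per-sample masks they were built from."""

    maps: dict
    masks: dict
    matched: bool = False


def boundary_sample_masks(labels: arena.BoundaryContactLabels) -> dict:
    lab = labels.labels
    return {b: lab == b for b in (N, S, E, W)}


def boundary_rate_maps(traj: Trajectory, spike_times_s, labels,
                       env: EnvironmentGeometry, matched: bool = False,
                       iterations: int = 100, seed=None) -> BoundaryRateMaps:
    """Split spiking by most recent boundary contact and build one rate map
    per boundary.  Samples before the first contact contribute to no map.

    With ``matched=True`` a single occupancy-matched draw is made per
    opposing pair (use :func:`matched_mask_pairs` to iterate draws; the
    shift/rescaling wrappers average statistics over ``iterations`` draws).
    """
    masks = boundary_sample_masks(labels)
    if matched:
        rng = np.random.default_rng(seed)
        pix = _pixel_ids(traj, env)
        n_pix = env.raster_shape[0] * env.raster_shape[1]
        for a, b in WALL_PAIRS.values():
            if masks[a].any() and masks[b].any():
                ca = _per_pixel_counts(pix, masks[a], n_pix)
                cb = _per_pixel_counts(pix, masks[b], n_pix)
                t = np.minimum(ca, cb)
                masks[a] = _subsample_to_targets(pix, masks[a], t, rng)
                masks[b] = _subsample_to_targets(pix, masks[b], t, rng)
    spike_samples = spike_sample_indices(traj, np.asarray(spike_times_s, float))
    maps = {}
    for b, m in masks.items():
        maps[b] = (rate_map(traj, None, env, sample_mask=m,
                            spike_samples=spike_samples)
                   if m.any() else None)
    return BoundaryRateMaps(maps=maps, masks=masks, matched=matched)


# -------------------------------------------------------------- grid shift


@dataclass
class ShiftResult:
    shift_cm: float
    shift_ratio: float          # shift / (scale / 2)
    peak_lag_px: tuple | None   # (drow, dcol)
    defined: bool = True


def grid_shift(map_a, map_b, scale_cm: float, dimension: str,
               pixel_cm: float = 2.5) -> ShiftResult:
    """Shift between two rate maps along one dimension.

    Cross-correlate at single-pixel lags within +-scale/2, partition positive
    correlations into 8-connected blobs, take the blob nearest the centre
    (minimum pixel distance), and read the |lag| of its maximum-r pixel along
    the dimension.  The ratio normalizes by the half-scale lag window.
    """
    from skimage import measure

    cg = correlogram(map_a, map_b, pixel_cm=pixel_cm)
    half = scale_cm / 2.0
    rows_cm, cols_cm = cg.lag_grids_cm()
    win = (np.abs(rows_cm)[:, None] <= half + 1e-9) & \
          (np.abs(cols_cm)[None, :] <= half + 1e-9)
    pos = win & cg.valid & (cg.r > 0)
    if not pos.any():
        return ShiftResult(np.nan, np.nan, None, defined=False)
    blobs = measure.label(pos, connectivity=2)
    rr, cc = np.nonzero(blobs > 0)
    d2 = (rr - cg.center[0]) ** 2 + (cc - cg.center[1]) ** 2
    nearest = blobs[rr[np.argmin(d2)], cc[np.argmin(d2)]]
    sel = blobs == nearest
    rvals = np.where(sel, cg.r, -np.inf)
    pr, pc = np.unravel_index(np.argmax(rvals), rvals.shape)
    drow = pr - cg.center[0]
    dcol = pc - cg.center[1]
    lag = dcol if dimension == "x" else drow
    shift = abs(lag) * pixel_cm
    return ShiftResult(shift_cm=shift, shift_ratio=shift / half,
                       peak_lag_px=(drow, dcol))


def grid_shift_matched(traj, spike_times_s, labels, env, scale_cm: float,
                       dimension: str, iterations: int = 100,
                       seed=None) -> ShiftResult:
    """Mean occupancy-matched shift over subsampling iterations (the final
    per-cell shift measure)."""
    rng = np.random.default_rng(seed)
    wa, wb = WALL_PAIRS[dimension]
    base = boundary_sample_masks(labels)
    if not (base[wa].any() and base[wb].any()):
        return ShiftResult(np.nan, np.nan, None, defined=False)
    pix = _pixel_ids(traj, env)
    n_pix = env.raster_shape[0] * env.raster_shape[1]
    ca = _per_pixel_counts(pix, base[wa], n_pix)
    cb = _per_pixel_counts(pix, base[wb], n_pix)
    t = np.minimum(ca, cb)
    spike_samples = spike_sample_indices(traj, np.asarray(spike_times_s, float))
    shifts = []
    for _ in range(iterations):
        ma = _subsample_to_targets(pix, base[wa], t, rng)
        mb = _subsample_to_targets(pix, base[wb], t, rng)
        rm_a = rate_map(traj, None, env, sample_mask=ma, spike_samples=spike_samples)
        rm_b = rate_map(traj, None, env, sample_mask=mb, spike_samples=spike_samples)
        res = grid_shift(rm_a, rm_b, scale_cm, dimension, pixel_cm=env.pixel_cm)
        if res.defined:
            shifts.append(res.shift_cm)
    if not shifts:
        return ShiftResult(np.nan, np.nan, None, defined=False)
    shift = float(np.mean(shifts))
    return ShiftResult(shift_cm=shift, shift_ratio=shift / (scale_cm / 2.0),
                       peak_lag_px=None)


# ----------------------------------------------------------- map resampling


def _map_array(m) -> np.ndarray:
    if isinstance(m, RateMap):
        return m.masked()
    return np.asarray(m, dtype=float)


def rescale_map(map_arr, dimension: str, new_px: int) -> np.ndarray:
    """Uniformly rescale a map along one dimension onto ``new_px`` pixels of
    unchanged pitch, by valid-weighted linear interpolation (NaNs stay NaN
    where no valid neighbour contributes)."""
    a = _map_array(map_arr)
    if dimension == "y":
        return rescale_map(a.T, "x", new_px).T
    old = a.shape[1]
    if new_px == old:
        return a.copy()
    x = (np.arange(new_px) + 0.5) * old / new_px - 0.5
    x0 = np.clip(np.floor(x).astype(int), 0, old - 1)
    x1 = np.clip(x0 + 1, 0, old - 1)
    f = np.clip(x - x0, 0.0, 1.0)
    v = np.nan_to_num(a)
    ok = np.isfinite(a).astype(float)
    num = v[:, x0] * (1 - f) + v[:, x1] * f
    den = ok[:, x0] * (1 - f) + ok[:, x1] * f
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 0.5] = np.nan
    return out


def overlap_r(a, b, min_overlap: int = MIN_OVERLAP_PIXELS) -> float:
    """Pearson r over mutually valid pixels of two equally-shaped maps."""
    a = _map_array(a)
    b = _map_array(b)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_overlap:
        return np.nan
    x, y = a[ok], b[ok]
    if x.std() < 1e-12 or y.std() < 1e-12:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _aligned_r(fam: np.ndarray, other: np.ndarray, dimension: str,
               anchor: str) -> float:
    """Correlation after registering the two maps at one edge of the
    dimension (``anchor``: 'start' = W/S edge, 'end' = E/N edge)."""
    if dimension == "y":
        return _aligned_r(fam.T, other.T, "x", anchor)
    k = min(fam.shape[1], other.shape[1])
    rows = min(fam.shape[0], other.shape[0])
    if anchor == "start":
        fa, ob = fam[:rows, :k], other[:rows, :k]
    else:
        fa, ob = fam[:rows, -k:], other[:rows, -k:]
    return overlap_r(fa, ob)


_ANCHOR_OF_WALL = {W: "start", S: "start", E: "end", N: "end"}


def alignment_test(boundary_map, familiar_map, boundary: int,
                   fam_len_cm: float, def_len_cm: float):
    """Is a boundary-conditioned deformed map more similar to the familiar
    map when registered at the conditioned boundary or at the opposite one?

    Returns ``(winner, r_corresponding, r_opposite)`` with winner in
    {'corresponding', 'opposite'}; exact ties go to 'corresponding'.
    """
    dim = DIM_OF_WALL[boundary]
    bm = _map_array(boundary_map)
    fm = _map_array(familiar_map)
    r_corr = _aligned_r(fm, bm, dim, _ANCHOR_OF_WALL[boundary])
    r_opp = _aligned_r(fm, bm, dim, _ANCHOR_OF_WALL[opposite_wall(boundary)])
    if np.isnan(r_corr) and np.isnan(r_opp):
        return ("undefined", r_corr, r_opp)
    winner = "opposite" if (np.nan_to_num(r_opp, nan=-2)
                            > np.nan_to_num(r_corr, nan=-2)) else "corresponding"
    return (winner, r_corr, r_opp)


# ------------------------------------------------------------- rescaling


@dataclass
class RescalingResult:
    factor: float               # best rescaled length / familiar length
    normalized_pct: float       # 0 = no rescaling, 100 = matches deformation
    best_len_cm: float
    best_r: float
    alignment: str              # anchor that won ('start'/'end')
    candidate_lens_cm: np.ndarray


def candidate_lengths(fam_len_cm: float, def_len_cm: float,
                      step_cm: float = 5.0, margin_cm: float = 10.0) -> np.ndarray:
    lo = min(fam_len_cm, def_len_cm) - margin_cm
    hi = max(fam_len_cm, def_len_cm) + margin_cm
    return np.arange(lo, hi + step_cm / 2.0, step_cm)


def rescaling_factor(familiar_map, deformed_map, fam_len_cm: float,
                     def_len_cm: float, dimension: str = "x",
                     alignments="both", pixel_cm: float = 2.5) -> RescalingResult:
    """Best-matching uniform rescaling of the familiar map.

    The familiar map is rescaled along the deformed dimension to candidate
    chamber lengths from 10 cm below the smaller through 10 cm above the
    larger length in 5 cm steps; at each, the correlation with the deformed
    map is taken under each permitted edge alignment.  ``alignments`` is
    'both' or a wall code fixing the anchor to that boundary.
    """
    fam = _map_array(familiar_map)
    dmap = _map_array(deformed_map)
    if alignments == "both":
        anchors = ["start", "end"]
    else:
        anchors = [_ANCHOR_OF_WALL[alignments]]
    cands = candidate_lengths(fam_len_cm, def_len_cm)
    best = (-np.inf, np.nan, "")
    for L in cands:
        npx = max(int(round(L / pixel_cm)), 1)
        resc = rescale_map(fam, dimension, npx)
        for anc in anchors:
            r = _aligned_r(resc, dmap, dimension, anc)
            if np.isfinite(r) and r > best[0]:
                best = (r, L, anc)
    if not np.isfinite(best[0]):
        return RescalingResult(np.nan, np.nan, np.nan, np.nan, "", cands)
    factor = best[1] / fam_len_cm
    if abs(def_len_cm - fam_len_cm) < 1e-9:
        norm = np.nan  # undefined for undeformed trials
    else:
        norm = (factor - 1.0) / (def_len_cm / fam_len_cm - 1.0) * 100.0
    return RescalingResult(factor=factor, normalized_pct=norm,
                           best_len_cm=best[1], best_r=best[0],
                           alignment=best[2], candidate_lens_cm=cands)


def boundary_conditioned_rescaling(traj, spike_times_s, labels,
                                   env_def: EnvironmentGeometry,
                                   familiar_map, fam_len_cm: float,
                                   def_len_cm: float, boundary: int,
                                   iterations: int = 100, seed=None):
    """Rescaling factor of one boundary-conditioned map (alignment fixed to
    the conditioned boundary) and of occupancy-matched whole-trial maps.

    The whole-trial comparator is the mean factor over ``iterations`` random
    subsets of the full data whose per-pixel sample counts match the boundary
    map's sampling distribution.
    """
    dim = DIM_OF_WALL[boundary]
    rng = np.random.default_rng(seed)
    masks = boundary_sample_masks(labels)
    bmask = masks[boundary]
    if not bmask.any():
        raise ValueError("conditioned boundary never contacted")
    spike_samples = spike_sample_indices(traj, np.asarray(spike_times_s, float))
    bmap = rate_map(traj, None, env_def, sample_mask=bmask,
                    spike_samples=spike_samples)
    bres = rescaling_factor(familiar_map, bmap, fam_len_cm, def_len_cm,
                            dimension=dim, alignments=boundary,
                            pixel_cm=env_def.pixel_cm)
    pix = _pixel_ids(traj, env_def)
    n_pix = env_def.raster_shape[0] * env_def.raster_shape[1]
    targets = _per_pixel_counts(pix, bmask, n_pix)
    whole_mask = labels.labels != arena.LABEL_NONE
    factors = []
    for _ in range(iterations):
        sub = _subsample_to_targets(pix, whole_mask, targets, rng)
        wmap = rate_map(traj, None, env_def, sample_mask=sub,
                        spike_samples=spike_samples)
        res = rescaling_factor(familiar_map, wmap, fam_len_cm, def_len_cm,
                               dimension=dim, alignments=boundary,
                               pixel_cm=env_def.pixel_cm)
        if np.isfinite(res.factor):
            factors.append(res.factor)
    whole_factor = float(np.mean(factors)) if factors else np.nan
    return bres.factor, whole_factor


# ------------------------------------------------- boundary-tethered prediction


def _anchored_copy(fam: np.ndarray, out_shape: tuple, boundary: int) -> np.ndarray:
    """Familiar map placed on the deformed raster, registered at the given
    boundary; the length-changed dimension uses a centred crop, the anchored
    dimension crops from the far side (compressions) or pads NaN (stretches).
    """
    rows_d, cols_d = out_shape
    out = np.full(out_shape, np.nan)
    dim = DIM_OF_WALL[boundary]

    def span(old: int, new: int, mode: str):
        # returns (src slice, dst slice)
        if mode == "center":
            if old >= new:
                o = (old - new) // 2
                return slice(o, o + new), slice(0, new)
            o = (new - old) // 2
            return slice(0, old), slice(o, o + old)
        k = min(old, new)
        if mode == "start":
            return slice(0, k), slice(0, k)
        return slice(old - k, old), slice(new - k, new)

    if dim == "x":
        anchor = "start" if boundary == W else "end"
        src_c, dst_c = span(fam.shape[1], cols_d, anchor)
        src_r, dst_r = span(fam.shape[0], rows_d, "center")
    else:
        anchor = "start" if boundary == S else "end"
        src_r, dst_r = span(fam.shape[0], rows_d, anchor)
        src_c, dst_c = span(fam.shape[1], cols_d, "center")
    out[dst_r, dst_c] = fam[src_r, src_c]
    return out


def predict_deformed_map(familiar_map, traj_def: Trajectory,
                         labels, env_fam: EnvironmentGeometry,
                         env_def: EnvironmentGeometry,
                         smooth: bool = True) -> RateMap:
    """Boundary-tethered prediction of a deformed-environment rate map.

    Each boundary contributes the familiar map registered at that boundary's
    deformed position (centred crop along a length-changed wall), weighted
    per pixel by the empirical probability of that boundary being the most
    recently contacted one; the weighted sum is then smoothed.  All pixels
    are retained (no visited-mask exclusion).
    """
    fam = _map_array(familiar_map)
    shape = env_def.raster_shape
    prob, counts, _ = arena.recency_bias_map(labels, traj_def, env_def)
    # pixels the rat never visited with a label take the trial-wide marginal,
    # so the prediction covers the full chamber (all pixels retained)
    tot = counts.sum(axis=(0, 1))
    marginal = tot / tot.sum() if tot.sum() > 0 else np.zeros(4)
    unseen = counts.sum(axis=2) == 0
    prob = prob.copy()
    prob[unseen] = marginal
    acc = np.zeros(shape)
    wsum = np.zeros(shape)
    for b in (N, S, E, W):
        wb = prob[:, :, b]
        if not np.nansum(wb) > 0:
            continue
        mb = _anchored_copy(fam, shape, b)
        w = np.nan_to_num(wb)
        contrib = np.where(np.isfinite(mb), mb, 0.0)
        acc += w * contrib
        wsum += w * np.isfinite(mb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(wsum > 0, acc, 0.0)
    if smooth:
        pred = smooth_map(pred, valid=np.ones(shape, dtype=bool))
    visited = np.ones(shape, dtype=bool)
    return RateMap(rate=pred, rate_raw=pred.copy(),
                   occupancy_s=np.nansum(counts, axis=2) * traj_def.dt_s,
                   visited=visited, pixel_cm=env_def.pixel_cm)


def matched_rescaling_map(familiar_map, env_def: EnvironmentGeometry) -> np.ndarray:
    """Familiar map uniformly rescaled to the deformed chamber dimensions
    (the comparator for the boundary-tethered prediction)."""
    fam = _map_array(familiar_map)
    rows_d, cols_d = env_def.raster_shape
    out = rescale_map(fam, "x", cols_d)
    out = rescale_map(out, "y", rows_d)
    return out


def prediction_similarity(recorded_map, predicted_map):
    """(r, Fisher z) between a recorded and a predicted map (z capped)."""
    r = overlap_r(recorded_map, predicted_map)
    if np.isnan(r):
        return np.nan, np.nan
    r_c = np.clip(r, -1 + 1e-10, 1 - 1e-10)
    return r, float(np.arctanh(r_c))


# --------------------------------------------------- population vectors


def population_vector_correlation(maps_familiar, maps_deformed,
                                  x_anchor: str = "start",
                                  y_anchor: str = "start"):
    """Per-pixel Pearson r across units between two map stacks.

    Stacks are (n_units, rows, cols) with identical unit ordering; they are
    registered edge-to-edge per dimension (``'start'``/``'end'``/``'center'``)
    before correlating.  Returns ``(r_map, column_means)`` where
    ``column_means`` averages r along each east-west column.
    """
    A = np.asarray([_map_array(m) for m in maps_familiar], dtype=float)
    B = np.asarray([_map_array(m) for m in maps_deformed], dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("unit sets differ")

    def sl(old, new, mode):
        k = min(old, new)
        if mode == "start":
            return slice(0, k), slice(0, k)
        if mode == "end":
            return slice(old - k, old), slice(new - k, new)
        oa, ob = (old - k) // 2, (new - k) // 2
        return slice(oa, oa + k), slice(ob, ob + k)

    ra, rb = sl(A.shape[1], B.shape[1], y_anchor)
    ca, cb = sl(A.shape[2], B.shape[2], x_anchor)
    A = A[:, ra, ca]
    B = B[:, rb, cb]
    n_u, rows, cols = A.shape
    r = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            x, y = A[:, i, j], B[:, i, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() < 1e-12 or ys.std() < 1e-12:
                continue
            r[i, j] = np.corrcoef(xs, ys)[0, 1]
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(r, axis=0)
    return r, col_means
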